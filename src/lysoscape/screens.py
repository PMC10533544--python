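"""Rule-based screens over annotation and alignment tables.

All inequality directions follow the source thresholds literally and
are centralised in :data:`THRESHOLDS` for auditability:

* AMG curation   — metabolic flag 'M', auxiliary score 1-3, viral
  context (structural/terminase/integrase) both upstream and
  downstream, category not in the exclusion list.
* CRISPR links   — spacer arrays with >= 3 spacers; hits with 100%
  spacer coverage and < 2 mismatches.
* homology links — bitscore > 50, e-value < 1e-3, identity > 70,
  alignment length > 2500 bp (all strict).
* family vote    — proteins with best-hit bitscore >= 50 vote; a family
  wins with >= 50% of all the provirus's proteins.
* recruitment    — e-value <= 1e-5, identity >= 95, alignment > 50 bp;
  a read counts once, for its best-bitscore virus; abundance is mapped
  reads per kb of viral genome per billion metagenome reads.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import pandas as pd

from .datamodel import AlignmentHit, ProvirusRecord, ViralGene

log = logging.getLogger("lysoscape")

THRESHOLDS = {
    "amg_score_range": (1, 3),            # inclusive
    "crispr_min_spacers": 3,
    "crispr_max_mismatches": 2,           # strict <
    "homology_min_bitscore": 50.0,        # strict >
    "homology_max_evalue": 1e-3,          # strict <
    "homology_min_identity": 70.0,        # strict >
    "homology_min_length": 2500,          # strict >
    "family_min_bitscore": 50.0,          # >=
    "family_min_fraction": 0.5,           # >=
    "recruit_max_evalue": 1e-5,           # <=
    "recruit_min_identity": 95.0,         # >=
    "recruit_min_length": 50,             # strict >
}

#: genes whose categories match these keywords are viral housekeeping,
#: not auxiliary metabolism
DEFAULT_AMG_EXCLUSIONS = ("DNA methylase", "nucleotide metabolism")

_CONTEXT_FLAGS = {"structural", "terminase", "integrase"}


@dataclass
class AMGRecord:
    gene_id: str
    provirus_id: str
    retained: bool
    rejection_reason: str  # flag | score | context | category | none
    category_label: str

    def __post_init__(self) -> None:
        if self.retained and self.rejection_reason != "none":
            raise ValueError("retained AMG with a rejection reason")


@dataclass
class HostLink:
    virus_id: str
    host_id: str
    evidence: str  # crispr | homology
    hit: AlignmentHit


@dataclass
class RecruitmentAbundance:
    virus_id: str
    metagenome_id: str
    mapped_reads: int
    virus_length_kb: float
    metagenome_reads: int

    @property
    def abundance(self) -> float:
        """Mapped reads per kb of viral genome per billion reads."""
        return self.mapped_reads / (
            self.virus_length_kb * self.metagenome_reads / 1e9
        )


# ---------------------------------------------------------------------------
# AMG curation
# ---------------------------------------------------------------------------

def curate_amgs(
    proviruses: Sequence[ProvirusRecord],
    exclusions: Sequence[str] = DEFAULT_AMG_EXCLUSIONS,
) -> List[AMGRecord]:
    """Screen candidate auxiliary metabolic genes.

    A gene is retained iff it has metabolic flag 'M', an auxiliary
    score of 1-3, at least one structural/terminase/integrase gene at a
    strictly smaller position index AND one at a strictly larger index,
    and its category does not match the exclusion keywords.  The first
    failing rule (in that order) is recorded as the rejection reason.
    """
    lo, hi = THRESHOLDS["amg_score_range"]
    records: List[AMGRecord] = []
    for pv in proviruses:
        genes = sorted(pv.genes, key=lambda g: g.position_index)
        context_idx = [
            g.position_index for g in genes if g.flags & _CONTEXT_FLAGS
        ]
        for g in genes:
            if g.metabolic_flag != "M":
                reason = "flag"
            elif g.auxiliary_score is None or not (lo <= g.auxiliary_score <= hi):
                reason = "score"
            elif not (
                any(i < g.position_index for i in context_idx)
                and any(i > g.position_index for i in context_idx)
            ):
                reason = "context"
            elif any(
                excl.lower() in (g.category_label or "").lower()
                for excl in exclusions
            ):
                reason = "category"
            else:
                reason = "none"
            records.append(
                AMGRecord(
                    gene_id=g.gene_id,
                    provirus_id=pv.provirus_id,
                    retained=reason == "none",
                    rejection_reason=reason,
                    category_label=g.category_label,
                )
            )
    return records


def amg_category_abundance(
    amg_records: Sequence[AMGRecord],
    group_of_provirus: Mapping[str, str],
    group_sizes: Mapping[str, int],
) -> pd.DataFrame:
    """Mean retained AMGs per viral genome, per (group, category).

    AMGs are deduplicated by gene_id before counting; the denominator
    is the number of viral genomes in the group.  Empty groups yield a
    missing abundance."""
    seen: Set[str] = set()
    counts: Dict[Tuple[str, str], int] = {}
    for rec in amg_records:
        if not rec.retained or rec.gene_id in seen:
            continue
        seen.add(rec.gene_id)
        group = group_of_provirus.get(rec.provirus_id)
        if group is None:
            continue
        counts[(group, rec.category_label)] = (
            counts.get((group, rec.category_label), 0) + 1
        )
    categories = sorted({c for _, c in counts})
    rows = []
    for group in sorted(group_sizes):
        n = group_sizes[group]
        for cat in categories:
            c = counts.get((group, cat), 0)
            rows.append(dict(
                group=group, category=cat, n_amgs=c,
                abundance=(c / n) if n else None,
            ))
    return pd.DataFrame(rows, columns=["group", "category", "n_amgs", "abundance"])


# ---------------------------------------------------------------------------
# host-evidence filters
# ---------------------------------------------------------------------------

def filter_crispr_links(
    hits: Sequence[AlignmentHit],
    spacer_lengths: Mapping[str, int],
    array_sizes: Mapping[str, int],
) -> List[HostLink]:
    """CRISPR-spacer host evidence.

    Spacers from arrays with < 3 spacers are discarded; a hit is
    retained iff its alignment length equals the spacer length (100%
    coverage) and it has < 2 mismatches.  The spacer query maps to the
    host; the subject is the virus."""
    links = []
    for h in hits:
        if array_sizes.get(h.query_id, 0) < THRESHOLDS["crispr_min_spacers"]:
            continue
        spacer_len = spacer_lengths.get(h.query_id)
        if spacer_len is None or h.aln_length != spacer_len:
            continue
        if h.mismatches >= THRESHOLDS["crispr_max_mismatches"]:
            continue
        links.append(HostLink(
            virus_id=h.subject_id, host_id=h.query_id, evidence="crispr", hit=h,
        ))
    return links


def filter_homology_links(hits: Sequence[AlignmentHit]) -> List[HostLink]:
    """Nucleotide-homology host evidence (virus query vs host genome):
    bitscore > 50, e-value < 1e-3, identity > 70%, length > 2500 bp."""
    links = []
    for h in hits:
        if (
            h.bitscore > THRESHOLDS["homology_min_bitscore"]
            and h.evalue < THRESHOLDS["homology_max_evalue"]
            and h.pct_identity > THRESHOLDS["homology_min_identity"]
            and h.aln_length > THRESHOLDS["homology_min_length"]
        ):
            links.append(HostLink(
                virus_id=h.query_id, host_id=h.subject_id,
                evidence="homology", hit=h,
            ))
    return links


# ---------------------------------------------------------------------------
# majority-rule family assignment
# ---------------------------------------------------------------------------

def assign_family_majority(
    protein_families: Mapping[str, Tuple[str, float]],
    n_proteins: int,
) -> Optional[str]:
    """Majority-rule viral family call for one provirus.

    ``protein_families`` maps protein id -> (best-hit family, bitscore);
    proteins with bitscore >= 50 vote for their family.  A family is
    assigned iff its votes reach >= 50% of ALL ``n_proteins`` of the
    provirus; otherwise None (unassigned)."""
    if n_proteins <= 0:
        return None
    votes: Dict[str, int] = {}
    for _, (family, bitscore) in protein_families.items():
        if bitscore >= THRESHOLDS["family_min_bitscore"]:
            votes[family] = votes.get(family, 0) + 1
    if not votes:
        return None
    n = max(votes.values())
    family = min(f for f, v in votes.items() if v == n)  # deterministic tie
    if n / n_proteins >= THRESHOLDS["family_min_fraction"]:
        return family
    return None


# ---------------------------------------------------------------------------
# read recruitment
# ---------------------------------------------------------------------------

def recruitment_abundance(
    hits: Sequence[AlignmentHit],
    virus_lengths_bp: Mapping[str, int],
    metagenome_reads: Mapping[str, int],
    metagenome_of_read: Optional[Mapping[str, str]] = None,
    metagenome_id: Optional[str] = None,
) -> List[RecruitmentAbundance]:
    """Recruitment abundances from read-vs-virus alignments.

    Hits are retained with e-value <= 1e-5, identity >= 95 and
    alignment length > 50 bp.  Each read is counted once, for its
    best-bitscore hit (ties broken by subject id).  Reads map to a
    metagenome via ``metagenome_of_read``, or all to ``metagenome_id``.
    """
    retained = [
        h for h in hits
        if h.evalue <= THRESHOLDS["recruit_max_evalue"]
        and h.pct_identity >= THRESHOLDS["recruit_min_identity"]
        and h.aln_length > THRESHOLDS["recruit_min_length"]
    ]
    best: Dict[str, AlignmentHit] = {}
    for h in retained:
        cur = best.get(h.query_id)
        if cur is None or (h.bitscore, cur.subject_id) > (cur.bitscore, h.subject_id):
            best[h.query_id] = h

    counts: Dict[Tuple[str, str], int] = {}
    for read, h in best.items():
        if metagenome_of_read is not None:
            mg = metagenome_of_read.get(read)
        else:
            mg = metagenome_id or "metagenome"
        if mg is None:
            continue
        counts[(h.subject_id, mg)] = counts.get((h.subject_id, mg), 0) + 1

    out = []
    for (virus, mg), n in sorted(counts.items()):
        length = virus_lengths_bp.get(virus)
        if length is None:
            raise ValueError(f"virus {virus}: no genome length provided")
        out.append(RecruitmentAbundance(
            virus_id=virus,
            metagenome_id=mg,
            mapped_reads=n,
            virus_length_kb=length / 1000.0,
            metagenome_reads=metagenome_reads[mg],
        ))
    return out


def abundance_table(records: Sequence[RecruitmentAbundance]) -> pd.DataFrame:
    return pd.DataFrame(
        [dict(virus_id=r.virus_id, metagenome_id=r.metagenome_id,
              mapped_reads=r.mapped_reads, virus_length_kb=r.virus_length_kb,
              metagenome_reads=r.metagenome_reads, abundance=r.abundance)
         for r in records],
        columns=["virus_id", "metagenome_id", "mapped_reads",
                 "virus_length_kb", "metagenome_reads", "abundance"],
    )
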