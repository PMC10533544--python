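"""Genomic features of (provirus-excised) host genomes.

Implements the feature set compared between lysogens and nonlysogens:
genome size, GC content, protein-coding density (PCD, predicted
proteins per kb), nitrogen/carbon atoms per residue side chain
(N-ARSC / C-ARSC) and relative codon frequencies — plus ocean depth-zone
classification and genome quality filtering.

Features of lysogens are computed on "pure" host genomes, i.e. after
the provirus intervals have been excised (:func:`excise_proviruses`).
"""
from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, replace
from typing import Dict, Iterable, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .datamodel import (
    GeneAnnotation,
    GenomeRecord,
    ProvirusRecord,
    SampleMetadata,
    TRNAAnnotation,
)

log = logging.getLogger("lysoscape")

#: nitrogen atoms in each amino-acid side chain
SIDE_CHAIN_N: Dict[str, int] = {
    "A": 0, "C": 0, "D": 0, "E": 0, "F": 0, "G": 0, "H": 2, "I": 0,
    "K": 1, "L": 0, "M": 0, "N": 1, "P": 0, "Q": 1, "R": 3, "S": 0,
    "T": 0, "V": 0, "W": 1, "Y": 0,
}

#: carbon atoms in each amino-acid side chain
SIDE_CHAIN_C: Dict[str, int] = {
    "G": 0,
    "A": 1, "S": 1, "C": 1,
    "T": 2, "D": 2, "N": 2,
    "V": 3, "P": 3, "M": 3, "E": 3, "Q": 3,
    "L": 4, "I": 4, "K": 4, "R": 4, "H": 4,
    "F": 7, "Y": 7,
    "W": 9,
}

#: the 64 codons in lexicographic (A<C<G<T) order
CODONS: Tuple[str, ...] = tuple(
    "".join(c) for c in itertools.product("ACGT", repeat=3)
)
CODON_INDEX: Dict[str, int] = {c: i for i, c in enumerate(CODONS)}

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class FeatureVector:
    """Per-genome feature summary.

    codon_freq is a 64-vector of relative frequencies (lexicographic
    codon order) summing to 1, or None if the genome has no CDS.
    """

    genome_id: str
    genome_size_bp: int
    gc: float
    pcd: float
    n_arsc: Optional[float]
    c_arsc: Optional[float]
    codon_freq: Optional[np.ndarray]


@dataclass
class ZoneCall:
    zone: Optional[str]  # epipelagic | mesopelagic | deep_sea
    aphotic: Optional[bool]
    hadal: Optional[bool]


# ---------------------------------------------------------------------------
# provirus excision
# ---------------------------------------------------------------------------

def _shift_annotation(ann, removed: List[Tuple[int, int]]):
    """Return the annotation shifted left past removed intervals, or
    None if it overlaps any removed interval by >= 1 bp."""
    shift = 0
    for s, e in removed:
        if ann.end >= s and ann.start <= e:
            return None
        if ann.start > e:
            shift += e - s + 1
    if shift == 0:
        return ann
    return replace(ann, start=ann.start - shift, end=ann.end - shift)


def excise_proviruses(
    genome: GenomeRecord, proviruses: Sequence[ProvirusRecord]
) -> GenomeRecord:
    """Remove provirus intervals from the genome; flanks are concatenated.

    CDS/tRNA annotations overlapping a removed interval by >= 1 bp are
    dropped; the coordinates of the remaining annotations are shifted
    consistently.  With an empty provirus list this is the identity.
    """
    by_contig: Dict[str, List[Tuple[int, int]]] = {}
    for pv in proviruses:
        if pv.host_genome_id != genome.genome_id:
            continue
        if pv.contig_id not in genome.contigs:
            raise ValueError(
                f"provirus {pv.provirus_id} on absent contig {pv.contig_id}"
            )
        by_contig.setdefault(pv.contig_id, []).append((pv.start, pv.end))

    new_contigs: Dict[str, str] = {}
    for cid, seq in genome.contigs.items():
        removed = sorted(by_contig.get(cid, []))
        if not removed:
            new_contigs[cid] = seq
            continue
        parts, cursor = [], 0
        for s, e in removed:
            parts.append(seq[cursor : s - 1])
            cursor = e
        parts.append(seq[cursor:])
        host_seq = "".join(parts)
        if host_seq:
            new_contigs[cid] = host_seq

    new_cds, new_trnas = [], []
    for ann in genome.cds:
        out = _shift_annotation(ann, sorted(by_contig.get(ann.contig_id, [])))
        if out is not None and out.contig_id in new_contigs:
            new_cds.append(out)
    for t in genome.trnas:
        out = _shift_annotation(t, sorted(by_contig.get(t.contig_id, [])))
        if out is not None and out.contig_id in new_contigs:
            new_trnas.append(out)

    return GenomeRecord(
        genome_id=genome.genome_id,
        contigs=new_contigs,
        completeness=genome.completeness,
        contamination=genome.contamination,
        taxonomy=genome.taxonomy,
        metadata=genome.metadata,
        cds=new_cds,
        trnas=new_trnas,
        mdt_hours=genome.mdt_hours,
    )


# ---------------------------------------------------------------------------
# feature computation
# ---------------------------------------------------------------------------

def gc_content(seq: str) -> float:
    """GC fraction over unambiguous bases (N excluded from numerator and
    denominator)."""
    gc = seq.count("G") + seq.count("C")
    acgt = gc + seq.count("A") + seq.count("T")
    return gc / acgt if acgt else float("nan")


def codon_counts(cds_nt_seqs: Iterable[str]) -> np.ndarray:
    """In-frame codon counts over CDS nucleotide sequences (64-vector;
    codons containing N are skipped)."""
    counts = np.zeros(64, dtype=np.int64)
    for seq in cds_nt_seqs:
        for i in range(0, len(seq) - len(seq) % 3, 3):
            idx = CODON_INDEX.get(seq[i : i + 3])
            if idx is not None:
                counts[idx] += 1
    return counts


def cds_nucleotide_seq(contig: str, ann: GeneAnnotation) -> str:
    sub = contig[ann.start - 1 : ann.end]
    return reverse_complement(sub) if ann.strand == "-" else sub


def arsc(proteins: Iterable[Optional[str]]) -> Tuple[Optional[float], Optional[float]]:
    """Mean side-chain N and C atoms per residue over a proteome.

    Residues outside the 20-letter alphabet (stops, X, ...) are skipped
    entirely: they contribute to neither numerator nor denominator.
    """
    n_tot = c_tot = residues = 0
    for prot in proteins:
        if not prot:
            continue
        for aa in prot:
            n = SIDE_CHAIN_N.get(aa)
            if n is None:
                continue
            n_tot += n
            c_tot += SIDE_CHAIN_C[aa]
            residues += 1
    if residues == 0:
        return None, None
    return n_tot / residues, c_tot / residues


def compute_features(genome: GenomeRecord) -> FeatureVector:
    """Compute the FeatureVector of a genome (excise proviruses first if
    host-only features are wanted)."""
    full_seq_gc_num = 0
    full_seq_acgt = 0
    for seq in genome.contigs.values():
        gc = seq.count("G") + seq.count("C")
        full_seq_gc_num += gc
        full_seq_acgt += gc + seq.count("A") + seq.count("T")
    gc = full_seq_gc_num / full_seq_acgt if full_seq_acgt else float("nan")

    size = genome.size_bp
    pcd = len(genome.cds) / (size / 1000.0) if size else 0.0

    if genome.cds:
        proteins = [a.protein_seq for a in genome.cds]
        if all(p is None for p in proteins):
            proteins = [
                _safe_translate(genome.contigs.get(a.contig_id, ""), a)
                for a in genome.cds
            ]
        n_arsc, c_arsc = arsc(proteins)
        counts = codon_counts(
            cds_nucleotide_seq(genome.contigs[a.contig_id], a)
            for a in genome.cds
        )
        total = counts.sum()
        codon_freq = counts / total if total else None
    else:
        n_arsc = c_arsc = None
        codon_freq = None

    return FeatureVector(
        genome_id=genome.genome_id,
        genome_size_bp=size,
        gc=gc,
        pcd=pcd,
        n_arsc=n_arsc,
        c_arsc=c_arsc,
        codon_freq=codon_freq,
    )


def _safe_translate(contig: str, ann: GeneAnnotation) -> Optional[str]:
    from .io import _translate

    try:
        return _translate(contig, ann)
    except Exception:
        return None


def features_table(features: Iterable[FeatureVector]) -> pd.DataFrame:
    """One row per genome; codon frequencies as 64 suffixed columns."""
    rows = []
    for fv in features:
        row = {
            "genome_id": fv.genome_id,
            "genome_size_bp": fv.genome_size_bp,
            "gc": fv.gc,
            "pcd": fv.pcd,
            "n_arsc": fv.n_arsc,
            "c_arsc": fv.c_arsc,
        }
        for i, codon in enumerate(CODONS):
            row[f"codon_{codon}"] = (
                fv.codon_freq[i] if fv.codon_freq is not None else None
            )
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# depth zones and quality
# ---------------------------------------------------------------------------

def classify_zone(
    metadata: Union[SampleMetadata, float, None]
) -> ZoneCall:
    """Ocean depth-zone call from sampling depth.

    Zones are half-open: epipelagic [0, 200), mesopelagic [200, 1000),
    deep sea [1000, inf).  Aphotic = depth >= 1000 m; hadal = depth >=
    6000 m.  Missing depth gives an all-missing call.
    """
    depth = metadata.depth_m if isinstance(metadata, SampleMetadata) else metadata
    if depth is None:
        return ZoneCall(zone=None, aphotic=None, hadal=None)
    if depth < 0:
        raise ValueError(f"negative depth {depth}")
    if depth < 200:
        zone = "epipelagic"
    elif depth < 1000:
        zone = "mesopelagic"
    else:
        zone = "deep_sea"
    return ZoneCall(zone=zone, aphotic=depth >= 1000, hadal=depth >= 6000)


def quality_filter(genomes: Iterable[GenomeRecord]) -> List[GenomeRecord]:
    """Retain genomes with completeness > 80 and contamination < 5
    (both strict).  Genomes with missing quality values are excluded
    with a logged warning."""
    kept = []
    for g in genomes:
        if g.completeness is None or g.contamination is None:
            log.warning(
                "genome %s: missing quality values; excluded", g.genome_id
            )
            continue
        if g.completeness > 80 and g.contamination < 5:
            kept.append(g)
    return kept
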