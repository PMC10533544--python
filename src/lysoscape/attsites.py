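"""Detection and analysis of provirus integration sites.

Site-specific integration duplicates a short host att core into exact
direct repeats (attL, attR) at the two provirus boundaries.  The
scanner enumerates maximal exact direct repeats with one copy starting
within a window (default 1000 bp) inside the left boundary and the
other copy ending within the same-sized window inside the right
boundary, keeps candidates of length [min_len, max_len] (default
12-145 bp), and selects the longest; ties are broken by the smallest
summed distance of attL start / attR end from the provirus boundaries,
then by leftmost position.

The observed att length range in marine proviruses extends down to
2 bp, but a 2-bp exact repeat inside two 1000-bp windows is a
guaranteed chance match; the default minimum of 12 bp favours
specificity and can be overridden down to 2 via ``min_len``.

Candidates are *maximal* matches clipped at the provirus boundaries:
extending a candidate by one base on either side (without leaving the
provirus) breaks the equality.  Nested sub-repeats are therefore not
enumerated separately.

Reconnecting the host sequence upstream of attL, one att core copy and
the host sequence downstream of attR reconstructs the empty
(pre-integration) locus exactly.
"""
from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .datamodel import (
    AttSite,
    GeneAnnotation,
    GenomeRecord,
    IntegrationLocus,
    ProvirusRecord,
    TRNAAnnotation,
)

log = logging.getLogger("lysoscape")

DEFAULT_WINDOW = 1000
DEFAULT_MIN_LEN = 12
DEFAULT_MAX_LEN = 145


def eligible_for_integration_analysis(
    provirus: ProvirusRecord, host: GenomeRecord, min_flank_orfs: int = 5
) -> bool:
    """True iff the host regions upstream and downstream of the provirus
    each contain >= ``min_flank_orfs`` CDS (viral CDS inside any
    provirus interval do not count)."""
    up = down = 0
    for ann in host.cds:
        if ann.contig_id != provirus.contig_id:
            continue
        if ann.end < provirus.start:
            up += 1
        elif ann.start > provirus.end:
            down += 1
    return up >= min_flank_orfs and down >= min_flank_orfs


def maximal_matches(
    a: str, b: str, min_len: int = 1
) -> List[Tuple[int, int, int]]:
    """Maximal exact common substrings between a and b.

    Returns (start_in_a, start_in_b, length) 0-based tuples, each the
    full run of equal characters along its diagonal (extension in either
    direction within the two strings breaks equality).
    """
    if not a or not b:
        return []
    arr_a = np.frombuffer(a.encode("ascii"), dtype=np.uint8)
    arr_b = np.frombuffer(b.encode("ascii"), dtype=np.uint8)
    out: List[Tuple[int, int, int]] = []
    # scan every diagonal; a run of equal chars of length L is one
    # maximal match
    for d in range(-(len(a) - 1), len(b)):
        if d >= 0:
            seg_a = arr_a[: len(b) - d]
            seg_b = arr_b[d:]
            off_a, off_b = 0, d
        else:
            seg_a = arr_a[-d:]
            seg_b = arr_b[: len(a) + d]
            off_a, off_b = -d, 0
        eq = seg_a == seg_b
        if not eq.any():
            continue
        # run boundaries
        padded = np.concatenate(([False], eq, [False]))
        diff = np.diff(padded.astype(np.int8))
        starts = np.flatnonzero(diff == 1)
        ends = np.flatnonzero(diff == -1)
        for s, e in zip(starts, ends):
            length = int(e - s)
            if length >= min_len:
                out.append((off_a + int(s), off_b + int(s), length))
    return out


def find_att(
    contig_seq: str,
    provirus_start: int,
    provirus_end: int,
    window: int = DEFAULT_WINDOW,
    min_len: int = DEFAULT_MIN_LEN,
    max_len: int = DEFAULT_MAX_LEN,
    provirus_id: str = "",
) -> Optional[AttSite]:
    """Scan for the attL/attR direct-repeat pair of one provirus.

    Coordinates are 1-based inclusive on the host contig.  For
    proviruses shorter than two windows the windows are truncated to
    non-overlap at the midpoint.  Returns None when no candidate
    passes the length bounds.
    """
    length = provirus_end - provirus_start + 1
    if length < 2:
        return None
    w = min(window, length // 2)
    if w < 1:
        return None

    # left region: copies must START in the first w bases of the
    # provirus but may extend up to max_len further; one extra base of
    # slack so a run longer than max_len is seen as such (and rejected)
    # rather than silently truncated at the region edge
    left_lo = provirus_start - 1  # 0-based
    left_hi = min(provirus_start - 1 + w + max_len, provirus_end)
    left = contig_seq[left_lo:left_hi]
    # right region: copies must END in the last w bases but may begin up
    # to max_len earlier (clipped at the provirus start)
    right_hi = provirus_end
    right_lo = max(provirus_end - w - max_len, provirus_start - 1)
    right = contig_seq[right_lo:right_hi]

    best = None
    for ia, ib, m_len in maximal_matches(left, right, min_len=min_len):
        if m_len > max_len:
            continue
        attL_start = left_lo + ia + 1  # back to 1-based
        attL_end = attL_start + m_len - 1
        attR_start = right_lo + ib + 1
        attR_end = attR_start + m_len - 1
        # copy 1 must start within the left window
        if attL_start - provirus_start >= w:
            continue
        # copy 2 must end within the right window
        if provirus_end - attR_end >= w:
            continue
        # the two copies must be distinct and ordered
        if attR_start <= attL_end:
            continue
        offset_sum = (attL_start - provirus_start) + (provirus_end - attR_end)
        key = (-m_len, offset_sum, attL_start, attR_start)
        if best is None or key < best[0]:
            best = (
                key,
                AttSite(
                    provirus_id=provirus_id,
                    attL_interval=(attL_start, attL_end),
                    attR_interval=(attR_start, attR_end),
                    length_bp=m_len,
                    core_seq=contig_seq[attL_start - 1 : attL_end],
                    boundary_offset_sum=offset_sum,
                ),
            )
    return best[1] if best else None


def reconstruct_locus(
    contig_seq: str,
    provirus_start: int,
    provirus_end: int,
    att: AttSite,
) -> str:
    """Empty-site reconstruction: host upstream of attL + one att core
    copy + host downstream of attR."""
    return (
        contig_seq[: att.attL_interval[0] - 1]
        + att.core_seq
        + contig_seq[att.attR_interval[1] :]
    )


def _overlaps(interval: Tuple[int, int], start: int, end: int) -> bool:
    return interval[0] <= end and interval[1] >= start


def classify_locus(
    att: AttSite,
    cds: Sequence[GeneAnnotation],
    trnas: Sequence[TRNAAnnotation],
    contig_id: Optional[str] = None,
) -> Tuple[str, Optional[str], Optional[str]]:
    """Classify the integration locus by what the att copies overlap:
    tRNA (takes precedence), protein-coding gene, else noncoding.

    Returns (locus_class, trna_isotype, gene_id)."""
    for t in trnas:
        if contig_id is not None and t.contig_id != contig_id:
            continue
        if _overlaps(att.attL_interval, t.start, t.end) or _overlaps(
            att.attR_interval, t.start, t.end
        ):
            return "tRNA", t.isotype, None
    for ann in cds:
        if contig_id is not None and ann.contig_id != contig_id:
            continue
        if _overlaps(att.attL_interval, ann.start, ann.end) or _overlaps(
            att.attR_interval, ann.start, ann.end
        ):
            return "protein_coding", None, ann.gene_id
    return "noncoding", None, None


def flank_genes(
    provirus: ProvirusRecord, host: GenomeRecord, n: int = 5
) -> List[GeneAnnotation]:
    """Up to n nearest host CDS on each side of the provirus."""
    up = [
        a for a in host.cds
        if a.contig_id == provirus.contig_id and a.end < provirus.start
    ]
    down = [
        a for a in host.cds
        if a.contig_id == provirus.contig_id and a.start > provirus.end
    ]
    up.sort(key=lambda a: a.end)
    down.sort(key=lambda a: a.start)
    return up[-n:] + down[:n]


def analyze_integration_sites(
    genomes: Sequence[GenomeRecord],
    proviruses: Sequence[ProvirusRecord],
    window: int = DEFAULT_WINDOW,
    min_len: int = DEFAULT_MIN_LEN,
    max_len: int = DEFAULT_MAX_LEN,
    min_flank_orfs: int = 5,
) -> Tuple[List[AttSite], List[IntegrationLocus], pd.DataFrame]:
    """Run the full integration-site stage.

    Only proviruses with >= ``min_flank_orfs`` host ORFs on each side
    are analysed.  Returns (att sites, classified loci, summary table
    with one row per analysed provirus)."""
    by_genome = {g.genome_id: g for g in genomes}
    atts: List[AttSite] = []
    loci: List[IntegrationLocus] = []
    rows = []
    for pv in proviruses:
        host = by_genome.get(pv.host_genome_id)
        if host is None or pv.contig_id not in host.contigs:
            continue
        if not eligible_for_integration_analysis(pv, host, min_flank_orfs):
            rows.append(dict(provirus_id=pv.provirus_id, eligible=False,
                             att_found=False, att_length=None,
                             locus_class=None, trna_isotype=None))
            continue
        seq = host.contigs[pv.contig_id]
        att = find_att(seq, pv.start, pv.end, window=window,
                       min_len=min_len, max_len=max_len,
                       provirus_id=pv.provirus_id)
        if att is None:
            rows.append(dict(provirus_id=pv.provirus_id, eligible=True,
                             att_found=False, att_length=None,
                             locus_class=None, trna_isotype=None))
            continue
        host_cds = [a for a in host.cds if a.contig_id == pv.contig_id]
        host_trnas = [t for t in host.trnas if t.contig_id == pv.contig_id]
        # viral features (inside the provirus) do not define the locus
        host_cds = [a for a in host_cds
                    if not (a.start > att.attL_interval[1]
                            and a.end < att.attR_interval[0])]
        host_trnas = [t for t in host_trnas
                      if not (t.start > att.attL_interval[1]
                              and t.end < att.attR_interval[0])]
        cls, isotype, gene_id = classify_locus(
            att, host_cds, host_trnas, contig_id=pv.contig_id
        )
        locus = IntegrationLocus(
            provirus_id=pv.provirus_id,
            reconstructed_seq=reconstruct_locus(seq, pv.start, pv.end, att),
            locus_class=cls,
            trna_isotype=isotype,
            gene_id=gene_id,
            flank_genes=flank_genes(pv, host),
        )
        atts.append(att)
        loci.append(locus)
        rows.append(dict(provirus_id=pv.provirus_id, eligible=True,
                         att_found=True, att_length=att.length_bp,
                         locus_class=cls, trna_isotype=isotype))
    return atts, loci, pd.DataFrame(
        rows, columns=["provirus_id", "eligible", "att_found", "att_length",
                       "locus_class", "trna_isotype"],
    )


def viral_trna_census(
    proviruses: Sequence[ProvirusRecord],
    genomes: Sequence[GenomeRecord],
) -> Counter:
    """Counts of tRNA isotypes encoded within provirus intervals."""
    by_genome = {g.genome_id: g for g in genomes}
    census: Counter = Counter()
    for pv in proviruses:
        host = by_genome.get(pv.host_genome_id)
        if host is None:
            continue
        for t in host.trnas:
            if t.contig_id == pv.contig_id and t.start >= pv.start and t.end <= pv.end:
                census[t.isotype] += 1
    return census


@dataclass
class HotspotSummary:
    class_fractions: Dict[str, float]
    trna_isotype_counts: Counter
    flank_category_counts: Counter
    n_loci: int


def hotspot_summary(
    loci: Sequence[IntegrationLocus], max_flank: int = 5
) -> HotspotSummary:
    """Tallies of locus classes, tRNA isotypes and flank-gene
    categories (<= ``max_flank`` genes per side are considered)."""
    n = len(loci)
    class_counts: Counter = Counter(l.locus_class for l in loci)
    isotypes: Counter = Counter(
        l.trna_isotype for l in loci if l.trna_isotype is not None
    )
    flank_cats: Counter = Counter()
    for l in loci:
        genes = l.flank_genes
        if len(genes) > 2 * max_flank:
            # keep the nearest max_flank genes per side (upstream genes
            # come first, nearest-last; downstream nearest-first)
            half = len(genes) // 2
            genes = genes[max(0, half - max_flank) : half + max_flank]
        for g in genes:
            if g.kegg_like_category:
                flank_cats[g.kegg_like_category] += 1
    fractions = {k: v / n for k, v in sorted(class_counts.items())} if n else {}
    return HotspotSummary(
        class_fractions=fractions,
        trna_isotype_counts=isotypes,
        flank_category_counts=flank_cats,
        n_loci=n,
    )
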