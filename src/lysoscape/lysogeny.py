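"""Lysogeny prevalence statistics.

A genome is a lysogen iff it carries at least one provirus.  The
lysogeny ratio (LyR) of a group is the fraction of its genomes that are
lysogens.  Polylysogeny (>= 2 distinct proviruses in one host) is
counted only over proviruses carrying a single-copy marker protein
(SCMP: TerL for tailed/unclassified viruses, Zot for Inovirales), so a
viral genome split across assembly contigs is not counted twice.

Group-size minima for reporting: genera need >= 5 genomes and classes
>= 20; smaller groups are emitted with the LyR flagged "suppressed"
rather than dropped, so tables stay auditable.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Dict, Iterable, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import GenomeRecord, ProvirusCategory, ProvirusRecord
from .features import classify_zone

log = logging.getLogger("lysoscape")

#: minimum group sizes per taxonomic rank for reporting a LyR
MIN_GROUP_SIZE = {"genus": 5, "class": 20}

#: fast growers have a predicted minimum doubling time below this (hours)
FAST_GROWER_MDT_H = 5.0


@dataclass
class LysogenySummary:
    group_key: str
    n_genomes: int
    n_lysogens: int
    lyr: float
    mean_proviruses_per_lysogen: Optional[float]
    n_polylysogens: int
    polylysogeny_ratio: Optional[float]
    suppressed: bool = False


@dataclass
class GrowthRecord:
    genome_id: str
    mdt_hours: float

    @property
    def fast_grower(self) -> bool:
        return self.mdt_hours < FAST_GROWER_MDT_H


def provirus_has_scmp(pv: ProvirusRecord) -> bool:
    """A provirus qualifies for polylysogeny counting iff it carries its
    category's single-copy marker: TerL for tailed/unclassified viruses,
    Zot for Inovirales."""
    if pv.category == ProvirusCategory.CAUDO_OR_UNCLASSIFIED:
        return any("terL" in g.flags for g in pv.genes)
    if pv.category == ProvirusCategory.INOVIRALES:
        return any("zot" in g.flags for g in pv.genes)
    return False


def scmp_provirus_count(
    host_proviruses: Sequence[ProvirusRecord],
) -> Tuple[int, bool]:
    """Number of SCMP-qualified proviruses in one host, and whether the
    host is a polylysogen (count >= 2)."""
    count = sum(1 for pv in host_proviruses if provirus_has_scmp(pv))
    return count, count >= 2


GroupFn = Callable[[GenomeRecord], Optional[str]]


def _grouping_fn(grouping: Union[str, GroupFn]) -> Tuple[GroupFn, Optional[str]]:
    """Resolve a grouping spec to (key function, rank for size minima).

    String specs: a taxonomy rank name ("class", "genus", ...),
    "environment", "zone", "environment_zone" or "all".
    """
    if callable(grouping):
        return grouping, None
    if grouping == "all":
        return (lambda g: "all"), None
    if grouping == "environment":
        return (lambda g: g.metadata.environment.value if g.metadata else None), None
    if grouping == "zone":
        return (lambda g: classify_zone(g.metadata).zone if g.metadata else None), None
    if grouping == "environment_zone":
        def env_zone(g: GenomeRecord) -> Optional[str]:
            if g.metadata is None:
                return None
            zone = classify_zone(g.metadata).zone
            if zone is None:
                return None  # missing depth: excluded from zone strata
            return f"{g.metadata.environment.value}:{zone}"
        return env_zone, None
    # taxonomy rank
    return (lambda g: g.taxonomy.get(grouping)), grouping


def lysogeny_summary(
    genomes: Sequence[GenomeRecord],
    proviruses: Sequence[ProvirusRecord],
    grouping: Union[str, GroupFn] = "all",
) -> List[LysogenySummary]:
    """Per-group lysogeny summaries.

    Groups smaller than the minimum for their taxonomic rank (genus < 5,
    class < 20 genomes) are emitted with ``suppressed=True``.  Genomes
    whose group key is missing (e.g. unlabelled rank, missing depth) are
    skipped.
    """
    key_fn, rank = _grouping_fn(grouping)
    min_size = MIN_GROUP_SIZE.get(rank or "", 0)

    pv_by_host: Dict[str, List[ProvirusRecord]] = {}
    for pv in proviruses:
        pv_by_host.setdefault(pv.host_genome_id, []).append(pv)

    groups: Dict[str, List[GenomeRecord]] = {}
    for g in genomes:
        key = key_fn(g)
        if key is None:
            continue
        groups.setdefault(key, []).append(g)

    out: List[LysogenySummary] = []
    for key in sorted(groups):
        members = groups[key]
        n = len(members)
        n_lys = 0
        n_pv = 0
        n_poly = 0
        for g in members:
            host_pvs = pv_by_host.get(g.genome_id, [])
            if host_pvs:
                n_lys += 1
                n_pv += len(host_pvs)
                _, poly = scmp_provirus_count(host_pvs)
                if poly:
                    n_poly += 1
        out.append(
            LysogenySummary(
                group_key=key,
                n_genomes=n,
                n_lysogens=n_lys,
                lyr=n_lys / n,
                mean_proviruses_per_lysogen=(n_pv / n_lys) if n_lys else None,
                n_polylysogens=n_poly,
                polylysogeny_ratio=(n_poly / n_lys) if n_lys else None,
                suppressed=n < min_size,
            )
        )
    return out


def summary_table(summaries: Iterable[LysogenySummary]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "group_key": s.group_key,
                "n_genomes": s.n_genomes,
                "n_lysogens": s.n_lysogens,
                "lyr": s.lyr if not s.suppressed else None,
                "mean_proviruses_per_lysogen": s.mean_proviruses_per_lysogen,
                "n_polylysogens": s.n_polylysogens,
                "polylysogeny_ratio": s.polylysogeny_ratio,
                "suppressed": s.suppressed,
            }
            for s in summaries
        ]
    )


def wilcoxon_rank_sum(
    sample_a: Sequence[float], sample_b: Sequence[float]
) -> Tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test (large-sample normal
    approximation, no continuity or tie correction)."""
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("rank-sum test requires two non-empty samples")
    stat, p = stats.ranksums(a, b)
    return float(stat), float(p)


def pearson_lyr_feature(
    genus_table: pd.DataFrame,
    feature_columns: Sequence[str],
    group_column: Optional[str] = None,
    lyr_column: str = "lyr",
    min_genera: int = 5,
    fdr: bool = False,
) -> pd.DataFrame:
    """Pearson correlation between genus-level LyR and per-genus median
    features, per (feature, group).

    Groups with fewer than ``min_genera`` genera, or zero variance in
    either variable, yield a missing r with the reason recorded.  Raw
    two-sided p-values are reported; set ``fdr=True`` for an additional
    Benjamini-Hochberg column.
    """
    if group_column is None:
        genus_table = genus_table.assign(_group="all")
        group_column = "_group"
    rows = []
    for group, sub in genus_table.groupby(group_column, sort=True):
        for feat in feature_columns:
            pair = sub[[lyr_column, feat]].dropna()
            n = len(pair)
            if n < min_genera:
                rows.append(dict(feature=feat, group=group, r=None, p=None,
                                 n=n, reason=f"n<{min_genera}"))
                continue
            x = pair[feat].to_numpy(dtype=float)
            y = pair[lyr_column].to_numpy(dtype=float)
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                rows.append(dict(feature=feat, group=group, r=None, p=None,
                                 n=n, reason="zero variance"))
                continue
            r, p = stats.pearsonr(x, y)
            rows.append(dict(feature=feat, group=group, r=float(r),
                             p=float(p), n=n, reason=None))
    out = pd.DataFrame(rows)
    if fdr and len(out):
        mask = out["p"].notna()
        q = np.full(len(out), np.nan)
        if mask.any():
            q[mask.to_numpy()] = stats.false_discovery_control(
                out.loc[mask, "p"].to_numpy()
            )
        out["q_bh"] = q
    return out


def fast_grower_fraction(
    records: Iterable[Union[GrowthRecord, GenomeRecord]],
) -> Optional[float]:
    """Fraction of genomes with MDT < 5 h; genomes with missing MDT are
    excluded from both numerator and denominator.  All-missing -> None."""
    mdts = []
    for r in records:
        mdt = r.mdt_hours if isinstance(r, (GrowthRecord, GenomeRecord)) else r
        if mdt is not None:
            mdts.append(mdt)
    if not mdts:
        return None
    return sum(1 for m in mdts if m < FAST_GROWER_MDT_H) / len(mdts)


def genus_lyr_table(
    genomes: Sequence[GenomeRecord],
    proviruses: Sequence[ProvirusRecord],
    feature_table: pd.DataFrame,
    feature_columns: Sequence[str],
    min_genomes: int = 5,
) -> pd.DataFrame:
    """Genus-level table of LyR and per-genus median features, for
    correlation analysis.  Genera with fewer than ``min_genomes``
    genomes are dropped (they are statistically unusable downstream)."""
    summaries = {
        s.group_key: s for s in lysogeny_summary(genomes, proviruses, "genus")
    }
    ft = feature_table.set_index("genome_id")
    rows = []
    genus_members: Dict[str, List[str]] = {}
    for g in genomes:
        genus = g.taxonomy.get("genus")
        if genus is not None:
            genus_members.setdefault(genus, []).append(g.genome_id)
    for genus in sorted(genus_members):
        members = genus_members[genus]
        if len(members) < min_genomes:
            continue
        row = {"genus": genus, "n_genomes": len(members),
               "lyr": summaries[genus].lyr}
        sub = ft.loc[[m for m in members if m in ft.index]]
        for feat in feature_columns:
            row[feat] = float(sub[feat].median()) if len(sub) else None
        rows.append(row)
    return pd.DataFrame(rows)
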