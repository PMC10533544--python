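"""Threshold clustering, dereplication and virus-host networks.

Clustering schemes are single-linkage connected components over pairs
passing ANI/coverage thresholds:

* host OTU  — ANI > 95 (strict) and coverage >= 60
* tvOTU     — ANI >= 95 and coverage >= 85 (species-level viral OTU)
* tVG       — identity >= 70, coverage ignored (viral genus)

The host-OTU identity bound is strict while the tvOTU bound is not;
this mirrors how the two rules are stated and the discrepancy is kept
deliberately (override via explicit thresholds if undesired).
Coverage is the alignment-length fraction of the shorter sequence.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple, Union

import networkx as nx
import pandas as pd

from .datamodel import GenomeRecord, InteractionEdge, ProvirusRecord
from .features import classify_zone
from .lysogeny import provirus_has_scmp

log = logging.getLogger("lysoscape")

#: (ani threshold, ani strict?, coverage threshold or None, coverage strict?)
SCHEMES: Dict[str, Tuple[float, bool, Optional[float], bool]] = {
    "host_OTU": (95.0, True, 60.0, False),
    "tvOTU": (95.0, False, 85.0, False),
    "tVG": (70.0, False, None, False),
}

#: per-environment display/enrichment minima for the infection network
TVC_MIN_GENOMES = {"seawater": 15, "sediment": 5}
GENUS_MIN_GENOMES = {"seawater": 20, "sediment": 5}

ZONES = ("epipelagic", "mesopelagic", "deep_sea")
ENVIRONMENTS = ("seawater", "sediment")


@dataclass
class SimilarityRecord:
    id_a: str
    id_b: str
    ani_pct: float
    coverage_pct: float = 100.0


@dataclass
class ClusterAssignment:
    scheme: str
    members: Dict[str, str]  # member_id -> cluster_id

    def cluster_of(self, member_id: str) -> str:
        return self.members[member_id]

    def clusters(self) -> Dict[str, List[str]]:
        out: Dict[str, List[str]] = {}
        for m, c in self.members.items():
            out.setdefault(c, []).append(m)
        return {c: sorted(ms) for c, ms in out.items()}


def read_similarity_table(path: Union[str, Path]) -> List[SimilarityRecord]:
    df = pd.read_csv(path, sep="\t")
    return [
        SimilarityRecord(
            id_a=str(r.id_a), id_b=str(r.id_b),
            ani_pct=float(r.ani_pct),
            coverage_pct=float(getattr(r, "coverage_pct", 100.0)),
        )
        for r in df.itertuples()
    ]


def threshold_cluster(
    similarities: Iterable[SimilarityRecord],
    members: Sequence[str],
    scheme: str = "tvOTU",
    id_thresh: Optional[float] = None,
    cov_thresh: Optional[float] = None,
    id_strict: Optional[bool] = None,
) -> ClusterAssignment:
    """Single-linkage clusters over pairs passing the scheme thresholds.

    ``members`` is the full roster; singletons become their own
    clusters.  A similarity row naming an unknown member is an error.
    Explicit ``id_thresh``/``cov_thresh`` override the scheme preset.
    """
    preset = SCHEMES.get(scheme)
    if preset is None and id_thresh is None:
        raise ValueError(f"unknown scheme {scheme!r} and no explicit thresholds")
    ani_t, ani_strict, cov_t, cov_strict = preset or (0.0, False, None, False)
    if id_thresh is not None:
        ani_t = id_thresh
    if id_strict is not None:
        ani_strict = id_strict
    if cov_thresh is not None:
        cov_t = cov_thresh

    roster = set(members)
    g = nx.Graph()
    g.add_nodes_from(members)
    for rec in similarities:
        for m in (rec.id_a, rec.id_b):
            if m not in roster:
                raise ValueError(f"similarity row references unknown member {m!r}")
        ani_ok = rec.ani_pct > ani_t if ani_strict else rec.ani_pct >= ani_t
        cov_ok = True
        if cov_t is not None:
            cov_ok = (rec.coverage_pct > cov_t if cov_strict
                      else rec.coverage_pct >= cov_t)
        if ani_ok and cov_ok:
            g.add_edge(rec.id_a, rec.id_b)

    assignment: Dict[str, str] = {}
    components = sorted(nx.connected_components(g), key=lambda c: min(c))
    for i, comp in enumerate(components, start=1):
        cid = f"{scheme}_{i:05d}"
        for m in comp:
            assignment[m] = cid
    return ClusterAssignment(scheme=scheme, members=assignment)


def dereplicate(
    assignment: ClusterAssignment, genomes: Sequence[GenomeRecord]
) -> List[GenomeRecord]:
    """Within each (cluster, sample) group keep one representative:
    highest completeness, then largest genome, then lexicographically
    smallest id.  Genomes absent from the assignment are kept."""
    groups: Dict[Tuple[str, str], List[GenomeRecord]] = {}
    passthrough: List[GenomeRecord] = []
    for g in genomes:
        cid = assignment.members.get(g.genome_id)
        if cid is None:
            passthrough.append(g)
            continue
        sample = g.metadata.sample_id if g.metadata else ""
        groups.setdefault((cid, sample), []).append(g)
    reps = [
        min(
            members,
            key=lambda g: (
                -(g.completeness if g.completeness is not None else -1),
                -g.size_bp,
                g.genome_id,
            ),
        )
        for members in groups.values()
    ]
    out = passthrough + reps
    return sorted(out, key=lambda g: g.genome_id)


# ---------------------------------------------------------------------------
# networks
# ---------------------------------------------------------------------------

def _genus_of(genomes: Sequence[GenomeRecord]) -> Dict[str, Optional[str]]:
    return {g.genome_id: g.taxonomy.get("genus") for g in genomes}


def infection_edges(
    proviruses: Sequence[ProvirusRecord],
    genomes: Sequence[GenomeRecord],
    environment: Optional[str] = None,
) -> Tuple[List[InteractionEdge], pd.DataFrame]:
    """tVC <-> host-genus infection edges.

    Edge weight = number of that tVC's proviruses found in genomes of
    that genus.  When ``environment`` is given, only hosts from that
    environment contribute and the enrichment flags use its display
    minima (tVC genome count >= 15 seawater / 5 sediment; genus genome
    count >= 20 seawater / 5 sediment).  Returns (edges, node table
    with enrichment flags).
    """
    genus_of = _genus_of(genomes)
    env_of = {
        g.genome_id: (g.metadata.environment.value if g.metadata else None)
        for g in genomes
    }
    genus_genomes: Dict[str, Set[str]] = {}
    for g in genomes:
        if environment is not None and env_of[g.genome_id] != environment:
            continue
        genus = genus_of[g.genome_id]
        if genus is not None:
            genus_genomes.setdefault(genus, set()).add(g.genome_id)

    weights: Dict[Tuple[str, str], int] = {}
    tvc_genomes: Dict[str, int] = {}
    skipped = 0
    for pv in proviruses:
        if environment is not None and env_of.get(pv.host_genome_id) != environment:
            continue
        if pv.tvc_id is None:
            skipped += 1
            continue
        tvc_genomes[pv.tvc_id] = tvc_genomes.get(pv.tvc_id, 0) + 1
        genus = genus_of.get(pv.host_genome_id)
        if genus is None:
            continue
        weights[(pv.tvc_id, genus)] = weights.get((pv.tvc_id, genus), 0) + 1
    if skipped:
        log.info("infection_edges: %d proviruses without tVC id excluded", skipped)

    edges = [
        InteractionEdge(node_a=tvc, node_b=genus, weight=w, edge_type="infection")
        for (tvc, genus), w in sorted(weights.items())
    ]

    tvc_min = TVC_MIN_GENOMES.get(environment or "", None)
    genus_min = GENUS_MIN_GENOMES.get(environment or "", None)
    node_rows = []
    for tvc, n in sorted(tvc_genomes.items()):
        node_rows.append(dict(
            node=tvc, node_type="tVC", n_genomes=n,
            enriched=(n >= tvc_min) if tvc_min is not None else None,
        ))
    for genus, members in sorted(genus_genomes.items()):
        node_rows.append(dict(
            node=genus, node_type="genus", n_genomes=len(members),
            enriched=(len(members) >= genus_min) if genus_min is not None else None,
        ))
    return edges, pd.DataFrame(
        node_rows, columns=["node", "node_type", "n_genomes", "enriched"]
    )


def host_range(
    proviruses: Sequence[ProvirusRecord],
    genomes: Sequence[GenomeRecord],
    cluster_attr: str = "tvc_id",
    ranks: Sequence[str] = ("genus", "class", "phylum"),
) -> pd.DataFrame:
    """Distinct host taxa per viral cluster at each rank, with
    multi-taxon flags (count >= 2).  Hosts missing a rank label are
    skipped for that rank."""
    tax_of = {g.genome_id: g.taxonomy for g in genomes}
    taxa: Dict[str, Dict[str, Set[str]]] = {}
    for pv in proviruses:
        cid = getattr(pv, cluster_attr)
        if cid is None:
            continue
        tax = tax_of.get(pv.host_genome_id)
        if tax is None:
            continue
        entry = taxa.setdefault(cid, {r: set() for r in ranks})
        for r in ranks:
            label = tax.get(r)
            if label is not None:
                entry[r].add(label)
    rows = []
    for cid in sorted(taxa):
        row = {"cluster_id": cid}
        for r in ranks:
            n = len(taxa[cid][r])
            row[f"host_range_{r}"] = n
            row[f"multi_{r}"] = n >= 2
        rows.append(row)
    return pd.DataFrame(rows)


def cosmopolitan_tvcs(
    proviruses: Sequence[ProvirusRecord],
    genomes: Sequence[GenomeRecord],
) -> Set[str]:
    """tVCs with >= 1 member provirus in each of the 6 groups
    {seawater, sediment} x {epipelagic, mesopelagic, deep_sea}.  Hosts
    with missing depth contribute to no group."""
    group_of: Dict[str, Optional[Tuple[str, str]]] = {}
    for g in genomes:
        if g.metadata is None:
            group_of[g.genome_id] = None
            continue
        zone = classify_zone(g.metadata).zone
        env = g.metadata.environment.value
        group_of[g.genome_id] = (env, zone) if zone and env in ENVIRONMENTS else None

    presence: Dict[str, Set[Tuple[str, str]]] = {}
    for pv in proviruses:
        if pv.tvc_id is None:
            continue
        grp = group_of.get(pv.host_genome_id)
        if grp is not None:
            presence.setdefault(pv.tvc_id, set()).add(grp)
    needed = {(e, z) for e in ENVIRONMENTS for z in ZONES}
    return {tvc for tvc, grps in presence.items() if grps >= needed}


def coinfection_edges(
    proviruses: Sequence[ProvirusRecord],
    genomes: Sequence[GenomeRecord],
) -> List[InteractionEdge]:
    """tVC <-> tVC coinfection edges: for each host, every unordered
    pair of distinct tVCs represented by >= 1 SCMP-bearing provirus
    increments the pair's weight by 1."""
    host_ids = {g.genome_id for g in genomes}
    tvcs_by_host: Dict[str, Set[str]] = {}
    for pv in proviruses:
        if pv.host_genome_id not in host_ids:
            continue
        if pv.tvc_id is None or not provirus_has_scmp(pv):
            continue
        tvcs_by_host.setdefault(pv.host_genome_id, set()).add(pv.tvc_id)
    weights: Dict[Tuple[str, str], int] = {}
    for host in sorted(tvcs_by_host):
        for a, b in combinations(sorted(tvcs_by_host[host]), 2):
            weights[(a, b)] = weights.get((a, b), 0) + 1
    return [
        InteractionEdge(node_a=a, node_b=b, weight=w, edge_type="coinfection")
        for (a, b), w in sorted(weights.items())
    ]


def edges_to_graph(
    edges: Sequence[InteractionEdge],
    node_table: Optional[pd.DataFrame] = None,
) -> nx.Graph:
    g = nx.Graph()
    if node_table is not None:
        for r in node_table.itertuples():
            g.add_node(r.node, node_type=r.node_type, size=int(r.n_genomes))
    for e in edges:
        g.add_edge(e.node_a, e.node_b, weight=e.weight, edge_type=e.edge_type)
    return g


def write_graphml(g: nx.Graph, path: Union[str, Path]) -> None:
    nx.write_graphml(g, str(path))


def edges_table(edges: Sequence[InteractionEdge]) -> pd.DataFrame:
    return pd.DataFrame(
        [dict(node_a=e.node_a, node_b=e.node_b, weight=e.weight,
              edge_type=e.edge_type) for e in edges],
        columns=["node_a", "node_b", "weight", "edge_type"],
    )
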