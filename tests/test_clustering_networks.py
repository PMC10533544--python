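"""Threshold clustering vs union-find oracle; dereplication; networks."""
import numpy as np
import pandas as pd
import pytest

from lysoscape.clustering import (
    ClusterAssignment,
    SimilarityRecord,
    coinfection_edges,
    cosmopolitan_tvcs,
    dereplicate,
    host_range,
    infection_edges,
    threshold_cluster,
)
from lysoscape.datamodel import (
    GenomeRecord,
    ProvirusRecord,
    SampleMetadata,
    TaxonomyLabel,
    ViralGene,
)


def _sim(a, b, ani, cov=100.0):
    return SimilarityRecord(id_a=a, id_b=b, ani_pct=ani, coverage_pct=cov)


class TestThresholdCluster:
    def test_tvotu_pair_within_thresholds(self):
        asg = threshold_cluster([_sim("a", "b", 96, 90)], ["a", "b"], "tvOTU")
        assert asg.cluster_of("a") == asg.cluster_of("b")

    def test_tvotu_pair_below_coverage(self):
        asg = threshold_cluster([_sim("a", "b", 96, 80)], ["a", "b"], "tvOTU")
        assert asg.cluster_of("a") != asg.cluster_of("b")

    def test_host_otu_identity_is_strict(self):
        asg = threshold_cluster([_sim("a", "b", 95.0, 90)], ["a", "b"],
                                "host_OTU")
        assert asg.cluster_of("a") != asg.cluster_of("b")
        asg = threshold_cluster([_sim("a", "b", 95.01, 90)], ["a", "b"],
                                "host_OTU")
        assert asg.cluster_of("a") == asg.cluster_of("b")

    def test_tvg_ignores_coverage(self):
        asg = threshold_cluster([_sim("a", "b", 70.0, 1.0)], ["a", "b"], "tVG")
        assert asg.cluster_of("a") == asg.cluster_of("b")

    def test_single_linkage_chain(self):
        sims = [_sim("a", "b", 96, 90), _sim("b", "c", 97, 95),
                _sim("a", "c", 60, 10)]
        asg = threshold_cluster(sims, ["a", "b", "c"], "tvOTU")
        assert len(set(asg.members.values())) == 1

    def test_singletons_form_own_clusters(self):
        asg = threshold_cluster([], ["a", "b", "c"], "tvOTU")
        assert len(set(asg.members.values())) == 3

    def test_unknown_member_is_error(self):
        with pytest.raises(ValueError, match="unknown member"):
            threshold_cluster([_sim("a", "zz", 99, 99)], ["a"], "tvOTU")

    def test_matches_union_find_oracle(self):
        """Single-linkage components equal a brute-force union-find
        over the filtered edge list on random instances."""
        rng = np.random.default_rng(17)
        for _ in range(25):
            n = int(rng.integers(5, 60))
            members = [f"m{i}" for i in range(n)]
            sims = []
            for _ in range(int(rng.integers(0, 3 * n))):
                i, j = rng.integers(0, n, size=2)
                if i == j:
                    continue
                sims.append(_sim(members[i], members[j],
                                 float(rng.uniform(60, 100)),
                                 float(rng.uniform(0, 100))))
            asg = threshold_cluster(sims, members, "tvOTU")

            # oracle: plain union-find
            parent = list(range(n))

            def find(x):
                while parent[x] != x:
                    parent[x] = parent[parent[x]]
                    x = parent[x]
                return x

            idx = {m: i for i, m in enumerate(members)}
            for s in sims:
                if s.ani_pct >= 95 and s.coverage_pct >= 85:
                    ra, rb = find(idx[s.id_a]), find(idx[s.id_b])
                    parent[ra] = rb
            for a in members:
                for b in members:
                    same_mine = asg.cluster_of(a) == asg.cluster_of(b)
                    same_oracle = find(idx[a]) == find(idx[b])
                    assert same_mine == same_oracle


def _genome(gid, sample="s1", completeness=95.0, size=400, genus="g1",
            clazz="c1", phylum="p1", env="seawater", depth=50.0):
    return GenomeRecord(
        genome_id=gid, contigs={f"{gid}_c1": "A" * size},
        completeness=completeness, contamination=1.0,
        taxonomy=TaxonomyLabel.from_values(
            domain="Bacteria", phylum=phylum, **{"class": clazz},
            order="o", family="f", genus=genus),
        metadata=SampleMetadata(sample_id=sample, environment=env,
                                depth_m=depth),
    )


def _pv(pid, host, tvc="X", flags=("terL",), category="caudo_or_unclassified"):
    genes = [ViralGene(gene_id=f"{pid}_g{i}", position_index=i, flags={f})
             for i, f in enumerate(flags, 1)]
    return ProvirusRecord(
        provirus_id=pid, host_genome_id=host, contig_id=f"{host}_c1",
        start=1, end=10, genes=genes, tvc_id=tvc, category=category,
    )


class TestDereplication:
    def test_highest_completeness_wins(self):
        g1 = _genome("a", completeness=95)
        g2 = _genome("b", completeness=90)
        asg = ClusterAssignment("host_OTU", {"a": "O1", "b": "O1"})
        assert [g.genome_id for g in dereplicate(asg, [g1, g2])] == ["a"]

    def test_different_samples_both_kept(self):
        g1 = _genome("a", sample="s1")
        g2 = _genome("b", sample="s2")
        asg = ClusterAssignment("host_OTU", {"a": "O1", "b": "O1"})
        assert len(dereplicate(asg, [g1, g2])) == 2

    def test_tie_breaks_to_lexicographic_id(self):
        g1 = _genome("zz", completeness=95, size=100)
        g2 = _genome("aa", completeness=95, size=100)
        asg = ClusterAssignment("host_OTU", {"zz": "O1", "aa": "O1"})
        assert [g.genome_id for g in dereplicate(asg, [g1, g2])] == ["aa"]

    def test_larger_genome_breaks_completeness_tie(self):
        g1 = _genome("a", completeness=95, size=100)
        g2 = _genome("b", completeness=95, size=200)
        asg = ClusterAssignment("host_OTU", {"a": "O1", "b": "O1"})
        assert [g.genome_id for g in dereplicate(asg, [g1, g2])] == ["b"]

    def test_never_removes_last_member_of_otu(self):
        rng = np.random.default_rng(3)
        genomes = [
            _genome(f"g{i}", sample=f"s{rng.integers(3)}",
                    completeness=float(rng.uniform(81, 100)))
            for i in range(30)
        ]
        members = {g.genome_id: f"O{rng.integers(8)}" for g in genomes}
        asg = ClusterAssignment("host_OTU", members)
        kept = dereplicate(asg, genomes)
        assert set(members.values()) == {members[g.genome_id] for g in kept}


class TestInfectionNetwork:
    def test_edge_weights_count_proviruses(self):
        genomes = [_genome("h1", genus="A"), _genome("h2", genus="A"),
                   _genome("h3", genus="B")]
        pvs = [_pv("p1", "h1"), _pv("p2", "h2"), _pv("p3", "h3")]
        edges, _ = infection_edges(pvs, genomes)
        w = {(e.node_a, e.node_b): e.weight for e in edges}
        assert w == {("X", "A"): 2, ("X", "B"): 1}

    def test_seawater_enrichment_threshold(self):
        genomes = [_genome(f"h{i}", genus="A") for i in range(30)]
        pvs = [_pv(f"p{i}", f"h{i}") for i in range(14)]
        _, nodes = infection_edges(pvs, genomes, environment="seawater")
        tvc_row = nodes[nodes["node"] == "X"].iloc[0]
        assert tvc_row["n_genomes"] == 14 and not tvc_row["enriched"]
        genus_row = nodes[nodes["node"] == "A"].iloc[0]
        assert genus_row["n_genomes"] == 30 and genus_row["enriched"]

    def test_sediment_thresholds_lower(self):
        genomes = [_genome(f"h{i}", genus="A", env="sediment")
                   for i in range(5)]
        pvs = [_pv(f"p{i}", f"h{i}") for i in range(5)]
        edges, nodes = infection_edges(pvs, genomes, environment="sediment")
        assert nodes[nodes["node"] == "X"].iloc[0]["enriched"]
        assert nodes[nodes["node"] == "A"].iloc[0]["enriched"]

    def test_weight_sum_equals_assigned_proviruses(self, small_parsed):
        genomes, proviruses = small_parsed
        edges, _ = infection_edges(proviruses, genomes)
        n_counted = sum(
            1 for pv in proviruses if pv.tvc_id is not None
        )
        assert sum(e.weight for e in edges) == n_counted

    def test_provirus_without_tvc_excluded(self):
        genomes = [_genome("h1", genus="A")]
        edges, _ = infection_edges([_pv("p1", "h1", tvc=None)], genomes)
        assert edges == []


class TestHostRange:
    def test_multi_class_flag(self):
        genomes = [_genome("h1", genus="g1", clazz="Gammaproteobacteria"),
                   _genome("h2", genus="g2", clazz="Bacilli")]
        pvs = [_pv("p1", "h1"), _pv("p2", "h2")]
        hr = host_range(pvs, genomes).set_index("cluster_id")
        assert hr.loc["X", "host_range_class"] == 2
        assert hr.loc["X", "multi_class"]
        assert not hr.loc["X", "multi_phylum"]

    def test_single_genus_no_flags(self):
        genomes = [_genome("h1"), _genome("h2")]
        pvs = [_pv("p1", "h1"), _pv("p2", "h2")]
        hr = host_range(pvs, genomes).set_index("cluster_id")
        assert hr.loc["X", "host_range_genus"] == 1
        assert not hr.loc["X", "multi_genus"]

    def test_multi_phylum_via_tvg(self):
        genomes = [_genome("h1", phylum="P1"), _genome("h2", phylum="P2")]
        pvs = [_pv("p1", "h1"), _pv("p2", "h2")]
        for pv in pvs:
            pv.tvg_id = "VG1"
        hr = host_range(pvs, genomes, cluster_attr="tvg_id")
        assert hr.set_index("cluster_id").loc["VG1", "multi_phylum"]


class TestCosmopolitan:
    def _genomes_for_groups(self, groups):
        depth = {"epipelagic": 50.0, "mesopelagic": 500.0, "deep_sea": 2000.0}
        return [
            _genome(f"h{i}", env=env, depth=depth[zone])
            for i, (env, zone) in enumerate(groups)
        ]

    def test_present_in_all_six_groups(self):
        groups = [(e, z) for e in ("seawater", "sediment")
                  for z in ("epipelagic", "mesopelagic", "deep_sea")]
        genomes = self._genomes_for_groups(groups)
        pvs = [_pv(f"p{i}", f"h{i}") for i in range(6)]
        assert cosmopolitan_tvcs(pvs, genomes) == {"X"}

    def test_five_of_six_not_cosmopolitan(self):
        groups = [(e, z) for e in ("seawater", "sediment")
                  for z in ("epipelagic", "mesopelagic", "deep_sea")][:5]
        genomes = self._genomes_for_groups(groups)
        pvs = [_pv(f"p{i}", f"h{i}") for i in range(5)]
        assert cosmopolitan_tvcs(pvs, genomes) == set()

    def test_missing_depth_contributes_nothing(self):
        groups = [(e, z) for e in ("seawater", "sediment")
                  for z in ("epipelagic", "mesopelagic", "deep_sea")][:5]
        genomes = self._genomes_for_groups(groups)
        extra = _genome("h5", env="sediment", depth=None)
        pvs = [_pv(f"p{i}", f"h{i}") for i in range(6)]
        assert cosmopolitan_tvcs(pvs, genomes + [extra]) == set()


class TestCoinfection:
    def test_two_scmp_tvcs_make_edge(self):
        genomes = [_genome("h1")]
        pvs = [_pv("p1", "h1", tvc="X"), _pv("p2", "h1", tvc="Y")]
        pvs[1].start, pvs[1].end = 20, 30
        edges = coinfection_edges(pvs, genomes)
        assert [(e.node_a, e.node_b, e.weight) for e in edges] == [("X", "Y", 1)]

    def test_non_scmp_provirus_excluded(self):
        genomes = [_genome("h1")]
        pvs = [_pv("p1", "h1", tvc="X"), _pv("p2", "h1", tvc="Y", flags=())]
        pvs[1].start, pvs[1].end = 20, 30
        assert coinfection_edges(pvs, genomes) == []

    def test_weight_accumulates_over_hosts(self):
        genomes = [_genome("h1"), _genome("h2")]
        pvs = []
        for h in ("h1", "h2"):
            a = _pv(f"{h}a", h, tvc="X")
            b = _pv(f"{h}b", h, tvc="Y")
            b.start, b.end = 20, 30
            pvs += [a, b]
        edges = coinfection_edges(pvs, genomes)
        assert edges[0].weight == 2
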