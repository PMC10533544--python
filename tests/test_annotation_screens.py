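"""AMG curation, host-evidence filters, family votes, recruitment."""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from lysoscape import io as lio
from lysoscape.datamodel import AlignmentHit, ProvirusRecord, ViralGene
from lysoscape.screens import (
    RecruitmentAbundance,
    amg_category_abundance,
    assign_family_majority,
    curate_amgs,
    filter_crispr_links,
    filter_homology_links,
    recruitment_abundance,
)


def _provirus(genes):
    return ProvirusRecord(
        provirus_id="pv", host_genome_id="G", contig_id="c",
        start=1, end=10_000, genes=genes,
    )


def _gene(idx, flags=(), metabolic=None, score=None, category=""):
    return ViralGene(
        gene_id=f"g{idx}", position_index=idx, flags=set(flags),
        metabolic_flag=metabolic, auxiliary_score=score,
        category_label=category,
    )


class TestAMGCuration:
    def _screen(self, target):
        genes = [
            _gene(1, flags={"integrase"}),
            target,
            _gene(3, flags={"structural"}),
        ]
        recs = curate_amgs([_provirus(genes)])
        return next(r for r in recs if r.gene_id == target.gene_id)

    def test_valid_candidate_retained(self):
        rec = self._screen(_gene(2, metabolic="M", score=2, category="CAZy"))
        assert rec.retained and rec.rejection_reason == "none"

    def test_score_above_three_rejected(self):
        rec = self._screen(_gene(2, metabolic="M", score=4, category="CAZy"))
        assert not rec.retained and rec.rejection_reason == "score"

    def test_context_only_upstream_rejected(self):
        genes = [
            _gene(1, flags={"integrase"}),
            _gene(2, metabolic="M", score=1, category="CAZy"),
        ]
        recs = curate_amgs([_provirus(genes)])
        rec = next(r for r in recs if r.gene_id == "g2")
        assert rec.rejection_reason == "context"

    def test_excluded_category_rejected(self):
        rec = self._screen(
            _gene(2, metabolic="M", score=1, category="DNA methylase")
        )
        assert rec.rejection_reason == "category"

    def test_non_metabolic_flag_rejected(self):
        rec = self._screen(_gene(2, metabolic=None, score=1, category="CAZy"))
        assert rec.rejection_reason == "flag"

    def test_reasons_partition_all_genes(self, small_parsed):
        _, proviruses = small_parsed
        recs = curate_amgs(proviruses)
        assert len(recs) == sum(len(pv.genes) for pv in proviruses)
        for r in recs:
            assert r.retained == (r.rejection_reason == "none")


class TestAMGAbundance:
    def _recs(self):
        from lysoscape.screens import AMGRecord
        return [
            AMGRecord(f"a{i}", f"pv{i}", True, "none", "CAZy")
            for i in range(6)
        ]

    def test_mean_per_genome(self):
        group_of = {f"pv{i}": "deep" for i in range(6)}
        out = amg_category_abundance(self._recs(), group_of, {"deep": 3})
        assert out.loc[0, "abundance"] == pytest.approx(2.0)

    def test_duplicate_gene_id_counted_once(self):
        from lysoscape.screens import AMGRecord
        recs = [AMGRecord("dup", "pv1", True, "none", "CAZy"),
                AMGRecord("dup", "pv2", True, "none", "CAZy")]
        out = amg_category_abundance(recs, {"pv1": "g", "pv2": "g"}, {"g": 2})
        assert out.loc[0, "n_amgs"] == 1

    def test_group_without_amgs_is_zero(self):
        group_of = {f"pv{i}": "deep" for i in range(6)}
        out = amg_category_abundance(
            self._recs(), group_of, {"deep": 3, "epi": 4}
        )
        epi = out[out["group"] == "epi"]
        assert (epi["abundance"] == 0.0).all()


def _hit(q="q", s="s", ident=97.0, length=100, mism=0, ev=1e-10, bits=100.0):
    return AlignmentHit(
        query_id=q, subject_id=s, pct_identity=ident, aln_length=length,
        mismatches=mism, gap_opens=0, qstart=1, qend=length, sstart=1,
        send=length, evalue=ev, bitscore=bits,
    )


class TestCrisprFilter:
    def test_full_length_one_mismatch_retained(self):
        hits = [_hit(q="sp1", length=32, mism=1)]
        links = filter_crispr_links(hits, {"sp1": 32}, {"sp1": 4})
        assert len(links) == 1 and links[0].evidence == "crispr"

    def test_partial_coverage_rejected(self):
        hits = [_hit(q="sp1", length=31, mism=0)]
        assert filter_crispr_links(hits, {"sp1": 32}, {"sp1": 4}) == []

    def test_two_mismatches_rejected(self):
        hits = [_hit(q="sp1", length=32, mism=2)]
        assert filter_crispr_links(hits, {"sp1": 32}, {"sp1": 4}) == []

    def test_small_array_discarded(self):
        hits = [_hit(q="sp1", length=32, mism=0)]
        assert filter_crispr_links(hits, {"sp1": 32}, {"sp1": 2}) == []


class TestHomologyFilter:
    def test_passing_hit(self):
        assert len(filter_homology_links(
            [_hit(ident=85, length=3000, ev=1e-5, bits=60)])) == 1

    @pytest.mark.parametrize("kw", [
        dict(length=2500),           # boundary: strict > 2500
        dict(ident=70.0),            # strict > 70
        dict(bits=50.0),             # strict > 50
        dict(ev=1e-3),               # strict < 1e-3
    ])
    def test_boundaries_are_strict(self, kw):
        base = dict(ident=85, length=3000, ev=1e-5, bits=60)
        base.update(kw)
        assert filter_homology_links([_hit(**base)]) == []


class TestFamilyMajority:
    def test_clear_majority(self):
        fams = {f"p{i}": ("Peduoviridae", 80.0) for i in range(6)}
        assert assign_family_majority(fams, 10) == "Peduoviridae"

    def test_exactly_half_is_assigned(self):
        fams = {f"p{i}": ("Kyanoviridae", 80.0) for i in range(5)}
        assert assign_family_majority(fams, 10) == "Kyanoviridae"

    def test_below_half_unassigned(self):
        fams = {f"p{i}": ("Kyanoviridae", 80.0) for i in range(4)}
        assert assign_family_majority(fams, 10) is None

    def test_low_bitscore_votes_ignored(self):
        fams = {f"p{i}": ("Kyanoviridae", 49.9) for i in range(9)}
        assert assign_family_majority(fams, 10) is None

    def test_zero_proteins_unassigned(self):
        assert assign_family_majority({}, 0) is None


class TestRecruitment:
    def test_worked_arithmetic(self):
        hits = [_hit(q=f"r{i}", s="v1", ident=97, length=100)
                for i in range(10)]
        (rec,) = recruitment_abundance(
            hits, {"v1": 5000}, {"m": 2_000_000_000}, metagenome_id="m"
        )
        assert rec.mapped_reads == 10
        assert rec.abundance == pytest.approx(1.0)

    def test_length_boundary_strict(self):
        hits = [_hit(q="r1", s="v1", length=50)]
        assert recruitment_abundance(hits, {"v1": 5000}, {"m": 10 ** 9},
                                     metagenome_id="m") == []

    def test_read_counted_once_per_virus(self):
        hits = [_hit(q="r1", s="v1", bits=100), _hit(q="r1", s="v1", bits=90)]
        (rec,) = recruitment_abundance(hits, {"v1": 5000}, {"m": 10 ** 9},
                                       metagenome_id="m")
        assert rec.mapped_reads == 1

    def test_multi_virus_read_goes_to_best_bitscore(self):
        hits = [_hit(q="r1", s="v1", bits=100), _hit(q="r1", s="v2", bits=150)]
        recs = recruitment_abundance(hits, {"v1": 5000, "v2": 5000},
                                     {"m": 10 ** 9}, metagenome_id="m")
        assert [r.virus_id for r in recs] == ["v2"]

    def test_missing_virus_length_is_error(self):
        with pytest.raises(ValueError, match="no genome length"):
            recruitment_abundance([_hit(s="vX")], {}, {"m": 10 ** 9},
                                  metagenome_id="m")

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        reads=st.integers(1, 10_000),
        length_kb=st.floats(1.0, 500.0),
        mg_reads=st.integers(10 ** 6, 10 ** 10),
    )
    def test_abundance_scaling_laws(self, reads, length_kb, mg_reads):
        """Abundance is linear in mapped reads and inversely linear in
        virus length and metagenome size."""
        base = RecruitmentAbundance("v", "m", reads, length_kb, mg_reads)
        double_reads = RecruitmentAbundance("v", "m", 2 * reads, length_kb,
                                            mg_reads)
        double_len = RecruitmentAbundance("v", "m", reads, 2 * length_kb,
                                          mg_reads)
        double_mg = RecruitmentAbundance("v", "m", reads, length_kb,
                                         2 * mg_reads)
        assert double_reads.abundance == pytest.approx(2 * base.abundance)
        assert double_len.abundance == pytest.approx(base.abundance / 2)
        assert double_mg.abundance == pytest.approx(base.abundance / 2)


class TestSimulatedFilterFidelity:
    """Every filter reproduces the simulator's recorded pass/fail
    status row for row."""

    def test_recruitment_rows(self, hit_tables):
        hits = lio.parse_hits(hit_tables.paths["recruit"])
        retained = recruitment_abundance(
            hits, hit_tables.virus_lengths_bp, hit_tables.metagenome_reads,
            metagenome_id="POV_epi",
        )
        n_kept = sum(r.mapped_reads for r in retained)
        assert n_kept == hit_tables.expected_pass["recruit"]

    def test_crispr_rows(self, hit_tables):
        hits = lio.parse_hits(hit_tables.paths["crispr"])
        links = filter_crispr_links(
            hits, hit_tables.spacer_lengths, hit_tables.array_sizes
        )
        kept = {l.host_id for l in links}
        for q, ok in hit_tables.row_truth["crispr"].items():
            assert (q in kept) == ok

    def test_homology_rows(self, hit_tables):
        hits = lio.parse_hits(hit_tables.paths["homology"])
        kept = {l.virus_id for l in filter_homology_links(hits)}
        for q, ok in hit_tables.row_truth["homology"].items():
            assert (q in kept) == ok
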