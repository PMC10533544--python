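"""att detection vs a brute-force enumeration oracle; locus analysis."""
import numpy as np
import pytest

from lysoscape.attsites import (
    analyze_integration_sites,
    classify_locus,
    eligible_for_integration_analysis,
    find_att,
    hotspot_summary,
    reconstruct_locus,
    viral_trna_census,
)
from lysoscape.datamodel import (
    AttSite,
    GeneAnnotation,
    GenomeRecord,
    IntegrationLocus,
    ProvirusRecord,
    TRNAAnnotation,
)


# ---------------------------------------------------------------------------
# oracle: enumerate every substring pair, apply the same selection rule
# ---------------------------------------------------------------------------

def oracle_find_att(seq, start, end, window, min_len, max_len):
    s0 = start - 1
    L = end - start + 1
    w = min(window, L // 2)
    best = None
    for i in range(s0, s0 + w):                       # attL start, 0-based
        for length in range(min_len, max_len + 1):
            if i + length > end:
                break
            sub = seq[i:i + length]
            for j_end in range(end - w + 1, end + 1):  # attR end, 1-based
                j = j_end - length                     # attR start, 0-based
                if j <= i + length - 1 or j < s0:
                    continue
                if seq[j:j_end] != sub:
                    continue
                # maximality within the provirus bounds
                if i - 1 >= s0 and j - 1 >= s0 and seq[i - 1] == seq[j - 1]:
                    continue
                if (i + length <= end - 1 and j_end <= end - 1
                        and seq[i + length] == seq[j_end]):
                    continue
                offset_sum = (i + 1 - start) + (end - j_end)
                key = (-length, offset_sum, i + 1, j + 1)
                if best is None or key < best[0]:
                    best = (key, (i + 1, i + length, j + 1, j_end, length))
    return best[1] if best else None


class TestFindAtt:
    def test_planted_repeat_detected(self):
        rng = np.random.default_rng(0)
        core = "ACGTACGTACGTACGTACGT"
        left = "".join(rng.choice(list("ACGT"), 300))
        mid = "".join(rng.choice(list("ACGT"), 2000))
        right = "".join(rng.choice(list("ACGT"), 300))
        seq = left + core + mid + core + right
        start = len(left) + 1
        end = len(left) + 2 * len(core) + len(mid)
        att = find_att(seq, start, end)
        assert att is not None
        assert att.length_bp == 20
        assert att.core_seq == core
        assert att.attL_interval == (start, start + 19)
        assert att.attR_interval == (end - 19, end)
        assert att.boundary_offset_sum == 0

    def test_longer_candidate_wins(self):
        # two planted repeat pairs, 15 bp and 9 bp
        rng = np.random.default_rng(1)
        r15 = "GATTACAGATTACAG"
        r9 = "CCCGGGTTT"
        fill = lambda n: "".join(rng.choice(list("ACGT"), n))
        seq = fill(50) + r15 + fill(20) + r9 + fill(800) + r9 + fill(30) + \
            r15 + fill(50)
        start, end = 51, len(seq) - 50
        att = find_att(seq, start, end, min_len=8)
        assert att is not None and att.length_bp == 15
        assert att.core_seq == r15

    def test_repeat_exceeding_max_len_rejected(self):
        rng = np.random.default_rng(2)
        core = "".join(rng.choice(list("ACGT"), 150))
        fill = lambda n: "".join(rng.choice(list("ACGT"), n))
        seq = fill(20) + core + fill(1500) + core + fill(20)
        start, end = 21, len(seq) - 20
        att = find_att(seq, start, end, min_len=12, max_len=145)
        # the 150-bp repeat is rejected; any survivor must be a shorter
        # chance repeat within bounds
        assert att is None or att.length_bp <= 145

    def test_no_candidate_returns_none(self):
        # a random provirus: no 12+ bp chance repeat between its windows
        rng = np.random.default_rng(5)
        seq = "".join(rng.choice(list("ACGT"), 1000))
        assert find_att(seq, 101, 900, min_len=12) is None

    def test_agrees_with_enumeration_oracle(self):
        """Exhaustive substring-pair enumeration on toy contigs returns
        the same selected repeat."""
        rng = np.random.default_rng(3)
        window, min_len, max_len = 60, 4, 50
        checked = 0
        for _ in range(40):
            # two-letter alphabet forces plenty of chance repeats
            seq = "".join(rng.choice(list("AC"), 420))
            start, end = 11, 410
            mine = find_att(seq, start, end, window=window,
                            min_len=min_len, max_len=max_len)
            theirs = oracle_find_att(seq, start, end, window, min_len, max_len)
            if theirs is None:
                assert mine is None
            else:
                assert mine is not None
                got = (mine.attL_interval[0], mine.attL_interval[1],
                       mine.attR_interval[0], mine.attR_interval[1],
                       mine.length_bp)
                assert got == theirs
                checked += 1
        assert checked > 10

    def test_short_provirus_windows_truncate_at_midpoint(self):
        # provirus of 40 bp: windows are 20 bp each; repeat across the
        # midpoint boundary must not be found twice
        seq = "T" * 10 + "ACGTACGTAC" + "G" * 20 + "ACGTACGTAC" + "T" * 10
        att = find_att(seq, 11, 50, window=1000, min_len=8)
        assert att is not None
        assert att.attL_interval == (11, 20)
        assert att.attR_interval == (41, 50)


class TestReconstruction:
    def test_reconstruction_removes_one_copy(self):
        seq = "AAAA" + "GC" + "TTTTTT" + "GC" + "CCCC"
        att = AttSite("pv", (5, 6), (13, 14), 2, "GC", 0)
        rec = reconstruct_locus(seq, 5, 14, att)
        assert rec == "AAAA" + "GC" + "CCCC"

    def test_ground_truth_reconstruction(self, small_truth, small_parsed):
        genomes, proviruses = small_parsed
        by_genome = {g.genome_id: g for g in genomes}
        assert proviruses
        for pv in proviruses:
            seq = by_genome[pv.host_genome_id].contigs[pv.contig_id]
            att = find_att(seq, pv.start, pv.end)
            assert att is not None, pv.provirus_id
            rec = reconstruct_locus(seq, pv.start, pv.end, att)
            assert rec == small_truth.expected_reconstruction(pv.provirus_id)


class TestEligibility:
    def _host(self, n_up, n_down, pv_start=1000, pv_end=2000):
        cds = [GeneAnnotation(f"u{i}", "c1", 10 * i + 1, 10 * i + 6)
               for i in range(n_up)]
        cds += [GeneAnnotation(f"d{i}", "c1", pv_end + 10 * i + 1,
                               pv_end + 10 * i + 6) for i in range(n_down)]
        g = GenomeRecord(genome_id="G", contigs={"c1": "A" * 4000}, cds=cds)
        pv = ProvirusRecord(provirus_id="pv", host_genome_id="G",
                            contig_id="c1", start=pv_start, end=pv_end)
        return pv, g

    def test_five_orfs_each_side_is_eligible(self):
        pv, g = self._host(6, 5)
        assert eligible_for_integration_analysis(pv, g)

    def test_four_downstream_is_ineligible(self):
        pv, g = self._host(5, 4)
        assert not eligible_for_integration_analysis(pv, g)

    def test_provirus_at_contig_start_ineligible(self):
        pv, g = self._host(0, 8, pv_start=1, pv_end=2000)
        assert not eligible_for_integration_analysis(pv, g)


class TestClassification:
    def test_trna_locus(self):
        att = AttSite("pv", (100, 119), (2100, 2119), 20, "A" * 20, 0)
        trnas = [TRNAAnnotation("c1", 90, 160, "+", "Leu")]
        assert classify_locus(att, [], trnas) == ("tRNA", "Leu", None)

    def test_trna_requires_overlap(self):
        att = AttSite("pv", (100, 119), (2100, 2119), 20, "A" * 20, 0)
        cds = [GeneAnnotation("gX", "c1", 80, 130)]
        trnas = [TRNAAnnotation("c1", 130 + 10, 130 + 80, "+", "Ser")]  # 10 bp away
        assert classify_locus(att, cds, trnas) == ("protein_coding", None, "gX")

    def test_noncoding(self):
        att = AttSite("pv", (100, 119), (2100, 2119), 20, "A" * 20, 0)
        assert classify_locus(att, [], []) == ("noncoding", None, None)

    def test_simulated_locus_classes_match_ground_truth(self, small_truth,
                                                        small_parsed):
        genomes, proviruses = small_parsed
        _, loci, table = analyze_integration_sites(genomes, proviruses)
        truth_cls = {p.provirus_id: p.locus_class
                     for p in small_truth.proviruses}
        analysed = table[table["att_found"].fillna(False)]
        assert len(analysed) > 0
        for row in analysed.itertuples():
            assert row.locus_class == truth_cls[row.provirus_id]


class TestCensusAndHotspots:
    def test_viral_trna_census(self, small_truth, small_parsed):
        genomes, proviruses = small_parsed
        census = viral_trna_census(proviruses, genomes)
        # oracle: count tRNA GFF features inside provirus intervals
        expected = {}
        by_genome = {g.genome_id: g for g in genomes}
        for pv in proviruses:
            for t in by_genome[pv.host_genome_id].trnas:
                if (t.contig_id == pv.contig_id and t.start >= pv.start
                        and t.end <= pv.end):
                    expected[t.isotype] = expected.get(t.isotype, 0) + 1
        assert dict(census) == expected

    def test_census_handles_und_and_empty(self):
        g = GenomeRecord(
            genome_id="G", contigs={"c1": "A" * 500},
            trnas=[TRNAAnnotation("c1", 100, 170, "+", "Und")],
        )
        pv = ProvirusRecord(provirus_id="pv", host_genome_id="G",
                            contig_id="c1", start=50, end=300)
        assert dict(viral_trna_census([pv], [g])) == {"Und": 1}
        assert dict(viral_trna_census([], [g])) == {}

    def test_hotspot_fractions(self):
        loci = (
            [IntegrationLocus("p", "X", "protein_coding", gene_id="g")] * 4
            + [IntegrationLocus("p", "X", "tRNA", trna_isotype="Leu")] * 2
            + [IntegrationLocus("p", "X", "noncoding")] * 4
        )
        s = hotspot_summary(loci)
        assert s.class_fractions == {
            "noncoding": 0.4, "protein_coding": 0.4, "tRNA": 0.2
        }
        assert s.trna_isotype_counts["Leu"] == 2

    def test_flank_truncated_to_nearest_five(self):
        genes = [GeneAnnotation(f"u{i}", "c", 100 * i + 1, 100 * i + 50,
                                kegg_like_category="up")
                 for i in range(7)]
        genes += [GeneAnnotation(f"d{i}", "c", 10_000 + 100 * i, 10_000 + 100 * i + 50,
                                 kegg_like_category="down")
                  for i in range(7)]
        locus = IntegrationLocus("p", "X", "noncoding", flank_genes=genes)
        s = hotspot_summary([locus])
        assert s.flank_category_counts == {"up": 5, "down": 5}

    def test_empty_locus_set(self):
        s = hotspot_summary([])
        assert s.class_fractions == {} and s.n_loci == 0
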