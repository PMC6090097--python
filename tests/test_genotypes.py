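"""Allele-frequency genotypes, VCF I/O and marker/sample filters."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import tetrags as tg
from tetrags.genotypes import FilterConfig


def _depth_matrix():
    ref = np.array([[6, 0, 0], [3, 5, 2]])
    alt = np.array([[2, 9, 0], [1, 0, 6]])
    return tg.AlleleDepthMatrix(["A", "B"], ["1:10:A:C", "1:20:G:T", "2:5:C:A"],
                                ref, alt)


class TestAlleleFrequencies:
    def test_direct_ratio_and_missing(self):
        af = tg.compute_allele_frequencies(_depth_matrix())
        assert af.af[0, 0] == pytest.approx(0.25)   # (6, 2)
        assert af.af[0, 1] == pytest.approx(1.0)    # (0, 9)
        assert np.isnan(af.af[0, 2])                # (0, 0) -> missing
        assert af.depth[0, 2] == 0

    def test_missing_iff_zero_depth(self):
        af = tg.compute_allele_frequencies(_depth_matrix())
        assert np.array_equal(np.isnan(af.af), af.depth == 0)


class TestVCFRoundTrip:
    def test_round_trip_preserves_depths(self, tmp_path):
        adm = _depth_matrix()
        path = tmp_path / "toy.vcf"
        tg.write_vcf_allele_depths(adm, path)
        back = tg.read_vcf_allele_depths(path)
        assert back.sample_ids == adm.sample_ids
        assert back.locus_ids == adm.locus_ids
        assert np.array_equal(back.ref_depth, adm.ref_depth)
        assert np.array_equal(back.alt_depth, adm.alt_depth)

    def test_missing_ad_reads_as_zero_depth(self, tmp_path):
        path = tmp_path / "m.vcf"
        path.write_text(
            "##fileformat=VCFv4.2\n##contig=<ID=1>\n"
            '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="AD">\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\tS2\n"
            "1\t10\t.\tA\tC\t.\t.\t.\tAD\t.\t6,2\n")
        adm = tg.read_vcf_allele_depths(path)
        assert adm.ref_depth[0, 0] == 0 and adm.alt_depth[0, 0] == 0
        assert adm.ref_depth[1, 0] == 6 and adm.alt_depth[1, 0] == 2

    def test_multiallelic_handling(self, tmp_path):
        path = tmp_path / "multi.vcf"
        path.write_text(
            "##fileformat=VCFv4.2\n##contig=<ID=1>\n"
            '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="AD">\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\n"
            "1\t10\t.\tA\tC,G\t.\t.\t.\tAD\t4,2,1\n"
            "1\t20\t.\tG\tT\t.\t.\t.\tAD\t5,5\n")
        with pytest.raises(ValueError, match="multiallelic"):
            tg.read_vcf_allele_depths(path)
        adm = tg.read_vcf_allele_depths(path, on_multiallelic="skip")
        assert adm.locus_ids == ["1:20:G:T"]


class TestFilterMarkers:
    def test_survivors_match_hand_application(self, toy_af):
        """Brute-force oracle: apply the four rules by hand on the toy
        matrix (see the fixture docstring for the per-locus design)."""
        out, report = tg.filter_markers(toy_af)
        assert out.locus_ids == ["1:1:A:C", "1:6:A:C"]
        assert out.sample_ids == toy_af.sample_ids
        by_rule = {s["rule"]: s["removed"] for s in report.steps}
        assert by_rule == {"coverage": 2, "maf": 1,
                           "marker_missingness": 1, "sample_missingness": 0}

    def test_high_frequency_locus_removed_by_maf(self, toy_af):
        out, _ = tg.filter_markers(toy_af)
        assert "1:2:A:C" not in out.locus_ids  # mean AF 0.995 > 0.99

    def test_permissive_config_is_identity(self, toy_af):
        cfg = FilterConfig(maf_min=0.0, coverage_min=0.0, coverage_max=np.inf,
                           marker_missing_max=1.0, sample_missing_max=1.0)
        out, report = tg.filter_markers(toy_af, cfg)
        assert out.locus_ids == toy_af.locus_ids
        assert out.sample_ids == toy_af.sample_ids
        np.testing.assert_array_equal(out.af, toy_af.af)
        assert report.removed("loci") == 0 and report.removed("samples") == 0

    def test_idempotent(self, toy_af):
        once, _ = tg.filter_markers(toy_af)
        twice, _ = tg.filter_markers(once)
        assert twice.locus_ids == once.locus_ids
        assert twice.sample_ids == once.sample_ids
        np.testing.assert_array_equal(twice.af, once.af)

    def test_surviving_values_unaltered(self, toy_af):
        out, _ = tg.filter_markers(toy_af)
        for j, lid in enumerate(out.locus_ids):
            col = toy_af.locus_ids.index(lid)
            np.testing.assert_array_equal(out.af[:, j], toy_af.af[:, col])

    def test_report_reconciles(self, toy_af):
        out, rep = tg.filter_markers(toy_af)
        assert rep.n_input_loci - rep.removed("loci") == rep.n_output_loci == out.n_loci
        assert (rep.n_input_samples - rep.removed("samples")
                == rep.n_output_samples == out.n_samples)

    def test_empty_result_is_an_error(self, toy_af):
        cfg = FilterConfig(coverage_min=1000.0, coverage_max=2000.0)
        with pytest.raises(ValueError, match="survive"):
            tg.filter_markers(toy_af, cfg)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_idempotence_property_on_random_matrices(self, seed):
        rng = np.random.default_rng(seed)
        n, L = rng.integers(3, 8), rng.integers(2, 12)
        depth = rng.poisson(8, size=(n, L))
        alt = rng.binomial(depth, rng.uniform(0, 1, size=(n, L)))
        adm = tg.AlleleDepthMatrix([f"S{i}" for i in range(n)],
                                   [f"1:{k+1}:A:C" for k in range(L)],
                                   depth - alt, alt)
        af = tg.compute_allele_frequencies(adm)
        cfg = FilterConfig(coverage_min=0.0, coverage_max=np.inf,
                           maf_min=0.01, marker_missing_max=0.6,
                           sample_missing_max=0.8)
        try:
            once, _ = tg.filter_markers(af, cfg)
        except ValueError:
            return  # everything filtered away: nothing to check
        twice, _ = tg.filter_markers(once, cfg)
        assert twice.locus_ids == once.locus_ids
        assert twice.sample_ids == once.sample_ids


class TestStringentSet:
    def test_complete_matrix_unchanged(self, toy_af):
        complete = toy_af.take_loci([0, 5])
        out, _ = tg.stringent_marker_set(complete)
        assert out.locus_ids == complete.locus_ids
        assert out.sample_ids == complete.sample_ids

    def test_one_percent_rule(self):
        af = np.full((100, 2), 0.5)
        af[:2, 1] = np.nan   # 2% missing
        m = tg.AlleleFrequencyMatrix([f"S{i}" for i in range(100)],
                                     ["1:1:A:C", "1:2:A:C"], af,
                                     np.where(np.isnan(af), 0, 10).astype(int))
        out, _ = tg.stringent_marker_set(m)
        assert out.locus_ids == ["1:1:A:C"]

    def test_sample_rule_on_surviving_loci(self, toy_af):
        # after dropping loci >1% missing, S0..S2 lose nothing; every sample
        # has complete data on the survivors and is retained
        out, rep = tg.stringent_marker_set(toy_af)
        assert out.locus_ids == ["1:1:A:C", "1:2:A:C", "1:5:A:C", "1:6:A:C"]
        assert out.n_samples == 4
        assert rep.n_output_loci == 4


class TestRandomMarkerSet:
    def _af(self, L=100, n=5):
        vals = np.random.default_rng(0).uniform(0.1, 0.9, size=(n, L))
        return tg.AlleleFrequencyMatrix([f"S{i}" for i in range(n)],
                                        [f"1:{k+1}:A:C" for k in range(L)],
                                        vals, np.full((n, L), 10))

    def test_all_loci_is_set_equal(self):
        af = self._af()
        out = tg.random_marker_set(af, af.n_loci, seed=1)
        assert set(out.locus_ids) == set(af.locus_ids)

    def test_deterministic_per_seed(self):
        af = self._af()
        a = tg.random_marker_set(af, 30, seed=9)
        b = tg.random_marker_set(af, 30, seed=9)
        assert a.locus_ids == b.locus_ids

    def test_pairwise_overlap_matches_hypergeometric_expectation(self):
        # two independent 50-of-100 draws overlap 25 in expectation
        af = self._af()
        sets = [set(tg.random_marker_set(af, 50, seed=s).locus_ids)
                for s in range(10)]
        overlaps = [len(a & b) for i, a in enumerate(sets)
                    for b in sets[i + 1:]]
        assert abs(np.mean(overlaps) - 25) < 3

    def test_too_many_markers_rejected(self):
        with pytest.raises(ValueError):
            tg.random_marker_set(self._af(), 101, seed=0)


class TestSubsampleIndividuals:
    def _af(self):
        vals = np.random.default_rng(1).uniform(0, 1, size=(20, 10))
        return tg.AlleleFrequencyMatrix([f"S{i}" for i in range(20)],
                                        [f"1:{k+1}:A:C" for k in range(10)],
                                        vals, np.full((20, 10), 10))

    def test_all_and_too_many(self):
        af = self._af()
        assert set(tg.subsample_individuals(af, 20, seed=0).sample_ids) == set(af.sample_ids)
        with pytest.raises(ValueError):
            tg.subsample_individuals(af, 21, seed=0)

    def test_exact_size_and_uniformity(self):
        af = self._af()
        counts = {s: 0 for s in af.sample_ids}
        n_draws = 400
        for s in range(n_draws):
            sub = tg.subsample_individuals(af, 5, seed=s)
            assert sub.n_samples == 5
            for sid in sub.sample_ids:
                counts[sid] += 1
        freqs = np.array(list(counts.values())) / n_draws
        # each sample should appear with frequency ~ 5/20 = 0.25
        assert np.all(np.abs(freqs - 0.25) < 0.1)
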