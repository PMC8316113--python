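"""Footprint statistics: UMI collapse, mapping conventions, length
distributions, Welch periodicity, plateau concentration."""

import math

import numpy as np
import pytest

from ambiribo.readquant import AlignmentSet, Read
from ambiribo.riboprof import (
    CoverageProfile,
    compare_length_distributions,
    footprint_coverage,
    footprint_to_total_ratio,
    length_distribution,
    plateau_concentration,
    umi_collapse,
    welch_periodicity,
)
from ambiribo.synthetic import simulate_footprints


def _fp(reads, ref_len=200):
    return AlignmentSet("ref", ref_len, reads)


class TestUmiCollapse:
    def test_identical_pair_collapses_to_one(self):
        alns = _fp([Read(5, 30, "+", "AAAAA"), Read(5, 30, "+", "AAAAA")])
        collapsed, rep = umi_collapse(alns)
        assert len(collapsed) == 1
        assert rep.depletion == 0.5

    def test_same_footprint_different_umis_kept(self):
        alns = _fp([Read(5, 30, "+", "AAAAA"), Read(5, 30, "+", "CCCCC")])
        collapsed, _ = umi_collapse(alns)
        assert len(collapsed) == 2

    def test_missing_umi_raises(self):
        with pytest.raises(ValueError):
            umi_collapse(_fp([Read(5, 30, "+")]))

    def test_idempotent(self, rdrp_segment, cfg):
        fps = simulate_footprints(rdrp_segment, "viral_plateau", cfg, 3000)
        once, _ = umi_collapse(fps)
        twice, rep = umi_collapse(once)
        assert len(twice) == len(once)
        assert rep.depletion == 0.0

    def test_occupancy_expectation_for_saturated_position(self):
        # 5,000 identical footprints with random 5-nt UMIs: expected
        # distinct count 1024 * (1 - (1023/1024)^5000) ~= 1016
        rng = np.random.default_rng(42)
        umis = ["".join(rng.choice(list("ACGT"), 5)) for _ in range(5000)]
        alns = _fp([Read(10, 30, "+", u) for u in umis])
        collapsed, _ = umi_collapse(alns)
        expected = 1024 * (1 - (1023 / 1024) ** 5000)
        assert abs(len(collapsed) - expected) <= 0.03 * expected


class TestFootprintCoverage:
    def test_center_mapping_conserves_read_count(self, rdrp_segment, cfg):
        fps = simulate_footprints(rdrp_segment, "host", cfg, 2000)
        prof = footprint_coverage(fps, "center", normalize=False)
        n_in_range = sum(1 for r in fps.reads if 27 <= r.length <= 39)
        assert prof.values.sum() == pytest.approx(n_in_range)

    def test_single_normalized_read_gives_million_over_length(self):
        alns = _fp([Read(50, 30, "+", "AAAAA")])
        prof = footprint_coverage(alns, "center", normalize=True)
        assert prof.values[60] == pytest.approx(1e6 / 30)
        assert np.count_nonzero(prof.values) == 30

    def test_out_of_range_lengths_excluded(self):
        alns = _fp([Read(0, 26, "+"), Read(0, 30, "+")])
        prof = footprint_coverage(alns, "center", length_range=(27, 39))
        assert prof.values.sum() == pytest.approx(1.0)

    def test_fiveprime_mapping_single_position(self):
        alns = _fp([Read(40, 33, "+")])
        prof = footprint_coverage(alns, "fiveprime")
        assert prof.values[40] == 1.0
        assert prof.values.sum() == 1.0

    def test_empty_input_zero_vector(self):
        prof = footprint_coverage(_fp([]), "center")
        assert prof.values.sum() == 0.0


class TestFootprintToTotalRatio:
    def _profile(self, values, normalized=True):
        return CoverageProfile("ref", "+", "center", np.asarray(values, float), normalized)

    def test_equal_densities_give_one(self):
        a = self._profile(np.ones(100))
        assert footprint_to_total_ratio(a, a, (10, 90)) == 1.0

    def test_zero_footprints_give_zero(self):
        fp = self._profile(np.zeros(100))
        rna = self._profile(np.ones(100))
        assert footprint_to_total_ratio(fp, rna, (0, 100)) == 0.0

    def test_zero_rna_flagged(self):
        fp = self._profile(np.ones(100))
        rna = self._profile(np.zeros(100))
        assert math.isnan(footprint_to_total_ratio(fp, rna, (0, 100)))

    def test_unnormalized_profiles_rejected(self):
        a = self._profile(np.ones(100), normalized=False)
        with pytest.raises(ValueError):
            footprint_to_total_ratio(a, a, (0, 100))


class TestLengthDistributions:
    def test_host_preset_mode_33(self, rdrp_segment, cfg):
        fps = simulate_footprints(rdrp_segment, "host", cfg, 5000)
        assert length_distribution(fps).mode == 33

    def test_identical_samples_not_significant(self):
        lengths = [33] * 100 + [32] * 50
        res = compare_length_distributions(lengths, lengths)
        assert res.statistic == 0.0
        assert res.pvalue > 0.99

    def test_host_vs_viral_presets_significant(self, rdrp_segment, cfg):
        host = simulate_footprints(rdrp_segment, "host", cfg, 5000)
        viral = simulate_footprints(rdrp_segment, "viral_plateau", cfg, 5000)
        res = compare_length_distributions(host, viral)
        assert res.significant

    def test_undersized_input_indeterminate(self):
        res = compare_length_distributions([33] * 10, [27] * 10)
        assert res.indeterminate


class TestWelchPeriodicity:
    def _impulse_train(self, length, period=3):
        v = np.zeros(length)
        v[::period] = 1.0
        return CoverageProfile("ref", "+", "fiveprime", v)

    def test_period_three_peaks_at_third(self):
        prof = self._impulse_train(1550)
        res = welch_periodicity(prof, (25, 1525))
        assert abs(res.peak_frequency - 1 / 3) <= 1 / 500

    def test_constant_vector_has_no_off_zero_peak(self):
        prof = CoverageProfile("ref", "+", "fiveprime", np.ones(1000))
        res = welch_periodicity(prof, (0, 1000), pad=0)
        assert res.flat

    def test_white_noise_peak_not_reproducibly_at_third(self):
        peaks = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            prof = CoverageProfile("ref", "+", "fiveprime", rng.random(1500))
            res = welch_periodicity(prof, (0, 1500), pad=0)
            peaks.append(res.peak_frequency)
        near_third = sum(abs(p - 1 / 3) <= 1 / 500 for p in peaks)
        assert near_third < 10

    def test_shift_invariance_of_estimator(self):
        base = np.zeros(1600)
        base[::3] = 1.0
        for offset in (1, 2, 7):
            a = CoverageProfile("r", "+", "fiveprime", base[: 1500])
            b = CoverageProfile("r", "+", "fiveprime", base[offset : 1500 + offset])
            ra = welch_periodicity(a, (0, 1500), pad=0)
            rb = welch_periodicity(b, (0, 1500), pad=0)
            assert ra.peak_frequency == rb.peak_frequency
            assert np.allclose(ra.power, rb.power, rtol=1e-8)

    def test_region_shorter_than_segment_raises(self):
        prof = self._impulse_train(400)
        with pytest.raises(ValueError, match="nperseg"):
            welch_periodicity(prof, (0, 400), pad=0)

    def test_wrong_mapping_rejected(self):
        prof = CoverageProfile("ref", "+", "center", np.ones(1000))
        with pytest.raises(ValueError):
            welch_periodicity(prof, (0, 1000))


class TestPlateauConcentration:
    def test_uniform_vector_gini_zero(self):
        res = plateau_concentration(np.ones(500))
        assert res.gini == pytest.approx(0.0, abs=1e-12)

    def test_single_position_gini(self):
        v = np.zeros(100)
        v[17] = 5.0
        res = plateau_concentration(v)
        assert res.gini == pytest.approx(99 / 100)
        assert res.mass90_fraction == pytest.approx(1 / 100)

    def test_scale_invariance(self):
        rng = np.random.default_rng(0)
        v = rng.random(300)
        a = plateau_concentration(v)
        b = plateau_concentration(17.3 * v)
        assert a.gini == pytest.approx(b.gini)
        assert a.mass90_fraction == b.mass90_fraction

    def test_all_zero_flagged(self):
        assert not plateau_concentration(np.zeros(10)).defined

    def test_viral_exceeds_host_at_matched_depth(self, rdrp_segment, cfg):
        cds = rdrp_segment.fwd_orf[:2]
        host = footprint_coverage(
            simulate_footprints(rdrp_segment, "host", cfg, 5000), "center"
        )
        viral = footprint_coverage(
            simulate_footprints(rdrp_segment, "viral_plateau", cfg, 5000), "center"
        )
        g_host = plateau_concentration(host, cds).gini
        g_viral = plateau_concentration(viral, cds).gini
        assert g_viral > g_host + 0.3
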