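import math

import numpy as np
import pandas as pd
import pytest

import dualreporter as dr
from dualreporter import decompose as dc


def _one_group(ch_green, ch_red):
    n = len(ch_green)
    return pd.DataFrame({
        "experiment_id": ["e"] * n,
        "animal_id": [f"a{i}" for i in range(n)],
        "ring": [1] * n,
        "cell_id": [f"int1.{i}" for i in range(n)],
        "nucleus_count": [2] * n,
        "ch_green": ch_green, "ch_red": ch_red,
    })


class TestPearsonR:
    def test_perfect_positive(self):
        assert dr.pearson_r([1, 2, 3], [2, 4, 6]) == pytest.approx(1.0)

    def test_perfect_negative(self):
        assert dr.pearson_r([1, 2, 3], [3, 2, 1]) == pytest.approx(-1.0)

    def test_half_correlation(self):
        assert dr.pearson_r([1, 2, 3], [1, 3, 2]) == pytest.approx(0.5)

    def test_degenerate_input_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            dr.pearson_r([1, 1, 1], [1, 2, 3])
        with pytest.raises(ValueError):
            dr.pearson_r([1, 2], [3, 4])


class TestCorrelatedUncorrelated:
    def test_identical_channels(self):
        corr, uncorr = dr.correlated_uncorrelated([1, 2, 3], [1, 2, 3])
        assert uncorr == 0.0
        assert corr == pytest.approx(1 / 6)  # (14/3 - 4) / 4

    def test_anticorrelated_pair(self):
        corr, uncorr = dr.correlated_uncorrelated([1, 3], [3, 1])
        assert uncorr == pytest.approx(0.5)
        assert corr == pytest.approx(-0.25)

    def test_constant_channel_has_zero_correlated(self):
        x = np.array([0.5, 1.0, 1.5, 2.0])
        y = np.full_like(x, x.mean())
        corr, uncorr = dr.correlated_uncorrelated(x, y)
        assert corr == pytest.approx(0.0, abs=1e-15)

    def test_errors(self):
        with pytest.raises(ValueError):
            dr.correlated_uncorrelated([1.0], [1.0])
        with pytest.raises(ValueError, match="normalization"):
            dr.correlated_uncorrelated([1, -3], [1, 1])


class TestNormalizeByGroup:
    def test_group_means_become_exactly_one(self):
        cells = _one_group([2.0, 4.0], [1.0, 1.0])
        norm, gains, skipped = dr.normalize_by_group(cells, min_group_size=2)
        assert norm["ch_green"].tolist() == [2 / 3, 4 / 3]
        assert norm["ch_green"].mean() == 1.0

    def test_a_value_is_ratio_of_group_means(self):
        cells = _one_group([100.0, 100.0, 100.0, 100.0, 100.0],
                           [50.0, 50.0, 50.0, 50.0, 50.0])
        _, gains, _ = dr.normalize_by_group(cells)
        assert gains[0].a_value == pytest.approx(0.5)
        assert gains[0].n == 5

    def test_ring_specific_setpoints_need_per_ring_normalization(
            self, four_point_two_ring_cells):
        norm, _, _ = dr.normalize_by_group(four_point_two_ring_cells,
                                           group_cols=("ring",),
                                           min_group_size=2)
        for ring in (1, 2):
            sub = norm[norm["ring"] == ring]
            assert sub["ch_green"].mean() == 1.0
            assert sub["ch_red"].mean() == 1.0
        pooled, _, _ = dr.normalize_by_group(four_point_two_ring_cells,
                                             group_cols=("experiment_id",),
                                             min_group_size=2)
        ring1 = pooled[pooled["ring"] == 1]
        assert ring1["ch_red"].mean() != 1.0

    def test_small_groups_skipped_and_logged(self):
        cells = _one_group([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        norm, gains, skipped = dr.normalize_by_group(cells, min_group_size=5)
        assert norm.empty and not gains
        assert "group size 3 < 5" in skipped[0][1]

    def test_zero_mean_group_skipped_with_reason(self):
        cells = _one_group([0.0] * 5, [1.0] * 5)
        norm, gains, skipped = dr.normalize_by_group(cells)
        assert norm.empty
        assert "zero group mean" in skipped[0][1]

    def test_tls_gain_estimator(self):
        rng = np.random.default_rng(0)
        x = rng.lognormal(0, 0.3, 200)
        cells = _one_group(x, 2.0 * x)
        _, gains, _ = dr.normalize_by_group(cells, gain_estimator="tls")
        assert gains[0].a_value == pytest.approx(2.0, rel=1e-9)


class TestDecomposeType1:
    def test_null_simulation_gives_zero_intrinsic_noise(self):
        p = dr.default_params("null_no_variation", experiment_type="typeI",
                              promoter_b="hsp-16.2")
        res = dr.decompose_type1(dr.simulate_cells(p, include_latent=False))
        assert (res.per_group["eta2_gamma"] == 0.0).all()
        assert res.aggregate["eta2_gamma"] == 0.0

    def test_intrinsic_only_matches_lognormal_closed_form(self):
        # sigma_gamma = 0.1, everything else 0: per channel CV2 = e^s2 - 1,
        # the channels are independent (correlated -> 0), so uncorrelated
        # -> e^s2 - 1 with s2 = 0.01
        p = dr.GenerativeParams(
            experiment_type="typeI", promoter_a="hsp-16.2",
            promoter_b="hsp-16.2", sigma_G_animal=0, sigma_G_cell=0,
            sigma_P=0, sigma_gamma=0.1, sigma_meas=0,
            n_experiments=1, n_animals_per_experiment=12500, seed=21)
        res = dr.decompose_type1(dr.simulate_cells(p, include_latent=False))
        expected = dr.expected_eta2(p).eta2_gamma_true
        assert expected == pytest.approx(math.expm1(0.01))
        assert res.aggregate["eta2_gamma"] == pytest.approx(expected, rel=0.05)

    def test_paper_like_allele_r2_exceeds_090(self):
        p = dr.default_params("paper_like", experiment_type="typeI",
                              promoter_b="hsp-16.2",
                              n_animals_per_experiment=100, seed=6)
        cells = dr.simulate_cells(p, include_latent=False)
        norm, _, _ = dr.normalize_by_group(cells)
        r = dr.pearson_r(norm["ch_green"], norm["ch_red"])
        assert r * r >= 0.9

    def test_per_experiment_replicates_emitted(self):
        p = dr.default_params("paper_like", experiment_type="typeI",
                              promoter_b="hsp-16.2", seed=2)
        res = dr.decompose_type1(dr.simulate_cells(p, include_latent=False))
        assert len(res.per_experiment) == 3
        assert {"eta2_gamma", "correlated"} <= set(res.per_experiment.columns)


class TestDecomposeType2:
    GAMMA = {"hsp-16.2": 0.02, "vit-2": 0.02}

    def _uniform_cells(self, uncorr_target=None):
        p = dr.default_params("paper_like", experiment_type="typeII", seed=5)
        return dr.simulate_cells(p, include_latent=False)

    def test_subtraction_arithmetic(self):
        # uncorrelated 0.05, gamma_a = gamma_b = 0.02 -> eta2_P = 0.03
        cells = self._uniform_cells()
        res = dr.decompose_type2(cells, ("hsp-16.2", "vit-2"), self.GAMMA)
        row = res.per_group.iloc[0]
        assert row["eta2_P_raw"] == pytest.approx(row["uncorrelated"] - 0.02)
        manual = 0.05 - 0.5 * (0.02 + 0.02)
        assert manual == pytest.approx(0.03)

    def test_negative_overshoot_clamped_and_flagged(self):
        cells = self._uniform_cells()
        big_gamma = {"hsp-16.2": 5.0, "vit-2": 5.0}
        res = dr.decompose_type2(cells, ("hsp-16.2", "vit-2"), big_gamma)
        assert (res.per_group["eta2_P_raw"] < 0).all()
        assert (res.per_group["eta2_P"] == 0.0).all()
        assert res.per_group["clamped"].all()

    def test_missing_gamma_names_available_promoters(self):
        cells = self._uniform_cells()
        with pytest.raises(KeyError, match="hsp-16.2"):
            dr.decompose_type2(cells, ("hsp-16.2", "vit-2"),
                               {"vit-2": 0.01})

    def test_ring_matched_gamma_preferred_with_fallback(self):
        lookup = {"p": {1: 0.1, 2: 0.2}}
        val, src = dr.gamma_for(lookup, "p", ring=2)
        assert val == 0.2 and src == "ring-matched"
        val, src = dr.gamma_for(lookup, "p", ring=4)
        assert val == pytest.approx(0.15) and src == "across-ring mean"

    def test_large_n_recovers_all_three_bins(self, large_type2_cells,
                                             large_type2_params,
                                             large_type1_gamma):
        res = dr.decompose_type2(large_type2_cells, ("hsp-16.2", "vit-2"),
                                 large_type1_gamma)
        exp = dr.expected_eta2(large_type2_params)
        assert res.aggregate["eta2_G"] == pytest.approx(exp.eta2_G_true,
                                                        rel=0.05)
        assert res.aggregate["eta2_P"] == pytest.approx(exp.eta2_P_true,
                                                        rel=0.05)


class TestPooledVsGrouped:
    def test_ring_setpoint_ratio_inflates_pooled_estimate(
            self, four_point_two_ring_cells):
        rep = dr.pooled_vs_grouped(four_point_two_ring_cells, ("pa", "pb"),
                                   min_group_size=2)
        assert rep["eta2_P_grouped"] == 0.0
        assert rep["eta2_P_pooled"] == pytest.approx(0.125)

    def test_equal_setpoints_pooled_matches_grouped(self):
        setpoints = {(prom, ring): 100.0 for prom in ("hsp-16.2", "vit-2")
                     for ring in (1, 2, 3, 4)}
        p = dr.default_params("paper_like", experiment_type="typeII",
                              setpoints=setpoints, n_experiments=1,
                              n_animals_per_experiment=1000, seed=5)
        cells = dr.simulate_cells(p, include_latent=False)
        rep = dr.pooled_vs_grouped(cells, ("hsp-16.2", "vit-2"))
        assert rep["inflation"] == pytest.approx(
            0.0, abs=0.10 * rep["eta2_P_grouped"])

    def test_null_equal_setpoints_both_exactly_zero(self):
        setpoints = {(prom, ring): 100.0 for prom in ("hsp-16.2", "vit-2")
                     for ring in (1, 2, 3, 4)}
        p = dr.default_params("null_no_variation", experiment_type="typeII",
                              setpoints=setpoints)
        cells = dr.simulate_cells(p, include_latent=False)
        rep = dr.pooled_vs_grouped(cells, ("hsp-16.2", "vit-2"))
        assert rep["eta2_P_grouped"] == 0.0
        assert rep["eta2_P_pooled"] == 0.0

    def test_single_ring_degenerates_with_warning(self):
        p = dr.default_params("paper_like", experiment_type="typeII",
                              cells_per_animal=1,
                              n_animals_per_experiment=20, seed=2)
        cells = dr.simulate_cells(p, include_latent=False)
        rep = dr.pooled_vs_grouped(cells, ("hsp-16.2", "vit-2"))
        assert rep["n_rings"] == 1
        assert "single ring" in rep["warning"]
        assert rep["inflation"] == pytest.approx(0.0, abs=1e-12)


class TestCompareBins:
    def test_separated_bins_significant(self):
        rep = dr.compare_bins({"low": [0.1, 0.11, 0.09],
                               "high": [0.30, 0.31, 0.29]})
        assert rep["method"] == "two-tailed t-test"
        assert rep["pvalue"] < 0.05
        assert rep["significant"]
        # hand-checked t statistic: |mean diff| / (s_p sqrt(2/3))
        assert abs(rep["statistic"]) == pytest.approx(24.49, rel=0.01)

    def test_identical_bins_t0_p1(self):
        rep = dr.compare_bins({"a": [0.1, 0.2, 0.3], "b": [0.1, 0.2, 0.3]})
        assert rep["statistic"] == 0.0
        assert rep["pvalue"] == pytest.approx(1.0)
        assert not rep["significant"]

    def test_three_bins_yield_three_tukey_contrasts(self):
        rep = dr.compare_bins({"a": [0.1, 0.12, 0.11],
                               "b": [0.2, 0.22, 0.21],
                               "c": [0.3, 0.32, 0.31]})
        assert rep["method"] == "one-way ANOVA + Tukey HSD"
        assert len(rep["contrasts"]) == 3
        assert all(c["significant"] for c in rep["contrasts"])

    def test_all_identical_values_error(self):
        with pytest.raises(ValueError, match="zero variance"):
            dr.compare_bins({"a": [0.1, 0.1, 0.1], "b": [0.1, 0.1, 0.1]})

    def test_nonnormal_bins_use_rank_tests(self):
        # one constant bin: Shapiro undefined -> rank-based branch
        rep = dr.compare_bins({"a": [0.1, 0.1, 0.1],
                               "b": [0.5, 0.6, 0.7]})
        assert rep["method"] == "Mann-Whitney U"

    def test_too_few_replicates_rejected(self):
        with pytest.raises(ValueError, match="replicate"):
            dr.compare_bins({"a": [0.1, 0.2], "b": [0.3, 0.4, 0.5]})


class TestCombinedScatter:
    def test_null_type1_points_on_diagonal(self):
        p = dr.default_params("null_no_variation", experiment_type="typeI",
                              promoter_b="hsp-16.2")
        cells = dr.simulate_cells(p, include_latent=False)
        norm, _, _ = dr.normalize_by_group(cells)
        pts = dr.combined_scatter([norm], [])
        assert (pts["x"] == pts["y"]).all()
        assert (pts["experiment_type"] == "typeI").all()

    def test_row_count_is_sum_of_cells(self):
        p1 = dr.default_params("paper_like", experiment_type="typeI",
                               promoter_b="hsp-16.2", seed=1)
        p2 = dr.default_params("paper_like", experiment_type="typeII", seed=2)
        n1, _, _ = dr.normalize_by_group(
            dr.simulate_cells(p1, include_latent=False))
        n2, _, _ = dr.normalize_by_group(
            dr.simulate_cells(p2, include_latent=False))
        pts = dr.combined_scatter([n1], [n2])
        assert len(pts) == len(n1) + len(n2)

    def test_type2_cloud_wider_than_type1(self):
        kw = dict(n_animals_per_experiment=417, n_experiments=3)
        p1 = dr.default_params("paper_like", experiment_type="typeI",
                               promoter_b="hsp-16.2", seed=1, **kw)
        p2 = dr.default_params("paper_like", experiment_type="typeII",
                               seed=2, **kw)
        n1, _, _ = dr.normalize_by_group(
            dr.simulate_cells(p1, include_latent=False))
        n2, _, _ = dr.normalize_by_group(
            dr.simulate_cells(p2, include_latent=False))
        pts = dr.combined_scatter([n1], [n2])
        spread = pts.assign(d=(pts["x"] - pts["y"]).abs()) \
                    .groupby("experiment_type")["d"].mean()
        assert spread["typeII"] > spread["typeI"]
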