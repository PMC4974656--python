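import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from saltpepper.clustering import (
    DEFAULT_BIN_EDGES_UM,
    PairTable,
    bin_similarity,
    build_pair_table,
    cortical_distance,
    depth_similarity_analysis,
    fit_exponential_decay,
    near_far_preference_test,
    orientation_difference,
    per_field_correlation,
    ranksum_test,
    robustness_filter,
    tuning_similarity,
)
from saltpepper.stimulus import FourierGrid, ScreenGeometry
from saltpepper.synthetic_data import SheetConfig, ground_truth_kernel, place_cells

GRID = FourierGrid(ScreenGeometry())


def sheet_pair_table(map_length_um, seed, n_cells=60, field_um=250.0,
                     planes=(0.0,), decorrelation=0.0, bias=0.35):
    """Pair table of ground-truth kernels for a simulated sheet."""
    cfg = SheetConfig(n_cells=n_cells, field_um=field_um,
                      plane_depths_um=planes, map_length_um=map_length_um,
                      column_decorrelation=decorrelation,
                      interneuron_fraction=0.0, seed=seed)
    cells = place_cells(cfg)
    ws, pos, oris, sfs = [], [], [], []
    lo, hi = GRID.sf_cpd.min(), GRID.sf_cpd.max()
    for c in cells:
        sf = float(np.clip(c.pref_sf_cpd, lo, hi))
        ws.append(ground_truth_kernel(c.pref_orientation_deg, sf, 20.0, 0.7,
                                      bias, GRID))
        pos.append([c.x_um, c.y_um, c.depth_um])
        oris.append(c.pref_orientation_deg)
        sfs.append(sf)
    return build_pair_table(np.array(ws), np.array(pos),
                            np.array(oris), np.array(sfs))


class TestSimilarityAndDistance:
    def test_identical_kernels(self):
        w = np.random.default_rng(0).normal(size=50)
        assert tuning_similarity(w, w) == pytest.approx(1.0)
        assert tuning_similarity(w, -w) == pytest.approx(-1.0)

    def test_orthogonal_checker_kernels(self):
        w1 = np.tile([1.0, -1.0], 8)
        w2 = np.tile([1.0, 1.0, -1.0, -1.0], 4)
        assert tuning_similarity(w1, w2) == pytest.approx(0.0, abs=1e-9)

    def test_constant_kernel_errors(self):
        with pytest.raises(ValueError):
            tuning_similarity(np.ones(10), np.arange(10.0))

    def test_distance_3_4_5(self):
        d, dz = cortical_distance((0, 0, 0), (30, 40, 40))
        assert (d, dz) == (50.0, 40.0)
        assert cortical_distance((30, 40, 40), (0, 0, 0)) == (d, dz)

    def test_same_position(self):
        assert cortical_distance((5, 5, 5), (5, 5, 5)) == (0.0, 0.0)

    @pytest.mark.parametrize("a,b,expected", [
        (10, 170, 20), (0, 90, 90), (45, 45, 0), (179, 1, 2),
    ])
    def test_orientation_difference(self, a, b, expected):
        assert orientation_difference(a, b) == pytest.approx(expected)

    @settings(derandomize=True, max_examples=100)
    @given(a=st.floats(0, 179.999), b=st.floats(0, 179.999))
    def test_orientation_difference_range_and_symmetry(self, a, b):
        d = orientation_difference(a, b)
        assert 0 <= d <= 90
        assert d == orientation_difference(b, a)


def ranksum_enumeration(x, y, alternative):
    """Independent oracle: exact p by enumerating group assignments."""
    pooled = np.concatenate([x, y])
    n = len(x)
    ranks = pd.Series(pooled).rank().to_numpy()
    w_obs = ranks[:n].sum()
    count = total = 0
    for comb in itertools.combinations(range(len(pooled)), n):
        w = ranks[list(comb)].sum()
        total += 1
        if alternative == "less" and w <= w_obs + 1e-9:
            count += 1
        elif alternative == "greater" and w >= w_obs - 1e-9:
            count += 1
        elif alternative == "two-sided":
            mu = ranks.sum() * n / len(pooled)
            if abs(w - mu) >= abs(w_obs - mu) - 1e-9:
                count += 1
    return count / total


class TestRankSum:
    def test_canonical_one_sixth(self):
        assert ranksum_test([1, 2], [3, 4], "less") == pytest.approx(1 / 6)

    def test_identical_large_samples(self):
        x = np.arange(1000) + np.random.default_rng(1).normal(0, 1e-6, 1000)
        assert ranksum_test(x, x + 1e-9, "two-sided") > 0.9

    def test_exact_matches_enumeration(self):
        rng = np.random.default_rng(2)
        for n, m in [(2, 2), (3, 4), (5, 5), (6, 6), (2, 6)]:
            for alt in ("less", "greater", "two-sided"):
                x = rng.normal(size=n)
                y = rng.normal(size=m)
                assert ranksum_test(x, y, alt) == pytest.approx(
                    ranksum_enumeration(x, y, alt)), (n, m, alt)

    def test_empty_sample_errors(self):
        with pytest.raises(ValueError):
            ranksum_test([], [1.0], "less")


class TestBinSimilarity:
    def _pairs(self, d, s, **extra):
        df = pd.DataFrame({"i": 0, "j": 1, "d_um": d, "delta_depth_um": 0.0,
                           "similarity": s, "field": 0, **extra})
        return PairTable(df)

    def test_constant_similarity(self):
        rng = np.random.default_rng(3)
        d = rng.uniform(0, 209, 2000)
        pt = self._pairs(d, np.full(2000, 0.3))
        curve = bin_similarity(pt)
        assert np.allclose(curve.mean, 0.3)
        assert np.all(curve.ranksum_p_vs_last[np.isfinite(curve.ranksum_p_vs_last)] > 0.4)
        assert curve.ranksum_p_vs_last[-1] == 1.0

    def test_pooled_bins_reproduce_global_mean(self):
        rng = np.random.default_rng(4)
        d = rng.uniform(0, 209, 5000)
        s = rng.normal(0.2, 0.3, 5000)
        curve = bin_similarity(self._pairs(d, s))
        pooled = (curve.mean * curve.n_pairs).sum() / curve.n_pairs.sum()
        assert pooled == pytest.approx(s.mean())
        assert curve.n_pairs.sum() == 5000

    def test_clustered_sheet_first_bin_significant(self):
        pt = sheet_pair_table(30.0, seed=0)
        curve = bin_similarity(pt)
        assert curve.ranksum_p_vs_last[0] < 0.01
        # means trend downwards overall
        assert curve.mean[0] > curve.mean[-1]

    def test_empty_bin_flagged(self):
        pt = self._pairs(np.array([10.0, 200.0]), np.array([0.5, 0.1]))
        curve = bin_similarity(pt)
        assert np.isnan(curve.mean[2])
        assert np.isnan(curve.ranksum_p_vs_last[2])


class TestExponentialFit:
    def test_noiseless_model_recovery(self):
        # build pairs whose bin means follow c + A exp(-d/lam) exactly
        centers = 0.5 * (np.asarray(DEFAULT_BIN_EDGES_UM)[:-1]
                         + np.asarray(DEFAULT_BIN_EDGES_UM)[1:])
        d = np.repeat(centers, 50)
        s = 0.1 + 0.4 * np.exp(-d / 38.0)
        df = pd.DataFrame({"i": 0, "j": 1, "d_um": d, "delta_depth_um": 0.0,
                           "similarity": s, "field": 0})
        fit = fit_exponential_decay(PairTable(df), n_boot=0)
        assert fit.amplitude == pytest.approx(0.4, abs=1e-6)
        assert fit.length_constant_um == pytest.approx(38.0, abs=1e-4)
        assert fit.asymptote == pytest.approx(0.1, abs=1e-6)

    def test_flat_curve_flagged_unidentifiable(self):
        rng = np.random.default_rng(5)
        d = rng.uniform(0, 209, 3000)
        s = rng.normal(0.2, 0.05, 3000)
        fit = fit_exponential_decay(
            PairTable(pd.DataFrame({"i": 0, "j": 1, "d_um": d,
                                    "delta_depth_um": 0.0, "similarity": s,
                                    "field": 0})), n_boot=20, seed=0)
        assert not fit.identifiable
        assert fit.ci95_lambda_um == (10.0, 160.0)

    def test_bootstrap_ci_brackets_point_estimate(self):
        pt = sheet_pair_table(30.0, seed=1)
        fit = fit_exponential_decay(pt, n_boot=100, seed=0)
        lo, hi = fit.ci95_lambda_um
        assert lo <= fit.length_constant_um <= hi


class TestNearFarAndCorrelation:
    def test_clustered_sheet_orientation_clusters(self):
        ps = [near_far_preference_test(sheet_pair_table(30.0, seed=s))
              for s in range(3)]
        assert np.median(ps) < 0.01

    def test_same_data_both_groups(self):
        rng = np.random.default_rng(6)
        vals = rng.uniform(0, 90, 4000)
        d = np.where(np.arange(4000) % 2 == 0, 20.0, 200.0)
        df = pd.DataFrame({"i": 0, "j": 1, "d_um": d, "delta_depth_um": 0.0,
                           "similarity": 0.1, "field": 0, "d_ori_deg": vals})
        p = near_far_preference_test(PairTable(df))
        assert 0.2 < p < 0.8

    def test_empty_group_errors(self):
        df = pd.DataFrame({"i": 0, "j": 1, "d_um": [60.0] * 5,
                           "delta_depth_um": 0.0, "similarity": 0.1,
                           "field": 0, "d_ori_deg": 10.0})
        with pytest.raises(ValueError):
            near_far_preference_test(PairTable(df))

    def test_exact_negative_line(self):
        d = np.linspace(0, 299, 100)
        s = 1 - d / 300.0
        df = pd.DataFrame({"i": 0, "j": 1, "d_um": d, "delta_depth_um": 0.0,
                           "similarity": s, "field": 0})
        r, p = per_field_correlation(PairTable(df), method="t")
        assert r == pytest.approx(-1.0)
        assert p < 1e-10

    def test_independent_similarity(self):
        rng = np.random.default_rng(7)
        df = pd.DataFrame({"i": 0, "j": 1, "d_um": rng.uniform(0, 200, 10_000),
                           "delta_depth_um": 0.0,
                           "similarity": rng.normal(0, 1, 10_000), "field": 0})
        r, _ = per_field_correlation(PairTable(df), method="t")
        assert abs(r) < 0.05

    def test_two_points_error(self):
        df = pd.DataFrame({"i": 0, "j": 1, "d_um": [0.0, 10.0],
                           "delta_depth_um": 0.0, "similarity": [1.0, 0.0],
                           "field": 0})
        with pytest.raises(ValueError):
            per_field_correlation(PairTable(df))


class TestDepthAnalysis:
    def test_pair_appears_only_in_its_depth_group(self):
        df = pd.DataFrame({"i": [0], "j": [1], "d_um": [30.0],
                           "delta_depth_um": [80.0], "similarity": [0.5],
                           "field": 0})
        curves = depth_similarity_analysis(PairTable(df), (0.0, 40.0, 80.0, 120.0))
        assert set(curves) == {80.0}

    def test_columnar_sheet_deep_pairs_cluster(self):
        pt = sheet_pair_table(30.0, seed=2, n_cells=45,
                              planes=(0.0, 40.0, 80.0, 120.0), decorrelation=0.0)
        curves = depth_similarity_analysis(pt, (0.0, 40.0, 80.0, 120.0))
        assert curves[120.0].ranksum_p_vs_last[0] < 0.05

    def test_decorrelated_sheet_deep_pairs_flat(self):
        ps = []
        for seed in range(3):
            pt = sheet_pair_table(30.0, seed=seed, n_cells=45,
                                  planes=(0.0, 40.0, 80.0, 120.0),
                                  decorrelation=1.0)
            curves = depth_similarity_analysis(pt, (0.0, 40.0, 80.0, 120.0))
            ps.append(curves[120.0].ranksum_p_vs_last[0])
        assert np.median(ps) > 0.05


class TestRobustnessFilter:
    def _cells(self, n=100, seed=0):
        rng = np.random.default_rng(seed)
        return pd.DataFrame({
            "kurtosis": rng.uniform(5, 40, n),
            "pref_sf_cpd": rng.uniform(0.01, 0.12, n),
            "roi_area_um2": rng.uniform(40, 250, n),
        })

    def test_roi_filter_keeps_exactly_80(self):
        cells = self._cells(100)
        idx = robustness_filter(cells, "roi_top_80pct")
        assert len(idx) == 80
        dropped = set(range(100)) - set(idx)
        assert cells.loc[list(dropped), "roi_area_um2"].max() <= \
            cells.loc[list(idx), "roi_area_um2"].min() + 1e-12

    def test_roi_filter_tie_break_by_id(self):
        cells = pd.DataFrame({"roi_area_um2": [10.0] * 5})
        idx = robustness_filter(cells, "roi_top_80pct")
        assert list(idx) == [0, 1, 2, 3]

    def test_kurtosis_filter_identity_when_all_pass(self):
        cells = self._cells()
        cells["kurtosis"] = 20.0
        assert len(robustness_filter(cells, "kurtosis_ge_15")) == len(cells)

    def test_peak_sf_filter(self):
        cells = self._cells()
        idx = robustness_filter(cells, "peak_sf_gt_0.025")
        assert np.all(cells.loc[idx, "pref_sf_cpd"] > 0.025)

    def test_unknown_mode_and_empty_result_error(self):
        cells = self._cells()
        with pytest.raises(ValueError):
            robustness_filter(cells, "bogus")
        cells["kurtosis"] = 1.0
        with pytest.raises(ValueError):
            robustness_filter(cells, "kurtosis_ge_15")


class TestPairTableConstruction:
    def test_order_invariance(self):
        rng = np.random.default_rng(8)
        ws = rng.normal(size=(10, 20))
        pos = rng.uniform(0, 100, (10, 3))
        perm = rng.permutation(10)
        a = build_pair_table(ws, pos).table
        b = build_pair_table(ws[perm], pos[perm]).table
        key = ["d_um", "similarity"]
        pd.testing.assert_frame_equal(
            a[key].sort_values(key).reset_index(drop=True).round(9),
            b[key].sort_values(key).reset_index(drop=True).round(9),
        )

    def test_constant_kernel_pairs_dropped(self):
        ws = np.vstack([np.ones(20), np.random.default_rng(9).normal(size=(3, 20))])
        pos = np.random.default_rng(10).uniform(0, 100, (4, 3))
        pt = build_pair_table(ws, pos)
        assert len(pt) == 3  # only the 3 non-constant kernels pair up
        assert 0 not in set(pt.i)

    def test_asymptote_rises_with_shared_bias(self):
        """More shared low-SF bias -> larger similarity asymptote."""
        fits = []
        for bias in (0.0, 0.3, 0.6, 1.0, 1.5):
            pt = sheet_pair_table(0.0, seed=11, n_cells=50, bias=bias)
            fits.append(np.mean(pt.similarity))
        assert np.all(np.diff(fits) > 0)
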