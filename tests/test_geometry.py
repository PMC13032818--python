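import numpy as np
import pytest
from scipy import optimize

import admixgeo as ag
from admixgeo.geometry import AdmixtureModel, F4PrimePoints

from conftest import random_table


def model_from(ft):
    p = ft.populations
    return AdmixtureModel(p[0], p[1], p[2], p[3:])


class TestRegressionPoints:
    def test_pair_count(self):
        ft = random_table(1, n_pops=7)  # 4 auxiliaries
        pts = ag.regression_points(ft, model_from(ft))
        assert pts.n == 6

    def test_exact_mixture_collinear(self, exact_mix):
        ft, model = exact_mix
        pts = ag.regression_points(ft, model)
        assert np.allclose(pts.y_coords, 0.3 * pts.x_coords, atol=1e-10)

    def test_matches_per_pair_f4prime(self):
        ft = random_table(2, n_pops=8)
        model = model_from(ft)
        pts = ag.regression_points(ft, model)
        for (i, j), px, py in zip(pts.pairs, pts.x_coords, pts.y_coords):
            assert px == pytest.approx(
                ag.f4_prime(ft, model.a, model.b, i, j), rel=1e-12
            )
            assert py == pytest.approx(
                ag.f4_prime(ft, model.x, model.b, i, j), rel=1e-12
            )


class TestAlphaJL:
    def test_exact_mixture_recovers_alpha(self, exact_mix):
        ft, model = exact_mix
        assert ag.alpha_jl(ag.regression_points(ft, model)) == pytest.approx(
            0.3, abs=1e-12
        )

    def test_single_pair_equals_f4_ratio(self):
        ft = random_table(3, n_pops=5)
        x, a, b, i, j = ft.populations
        pts = F4PrimePoints(
            [(i, j)],
            [ag.f4_prime(ft, a, b, i, j)],
            [ag.f4_prime(ft, x, b, i, j)],
        )
        ratio = ag.f4(ft, x, b, i, j) / ag.f4(ft, a, b, i, j)
        assert ag.alpha_jl(pts) == pytest.approx(ratio, rel=1e-14)

    def test_matches_numeric_least_squares(self):
        rng = np.random.default_rng(8)
        xs = rng.normal(size=15)
        ys = 0.4 * xs + rng.normal(scale=0.3, size=15)
        pts = F4PrimePoints([("i", f"j{k}") for k in range(15)], xs, ys)
        closed = ag.alpha_jl(pts)
        num = optimize.minimize_scalar(
            lambda a: float(np.sum((ys - a * xs) ** 2)),
            bounds=(-5, 5),
            method="bounded",
            options={"xatol": 1e-12},
        ).x
        assert closed == pytest.approx(num, abs=1e-9)

    def test_all_zero_x_is_undefined_slope(self):
        pts = F4PrimePoints([("i", "j")] * 3, np.zeros(3), np.ones(3))
        with pytest.raises(ValueError, match="slope"):
            ag.alpha_jl(pts)

    def test_slope_invariant_under_common_rescale(self):
        rng = np.random.default_rng(4)
        xs, ys = rng.normal(size=10), rng.normal(size=10)
        pairs = [("i", f"j{k}") for k in range(10)]
        a1 = ag.alpha_jl(F4PrimePoints(pairs, xs, ys))
        a2 = ag.alpha_jl(F4PrimePoints(pairs, 37.5 * xs, 37.5 * ys))
        assert a1 == pytest.approx(a2, rel=1e-12)


class TestAngles:
    def test_exact_mixture_angles_180(self, exact_mix):
        ft, model = exact_mix
        assert ag.angle_pre_jl(ft, model) == pytest.approx(180.0, abs=1e-5)
        assert ag.angle_post_jl(ft, model) == pytest.approx(180.0, abs=1e-5)

    def test_orthogonal_difference_vectors_90(self):
        freqs = np.column_stack(
            [
                [0.0, 0.0],  # x
                [1.0, 0.0],  # a
                [0.0, 1.0],  # b
                [0.1, 0.2], [0.3, 0.4], [0.5, 0.6], [0.7, 0.9],
            ]
        )
        ft = ag.FrequencyTable(freqs, ["x", "a", "b", "i1", "i2", "i3", "i4"])
        model = AdmixtureModel("x", "a", "b", ["i1", "i2", "i3", "i4"])
        assert ag.angle_pre_jl(ft, model) == pytest.approx(90.0, abs=1e-9)

    def test_cos_phi_two_routes_agree(self):
        ft = random_table(6, n_pops=8)
        model = model_from(ft)
        phi = ag.angle_pre_jl(ft, model)
        dx = ft.column(model.a) - ft.column(model.x)
        dy = ft.column(model.b) - ft.column(model.x)
        direct = float(dx @ dy) / np.sqrt(float(dx @ dx) * float(dy @ dy))
        assert np.cos(np.radians(phi)) == pytest.approx(direct, abs=1e-12)

    def test_coincident_vertex_raises(self):
        ft = random_table(7, n_pops=8)
        dup = ag.FrequencyTable(
            np.column_stack([ft.freqs[:, 1], ft.freqs[:, 1:]]),
            ["x"] + ft.populations[1:],
        )
        model = AdmixtureModel("x", "P1", "P2", ["P3", "P4", "P5", "P6"])
        with pytest.raises(ValueError, match="coincide"):
            ag.angle_pre_jl(dup, model)

    def test_post_jl_blind_auxiliary_set_raises(self):
        # aux pairs differ only along (1, -1); x - a = (0.125, 0.125) is
        # orthogonal to that direction (dyadic values keep it exact)
        cols = {
            "x": np.array([0.375, 0.625]),
            "a": np.array([0.25, 0.5]),
            "b": np.array([0.75, 0.25]),
        }
        for k, e in enumerate((0.0, 0.0625, 0.125, 0.1875)):
            cols[f"i{k}"] = np.array([0.5 + e, 0.5 - e])
        ft = ag.FrequencyTable(np.column_stack(list(cols.values())), list(cols))
        model = AdmixtureModel("x", "a", "b", ["i0", "i1", "i2", "i3"])
        with pytest.raises(ValueError, match="blind"):
            ag.angle_post_jl(ft, model)

    def test_angles_invariant_under_source_relabel(self):
        ft = random_table(10, n_pops=8)
        model = model_from(ft)
        assert ag.angle_pre_jl(ft, model) == pytest.approx(
            ag.angle_pre_jl(ft, model.swapped()), abs=1e-10
        )
        assert ag.angle_post_jl(ft, model) == pytest.approx(
            ag.angle_post_jl(ft, model.swapped()), abs=1e-10
        )

    def test_angles_within_bounds(self):
        for seed in range(5):
            ft = random_table(seed, n_pops=8)
            model = model_from(ft)
            assert 0.0 <= ag.angle_pre_jl(ft, model) <= 180.0
            assert 0.0 <= ag.angle_post_jl(ft, model) <= 180.0


class TestF4Ratios:
    def test_exact_mixture_all_ratios_equal_alpha(self, exact_mix):
        ft, model = exact_mix
        ratios = ag.f4_ratio_distribution(ft, model)
        assert all(r.defined for r in ratios)
        assert all(r.ratio == pytest.approx(0.3, abs=1e-10) for r in ratios)
        assert ag.in_range_mean(ratios) == pytest.approx(0.3, abs=1e-10)

    def test_matches_per_pair_brute_force(self):
        ft = random_table(11, n_pops=8)
        model = model_from(ft)
        for r in ag.f4_ratio_distribution(ft, model):
            i, j = r.pair
            expected = ag.f4(ft, model.x, model.b, i, j) / ag.f4(
                ft, model.a, model.b, i, j
            )
            assert r.ratio == pytest.approx(expected, rel=1e-12)

    def test_undefined_ratio_flagged_not_dropped(self):
        # duplicate auxiliary columns -> f4(a,b;i,j) = 0 for that pair
        rng = np.random.default_rng(0)
        cols = rng.uniform(0.1, 0.9, size=(50, 6))
        cols = np.column_stack([cols, cols[:, 3]])  # i4 duplicates i1
        ft = ag.FrequencyTable(cols, ["x", "a", "b", "i1", "i2", "i3", "i4"])
        model = AdmixtureModel("x", "a", "b", ["i1", "i2", "i3", "i4"])
        ratios = ag.f4_ratio_distribution(ft, model)
        undefined = [r for r in ratios if not r.defined]
        assert len(ratios) == 6
        assert [r.pair for r in undefined] == [("i1", "i4")]
        assert not undefined[0].in_range


class TestAlphaPre:
    def test_exact_mixture(self, exact_mix):
        ft, model = exact_mix
        assert ag.alpha_pre_jl(ft, model) == pytest.approx(0.3, abs=1e-12)

    def test_matches_numeric_least_squares(self):
        ft = random_table(14, n_pops=8)
        model = model_from(ft)
        da = ft.column(model.a) - ft.column(model.b)
        dx = ft.column(model.x) - ft.column(model.b)
        num = optimize.minimize_scalar(
            lambda a: float(np.sum((dx - a * da) ** 2)),
            bounds=(-5, 5),
            method="bounded",
            options={"xatol": 1e-12},
        ).x
        assert ag.alpha_pre_jl(ft, model) == pytest.approx(num, abs=1e-9)

    def test_jl_estimate_closer_to_truth_than_raw_projection(self):
        """Drift and sampling noise bias the raw-frequency projection; the
        JL estimate should beat it in most replicates."""
        wins = 0
        for seed in range(20):
            ds, truth = ag.simulate_triplet(ag.SimSpec(s=20_000, seed=seed))
            ft = ag.compute_frequency_table(ds)
            m = truth.model()
            a_jl = ag.alpha_jl(ag.regression_points(ft, m))
            a_pre = ag.alpha_pre_jl(ft, m)
            if abs(a_jl - 0.2) < abs(a_pre - 0.2):
                wins += 1
        assert wins >= 11


class TestF3Test:
    def test_midpoint_mixture_negative(self):
        rng = np.random.default_rng(5)
        a = rng.uniform(0.1, 0.9, 100)
        b = rng.uniform(0.1, 0.9, 100)
        cols = [a, b, (a + b) / 2] + [rng.uniform(0.1, 0.9, 100) for _ in range(4)]
        ft = ag.FrequencyTable(
            np.column_stack(cols), ["a", "b", "x", "i1", "i2", "i3", "i4"]
        )
        model = AdmixtureModel("x", "a", "b", ["i1", "i2", "i3", "i4"])
        val, is_admix = ag.f3_admixture_test(ft, model)
        assert val < 0 and is_admix

    def test_drifted_target_positive_f3_but_post_jl_admixture(self):
        """Heavy drift can hide admixture from the classical f3 test while
        the projected angle still reveals it."""
        ds, truth = ag.simulate_triplet(ag.SimSpec(s=20_000, seed=4))
        ft = ag.compute_frequency_table(ds)
        m = truth.model()
        val, is_admix = ag.f3_admixture_test(ft, m)
        assert val > 0 and not is_admix
        assert ag.angle_pre_jl(ft, m) < 90 < ag.angle_post_jl(ft, m)

    def test_delegates_to_f3(self):
        ft = random_table(16, n_pops=8)
        model = model_from(ft)
        val, _ = ag.f3_admixture_test(ft, model)
        assert val == ag.f3(ft, model.a, model.b, model.x)


class TestOutliers:
    def test_exact_mixture_all_residuals_zero(self, exact_mix):
        ft, model = exact_mix
        pts = ag.regression_points(ft, model)
        ranked = ag.rank_outlier_pairs(pts, 0.3, pts.n)
        assert all(abs(r) < 1e-10 for _, r in ranked)

    def test_contaminated_pair_ranks_first(self):
        rng = np.random.default_rng(3)
        xs = rng.normal(size=10)
        ys = 0.5 * xs + rng.normal(scale=0.01, size=10)
        ys[4] += 3.0
        pairs = [("i", f"j{k}") for k in range(10)]
        pts = F4PrimePoints(pairs, xs, ys)
        ranked = ag.rank_outlier_pairs(pts, 0.5, 3)
        assert ranked[0][0] == ("i", "j4")
        assert ranked[0][1] == pytest.approx(3.0, abs=0.1)

    def test_k_zero_and_k_too_large(self):
        pts = F4PrimePoints([("i", "j")], [1.0], [1.0])
        assert ag.rank_outlier_pairs(pts, 1.0, 0) == []
        with pytest.raises(ValueError):
            ag.rank_outlier_pairs(pts, 1.0, 2)


class TestModelIdentities:
    def test_source_swap_on_exact_mixture(self, exact_mix):
        ft, model = exact_mix
        a1 = ag.alpha_jl(ag.regression_points(ft, model))
        a2 = ag.alpha_jl(ag.regression_points(ft, model.swapped()))
        assert a2 == pytest.approx(1.0 - a1, abs=1e-10)

    def test_source_swap_within_bootstrap_ci_on_drifted_data(self, sim_data):
        _, truth, ft = sim_data
        m = truth.model()
        a1 = ag.alpha_jl(ag.regression_points(ft, m))
        a2 = ag.alpha_jl(ag.regression_points(ft, m.swapped()))
        _, d2 = ag.bootstrap_aux(
            ft, m, ag.BootstrapSpec(n_replicates=500, seed=0), "alpha"
        )
        assert abs((1.0 - a2) - a1) <= 2 * d2 + 1e-6

    def test_inverted_model_slope(self):
        """Fitting a source as the target on an exact mixture gives slope
        -alpha/(1-alpha)."""
        for alpha in (0.2, 0.3, 0.45):
            ft, model = ag.exact_mixture_table(800, alpha, 5, seed=7)
            inverted = AdmixtureModel(model.b, model.a, model.x, model.aux)
            slope = ag.alpha_jl(ag.regression_points(ft, inverted))
            assert slope == pytest.approx(-alpha / (1 - alpha), abs=1e-9)


class TestModelValidation:
    def test_distinct_labels_required(self):
        with pytest.raises(ValueError, match="distinct"):
            AdmixtureModel("x", "x", "b", ["i1", "i2", "i3", "i4"])

    def test_minimum_auxiliaries(self):
        with pytest.raises(ValueError, match="at least 4"):
            AdmixtureModel("x", "a", "b", ["i1", "i2", "i3"])


def test_analyze_and_result_log(sim_data):
    _, truth, ft = sim_data
    res = ag.analyze(
        ft, truth.model(), bootstrap=ag.BootstrapSpec(n_replicates=200, seed=3)
    )
    assert res.s == ft.s
    assert res.delta1 > 0 and res.delta2 is not None
    log = ag.result_log(res)
    assert "alpha =" in log and "varphi" in log and "verdict:" in log
    assert f"SNPs (effective): {ft.s}" in log
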