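import numpy as np
import pytest
from scipy import stats

from protraj.trajectory import (
    GeneCurve,
    SplineSpec,
    beam_test,
    benjamini_hochberg,
    cluster_gene_curves,
    fit_spline_curve,
    natural_spline_basis,
    trajectory_de_test,
)


class TestSplineFit:
    def test_constant_reproduced(self, rng):
        d = np.sort(rng.uniform(0, 3, 30))
        c = fit_spline_curve(d, np.full(30, 4.2))
        assert np.allclose(c.fitted, 4.2, atol=1e-8)
        assert c.residual_variance == pytest.approx(0.0, abs=1e-12)

    def test_linear_in_span(self, rng):
        d = np.sort(rng.uniform(0, 3, 40))
        c = fit_spline_curve(d, 1.0 - 2.0 * d)
        assert np.allclose(c.fitted, 1.0 - 2.0 * c.grid, atol=1e-8)

    def test_noisy_cubic_grid_error(self, rng):
        n, sd = 200, 0.5
        d = np.sort(rng.uniform(0, 1, n))
        truth = 2 * d**3 - 1.5 * d
        y = truth + rng.normal(scale=sd, size=n)
        c = fit_spline_curve(d, y, SplineSpec(df=3))
        truth_grid = 2 * c.grid**3 - 1.5 * c.grid
        assert np.abs(c.fitted - truth_grid).max() < 3 * sd / np.sqrt(n / 3)

    def test_identical_distances_rejected(self):
        with pytest.raises(ValueError, match="identical"):
            fit_spline_curve(np.ones(20), np.arange(20.0))

    def test_basis_contains_linear_and_has_df_columns(self, rng):
        x = np.sort(rng.uniform(0, 5, 50))
        B = natural_spline_basis(x, df=3)
        assert B.shape == (50, 3)
        coef, res, *_ = np.linalg.lstsq(
            np.column_stack([np.ones(50), B]), 2 + 3 * x, rcond=None
        )
        fitted = np.column_stack([np.ones(50), B]) @ coef
        assert np.allclose(fitted, 2 + 3 * x, atol=1e-8)


class TestTrajectoryDe:
    def test_zero_variance_gene(self, rng):
        d = np.sort(rng.uniform(0, 3, 50))
        Y = np.vstack([np.full(50, 2.0), rng.normal(size=50)])
        res, retained = trajectory_de_test(Y, ["flat", "noise"], d)
        assert res[0].lrt_stat == 0.0 and res[0].p_value == 1.0
        assert "flat" not in retained

    def test_planted_monotone_gene_retained(self, rng):
        n = 200
        d = np.sort(rng.uniform(0, 3, n))
        y = 2.0 * d / 3 + rng.normal(size=n)
        res, retained = trajectory_de_test(y[None, :], ["g"], d)
        assert retained == ["g"]

    def test_lrt_nonnegative_every_gene(self, rng):
        d = rng.uniform(0, 3, 80)
        Y = rng.normal(size=(200, 80))
        res, _ = trajectory_de_test(Y, [f"g{i}" for i in range(200)], d)
        assert min(r.lrt_stat for r in res) >= -1e-8


class TestBenjaminiHochberg:
    def test_hand_computed_step_up(self):
        assert np.allclose(
            benjamini_hochberg(np.array([0.01, 0.02, 0.03])), [0.03, 0.03, 0.03]
        )

    def test_degenerate_cases(self):
        assert benjamini_hochberg(np.array([0.2]))[0] == pytest.approx(0.2)
        assert np.allclose(benjamini_hochberg(np.ones(5)), 1.0)
        with pytest.raises(ValueError):
            benjamini_hochberg(np.array([1.5]))

    def test_permutation_invariance_and_statsmodels_agreement(self, rng):
        from statsmodels.stats.multitest import multipletests

        p = rng.uniform(size=40)
        q = benjamini_hochberg(p)
        perm = rng.permutation(40)
        assert np.allclose(benjamini_hochberg(p[perm]), q[perm])
        _, q_sm, *_ = multipletests(p, method="fdr_bh")
        assert np.allclose(q, q_sm)


class TestBeam:
    def test_duplicated_path_never_significant(self, rng):
        n = 60
        d = np.sort(rng.uniform(0, 3, n))
        Y = rng.normal(size=(500, n))
        res, retained = beam_test(Y, d, Y.copy(), d.copy(),
                                  [f"g{i}" for i in range(500)])
        assert retained == []
        assert min(r.lrt_stat for r in res) >= -1e-8

    def test_planted_branch_specific_gene(self, rng):
        n = 150
        d1 = np.sort(rng.uniform(0, 3, n))
        d2 = np.sort(rng.uniform(0, 3, n))
        y1 = rng.normal(size=n)
        y2 = 2.0 * d2 / 3 + rng.normal(size=n)
        res, retained = beam_test(y1[None, :], d1, y2[None, :], d2, ["g"])
        assert retained == ["g"]

    def test_too_few_samples_raises(self, rng):
        with pytest.raises(ValueError, match="df \\+ 2"):
            beam_test(np.ones((1, 3)), np.arange(3.0),
                      np.ones((1, 30)), np.arange(30.0), ["g"])


class TestClustering:
    def _curves(self, shapes, n_each, rng, noise=0.03):
        g = np.linspace(0, 1, 100)
        out = []
        for name, f in shapes:
            for i in range(n_each):
                out.append(GeneCurve(f"{name}{i}", g,
                                     f(g) + noise * rng.normal(size=100), 0.1))
        return out

    def test_anticorrelated_perfect_split(self, rng):
        curves = self._curves(
            [("up", lambda g: g), ("dn", lambda g: -g)], 10, rng
        )
        modules = cluster_gene_curves(curves, k=2)
        members = sorted(tuple(sorted(m.gene_ids)) for m in modules)
        assert {g[:2] for g in members[0]} in ({"dn"}, {"up"})
        assert all(len(m.gene_ids) == 10 for m in modules)
        dirs = {m.direction for m in modules}
        assert dirs == {"up", "down"}

    def test_silhouette_selects_three_planted_shapes(self, rng):
        curves = self._curves(
            [("rise", lambda g: g), ("fall", lambda g: 1 - g),
             ("ridge", lambda g: np.sin(np.pi * g))], 8, rng
        )
        modules = cluster_gene_curves(curves, k="auto")
        assert len(modules) == 3
        for m in modules:
            prefixes = {g.rstrip("0123456789") for g in m.gene_ids}
            assert len(prefixes) == 1

    def test_identical_curves_warn_and_return_min_k(self, rng):
        g = np.linspace(0, 1, 50)
        curves = [GeneCurve(f"c{i}", g, g.copy(), 0.1) for i in range(6)]
        with pytest.warns(UserWarning, match="identical"):
            modules = cluster_gene_curves(curves, k="auto", k_range=(2, 4))
        assert len(modules) == 2

    def test_constant_curve_flagged(self, rng):
        g = np.linspace(0, 1, 50)
        curves = [GeneCurve("flat", g, np.ones(50), 0.1)] + [
            GeneCurve(f"c{i}", g, g + 0.01 * rng.normal(size=50), 0.1)
            for i in range(5)
        ]
        with pytest.warns(UserWarning, match="constant"):
            cluster_gene_curves(curves, k=2)


def test_pipeline_determinism_retained_sets(small_cohort):
    expr, annot, events, truth = small_cohort
    ids = [s for s in expr.sample_ids if truth.state[s] in (1, 2, 3)]
    d = truth.pseudotime[ids].to_numpy()
    sub = expr.subset_samples(ids)
    _, r1 = trajectory_de_test(sub.values, sub.gene_ids, d)
    _, r2 = trajectory_de_test(sub.values, sub.gene_ids, d)
    assert r1 == r2


def test_module_direction_matches_spearman_sign(small_cohort):
    expr, annot, events, truth = small_cohort
    ids = [s for s in expr.sample_ids if truth.state[s] in (1, 2, 3)]
    d = truth.pseudotime[ids].to_numpy()
    sub = expr.subset_samples(ids)
    _, retained = trajectory_de_test(sub.values, sub.gene_ids, d,
                                     fdr_threshold=1e-4)
    assert len(retained) >= 10
    curves = []
    gene_idx = {g: i for i, g in enumerate(sub.gene_ids)}
    for g in retained:
        c = fit_spline_curve(d, sub.values[gene_idx[g]])
        c.gene_id = g
        curves.append(c)
    modules = cluster_gene_curves(curves, k=2)
    agree = total = 0
    for m in modules:
        if m.direction not in ("up", "down"):
            continue
        sign = 1 if m.direction == "up" else -1
        for g in m.gene_ids:
            rho = stats.spearmanr(d, sub.values[gene_idx[g]]).statistic
            agree += (np.sign(rho) == sign)
            total += 1
    assert agree / total >= 0.95
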