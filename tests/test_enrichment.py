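import itertools

import numpy as np
import pytest
from scipy import stats

from protraj.enrichment import (
    binomial_state_enrichment,
    compute_gii,
    compute_tmb,
    fisher_gene_set_enrichment,
    running_sum_enrichment,
    running_sum_score,
    spearman_trend,
    transition_driver_test,
)
from protraj.io import EventMatrix, GeneSetCollection


class TestRunningSum:
    @pytest.mark.parametrize(
        "labels, expected",
        [([1, 1, -1, -1], 1.0), ([-1, -1, 1, 1], -1.0), ([1, -1, 1, -1], 0.5)],
    )
    def test_hand_walk_scores(self, labels, expected):
        assert running_sum_score(np.array(labels)) == pytest.approx(expected)

    def test_reversal_negates_score(self, rng):
        labels = rng.choice([1, -1], size=30)
        if len(set(labels)) < 2:
            labels[:2] = [1, -1]
        s = running_sum_score(labels)
        assert running_sum_score(labels[::-1]) == pytest.approx(-s)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            running_sum_score(np.ones(5))

    def test_permutation_p_matches_exhaustive_enumeration(self):
        labels = np.array([1, 1, -1, 1, -1, -1])
        res = running_sum_enrichment(labels, n_perm=10000, seed=3)
        obs = abs(res.score)
        perms = set(itertools.permutations(labels))
        exact = np.mean([
            abs(running_sum_score(np.array(p))) >= obs - 1e-12 for p in perms
        ])
        se = np.sqrt(exact * (1 - exact) / res.n_permutations)
        assert abs(res.p_value - exact) <= 3 * se + 1 / res.n_permutations

    def test_seed_invariance_within_mc_error(self):
        labels = np.array([1, -1, 1, 1, -1, -1, 1, -1, -1, 1])
        ps = [running_sum_enrichment(labels, n_perm=10000, seed=s).p_value
              for s in (1, 2, 3)]
        assert max(ps) - min(ps) < 0.03

    def test_missing_labels_excluded(self):
        labels = np.array([1.0, np.nan, 1.0, -1.0, -1.0])
        res = running_sum_enrichment(labels, n_perm=100, seed=0)
        assert res.n_plus == 2 and res.n_minus == 2


class TestSpearmanTrend:
    def test_perfect_correlations(self, rng):
        d = np.sort(rng.uniform(0, 3, 30))
        rho, p, curve = spearman_trend(d, d.copy())
        assert rho == pytest.approx(1.0)
        rho2, _, _ = spearman_trend(d, -d)
        assert rho2 == pytest.approx(-1.0)

    def test_constant_values_flagged_zero(self, rng):
        d = np.sort(rng.uniform(0, 3, 20))
        rho, p, _ = spearman_trend(d, np.ones(20))
        assert rho == 0.0 and p == 1.0

    def test_null_calibration(self, rng):
        hits = 0
        reps = 500
        d = np.arange(50.0)
        for _ in range(reps):
            _, p, _ = spearman_trend(d, rng.normal(size=50))
            hits += p < 0.05
        assert hits / reps <= 0.07


class TestFisherGeneSets:
    def test_perfect_overlap_closed_form(self):
        universe = [f"g{i}" for i in range(20)]
        module = universe[:10]
        coll = GeneSetCollection({"S": list(module)})
        df = fisher_gene_set_enrichment(module, coll, universe)
        from math import comb

        assert df.loc[0, "p_value"] == pytest.approx(1 / comb(20, 10))

    def test_zero_and_expected_overlap(self):
        universe = [f"g{i}" for i in range(40)]
        coll = GeneSetCollection({
            "disjoint": universe[20:30],
            "expected": universe[:5] + universe[20:25],
        })
        df = fisher_gene_set_enrichment(universe[:10], coll, universe)
        d = df.set_index("set_name")
        assert d.loc["disjoint", "p_value"] <= 1.0
        # right tail at zero successes is 1
        df2 = fisher_gene_set_enrichment(
            universe[:10], GeneSetCollection({"far": universe[30:]}), universe
        )
        assert df2.loc[0, "overlap"] == 0
        assert df2.loc[0, "p_value"] == pytest.approx(1.0)

    def test_set_outside_universe_skipped(self):
        universe = ["a", "b", "c", "d"]
        coll = GeneSetCollection({"out": ["x", "y"]})
        df = fisher_gene_set_enrichment(["a"], coll, universe)
        assert "skipped" in df.loc[0, "note"]
        assert np.isnan(df.loc[0, "p_value"])


class TestDriverTests:
    def _events(self, values, ids=None):
        n = values.shape[0]
        sample_ids = [f"s{i}" for i in range(n)]
        ids = ids or [f"e{j}" for j in range(values.shape[1])]
        return EventMatrix(sample_ids, ids, values), sample_ids

    def test_fisher_matches_hypergeometric_closed_form(self, rng):
        for _ in range(20):
            n_early, n_late = rng.integers(5, 40, size=2)
            vals = np.concatenate([
                rng.integers(0, 2, size=n_early), rng.integers(0, 2, size=n_late)
            ])[:, None]
            ev, sids = self._events(vals)
            states = {s: (1 if i < n_early else 2) for i, s in enumerate(sids)}
            res = transition_driver_test(ev, states, [(1, 2)])
            r = res[0]
            _, p_ref = stats.fisher_exact(
                [[r.a, r.b], [r.c, r.d]], alternative="greater"
            )
            assert r.p_value == pytest.approx(p_ref, abs=1e-12)

    def test_absent_later_state_p_one(self):
        vals = np.array([[1]] * 5 + [[0]] * 10)
        ev, sids = self._events(vals)
        states = {s: (1 if i < 5 else 2) for i, s in enumerate(sids)}
        res = transition_driver_test(ev, states, [(1, 2)])
        assert res[0].p_value == pytest.approx(1.0)

    def test_strong_jump_detected(self):
        vals = np.concatenate([
            np.repeat([0, 1], [98, 2]), np.repeat([0, 1], [60, 40])
        ])[:, None]
        ev, sids = self._events(vals)
        states = {s: (1 if i < 100 else 2) for i, s in enumerate(sids)}
        res = transition_driver_test(ev, states, [(1, 2)])
        assert res[0].fdr < 1e-2

    def test_empty_state_rejected(self):
        ev, sids = self._events(np.ones((4, 1), dtype=int))
        states = {s: 1 for s in sids}
        with pytest.raises(ValueError, match="empty"):
            transition_driver_test(ev, states, [(1, 2)])


def test_tmb_and_gii_arithmetic():
    assert np.allclose(compute_tmb(np.array([0, 38, 30]), 38.0),
                       [0.0, 1.0, 30 / 38])
    with pytest.raises(ValueError):
        compute_tmb(np.array([1]), 0.0)
    M = np.array([[1.0, -1.0, 0.5], [0.0, 0.0, 0.0]])
    assert np.allclose(compute_gii(M), [2.5, 0.0])
    assert np.allclose(compute_gii(2 * M), 2 * compute_gii(M))


def test_binomial_state_enrichment_closed_form():
    assert binomial_state_enrichment(np.full(10, 3), 3, 0.5) == \
        pytest.approx(2.0**-10)
    # k equal to the expectation is not enriched
    labels = np.repeat([1, 2], [5, 5])
    assert binomial_state_enrichment(labels, 1, 0.5) >= 0.5
    with pytest.raises(ValueError):
        binomial_state_enrichment(labels, 1, 1.0)
    with pytest.raises(ValueError):
        binomial_state_enrichment(np.array([]), 1, 0.5)
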