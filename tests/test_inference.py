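import itertools

import numpy as np
import pandas as pd
import pytest

from srcconn.inference import (conjunction, contrast_z, eta_squared, holm_bonferroni,
                               manova_stepdown, permutation_maxstat, voxelwise_log_f)


def brute_force_holm(p):
    """Closure-principle step-down with Bonferroni local tests.

    Adjusted p of hypothesis i = max over subsets S containing i of the
    Bonferroni p-value min_{j in S} |S| p_j; Holm's procedure is its
    shortcut, so the two must agree exactly.
    """
    p = np.asarray(p, float)
    m = len(p)
    adj = np.zeros(m)
    for i in range(m):
        best = 0.0
        for r in range(1, m + 1):
            for S in itertools.combinations(range(m), r):
                if i in S:
                    best = max(best, min(1.0, len(S) * p[list(S)].min()))
        adj[i] = best
    return adj


class TestHolm:
    def test_worked_example(self):
        out = holm_bonferroni([0.01, 0.04, 0.03])
        assert np.allclose(out, [0.03, 0.06, 0.06])

    def test_single_and_capped(self):
        assert holm_bonferroni([0.2]) == pytest.approx([0.2])
        assert np.all(holm_bonferroni([1.0, 1.0, 1.0]) == 1.0)

    def test_matches_closure_enumeration(self, rng):
        for _ in range(50):
            m = int(rng.integers(1, 7))
            p = rng.uniform(size=m)
            assert np.allclose(holm_bonferroni(p), brute_force_holm(p), atol=1e-12)

    def test_monotone_and_dominates_raw(self, rng):
        p = rng.uniform(size=10)
        adj = holm_bonferroni(p)
        assert np.all(adj >= p)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-15)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            holm_bonferroni([0.5, 1.5])
        with pytest.raises(ValueError):
            holm_bonferroni([[0.1, 0.2]])


class TestLogF:
    def test_hand_computed_f(self):
        # groups (1,2,3) vs (4,5,6): SSB=13.5, MSW=1 -> F = 13.5
        X = np.array([[1.0], [2.0], [3.0], [4.0], [5.0], [6.0]])
        sm = voxelwise_log_f(X, ["a"] * 3 + ["b"] * 3)
        assert np.exp(sm.values[0]) == pytest.approx(13.5)

    def test_eta_squared_hand_computed(self):
        x = np.array([1.0, 2, 3, 4, 5, 6, 7, 8, 9])
        codes = np.array([0, 0, 0, 1, 1, 1, 2, 2, 2])
        assert eta_squared(x, codes, 3) == pytest.approx(54.0 / 60.0)

    def test_zero_within_variance_rejected(self):
        X = np.array([[1.0], [1.0], [2.0], [2.0]])
        with pytest.raises(ValueError, match="within-group"):
            voxelwise_log_f(X, ["a", "a", "b", "b"])

    def test_degenerate_zero_between_flagged(self, rng):
        noise = rng.standard_normal(4)
        X = np.column_stack([np.array([1.0, 2.0, 1.0, 2.0]), noise])
        sm = voxelwise_log_f(X, ["a", "a", "b", "b"])
        assert sm.degenerate[0] and not sm.degenerate[1]
        assert np.isfinite(sm.values).all()


class TestPermutationMaxstat:
    def test_huge_shift_gets_minimum_p(self, rng):
        X = rng.standard_normal((30, 10))
        X[:10, 3] += 50.0
        res = permutation_maxstat(X, ["a"] * 10 + ["b"] * 10 + ["c"] * 10,
                                  n_perm=200, seed=0)
        assert res.corrected_p[3] == pytest.approx(1.0 / 201.0)
        assert res.corrected_p.min() == res.corrected_p[3]

    def test_same_seed_same_null(self, rng):
        X = rng.standard_normal((18, 5))
        g = ["a", "b", "c"] * 6
        r1 = permutation_maxstat(X, g, n_perm=150, seed=5)
        r2 = permutation_maxstat(X, g, n_perm=150, seed=5)
        assert np.array_equal(r1.max_null, r2.max_null)

    def test_corrected_p_bounds(self, rng):
        X = rng.standard_normal((18, 8))
        res = permutation_maxstat(X, ["a", "b", "c"] * 6, n_perm=100, seed=1)
        assert np.all(res.corrected_p >= 1 / 101.0)
        assert np.all(res.corrected_p <= 1.0)

    def test_min_permutations_enforced(self, rng):
        with pytest.raises(ValueError):
            permutation_maxstat(rng.standard_normal((12, 3)), ["a", "b"] * 6,
                                n_perm=50)


class TestConjunction:
    def test_min_rule(self):
        mz, sig = conjunction(np.array([2.5, 2.5]), np.array([1.0, 2.2]))
        assert np.allclose(mz, [1.0, 2.2])
        assert list(sig) == [False, True]

    def test_commutative_and_dominated(self, rng):
        a, b = rng.standard_normal(20), rng.standard_normal(20)
        m1, s1 = conjunction(a, b)
        m2, s2 = conjunction(b, a)
        assert np.array_equal(m1, m2)
        assert np.all(m1 <= a) and np.all(m1 <= b)

    def test_grid_mismatch(self):
        with pytest.raises(ValueError, match="grids"):
            conjunction(np.zeros(3), np.zeros(4))

    def test_contrast_z_detects_planted_shift(self, rng):
        X = rng.standard_normal((30, 4))
        g = np.array(["a"] * 15 + ["b"] * 15)
        X[g == "a", 2] += 2.0
        z = contrast_z(X, g, "a", "b", n_perm=500, seed=0)
        assert z[2] > 1.96
        assert np.abs(z[[0, 1, 3]]).max() < 1.96


class TestStepdown:
    @staticmethod
    def _table(rng, n=20, shift=0.0):
        X = rng.standard_normal((3 * n, 4))
        groups = np.repeat(["control", "tinnitus", "pain"], n)
        X[groups != "control", 0] += shift
        return pd.DataFrame(X, columns=list("wxyz")), groups

    def test_planted_shift_survives_stepdown(self, rng):
        df, groups = self._table(rng, shift=1.5)
        rep = manova_stepdown(df, groups,
                              [{"name": "fam", "features": list("wxyz")}])
        assert rep.multivariate[0]["p"] < 0.05
        uni = {u["feature"]: u for u in rep.univariate}
        assert uni["w"]["p_holm"] < 0.05
        pw = [p for p in rep.pairwise if p["feature"] == "w"]
        assert len(pw) == 3  # all three pairwise contrasts reported
        assert all(0 <= p["eta_sq"] <= 1 for p in pw)

    def test_null_rarely_significant(self, rng):
        hits = 0
        for _ in range(40):
            df, groups = self._table(rng)
            rep = manova_stepdown(df, groups,
                                  [{"name": "fam", "features": list("wxyz")}])
            hits += rep.multivariate[0]["p"] < 0.05
        assert hits <= 6

    def test_nested_families_gate_subfamilies(self, rng):
        df, groups = self._table(rng, shift=2.0)
        fams = [{"name": "top", "features": list("wxyz"),
                 "subfamilies": [{"name": "wx", "features": ["w", "x"]},
                                 {"name": "yz", "features": ["y", "z"]}]}]
        rep = manova_stepdown(df, groups, fams)
        names = [m["family"] for m in rep.multivariate]
        assert names[0] == "top"
        assert set(names[1:]) == {"wx", "yz"}
        # only features under significant subfamilies reach univariate stage
        feats = {u["feature"] for u in rep.univariate}
        assert "w" in feats and "y" not in feats

    def test_single_feature_family_is_anova(self, rng):
        df, groups = self._table(rng, shift=1.5)
        rep = manova_stepdown(df, groups, [{"name": "solo", "features": ["w"]}])
        assert rep.multivariate[0]["statistic"] == "anova"

    def test_family_too_large_rejected(self, rng):
        df, groups = self._table(rng, n=4)
        with pytest.raises(ValueError, match="smallest group"):
            manova_stepdown(df, groups, [{"name": "fam", "features": list("wxyz")}])

    def test_pillai_matches_univariate_f_for_one_dv(self, rng):
        # consistency of the multivariate machinery with plain ANOVA
        from scipy.stats import f_oneway

        df, groups = self._table(rng, shift=1.0)
        rep = manova_stepdown(df, groups, [{"name": "solo", "features": ["w"]}])
        F_ref, p_ref = f_oneway(*(df["w"][groups == g] for g in
                                  ("control", "tinnitus", "pain")))
        assert rep.multivariate[0]["F"] == pytest.approx(F_ref)
        assert rep.multivariate[0]["p"] == pytest.approx(p_ref)
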