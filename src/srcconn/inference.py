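"""Group statistics: permutation max-statistic maps, conjunction, MANOVA step-down.

Three inference routes mirror the whole-brain and ROI analyses:

* voxelwise log-F maps with familywise correction by the permutation
  max-statistic (labels shuffled, the maximum statistic across all features
  and bands forming the null distribution);
* minimum-statistic conjunction of two patient-minus-control contrast Z
  maps (significant where both contrasts exceed the threshold);
* a MANOVA -> ANOVA -> pairwise step-down over declared feature families,
  with Holm-Bonferroni correction across the univariate tests and
  eta-squared (SS_effect / SS_total) effect sizes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "StatMap", "PermutationResult", "StepdownReport",
    "voxelwise_log_f", "permutation_maxstat", "contrast_z", "conjunction",
    "holm_bonferroni", "manova_stepdown",
]


def _as_groups(groups) -> tuple[np.ndarray, list]:
    groups = np.asarray(groups)
    levels = list(dict.fromkeys(groups.tolist()))  # stable order of appearance
    codes = np.array([levels.index(g) for g in groups])
    return codes, levels


def _f_oneway_matrix(X: np.ndarray, codes: np.ndarray, n_groups: int) -> np.ndarray:
    """Vectorized one-way F over columns of X (n_subj x n_feat)."""
    n = X.shape[0]
    grand = X.mean(axis=0)
    ssb = np.zeros(X.shape[1])
    ssw = np.zeros(X.shape[1])
    for g in range(n_groups):
        Xg = X[codes == g]
        mg = Xg.mean(axis=0)
        ssb += len(Xg) * (mg - grand) ** 2
        ssw += ((Xg - mg) ** 2).sum(axis=0)
    df1, df2 = n_groups - 1, n - n_groups
    with np.errstate(divide="ignore", invalid="ignore"):
        return (ssb / df1) / (ssw / df2)


def eta_squared(x: np.ndarray, codes: np.ndarray, n_groups: int) -> float:
    """SS_between / SS_total for a single feature."""
    grand = x.mean()
    sst = ((x - grand) ** 2).sum()
    ssb = sum(len(x[codes == g]) * (x[codes == g].mean() - grand) ** 2
              for g in range(n_groups))
    return float(ssb / sst) if sst > 0 else 0.0


@dataclass
class StatMap:
    """Per-feature statistic map (natural-log F by default)."""

    values: np.ndarray
    statistic: str
    groups: tuple
    feature_names: tuple | None = None
    degenerate: np.ndarray | None = None  # True where the numerator vanished


def voxelwise_log_f(features: np.ndarray, groups, feature_names=None) -> StatMap:
    """ln F per feature for a one-way between-group comparison.

    ``features`` is subjects x features.  Zero within-group variance is an
    error; zero between-group variance yields -inf which is floored to the
    smallest representable log with the feature flagged degenerate.
    """
    X = np.asarray(features, float)
    codes, levels = _as_groups(groups)
    if len(levels) < 2:
        raise ValueError("need at least two groups")
    if np.min(np.bincount(codes)) < 2:
        raise ValueError("need at least two subjects per group")
    F = _f_oneway_matrix(X, codes, len(levels))
    if np.any(~np.isfinite(F)):
        raise ValueError("zero within-group variance for some feature")
    degenerate = F <= 0
    logF = np.log(np.where(degenerate, np.finfo(float).tiny, F))
    return StatMap(values=logF, statistic="log_F", groups=tuple(levels),
                   feature_names=tuple(feature_names) if feature_names is not None else None,
                   degenerate=degenerate)


@dataclass
class PermutationResult:
    observed: np.ndarray          # observed statistic per feature (F scale)
    max_null: np.ndarray          # (n_perm,) max-statistic null distribution
    corrected_p: np.ndarray
    threshold: float              # (1 - alpha) empirical quantile of the max
    alpha: float
    n_perm: int
    seed: int | None

    @property
    def significant(self) -> np.ndarray:
        return self.corrected_p <= self.alpha


def permutation_maxstat(features: np.ndarray, groups, n_perm: int = 5000,
                        alpha: float = 0.05, seed: int | None = None) -> PermutationResult:
    """Familywise-corrected voxelwise comparison via the max-statistic.

    Group labels are permuted ``n_perm`` times; each permutation's maximum
    F across all features (and bands, if the feature axis spans them) forms
    the null; corrected p for a feature is
    (1 + #{perm max >= observed}) / (n_perm + 1).
    """
    if n_perm < 100:
        raise ValueError("use at least 100 permutations")
    X = np.asarray(features, float)
    codes, levels = _as_groups(groups)
    k = len(levels)
    obs = _f_oneway_matrix(X, codes, k)
    rng = np.random.default_rng(seed)
    max_null = np.empty(n_perm)
    for p in range(n_perm):
        max_null[p] = _f_oneway_matrix(X, rng.permutation(codes), k).max()
    corrected = (1.0 + (max_null[None, :] >= obs[:, None]).sum(axis=1)) / (n_perm + 1.0)
    threshold = float(np.quantile(max_null, 1.0 - alpha))
    return PermutationResult(observed=obs, max_null=max_null, corrected_p=corrected,
                             threshold=threshold, alpha=alpha, n_perm=n_perm, seed=seed)


def contrast_z(features: np.ndarray, groups, group_a, group_b,
               n_perm: int = 1000, seed: int | None = None) -> np.ndarray:
    """Signed Z map of the a-minus-b contrast via the permutation null.

    The per-feature mean difference is referred to its label-permutation
    distribution; the one-sided empirical p (a > b) is converted to a
    normal quantile, so Z > 1.96 marks features where group a exceeds
    group b at two-sided 5%.
    """
    X = np.asarray(features, float)
    groups = np.asarray(groups)
    sel = (groups == group_a) | (groups == group_b)
    X, g = X[sel], groups[sel]
    is_a = g == group_a
    obs = X[is_a].mean(axis=0) - X[~is_a].mean(axis=0)
    rng = np.random.default_rng(seed)
    count = np.zeros(X.shape[1])
    for _ in range(n_perm):
        perm = rng.permutation(is_a)
        diff = X[perm].mean(axis=0) - X[~perm].mean(axis=0)
        count += diff >= obs
    p_one = (1.0 + count) / (n_perm + 1.0)
    return stats.norm.isf(p_one)


def conjunction(z1: np.ndarray, z2: np.ndarray, z_thresh: float = 1.96
                ) -> tuple[np.ndarray, np.ndarray]:
    """Minimum-statistic conjunction of two contrast Z maps.

    Returns (min-Z map, boolean significance at ``z_thresh``); a feature is
    significant only if *both* contrasts exceed the threshold, testing for
    a shared processing component.
    """
    z1, z2 = np.asarray(z1, float), np.asarray(z2, float)
    if z1.shape != z2.shape:
        raise ValueError(f"contrast grids differ: {z1.shape} vs {z2.shape}")
    mz = np.minimum(z1, z2)
    return mz, mz > z_thresh


def holm_bonferroni(p_values) -> np.ndarray:
    """Holm's step-down adjusted p-values, returned in the input order.

    adjusted_(k) = max_{j <= k} min(1, (m - j + 1) p_(j)) over the
    ascending order statistics.
    """
    p = np.asarray(p_values, float)
    if p.ndim != 1:
        raise ValueError("expected a 1-D vector of p-values")
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.minimum((m - np.arange(m)) * p[order], 1.0)
    adj = np.maximum.accumulate(adj)
    out = np.empty(m)
    out[order] = adj
    return out


# ---------------------------------------------------------------------------
# MANOVA -> ANOVA -> pairwise step-down


@dataclass
class StepdownReport:
    multivariate: list[dict] = field(default_factory=list)
    univariate: list[dict] = field(default_factory=list)
    pairwise: list[dict] = field(default_factory=list)

    def frames(self):
        import pandas as pd

        return (pd.DataFrame(self.multivariate), pd.DataFrame(self.univariate),
                pd.DataFrame(self.pairwise))


def _pillai_test(Y: np.ndarray, codes: np.ndarray, n_groups: int,
                 statistic: str = "pillai") -> dict:
    """Multivariate group test via statsmodels MANOVA (Pillai by default)."""
    import pandas as pd
    from statsmodels.multivariate.manova import MANOVA

    k = Y.shape[1]
    df = pd.DataFrame(Y, columns=[f"y{i}" for i in range(k)])
    df["grp"] = codes.astype(str)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        mv = MANOVA.from_formula(" + ".join(df.columns[:-1]) + " ~ C(grp)", data=df)
        res = mv.mv_test().results["C(grp)"]["stat"]
    row = {"pillai": "Pillai's trace", "wilks": "Wilks' lambda"}[statistic]
    s = min(k, n_groups - 1)
    value = float(res.loc[row, "Value"])
    eta = value / s if statistic == "pillai" else 1.0 - value ** (1.0 / s)
    return {
        "statistic": statistic, "value": value,
        "F": float(res.loc[row, "F Value"]),
        "df1": float(res.loc[row, "Num DF"]), "df2": float(res.loc[row, "Den DF"]),
        "p": float(res.loc[row, "Pr > F"]), "eta_sq": float(eta),
    }


def _anova_feature(x: np.ndarray, codes: np.ndarray, n_groups: int) -> dict:
    groups = [x[codes == g] for g in range(n_groups)]
    F, p = stats.f_oneway(*groups)
    return {"F": float(F), "p": float(p), "eta_sq": eta_squared(x, codes, n_groups)}


def manova_stepdown(feature_table, groups, families, alpha: float = 0.05,
                    statistic: str = "pillai") -> StepdownReport:
    """Nested MANOVA -> univariate ANOVA -> pairwise contrasts.

    ``feature_table`` is a DataFrame (subjects x features); ``families`` is
    a list of nested specs ``{"name", "features", "subfamilies": [...]}``.
    A family's multivariate test gates its subfamilies; the univariate
    ANOVAs of all leaf features reached under one top-level family are
    Holm-corrected together, and the three pairwise contrasts (two-group
    one-way ANOVAs with eta-squared) are reported only where the corrected
    univariate test survives.
    """
    import pandas as pd

    X = pd.DataFrame(feature_table)
    codes, levels = _as_groups(groups)
    n_groups = len(levels)
    report = StepdownReport()

    def mv_node(spec, parent: str | None, top: str) -> list[str]:
        name = spec["name"]
        feats = list(spec["features"])
        missing = [f for f in feats if f not in X.columns]
        if missing:
            raise ValueError(f"family {name!r}: unknown features {missing}")
        if np.min(np.bincount(codes)) <= len(feats):
            raise ValueError(
                f"family {name!r} has {len(feats)} features but the smallest group "
                "is not larger than that; reduce the family")
        Y = X[feats].to_numpy(float)
        if len(feats) == 1:
            uni = _anova_feature(Y[:, 0], codes, n_groups)
            rec = {"family": name, "parent": parent, "statistic": "anova",
                   "value": uni["F"], "F": uni["F"],
                   "df1": n_groups - 1.0, "df2": float(len(codes) - n_groups),
                   "p": uni["p"], "eta_sq": uni["eta_sq"]}
        else:
            rec = {"family": name, "parent": parent,
                   **_pillai_test(Y, codes, n_groups, statistic)}
        report.multivariate.append(rec)
        if rec["p"] >= alpha:
            return []
        subs = spec.get("subfamilies")
        if subs:
            leaves: list[str] = []
            for sub in subs:
                leaves += mv_node(sub, name, top)
            return leaves
        return feats

    for fam in families:
        leaves = mv_node(fam, None, fam["name"])
        if not leaves:
            continue
        uni = [_anova_feature(X[f].to_numpy(float), codes, n_groups) for f in leaves]
        adj = holm_bonferroni([u["p"] for u in uni])
        for f, u, pa in zip(leaves, uni, adj):
            report.univariate.append({"family": fam["name"], "feature": f,
                                      "F": u["F"], "p": u["p"], "p_holm": float(pa),
                                      "eta_sq": u["eta_sq"]})
            if pa < alpha:
                x = X[f].to_numpy(float)
                for a in range(n_groups):
                    for b in range(a + 1, n_groups):
                        sel = (codes == a) | (codes == b)
                        pw = _anova_feature(x[sel], (codes[sel] == b).astype(int), 2)
                        report.pairwise.append({
                            "feature": f, "group_a": levels[a], "group_b": levels[b],
                            "F": pw["F"], "p": pw["p"], "eta_sq": pw["eta_sq"]})
    return report
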