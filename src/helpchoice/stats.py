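"""Individual-difference statistics relating helping behavior to traits.

Pearson correlations use a permutation p-value (two-sided, on |r|) and a
percentile bootstrap confidence interval, with Bonferroni adjustment across
a declared family of tests; group comparisons use Welch's t (two groups) or
Welch's one-way ANOVA (more groups) with normality and variance-homogeneity
diagnostics; median splits on traits feed a trait x scenario-category grid
of Cohen's d effect sizes on willingness to help.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "correlate",
    "CorrelationResult",
    "group_compare",
    "GroupCompareResult",
    "cohens_d",
    "trait_effect_grid",
]


def _pearson_r(x: np.ndarray, y: np.ndarray) -> float:
    xc = x - x.mean()
    yc = y - y.mean()
    return float(xc @ yc / np.sqrt((xc @ xc) * (yc @ yc)))


@dataclass
class CorrelationResult:
    pair: tuple
    r: float
    p: float
    p_adjusted: float
    ci_low: float
    ci_high: float
    n: int
    n_permutations: int
    n_bootstrap: int


def correlate(x, y, n_perm: int = 5000, n_boot: int = 5000,
              family_size: int = 1, seed=None,
              pair=("x", "y")) -> CorrelationResult:
    """Pearson correlation with permutation p and bootstrap CI.

    The permutation null shuffles one vector; the two-sided p is the
    proportion of permuted |r| >= observed |r| (with the +1/(N+1)
    correction so p is never exactly zero). The 95% CI is the percentile
    bootstrap over paired resampling. ``p_adjusted`` is Bonferroni:
    ``min(1, p * family_size)``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    n = x.size
    if n < 5:
        raise ValueError("need at least 5 paired finite observations")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance: correlation undefined")
    r_obs = _pearson_r(x, y)
    rng = np.random.default_rng(seed)
    # vectorized permutations: shuffle y as rows of a matrix
    xc = x - x.mean()
    xnorm = np.sqrt(xc @ xc)
    perms = rng.permuted(np.tile(y, (n_perm, 1)), axis=1)
    pc = perms - perms.mean(axis=1, keepdims=True)
    null = (pc @ xc) / (xnorm * np.linalg.norm(pc, axis=1))
    p = (np.sum(np.abs(null) >= abs(r_obs)) + 1) / (n_perm + 1)
    idx = rng.integers(0, n, size=(n_boot, n))
    bx = x[idx]
    by = y[idx]
    bxc = bx - bx.mean(axis=1, keepdims=True)
    byc = by - by.mean(axis=1, keepdims=True)
    with np.errstate(invalid="ignore"):
        boots = np.sum(bxc * byc, axis=1) / (
            np.linalg.norm(bxc, axis=1) * np.linalg.norm(byc, axis=1))
    boots = boots[np.isfinite(boots)]
    ci_low, ci_high = np.percentile(boots, [2.5, 97.5])
    return CorrelationResult(
        pair=tuple(pair), r=r_obs, p=float(p),
        p_adjusted=float(min(1.0, p * family_size)),
        ci_low=float(ci_low), ci_high=float(ci_high), n=n,
        n_permutations=n_perm, n_bootstrap=n_boot)


@dataclass
class GroupCompareResult:
    test: str                  # "welch_t" or "welch_anova"
    statistic: float
    df: tuple
    p: float
    group_sizes: dict
    diagnostics: dict          # normality and variance-homogeneity checks


def group_compare(values, groups) -> GroupCompareResult:
    """Welch's t (2 groups) or Welch's one-way ANOVA (>2 groups).

    Diagnostics report D'Agostino-Pearson normality per group, Levene's test
    (two groups) and Bartlett's test (more than two groups) for equality of
    variances; the Welch tests themselves do not assume equal variances.
    """
    import pingouin as pg

    df = pd.DataFrame({"value": np.asarray(values, dtype=float),
                       "group": np.asarray(groups)}).dropna()
    sizes = df.groupby("group").size()
    if (sizes < 3).any():
        raise ValueError(f"group(s) with n < 3: "
                         f"{list(sizes.index[sizes < 3])}")
    arrays = [g["value"].to_numpy() for _, g in df.groupby("group")]
    diagnostics = {}
    for name, arr in zip(sizes.index, arrays):
        if len(arr) >= 8 and np.std(arr) > 0:
            stat, p = sps.normaltest(arr)
            diagnostics[f"normality_{name}"] = {"stat": float(stat),
                                                "p": float(p)}
    if all(np.std(a) > 0 for a in arrays):
        if len(arrays) == 2:
            stat, p = sps.levene(*arrays)
            diagnostics["levene"] = {"stat": float(stat), "p": float(p)}
        else:
            stat, p = sps.bartlett(*arrays)
            diagnostics["bartlett"] = {"stat": float(stat), "p": float(p)}
    if len(arrays) == 2:
        if np.array_equal(arrays[0], arrays[1]):
            return GroupCompareResult(
                test="welch_t", statistic=0.0,
                df=(float(len(arrays[0]) + len(arrays[1]) - 2),), p=1.0,
                group_sizes=sizes.to_dict(), diagnostics=diagnostics)
        res = sps.ttest_ind(arrays[0], arrays[1], equal_var=False)
        return GroupCompareResult(
            test="welch_t", statistic=float(res.statistic),
            df=(float(res.df),), p=float(res.pvalue),
            group_sizes=sizes.to_dict(), diagnostics=diagnostics)
    aov = pg.welch_anova(dv="value", between="group", data=df)
    return GroupCompareResult(
        test="welch_anova", statistic=float(aov["F"].iloc[0]),
        df=(float(aov["ddof1"].iloc[0]), float(aov["ddof2"].iloc[0])),
        p=float(aov["p_unc"].iloc[0]),
        group_sizes=sizes.to_dict(), diagnostics=diagnostics)


def cohens_d(high: np.ndarray, low: np.ndarray) -> float:
    """Cohen's d with the pooled standard deviation; positive d means the
    high group scores higher."""
    high = np.asarray(high, dtype=float)
    low = np.asarray(low, dtype=float)
    n1, n2 = len(high), len(low)
    if n1 < 2 or n2 < 2:
        return np.nan
    s2 = (((n1 - 1) * np.var(high, ddof=1) + (n2 - 1) * np.var(low, ddof=1))
          / (n1 + n2 - 2))
    if s2 == 0:
        return 0.0 if np.mean(high) == np.mean(low) else np.inf
    return float((np.mean(high) - np.mean(low)) / np.sqrt(s2))


def median_split(scores: pd.Series) -> pd.Series:
    """High = strictly above the median; ties go to the low group."""
    med = scores.median()
    return (scores > med).map({True: "high", False: "low"})


def trait_effect_grid(decisions: pd.DataFrame, traits: pd.DataFrame,
                      category_col: str = "category",
                      wth_col: str = "wth_code",
                      n_boot: int = 2000, seed=None) -> pd.DataFrame:
    """Trait x scenario-category grid of Cohen's d with bootstrap CIs.

    For each trait, participants are median-split into high and low groups;
    for each scenario category, per-participant mean WTH in that category is
    compared between groups through Cohen's d (positive = the high-trait
    group is more willing to help). Cells whose split leaves an empty group
    are marked not-applicable (NaN).
    """
    if category_col not in decisions.columns:
        raise ValueError(f"decisions must carry a {category_col!r} column")
    rng = np.random.default_rng(seed)
    per = (decisions.groupby(["participant_id", category_col])[wth_col]
           .mean().rename("wth").reset_index())
    trait_cols = [c for c in traits.columns if c != "participant_id"]
    rows = []
    for trait in trait_cols:
        tser = traits.set_index("participant_id")[trait].dropna()
        split = median_split(tser)
        for cat, grp in per.groupby(category_col):
            merged = grp.set_index("participant_id").join(
                split.rename("grp"), how="inner")
            hi = merged.loc[merged["grp"] == "high", "wth"].to_numpy()
            lo = merged.loc[merged["grp"] == "low", "wth"].to_numpy()
            if len(hi) < 2 or len(lo) < 2:
                rows.append({"trait": trait, "category": cat, "d": np.nan,
                             "ci_low": np.nan, "ci_high": np.nan,
                             "n_high": len(hi), "n_low": len(lo)})
                continue
            d = cohens_d(hi, lo)
            boots = np.empty(n_boot)
            for bi in range(n_boot):
                boots[bi] = cohens_d(hi[rng.integers(0, len(hi), len(hi))],
                                     lo[rng.integers(0, len(lo), len(lo))])
            boots = boots[np.isfinite(boots)]
            lo_ci, hi_ci = np.percentile(boots, [2.5, 97.5])
            rows.append({"trait": trait, "category": cat, "d": d,
                         "ci_low": float(lo_ci), "ci_high": float(hi_ci),
                         "n_high": len(hi), "n_low": len(lo)})
    return pd.DataFrame(rows)
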