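"""Metadata-association statistics: binning, two/multi-group tests, trends.

Covers the usual covariate analyses of cohort studies:

* ``bin_metadata`` -- six contiguous 5-year age bins and the WHO BMI
  categories (underweight < 18.5, normal [18.5, 25), obese >= 25).
* ``two_group_test`` -- Wilcoxon rank-sum, or White's-style nonparametric
  comparison realized as a seeded permutation test of the mean difference
  with a bootstrap 95% CI.
* ``multi_group_test`` -- Kruskal-Wallis with eta-squared effect size and
  Tukey-Kramer post hoc pairwise comparisons.
* ``trend_summary`` -- Spearman correlation of feature abundance against an
  ordinal bin index, BH-corrected across the feature family, with an
  increasing/decreasing/none label.
"""

from __future__ import annotations

from dataclasses import dataclass
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .diversity import rank_sum_test

__all__ = [
    "bin_metadata",
    "two_group_test",
    "TwoGroupResult",
    "multi_group_test",
    "trend_summary",
]

BMI_LABELS = ("underweight", "normal", "obese")


def bin_metadata(
    meta: pd.DataFrame,
    age_start: float | None = None,
    bmi_cuts: tuple[float, float] = (18.5, 25.0),
    n_age_bins: int = 6,
) -> pd.DataFrame:
    """Attach ``age_bin`` / ``bmi_bin`` columns (plus an ``age_out_of_range`` flag).

    Age bins are ``[a, a+5)`` starting at ``age_start`` (default: observed
    minimum floored to a multiple of 5), exactly ``n_age_bins`` of them with
    the last bin closed on the right.  BMI below the first cut is
    underweight, in ``[cut1, cut2)`` normal, at or above the second cut
    obese (boundary 18.5 -> normal, boundary 25.0 -> obese).  Samples with
    ages outside the binned span keep NA bins and are flagged.
    """
    out = meta.copy()
    age = pd.to_numeric(out["age"], errors="coerce")
    if age_start is None:
        age_start = float(np.floor(age.min() / 5.0) * 5.0)
    edges = age_start + 5.0 * np.arange(n_age_bins + 1)
    idx = np.floor((age - age_start) / 5.0)
    idx = idx.where((age >= edges[0]) & (age <= edges[-1]))
    idx = idx.clip(upper=n_age_bins - 1)  # close the last bin on the right
    labels = [f"[{edges[i]:g},{edges[i + 1]:g})" for i in range(n_age_bins - 1)]
    labels.append(f"[{edges[-2]:g},{edges[-1]:g}]")
    out["age_bin"] = pd.Categorical(
        [labels[int(i)] if pd.notna(i) else None for i in idx],
        categories=labels,
        ordered=True,
    )
    out["age_out_of_range"] = idx.isna() & age.notna()

    bmi = pd.to_numeric(out["bmi"], errors="coerce")
    cut1, cut2 = bmi_cuts
    bmi_bin = np.select(
        [bmi < cut1, bmi < cut2, bmi >= cut2],
        BMI_LABELS,
        default=None,
    )
    out["bmi_bin"] = pd.Categorical(bmi_bin, categories=list(BMI_LABELS), ordered=True)
    return out


@dataclass
class TwoGroupResult:
    statistic: float
    p: float
    direction: str  # group label with the larger central tendency, "" if tied
    ci: tuple[float, float]  # 95% CI of the mean difference (group1 - group2)
    method: str


def two_group_test(
    values,
    labels,
    method: str = "wilcoxon",
    n_perm: int = 1000,
    n_boot: int = 1000,
    seed: int = 0,
) -> TwoGroupResult:
    """Compare one feature between two groups.

    ``wilcoxon``: two-sided rank-sum.  ``whites``: two-sided permutation
    test of the difference in means (``n_perm`` permutations, p bounded
    below by 1/(n_perm+1)).  Both report a bootstrap 95% CI of the mean
    difference.  Deterministic given ``seed``.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    levels = list(pd.unique(labels))
    if len(levels) != 2:
        raise ValueError(f"two_group_test requires exactly two groups, got {levels}")
    a = values[labels == levels[0]]
    b = values[labels == levels[1]]
    if a.size < 3 or b.size < 3:
        raise ValueError("each group needs at least 3 values")
    diff = float(a.mean() - b.mean())
    rng = np.random.default_rng(seed)
    if method == "wilcoxon":
        statistic, p = rank_sum_test(a, b)
    elif method == "whites":
        pooled = np.concatenate([a, b])
        count = 0
        for _ in range(n_perm):
            perm = rng.permutation(pooled)
            if abs(perm[: a.size].mean() - perm[a.size :].mean()) >= abs(diff) - 1e-12:
                count += 1
        statistic, p = diff, (count + 1) / (n_perm + 1)
    else:
        raise ValueError(f"unknown method {method!r}")
    boot = np.empty(n_boot)
    for i in range(n_boot):
        boot[i] = (
            a[rng.integers(0, a.size, a.size)].mean()
            - b[rng.integers(0, b.size, b.size)].mean()
        )
    ci = (float(np.quantile(boot, 0.025)), float(np.quantile(boot, 0.975)))
    direction = levels[0] if diff > 0 else levels[1] if diff < 0 else ""
    return TwoGroupResult(float(statistic), float(p), direction, ci, method)


def multi_group_test(values, groups) -> tuple[float, float, float, pd.DataFrame]:
    """Kruskal-Wallis across >= 3 groups with eta^2 and Tukey-Kramer post hoc.

    Returns (H, p, eta_squared, pairwise table).  eta^2 = (H - k + 1)/(n - k).
    The post hoc step is classic Tukey-Kramer on group means with the
    unequal-n correction, p-values from the studentized range distribution.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    levels = list(pd.unique(groups))
    k = len(levels)
    if k < 3:
        raise ValueError("multi_group_test requires at least 3 groups")
    split = [values[groups == g] for g in levels]
    sizes = np.array([s.size for s in split])
    if (sizes < 2).any():
        raise ValueError("every group needs at least 2 values")
    n = int(sizes.sum())
    h, p = stats.kruskal(*split)
    eta2 = (h - k + 1) / (n - k)
    # Tukey-Kramer
    means = np.array([s.mean() for s in split])
    msw = sum(((s - s.mean()) ** 2).sum() for s in split) / (n - k)
    rows = []
    for i in range(k):
        for j in range(i + 1, k):
            se = np.sqrt(msw / 2.0 * (1.0 / sizes[i] + 1.0 / sizes[j]))
            q = abs(means[i] - means[j]) / se if se > 0 else np.inf
            pq = float(stats.studentized_range.sf(q, k, n - k)) if np.isfinite(q) else 0.0
            rows.append(
                {
                    "group1": levels[i],
                    "group2": levels[j],
                    "mean_diff": float(means[i] - means[j]),
                    "q": float(q),
                    "p": pq,
                }
            )
    return float(h), float(p), float(eta2), pd.DataFrame(rows)


def trend_summary(
    features: pd.DataFrame,
    bins: pd.Series,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Monotone-trend screen of features against ordered bins.

    ``features``: feature x sample abundance frame; ``bins``: ordered
    categorical per sample.  Spearman rho of abundance against the ordinal
    bin index, BH correction across the whole feature family, and a
    direction label (increasing / decreasing / none; constant features or
    BH p >= alpha give none).
    """
    bins = bins.reindex(features.columns)
    if not isinstance(bins.dtype, pd.CategoricalDtype) or not bins.cat.ordered:
        bins = pd.Categorical(bins, ordered=True)
        bins = pd.Series(bins, index=features.columns)
    codes = bins.cat.codes.to_numpy()
    keep = codes >= 0  # drop samples with NA bins
    if len(np.unique(codes[keep])) < 3:
        raise ValueError("need at least 3 ordered bins with data")
    rows = []
    for fid, row in features.iterrows():
        x = row.to_numpy(dtype=float)[keep]
        if np.ptp(x) == 0:
            rows.append({"feature": fid, "rho": np.nan, "p": 1.0})
            continue
        rho, p = stats.spearmanr(x, codes[keep])
        rows.append({"feature": fid, "rho": float(rho), "p": float(p)})
    out = pd.DataFrame(rows).set_index("feature")
    out["p_bh"] = multipletests(out["p"].to_numpy(), method="fdr_bh")[1]
    out["direction"] = "none"
    sig = out["p_bh"] < alpha
    out.loc[sig & (out["rho"] > 0), "direction"] = "increasing"
    out.loc[sig & (out["rho"] < 0), "direction"] = "decreasing"
    return out
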