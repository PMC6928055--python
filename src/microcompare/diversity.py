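"""Per-sample alpha diversity (Shannon, Gini-Simpson, Chao1) and group tests.

Shannon uses the natural log by default (the vegan convention), Simpson is
the Gini-Simpson probability ``1 - sum(p^2)``, and Chao1 is the
bias-corrected richness estimator ``S_obs + F1(F1-1)/(2(F2+1))`` (defined
even without doubletons).  Group comparison is the two-sided Wilcoxon
rank-sum test with Benjamini-Hochberg correction across the whole family of
(metric, group-pair) tests emitted together.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .tables import AbundanceTable

__all__ = ["shannon", "simpson", "chao1", "alpha_diversity", "compare_groups"]


def _proportions(x) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError("expected a single sample (1-D vector)")
    if (x < 0).any():
        raise ValueError("negative abundances")
    total = x.sum()
    if total == 0:
        raise ValueError("all-zero sample")
    return x / total


def shannon(x, base: float | None = None) -> float:
    """Shannon entropy H = -sum p_i log p_i (natural log unless ``base``)."""
    p = _proportions(x)
    p = p[p > 0]
    h = float(-(p * np.log(p)).sum())
    return h / np.log(base) if base else h


def simpson(x) -> float:
    """Gini-Simpson index D = 1 - sum p_i^2."""
    p = _proportions(x)
    return float(1.0 - (p**2).sum())


def chao1(counts) -> float:
    """Bias-corrected Chao1 richness: S_obs + F1(F1-1)/(2(F2+1))."""
    c = np.asarray(counts)
    if not np.allclose(c, np.round(c)):
        raise ValueError("chao1 requires integer counts")
    c = np.round(c).astype(np.int64)
    if (c < 0).any():
        raise ValueError("negative counts")
    if c.sum() == 0:
        raise ValueError("all-zero sample")
    s_obs = int((c > 0).sum())
    f1 = int((c == 1).sum())
    f2 = int((c == 2).sum())
    return s_obs + f1 * (f1 - 1) / (2.0 * (f2 + 1))


_METRICS = {"shannon": shannon, "simpson": simpson, "chao1": chao1}


def alpha_diversity(
    table: AbundanceTable, metrics: tuple[str, ...] = ("shannon", "simpson", "chao1")
) -> pd.DataFrame:
    """Per-sample index values, one row per sample, one column per metric.

    Chao1 needs counts; Shannon and Simpson accept either counts or
    proportions (they are scale-invariant).
    """
    unknown = set(metrics) - set(_METRICS)
    if unknown:
        raise ValueError(f"unknown metrics: {sorted(unknown)}")
    if "chao1" in metrics and table.kind != "counts":
        raise ValueError("chao1 requires a counts table")
    vals = table.values()
    out = {m: [float(_METRICS[m](vals[:, j])) for j in range(table.n_samples)] for m in metrics}
    return pd.DataFrame(out, index=table.sample_ids)


def rank_sum_test(a, b) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney).

    Exact enumeration for small tie-free groups, mid-ranks with normal
    approximation and continuity correction otherwise (scipy's 'auto' rule).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 samples")
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method="auto")
    return float(res.statistic), float(res.pvalue)


def compare_groups(
    diversity: pd.DataFrame,
    grouping: pd.Series,
    pairwise: bool = True,
) -> pd.DataFrame:
    """Rank-sum tests of every metric between groups, BH-corrected jointly.

    ``grouping`` maps sample id -> group label.  With ``pairwise`` (default)
    all unordered group pairs are tested, reproducing the
    region-by-region design; otherwise exactly two groups are required.
    BH correction is applied across all rows emitted together.
    """
    grouping = grouping.reindex(diversity.index)
    if grouping.isna().any():
        raise ValueError("grouping missing for some samples")
    levels = list(pd.unique(grouping))
    if len(levels) < 2:
        raise ValueError("need at least two groups")
    if not pairwise and len(levels) != 2:
        raise ValueError("pairwise=False requires exactly two groups")
    pairs = list(itertools.combinations(levels, 2))
    rows = []
    for metric in diversity.columns:
        for g1, g2 in pairs:
            a = diversity.loc[grouping == g1, metric].to_numpy()
            b = diversity.loc[grouping == g2, metric].to_numpy()
            w, p = rank_sum_test(a, b)
            rows.append(
                {"metric": metric, "group1": g1, "group2": g2, "statistic": w, "p": p}
            )
    out = pd.DataFrame(rows)
    out["p_bh"] = multipletests(out["p"].to_numpy(), method="fdr_bh")[1]
    return out
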