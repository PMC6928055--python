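"""Core-microbiota identification with bootstrap stability scoring.

A feature qualifies as *core* in a cohort when it is present at >= 0.1%
relative abundance in >= 70% of the cohort's samples.  To guard against
fragile calls, the qualification is repeated over bootstrap resamples of
the cohort (default 1000 draws with replacement, resample size = n); the
*bootstrap score* is the percentage of resamples in which the feature
qualified (0-100), and a feature is called core when its score clears a
cutoff (default 80).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .tables import AbundanceTable

__all__ = ["core_qualifies", "bootstrap_core", "compare_cores"]


def core_qualifies(
    table: AbundanceTable,
    min_prevalence: float = 0.70,
    min_abund: float = 0.001,
) -> set[str]:
    """Features at >= ``min_abund`` relative abundance in >= ``min_prevalence``
    of the samples."""
    if table.kind != "relative":
        raise ValueError("core_qualifies requires a relative table")
    if table.n_samples == 0:
        raise ValueError("empty cohort")
    hits = (table.values() >= min_abund).mean(axis=1)
    return set(table.data.index[hits >= min_prevalence])


def bootstrap_core(
    table: AbundanceTable,
    iterations: int = 1000,
    subset_size: int | None = None,
    replace: bool = True,
    seed: int = 0,
    min_prevalence: float = 0.70,
    min_abund: float = 0.001,
    score_cutoff: float = 80.0,
) -> pd.DataFrame:
    """Bootstrap-score every feature's core status within one cohort.

    Each iteration draws ``subset_size`` samples (default n, with
    replacement -- an ordinary bootstrap) and re-evaluates the
    prevalence/abundance rule; the score is 100 x the fraction of
    iterations in which the feature qualified.  Returns one row per
    feature: ``prevalence`` (at the abundance threshold, on the full
    cohort), ``median_abundance``, ``bootstrap_score`` and ``is_core``
    (score >= ``score_cutoff``).  Deterministic given ``seed``.
    """
    if table.kind != "relative":
        raise ValueError("bootstrap_core requires a relative table")
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    n = table.n_samples
    size = n if subset_size is None else int(subset_size)
    if size < 2:
        raise ValueError("subset_size must be >= 2")
    if size > n and not replace:
        raise ValueError("subset_size exceeds cohort size for draws without replacement")

    vals = table.values()
    above = vals >= min_abund  # features x samples
    rng = np.random.default_rng(seed)
    appearances = np.zeros(table.n_features, dtype=np.int64)
    for _ in range(iterations):
        idx = rng.choice(n, size=size, replace=replace)
        appearances += above[:, idx].mean(axis=1) >= min_prevalence
    score = 100.0 * appearances / iterations
    report = pd.DataFrame(
        {
            "prevalence": above.mean(axis=1),
            "median_abundance": np.median(vals, axis=1),
            "bootstrap_score": score,
            "is_core": score >= score_cutoff,
        },
        index=table.data.index,
    )
    report.attrs["score_cutoff"] = score_cutoff
    return report


def compare_cores(report_a: pd.DataFrame, report_b: pd.DataFrame, labels=("TR", "UR")) -> dict:
    """Shared/exclusive core sets of two cohort reports over one universe.

    Returns shared and per-cohort-exclusive core feature lists plus a
    median-abundance table in which features failing the score cutoff in a
    cohort carry NA for that cohort.
    """
    if set(report_a.index) != set(report_b.index):
        raise ValueError("core reports cover different feature universes")
    report_b = report_b.reindex(report_a.index)
    core_a = set(report_a.index[report_a["is_core"]])
    core_b = set(report_b.index[report_b["is_core"]])
    either = sorted(core_a | core_b)
    medians = pd.DataFrame(index=pd.Index(either, name="feature"))
    for label, rep, core in ((labels[0], report_a, core_a), (labels[1], report_b, core_b)):
        med = rep.loc[either, "median_abundance"].copy()
        med[[f not in core for f in either]] = np.nan  # NA: failed the score cutoff
        medians[f"median_{label}"] = med
        medians[f"score_{label}"] = rep.loc[either, "bootstrap_score"]
    return {
        "shared": sorted(core_a & core_b),
        f"{labels[0]}_exclusive": sorted(core_a - core_b),
        f"{labels[1]}_exclusive": sorted(core_b - core_a),
        "medians": medians,
    }
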