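"""Planted-truth benchmark studies for every pipeline stage.

Each builder assembles a synthetic two-cohort study shaped like the
tribal/urban comparison (75 + 80 samples, uniform 10k-60k read depths) with
one stage's ground truth planted, and returns everything needed to score
recovery.  The test-suite and the reproduction script both draw their
inputs from here, so the evaluated conditions are defined once.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .simulate import (
    CohortSpec,
    PlantedCore,
    PlantedEffect,
    default_spec,
    diversity_gap_spec,
    generate_cohorts,
    lognormal_component,
)

__all__ = [
    "diversity_gap_study",
    "two_cluster_study",
    "dmm_study",
    "core_study",
    "effect_study",
    "network_study",
    "separable_study",
]


def diversity_gap_study(seed: int, scale: float = 5.0):
    """75 TR / 80 UR cohorts with TR's components flattened (scale x) toward
    uniformity -- the planted diversity gap."""
    spec = diversity_gap_spec(default_spec(n_features=300, seed=seed), "TR", scale)
    return generate_cohorts(spec)


def two_cluster_study(seed: int):
    """Two cohorts with distinct dominant components: true cluster count 2."""
    return generate_cohorts(default_spec(n_features=200, seed=seed))


def dmm_study(seed: int, n_components: int = 3, n_features: int = 100):
    """150 samples from ``n_components`` distinct Dirichlet-multinomial
    components (TR mixes the first two, UR is the third); truth in
    ``meta['component']``."""
    comps = [
        lognormal_component(n_features, seed=seed * 10 + i, label=f"comp{i}")
        for i in range(n_components)
    ]
    w_tr = np.zeros(n_components)
    w_tr[: max(n_components - 1, 1)] = 1.0 / max(n_components - 1, 1)
    w_ur = np.zeros(n_components)
    w_ur[-1] = 1.0
    spec = CohortSpec(
        n_samples={"TR": 75, "UR": 75},
        n_features=n_features,
        components=comps,
        component_weights={"TR": w_tr, "UR": w_ur},
        seed=seed,
    )
    return generate_cohorts(spec)


def core_study(seed: int):
    """Planted core structure: 5 shared cores, 3 TR-exclusive cores, and 5
    low-prevalence decoys; returns (table, meta, truth dict)."""
    n_features = 150
    comp = lognormal_component(n_features, seed=4242, label="shared")
    shared = [PlantedCore(i, 0.92, 0.01) for i in range(5)]
    # TR-exclusive cores are pinned to low prevalence in UR so their natural
    # component abundance cannot make them core there by accident
    tr_only = [PlantedCore(i, 0.92, 0.01, cohort="TR") for i in range(5, 8)]
    tr_only += [PlantedCore(i, 0.20, 0.005, cohort="UR") for i in range(5, 8)]
    decoys = [PlantedCore(i, 0.40, 0.01) for i in range(8, 13)]
    spec = CohortSpec(
        n_samples={"TR": 75, "UR": 80},
        n_features=n_features,
        components=[comp],
        component_weights={"TR": np.array([1.0]), "UR": np.array([1.0])},
        planted_core=shared + tr_only + decoys,
        seed=seed,
    )
    table, meta = generate_cohorts(spec)
    fid = lambda i: f"OTU_{i + 1}"
    truth = {
        "shared": {fid(i) for i in range(5)},
        "tr_only": {fid(i) for i in range(5, 8)},
        "decoys": {fid(i) for i in range(8, 13)},
    }
    return table, meta, truth


def effect_study(seed: int, fold: float = 8.0, n_features: int = 200):
    """5 planted fold-change effects among ``n_features`` shared-component
    features (~0.5% baseline abundance); ``fold=1`` gives pure null data.
    Returns (table, meta, set of planted feature ids)."""
    comp = lognormal_component(n_features, seed=1234, label="shared")
    target = 0.005 * comp.alpha.sum()  # ~0.5% mean relative abundance
    cand = np.argsort(np.abs(comp.alpha - target))[:5]
    effects = [
        PlantedEffect(int(f), "TR" if i % 2 == 0 else "UR", fold)
        for i, f in enumerate(cand)
    ]
    spec = CohortSpec(
        n_samples={"TR": 75, "UR": 80},
        n_features=n_features,
        components=[comp],
        component_weights={"TR": np.array([1.0]), "UR": np.array([1.0])},
        planted_effects=effects if fold != 1 else [],
        seed=seed,
    )
    table, meta = generate_cohorts(spec)
    truth = {f"OTU_{int(f) + 1}" for f in cand} if fold != 1 else set()
    return table, meta, truth


def network_study(seed: int, n_independent: int = 50, n_samples: int = 80, rho: float = 0.9):
    """Independent features plus one planted correlated pair (ids 'pair_a',
    'pair_b'); returns a node x sample frame."""
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n_independent, n_samples))
    a = rng.normal(size=n_samples)
    b = rho * a + np.sqrt(1 - rho**2) * rng.normal(size=n_samples)
    ids = [f"ind_{i}" for i in range(n_independent)] + ["pair_a", "pair_b"]
    cols = [f"S_{j + 1}" for j in range(n_samples)]
    return pd.DataFrame(np.vstack([X, a, b]), index=ids, columns=cols)


def separable_study(seed: int, n_features: int = 120):
    """Cohorts drawn from different components: essentially separable."""
    return generate_cohorts(default_spec(n_features=n_features, seed=seed))
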