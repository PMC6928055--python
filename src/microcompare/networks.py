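"""Co-occurrence networks from Spearman correlations with a randomization null.

Edges between features (taxa, function abundances, diversity indices,
numeric metadata) are called when the observed Spearman correlation clears
BOTH a BH-corrected p-value cutoff and a *critical r* derived from a
pair-swap randomization null:

* ``swap_null`` runs a random walk over tables: at each step, every feature
  row independently swaps the values of one uniformly chosen sample pair,
  and all pairwise correlations of the walking table are recorded.  The
  walk's stationary law is an independent per-row permutation of samples,
  i.e. the exact permutation null; the pooled correlations form the null
  distribution (its mean is the "expectancy value").  ``mode="fresh"``
  instead perturbs the original table by a single swap per row each step.
* ``critical_r`` is the two-sided |r| quantile of that null at the chosen
  confidence (default 99%).

The observed table is never mutated.  Networks export as Cytoscape-readable
SIF, GraphML, or an edge TSV.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import networkx as nx
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "spearman_matrix",
    "swap_null",
    "critical_r",
    "CorrelationNetwork",
    "build_network",
    "export_network",
    "read_sif",
]


def _as_frame(block) -> pd.DataFrame:
    frame = block.data if hasattr(block, "data") else pd.DataFrame(block)
    return frame.astype(float)


def stack_blocks(blocks: dict[str, pd.DataFrame]) -> tuple[pd.DataFrame, pd.Series]:
    """Align feature blocks (taxa/functions/diversity/metadata) on samples.

    ``blocks`` maps a node kind to a feature x sample frame; samples are
    intersected, rows concatenated.  Returns the stacked frame and a
    node-kind Series.
    """
    frames = {k: _as_frame(v) for k, v in blocks.items()}
    common = None
    for f in frames.values():
        common = f.columns if common is None else common.intersection(f.columns)
    if common is None or len(common) < 4:
        raise ValueError("need at least 4 common samples across blocks")
    stacked = pd.concat([f[common] for f in frames.values()], axis=0)
    kinds = pd.Series(
        np.repeat(list(frames), [len(f) for f in frames.values()]), index=stacked.index
    )
    if stacked.index.has_duplicates:
        raise ValueError("duplicate node ids across blocks")
    return stacked, kinds


def spearman_matrix(
    features: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """All-pairs Spearman (mid-rank ties) with raw and BH-corrected p-values.

    ``features`` is a node x sample frame with >= 4 samples.  Constant rows
    yield NA correlations (excluded from the BH family).  BH is applied
    across all emitted (upper-triangle) pairs jointly.
    """
    X = features.to_numpy(dtype=float)
    if X.shape[1] < 4:
        raise ValueError("need at least 4 samples")
    r, p = stats.spearmanr(X, axis=1)
    if np.ndim(r) == 0:  # scipy collapses the 2-variable case to a scalar
        r = np.array([[1.0, float(r)], [float(r), 1.0]])
        p = np.array([[0.0, float(p)], [float(p), 0.0]])
    const = np.ptp(X, axis=1) == 0
    r[const, :] = r[:, const] = np.nan
    p[const, :] = p[:, const] = np.nan
    np.fill_diagonal(r, 1.0)
    np.fill_diagonal(p, 0.0)
    iu = np.triu_indices_from(r, k=1)
    flat_p = p[iu]
    bh = np.full_like(flat_p, np.nan)
    ok = ~np.isnan(flat_p)
    if ok.any():
        bh[ok] = multipletests(flat_p[ok], method="fdr_bh")[1]
    p_bh = np.full_like(p, np.nan)
    p_bh[iu] = bh
    p_bh.T[iu] = bh
    np.fill_diagonal(p_bh, 0.0)
    ids = features.index
    return (
        pd.DataFrame(r, index=ids, columns=ids),
        pd.DataFrame(p, index=ids, columns=ids),
        pd.DataFrame(p_bh, index=ids, columns=ids),
    )


def swap_null(
    features: pd.DataFrame,
    steps: int = 10_000,
    seed: int = 0,
    mode: str = "walk",
) -> np.ndarray:
    """Pair-swap randomization null of all pairwise Spearman correlations.

    Each step swaps one uniformly chosen sample pair independently within
    every feature row and records every off-diagonal pairwise correlation
    of the current table; the pooled values over all steps are returned
    (float32).  ``mode="walk"`` (default) lets swaps accumulate -- the walk
    mixes to independent per-row permutations; ``mode="fresh"`` restarts
    from the observed table at every step.  The input is never mutated.
    """
    if steps < 1:
        raise ValueError("steps must be >= 1")
    if mode not in ("walk", "fresh"):
        raise ValueError(f"unknown mode {mode!r}")
    X = features.to_numpy(dtype=float)
    f, n = X.shape
    if f < 2 or n < 3:
        raise ValueError("need at least 2 features and 3 samples")
    # Spearman = Pearson on ranks; swapping values within a row permutes the
    # ranks identically, so we walk on standardized ranks and use matmuls.
    ranks = stats.rankdata(X, axis=1)
    z = ranks - ranks.mean(axis=1, keepdims=True)
    sd = z.std(axis=1, keepdims=True)
    const = sd[:, 0] == 0
    sd[const] = 1.0
    z = z / (sd * np.sqrt(n))
    rng = np.random.default_rng(seed)
    iu = np.triu_indices(f, k=1)
    null = np.empty((steps, iu[0].size), dtype=np.float32)
    cur = z.copy()
    rows = np.arange(f)
    for t in range(steps):
        if mode == "fresh":
            cur = z.copy()
        i = rng.integers(0, n, size=f)
        j = rng.integers(0, n - 1, size=f)
        j = np.where(j >= i, j + 1, j)  # j != i, uniform over pairs
        ci, cj = cur[rows, i].copy(), cur[rows, j]
        cur[rows, i] = cj
        cur[rows, j] = ci
        corr = cur @ cur.T
        null[t] = corr[iu]
    if const.any():
        keep = ~(const[iu[0]] | const[iu[1]])
        null = null[:, keep]
    return null.ravel()


def critical_r(null: np.ndarray, confidence: float = 0.99) -> float:
    """Two-sided critical correlation: the ``confidence`` quantile of |null r|.

    Linear-interpolation (type-7) quantile; monotone non-decreasing in the
    confidence level.
    """
    null = np.asarray(null)
    if null.size == 0:
        raise ValueError("empty null sample")
    if not 0 < confidence < 1:
        raise ValueError("confidence must lie in (0, 1)")
    return float(np.quantile(np.abs(null), confidence))


@dataclass
class CorrelationNetwork:
    graph: nx.Graph
    critical_r: float
    confidence: float
    p_cutoff: float
    null_summary: dict = field(default_factory=dict)

    @property
    def edges(self) -> pd.DataFrame:
        rows = [
            {"source": u, "target": v, "r": d["r"], "sign": d["sign"]}
            for u, v, d in self.graph.edges(data=True)
        ]
        return pd.DataFrame(rows, columns=["source", "target", "r", "sign"])


def build_network(
    r_obs: pd.DataFrame,
    p_bh: pd.DataFrame,
    critical_r: float,
    p_cutoff: float = 0.01,
    confidence: float = 0.99,
    node_kinds: pd.Series | None = None,
    null: np.ndarray | None = None,
) -> CorrelationNetwork:
    """Call edges where |r| > critical_r AND BH-p < p_cutoff.

    Undirected, no self-edges; edge sign is the sign of r.  ``node_kinds``
    annotates nodes (taxon/otu/function/diversity/metadata).  The null
    summary records the expectancy value (null mean) and quantiles.
    """
    if list(r_obs.index) != list(p_bh.index) or list(r_obs.columns) != list(p_bh.columns):
        raise ValueError("r and p matrices are not aligned")
    g = nx.Graph()
    for node in r_obs.index:
        g.add_node(node, kind=str(node_kinds.get(node, "feature")) if node_kinds is not None else "feature")
    ids = list(r_obs.index)
    rv = r_obs.to_numpy()
    pv = p_bh.to_numpy()
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            r = rv[i, j]
            p = pv[i, j]
            if np.isnan(r) or np.isnan(p):
                continue
            if abs(r) > critical_r and p < p_cutoff:
                g.add_edge(
                    ids[i], ids[j], r=float(r), sign="+" if r > 0 else "-", passed=True
                )
    summary = {}
    if null is not None:
        null = np.asarray(null, dtype=float)
        summary = {
            "expectancy": float(null.mean()),
            "q01": float(np.quantile(null, 0.01)),
            "q50": float(np.quantile(null, 0.50)),
            "q99": float(np.quantile(null, 0.99)),
        }
    return CorrelationNetwork(
        graph=g,
        critical_r=float(critical_r),
        confidence=confidence,
        p_cutoff=p_cutoff,
        null_summary=summary,
    )


def export_network(net: CorrelationNetwork, path, fmt: str = "sif") -> None:
    """Write the network as SIF (``source  sign  target``), GraphML or edge TSV."""
    if fmt == "sif":
        with open(path, "wt", encoding="utf-8") as fh:
            for u, v, d in net.graph.edges(data=True):
                fh.write(f"{u}\t{d['sign']}\t{v}\n")
    elif fmt == "graphml":
        nx.write_graphml(net.graph, path)
    elif fmt == "tsv":
        net.edges.to_csv(path, sep="\t", index=False)
    else:
        raise ValueError(f"unknown format {fmt!r}")


def read_sif(path) -> list[tuple[str, str, str]]:
    """Parse a SIF file back into (source, sign, target) triples."""
    out = []
    with open(path, "rt", encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            u, sign, v = line.split("\t")
            out.append((u, sign, v))
    return out
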