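"""Enterotype analysis: JSD ordination, PAM/CH clustering and DMM mixtures.

Two complementary routes to community types are provided:

* **Distance-based**: root Jensen-Shannon divergence between sample
  profiles, classical PCoA ordination, partitioning-around-medoids (PAM)
  clustering, and Calinski-Harabasz (CH) selection of the cluster count.
* **Model-based**: Dirichlet-multinomial mixtures (DMM) fitted by EM with
  Minka fixed-point concentration updates; the number of components is
  chosen by minimizing the Laplace-approximated negative model evidence
  ("Laplace score").

The root-JSD (a true metric) is the default distance, matching the classic
enterotyping convention; raw JSD is available with ``sqrt=False``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import digamma, gammaln, logsumexp, polygamma
from sklearn.cluster import KMeans
from sklearn.metrics import calinski_harabasz_score
from skbio import DistanceMatrix

from .tables import AbundanceTable

__all__ = [
    "jsd_distance",
    "pcoa",
    "PcoaResult",
    "pam",
    "ClusteringResult",
    "ch_index",
    "optimal_k",
    "EnterotypeModel",
    "fit_dmm",
    "select_k_dmm",
]


# -- Jensen-Shannon distance --------------------------------------------


def jsd_distance(
    table: AbundanceTable, pseudocount: float = 1e-6, sqrt: bool = True
) -> DistanceMatrix:
    """Pairwise (root) Jensen-Shannon divergence between sample profiles.

    Zeros are replaced by ``pseudocount`` and columns renormalized before
    the divergence (natural log) is computed.  With ``sqrt=True`` (default)
    the returned values are sqrt(JSD), a true metric bounded by sqrt(ln 2).
    """
    if table.kind != "relative":
        raise ValueError("jsd_distance requires a relative table")
    p = table.values()
    if pseudocount:
        p = np.where(p == 0, pseudocount, p)
        p = p / p.sum(axis=0)
    # JSD(P,Q) = H(M) - (H(P)+H(Q))/2 with M the midpoint
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(p > 0, p * np.log(p), 0.0)
    h = -plogp.sum(axis=0)
    n = p.shape[1]
    d = np.zeros((n, n))
    for i in range(n):
        m = 0.5 * (p[:, i : i + 1] + p[:, i + 1 :])
        with np.errstate(divide="ignore", invalid="ignore"):
            hm = -np.where(m > 0, m * np.log(m), 0.0).sum(axis=0)
        jsd = hm - 0.5 * (h[i] + h[i + 1 :])
        d[i, i + 1 :] = d[i + 1 :, i] = np.maximum(jsd, 0.0)
    if sqrt:
        d = np.sqrt(d)
    return DistanceMatrix(d, ids=table.sample_ids)


# -- PCoA ----------------------------------------------------------------


@dataclass
class PcoaResult:
    """Classical-scaling embedding with the full eigenvalue spectrum."""

    coordinates: pd.DataFrame  # samples x axes, ordered by eigenvalue
    eigenvalues: np.ndarray  # all eigenvalues, negatives included

    def positive_axes(self) -> np.ndarray:
        """Embedding restricted to axes with positive eigenvalues."""
        keep = np.flatnonzero(self.eigenvalues > 1e-9 * max(self.eigenvalues.max(), 1))
        return self.coordinates.to_numpy()[:, keep]


def pcoa(dist: DistanceMatrix) -> PcoaResult:
    """Principal coordinate analysis of a distance matrix.

    Classical scaling: eigendecomposition of the double-centered squared
    distances, axes ordered by decreasing eigenvalue.  Negative eigenvalues
    -- possible whenever the distance is non-Euclidean -- are reported in
    ``eigenvalues`` rather than silently dropped; their axes carry zero
    coordinates.
    """
    d = dist.data
    if not np.allclose(d, d.T, atol=1e-12):
        raise ValueError("distance matrix must be symmetric")
    n = d.shape[0]
    centered = np.eye(n) - np.ones((n, n)) / n
    gram = -0.5 * centered @ (d**2) @ centered
    eigvals, eigvecs = np.linalg.eigh((gram + gram.T) / 2.0)
    order = np.argsort(eigvals)[::-1]
    eigvals = eigvals[order]
    eigvecs = eigvecs[:, order]
    coords = eigvecs * np.sqrt(np.maximum(eigvals, 0.0))[None, :]
    frame = pd.DataFrame(
        coords, index=list(dist.ids), columns=[f"PC{i + 1}" for i in range(n)]
    )
    return PcoaResult(coordinates=frame, eigenvalues=eigvals)


# -- PAM clustering ------------------------------------------------------


@dataclass
class ClusteringResult:
    k: int
    medoids: np.ndarray  # sample indices
    assignment: np.ndarray  # medoid slot per sample
    cost: float  # total distance to assigned medoids
    ch: float | None = None

    def labels(self) -> np.ndarray:
        return self.assignment


def _assign(d: np.ndarray, medoids: np.ndarray) -> tuple[np.ndarray, float]:
    sub = d[medoids]  # k x n
    # ties broken toward the lowest medoid slot (argmin convention)
    assignment = sub.argmin(axis=0)
    cost = float(sub[assignment, np.arange(d.shape[0])].sum())
    return assignment, cost


def _pam_swap(d: np.ndarray, medoids: np.ndarray, k: int, max_iter: int) -> tuple:
    n = d.shape[0]
    medoids = np.array(sorted(medoids))
    assignment, cost = _assign(d, medoids)
    for _ in range(max_iter):
        best = (0.0, None)
        others = np.setdiff1d(np.arange(n), medoids)
        for slot in range(k):
            trial = medoids.copy()
            for h in others:
                trial[slot] = h
                _, c = _assign(d, trial)
                delta = c - cost
                if delta < best[0] - 1e-12:
                    best = (delta, (slot, h))
        if best[1] is None:
            break
        slot, h = best[1]
        medoids[slot] = h
        medoids = np.array(sorted(medoids))
        assignment, cost = _assign(d, medoids)
    return medoids, assignment, cost


def pam(
    dist: DistanceMatrix, k: int, seed: int = 0, max_iter: int = 300, restarts: int = 4
) -> ClusteringResult:
    """Partitioning around medoids: greedy BUILD then steepest-descent SWAP.

    BUILD seeds the first medoid as the 1-median and adds the point giving
    the largest cost decrease; SWAP repeatedly applies the single best
    (medoid, non-medoid) exchange until no swap lowers the cost, so the
    cost is non-increasing.  Because single-swap descent can stall in local
    optima, ``restarts`` additional SWAP passes from seeded random medoid
    sets are run and the cheapest solution kept.  Ties are broken by lowest
    sample index; deterministic given ``seed``.
    """
    d = dist.data
    n = d.shape[0]
    if not 2 <= k <= n:
        raise ValueError(f"k must be in [2, {n}], got {k}")
    # BUILD
    medoids = [int(d.sum(axis=1).argmin())]
    while len(medoids) < k:
        current = d[medoids].min(axis=0)
        gains = np.maximum(current[None, :] - d, 0.0).sum(axis=1)
        gains[medoids] = -np.inf
        medoids.append(int(gains.argmax()))
    best = _pam_swap(d, np.array(medoids), k, max_iter)
    rng = np.random.default_rng(seed)
    for _ in range(restarts):
        init = rng.choice(n, size=k, replace=False)
        cand = _pam_swap(d, init, k, max_iter)
        if cand[2] < best[2] - 1e-12:
            best = cand
    medoids, assignment, cost = best
    return ClusteringResult(k=k, medoids=medoids, assignment=assignment, cost=cost)


def ch_index(embedding: np.ndarray, assignment: np.ndarray) -> float:
    """Calinski-Harabasz index [SS_B/(k-1)] / [SS_W/(n-k)] on an embedding."""
    if len(np.unique(assignment)) < 2:
        raise ValueError("CH index needs at least two clusters")
    return float(calinski_harabasz_score(np.asarray(embedding), np.asarray(assignment)))


def optimal_k(
    dist: DistanceMatrix, k_max: int = 7, seed: int = 0
) -> tuple[int, dict[int, float], dict[int, ClusteringResult]]:
    """PAM for k = 2..k_max, scored by CH on the positive-axis PCoA embedding.

    Returns (best k, CH per k, clustering per k).
    """
    n = len(dist.ids)
    if not 2 <= k_max < n:
        raise ValueError("k_max must lie in [2, n_samples)")
    emb = pcoa(dist).positive_axes()
    scores: dict[int, float] = {}
    fits: dict[int, ClusteringResult] = {}
    for k in range(2, k_max + 1):
        fit = pam(dist, k, seed=seed)
        fit.ch = ch_index(emb, fit.assignment)
        scores[k] = fit.ch
        fits[k] = fit
    best = max(scores, key=lambda k: (scores[k], -k))
    return best, scores, fits


# -- Dirichlet-multinomial mixtures -------------------------------------


@dataclass
class EnterotypeModel:
    """A fitted Dirichlet-multinomial mixture.

    ``log_likelihood`` is the data log likelihood at the optimum;
    ``objective_trace`` is the maximized EM objective per iteration (the log
    posterior when a concentration prior is active), guaranteed
    non-decreasing; ``laplace_score`` is the Laplace-approximated negative
    log model evidence (lower is better).
    """

    K: int
    alpha: np.ndarray  # K x n_features, > 0
    pi: np.ndarray  # mixture weights, sums to 1
    responsibilities: np.ndarray  # n_samples x K, rows sum to 1
    log_likelihood: float
    laplace_score: float
    objective: float = np.nan
    objective_trace: list[float] = field(default_factory=list, repr=False)
    feature_ids: list[str] | None = None

    @property
    def log_likelihood_trace(self) -> list[float]:
        """Alias for the EM objective trace (monotone non-decreasing)."""
        return self.objective_trace

    def hard_assignment(self) -> np.ndarray:
        return self.responsibilities.argmax(axis=1)

    def top_features(self, m: int = 20) -> pd.DataFrame:
        """Top-m features per component by share of the component's alpha mass."""
        rows = []
        ids = self.feature_ids or [f"f{i}" for i in range(self.alpha.shape[1])]
        for k in range(self.K):
            share = self.alpha[k] / self.alpha[k].sum()
            for i in np.argsort(share)[::-1][:m]:
                rows.append(
                    {"component": k, "feature": ids[i], "alpha_share": float(share[i])}
                )
        return pd.DataFrame(rows)


def _dirmult_loglik(X: np.ndarray, alpha: np.ndarray) -> np.ndarray:
    """log DirMult(x_i | alpha_k) for all samples x components.

    X: n x J counts, alpha: K x J.  Returns n x K.  The multinomial
    coefficient is omitted (constant across components).
    """
    A = alpha.sum(axis=1)  # K
    N = X.sum(axis=1)  # n
    term0 = gammaln(A)[None, :] - gammaln(N[:, None] + A[None, :])
    # sum_j lgamma(x_ij + a_kj) - lgamma(a_kj)
    term1 = gammaln(X[:, None, :] + alpha[None, :, :]).sum(axis=2) - gammaln(alpha).sum(
        axis=1
    )[None, :]
    return term0 + term1


def _minka_update(
    X: np.ndarray, z: np.ndarray, alpha: np.ndarray, prior_rate: float, inner: int = 3
) -> np.ndarray:
    """Responsibility-weighted Minka fixed-point update of each component's alpha.

    With ``prior_rate`` > 0 the update maximizes the log posterior under an
    Exp(prior_rate) prior per concentration (the rate adds to the update's
    denominator), keeping estimates off the zero boundary.
    """
    N = X.sum(axis=1)
    new = alpha.copy()
    for k in range(alpha.shape[0]):
        w = z[:, k]
        if w.sum() < 1e-12:
            continue
        a = new[k]
        for _ in range(inner):
            A = a.sum()
            num = (w[:, None] * (digamma(X + a[None, :]) - digamma(a)[None, :])).sum(axis=0)
            den = (w * (digamma(N + A) - digamma(A))).sum() + prior_rate
            if den <= 0:
                break
            a = np.maximum(a * num / den, 1e-10)
        new[k] = a
    return new


def _laplace_score(
    X: np.ndarray,
    model_alpha: np.ndarray,
    z: np.ndarray,
    objective: float,
) -> float:
    """Laplace-approximated negative log model evidence (lower is better).

    score = -[log posterior at the mode + (d/2) ln 2pi - (1/2) ln|H|], with
    H the observed information of the concentration parameters approximated
    block-diagonally per component (responsibilities held fixed).  Each
    curvature direction contributes max(0, (1/2) ln(h/2pi)): flat or
    boundary directions (features absent from a component) are carried by
    their prior mass and cannot inflate the evidence.
    """
    N = X.sum(axis=1)
    penalty = 0.0
    for k in range(model_alpha.shape[0]):
        a = model_alpha[k]
        A = a.sum()
        w = z[:, k]
        diag = (w[:, None] * (polygamma(1, a)[None, :] - polygamma(1, X + a[None, :]))).sum(
            axis=0
        )
        rank1 = (w * (polygamma(1, N + A) - polygamma(1, A))).sum()
        H = np.diag(diag) + rank1  # rank-one term is constant across entries
        eig = np.linalg.eigvalsh(H)
        contrib = 0.5 * np.log(np.clip(eig, 1e-300, None) / (2 * np.pi))
        penalty += float(np.clip(contrib, 0.0, None).sum())
    return -objective + penalty


def fit_dmm(
    table: AbundanceTable,
    K: int,
    seed: int = 0,
    restarts: int = 5,
    tol: float = 1e-8,
    max_iter: int = 1000,
    top_features: int | None = 500,
    prior_rate: float = 1.0,
) -> EnterotypeModel:
    """Fit a K-component Dirichlet-multinomial mixture by EM.

    E-step: responsibilities proportional to pi_k DirMult(x_i | alpha_k).
    M-step: pi from responsibility means; alpha_k by responsibility-weighted
    Minka fixed-point iterations, regularized by a weak Exp(``prior_rate``)
    prior per concentration (``prior_rate=0`` gives plain maximum
    likelihood; the default keeps boundary features identifiable, which the
    Laplace model selection needs).  Convergence when the relative change of
    the EM objective drops below ``tol``; the best of ``restarts`` random
    initializations is kept.  By default only the ``top_features`` most
    abundant features enter the fit (tractability); pass ``None`` for the
    full table.
    """
    if table.kind != "counts":
        raise ValueError("fit_dmm requires a counts table")
    work = table
    if top_features is not None and table.n_features > top_features:
        order = table.data.sum(axis=1).sort_values(ascending=False)
        work = table.select_features(order.index[:top_features])
    X = work.values().T  # n x J
    n, J = X.shape
    if K < 1:
        raise ValueError("K must be >= 1")
    if K > n:
        raise ValueError(f"K={K} exceeds n_samples={n}")
    if (X.sum(axis=1) == 0).any():
        raise ValueError("empty samples are not allowed")

    best: EnterotypeModel | None = None
    for r in range(max(1, restarts)):
        rng = np.random.default_rng(np.random.SeedSequence([int(seed), K, r]))
        model = _fit_dmm_once(X, K, rng, tol, max_iter, prior_rate, kmeans_init=(r == 0))
        if best is None or model.objective > best.objective:
            best = model
    assert best is not None
    best.feature_ids = work.feature_ids
    best.laplace_score = _laplace_score(X, best.alpha, best.responsibilities, best.objective)
    return best


def _fit_dmm_once(X, K, rng, tol, max_iter, prior_rate, kmeans_init=False) -> EnterotypeModel:
    n, J = X.shape
    props = (X + 0.5) / (X + 0.5).sum(axis=1, keepdims=True)
    if K == 1:
        z = np.ones((n, 1))
    elif kmeans_init:
        # soft k-means on log-proportions: a stable, informative start
        km = KMeans(
            n_clusters=K, n_init=5, random_state=int(rng.integers(2**31))
        ).fit(np.log(props))
        z = np.full((n, K), 0.05 / max(K - 1, 1))
        z[np.arange(n), km.labels_] = 0.95
    else:
        # soft random partition, sharpened toward a hard one
        z = rng.dirichlet(np.full(K, 0.2), size=n)
    mean_prop = (z.T @ props) / z.sum(axis=0)[:, None]
    alpha = np.maximum(mean_prop * 30.0, 1e-6)  # moderate initial concentration
    pi = z.mean(axis=0)

    def log_prior(a: np.ndarray) -> float:
        if prior_rate <= 0:
            return 0.0
        return float(a.size * np.log(prior_rate) - prior_rate * a.sum())

    trace: list[float] = []
    objective = -np.inf
    loglik = -np.inf
    for _ in range(max_iter):
        logp = _dirmult_loglik(X, alpha) + np.log(np.maximum(pi, 1e-300))[None, :]
        loglik = float(logsumexp(logp, axis=1).sum())
        new_objective = loglik + log_prior(alpha)
        z = np.exp(logp - logsumexp(logp, axis=1)[:, None])
        trace.append(new_objective)
        if np.isfinite(objective) and abs(new_objective - objective) <= tol * max(
            abs(objective), 1.0
        ):
            objective = new_objective
            break
        objective = new_objective
        pi = np.maximum(z.mean(axis=0), 1e-12)
        pi = pi / pi.sum()
        alpha = _minka_update(X, z, alpha, prior_rate)
    return EnterotypeModel(
        K=K,
        alpha=alpha,
        pi=pi,
        responsibilities=z,
        log_likelihood=loglik,
        laplace_score=np.nan,
        objective=objective,
        objective_trace=trace,
    )


def select_k_dmm(
    table: AbundanceTable,
    k_range=range(1, 8),
    seed: int = 0,
    restarts: int = 3,
    tol: float = 1e-8,
    max_iter: int = 500,
    top_features: int | None = 500,
    prior_rate: float = 1.0,
    top_m: int = 20,
) -> tuple[EnterotypeModel, pd.DataFrame]:
    """Fit DMMs over ``k_range`` and keep the minimum-Laplace-score model.

    Returns the winning model and the per-k score profile (with log
    likelihoods).  The winning model also reports each component's top
    ``top_m`` features by alpha mass.
    """
    k_range = list(k_range)
    if not k_range:
        raise ValueError("k_range must be non-empty")
    rows = []
    models = {}
    for k in k_range:
        m = fit_dmm(
            table,
            k,
            seed=seed,
            restarts=restarts,
            tol=tol,
            max_iter=max_iter,
            top_features=top_features,
            prior_rate=prior_rate,
        )
        models[k] = m
        rows.append(
            {"k": k, "laplace_score": m.laplace_score, "log_likelihood": m.log_likelihood}
        )
    profile = pd.DataFrame(rows).set_index("k")
    best_k = int(profile["laplace_score"].idxmin())
    best = models[best_k]
    profile.attrs["top_features"] = best.top_features(top_m)
    return best, profile
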