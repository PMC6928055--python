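"""JSD distances, PCoA, PAM/CH clustering and DMM mixtures."""

import itertools

import numpy as np
import pandas as pd
import pytest
from skbio import DistanceMatrix
from sklearn.metrics import adjusted_rand_score

import microcompare as mc
from microcompare import AbundanceTable
from microcompare.benchmarks import dmm_study
from microcompare.enterotypes import _laplace_score
from microcompare.simulate import CohortSpec, generate_cohorts, lognormal_component


def rel_table(cols: dict) -> AbundanceTable:
    data = pd.DataFrame(cols)
    data.index = [f"f{i}" for i in range(len(data))]
    return AbundanceTable(data=data, kind="relative")


class TestJsd:
    def test_identical_profiles_zero(self):
        t = rel_table({"a": [0.2, 0.3, 0.5], "b": [0.2, 0.3, 0.5]})
        assert mc.jsd_distance(t)[("a", "b")] == pytest.approx(0.0, abs=1e-8)

    def test_disjoint_supports_maximal(self):
        t = rel_table({"a": [1.0, 0.0], "b": [0.0, 1.0]})
        d = mc.jsd_distance(t, pseudocount=1e-15)
        assert d[("a", "b")] == pytest.approx(np.sqrt(np.log(2)), abs=1e-4)

    def test_hand_computed_fixture(self):
        # P=(1/2,1/2), Q=(1,0): JSD = ln2 - (3/4)ln3 + (1/2)ln2 ... = 0.21576
        t = rel_table({"p": [0.5, 0.5], "q": [1.0, 0.0]})
        d2 = mc.jsd_distance(t, pseudocount=0, sqrt=False)
        assert d2[("p", "q")] == pytest.approx(0.215762, abs=1e-5)
        d = mc.jsd_distance(t, pseudocount=0, sqrt=True)
        assert d[("p", "q")] == pytest.approx(0.464502, abs=1e-5)

    def test_metric_axioms_on_random_triples(self, rng):
        n = 30
        p = rng.dirichlet(np.ones(15) * 0.4, size=n).T
        t = AbundanceTable(
            data=pd.DataFrame(p, columns=[f"s{i}" for i in range(n)]), kind="relative"
        )
        d = mc.jsd_distance(t).data
        assert np.allclose(d, d.T, atol=1e-12)
        assert np.allclose(np.diag(d), 0.0)
        idx = rng.integers(0, n, size=(1000, 3))
        i, j, k = idx.T
        assert (d[i, j] <= d[i, k] + d[k, j] + 1e-10).all()


class TestPcoa:
    def test_equilateral_triangle_two_equal_axes(self):
        d = DistanceMatrix(np.array([[0, 1, 1], [1, 0, 1], [1, 1, 0]], dtype=float))
        res = mc.pcoa(d)
        assert res.eigenvalues[0] == pytest.approx(res.eigenvalues[1], rel=1e-9)
        assert res.eigenvalues[0] > 0

    def test_collinear_points_recovered(self):
        x = np.array([0.0, 1.0, 2.5, 7.0, 11.0])
        d = DistanceMatrix(np.abs(x[:, None] - x[None, :]))
        res = mc.pcoa(d)
        emb = res.coordinates.to_numpy()[:, 0]
        rec = np.abs(emb[:, None] - emb[None, :])
        assert np.allclose(rec, d.data, atol=1e-8)
        assert (np.abs(res.eigenvalues[1:]) < 1e-8 * res.eigenvalues[0]).all()

    def test_permutation_equivariance(self, rng):
        pts = rng.normal(size=(8, 3))
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        ids = [f"s{i}" for i in range(8)]
        res = mc.pcoa(DistanceMatrix(d, ids=ids))
        perm = rng.permutation(8)
        res_p = mc.pcoa(DistanceMatrix(d[np.ix_(perm, perm)], ids=[ids[i] for i in perm]))
        a = res.coordinates.loc[[ids[i] for i in perm]].to_numpy()
        b = res_p.coordinates.to_numpy()
        # same embedding up to per-axis sign
        k = res.positive_axes().shape[1]
        for ax in range(k):
            assert np.allclose(a[:, ax], b[:, ax], atol=1e-8) or np.allclose(
                a[:, ax], -b[:, ax], atol=1e-8
            )

    def test_negative_eigenvalues_reported(self, rng):
        # raw JSD (squared distances non-Euclidean) must expose negatives
        p = rng.dirichlet(np.ones(10) * 0.3, size=12).T
        t = AbundanceTable(
            data=pd.DataFrame(p, columns=[f"s{i}" for i in range(12)]), kind="relative"
        )
        res = mc.pcoa(mc.jsd_distance(t, sqrt=False))
        assert (res.eigenvalues < -1e-12).any()


def brute_force_pam_cost(d: np.ndarray, k: int) -> float:
    n = d.shape[0]
    return min(
        d[list(m)].min(axis=0).sum() for m in itertools.combinations(range(n), k)
    )


class TestPam:
    def test_two_separated_pairs(self):
        d = np.array(
            [
                [0, 1, 9, 9],
                [1, 0, 9, 9],
                [9, 9, 0, 1],
                [9, 9, 1, 0],
            ],
            dtype=float,
        )
        fit = mc.pam(DistanceMatrix(d), 2)
        assert fit.assignment[0] == fit.assignment[1]
        assert fit.assignment[2] == fit.assignment[3]
        assert fit.assignment[0] != fit.assignment[2]

    @pytest.mark.parametrize("n,k", [(6, 2), (7, 3), (8, 2), (8, 4)])
    def test_matches_exhaustive_optimum(self, n, k, rng):
        for _ in range(5):
            pts = rng.normal(size=(n, 2))
            d = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
            fit = mc.pam(DistanceMatrix(d), k)
            assert fit.cost == pytest.approx(brute_force_pam_cost(d, k), abs=1e-9)

    def test_k_equals_n_zero_cost(self, rng):
        pts = rng.normal(size=(5, 2))
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        fit = mc.pam(DistanceMatrix(d), 5)
        assert fit.cost == pytest.approx(0.0, abs=1e-12)

    def test_medoids_belong_to_their_clusters(self, rng):
        pts = rng.normal(size=(20, 2))
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        fit = mc.pam(DistanceMatrix(d), 4)
        for slot, m in enumerate(fit.medoids):
            assert fit.assignment[m] == slot

    def test_k_out_of_range(self):
        d = DistanceMatrix(np.zeros((3, 3)))
        with pytest.raises(ValueError):
            mc.pam(d, 1)


def manual_ch(X, labels):
    n = len(X)
    k = len(np.unique(labels))
    grand = X.mean(axis=0)
    ssb = sum(
        (labels == g).sum() * np.sum((X[labels == g].mean(axis=0) - grand) ** 2)
        for g in np.unique(labels)
    )
    ssw = sum(
        np.sum((X[labels == g] - X[labels == g].mean(axis=0)) ** 2)
        for g in np.unique(labels)
    )
    return (ssb / (k - 1)) / (ssw / (n - k))


class TestChIndex:
    def test_matches_formula_on_fixture(self, rng):
        X = rng.normal(size=(10, 3))
        labels = np.array([0, 0, 0, 1, 1, 1, 2, 2, 2, 2])
        assert mc.ch_index(X, labels) == pytest.approx(manual_ch(X, labels), rel=1e-10)

    def test_two_blobs_argmax_at_two(self, rng):
        pts = np.vstack([rng.normal(0, 0.1, (15, 2)), rng.normal(5, 0.1, (15, 2))])
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        best, scores, _ = mc.optimal_k(DistanceMatrix(d), k_max=6)
        assert best == 2

    def test_single_cluster_rejected(self, rng):
        with pytest.raises(ValueError):
            mc.ch_index(rng.normal(size=(5, 2)), np.zeros(5, dtype=int))


class TestDmm:
    def test_single_component_closed_behaviour(self):
        table, _ = dmm_study(0, n_components=1, n_features=30)
        m = mc.fit_dmm(table, 1, restarts=1, seed=0)
        assert np.allclose(m.responsibilities, 1.0)
        # fitted mean proportions track the empirical mean proportions
        props = table.values() / table.values().sum(axis=0)
        fitted = m.alpha[0] / m.alpha[0].sum()
        order = {f: i for i, f in enumerate(table.feature_ids)}
        fitted_full = np.zeros(table.n_features)
        for f, i in zip(m.feature_ids, range(len(fitted))):
            fitted_full[order[f]] = fitted[i]
        assert np.corrcoef(fitted_full, props.mean(axis=1))[0, 1] > 0.99

    def test_objective_trace_monotone(self):
        table, _ = dmm_study(1, n_components=2, n_features=40)
        m = mc.fit_dmm(table, 2, restarts=2, seed=3)
        trace = np.array(m.objective_trace)
        assert (np.diff(trace) >= -1e-6 * np.abs(trace[:-1])).all()

    def test_responsibilities_row_stochastic(self):
        table, _ = dmm_study(2, n_components=2, n_features=40)
        m = mc.fit_dmm(table, 3, restarts=1, seed=0)
        assert np.allclose(m.responsibilities.sum(axis=1), 1.0, atol=1e-8)
        assert m.pi.sum() == pytest.approx(1.0, abs=1e-9)
        assert (m.alpha > 0).all()

    def test_three_component_recovery(self):
        table, meta = dmm_study(3)
        m = mc.fit_dmm(table, 3, restarts=2, seed=0)
        ari = adjusted_rand_score(meta["component"], m.hard_assignment())
        assert ari >= 0.9

    def test_label_permutation_leaves_laplace_unchanged(self):
        table, _ = dmm_study(4, n_components=2, n_features=40)
        m = mc.fit_dmm(table, 2, restarts=1, seed=1)
        X = table.select_features(m.feature_ids).values().T
        perm = [1, 0]
        score_perm = _laplace_score(
            X, m.alpha[perm], m.responsibilities[:, perm], m.objective
        )
        assert score_perm == pytest.approx(m.laplace_score, rel=1e-12)

    def test_k_exceeding_samples_rejected(self):
        table, _ = dmm_study(5, n_components=1, n_features=20)
        with pytest.raises(ValueError):
            mc.fit_dmm(table, table.n_samples + 1)

    def test_select_k_single_component(self):
        table, _ = dmm_study(6, n_components=1, n_features=50)
        best, profile = mc.select_k_dmm(table, k_range=range(1, 4), seed=0, restarts=2)
        assert best.K == 1
        assert profile["laplace_score"].idxmin() == 1

    def test_top_features_report(self):
        table, _ = dmm_study(7, n_components=2, n_features=40)
        best, profile = mc.select_k_dmm(table, k_range=[2], seed=0, restarts=1, top_m=5)
        top = best.top_features(5)
        assert len(top) == 2 * 5
        assert set(top["feature"]) <= set(table.feature_ids)
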