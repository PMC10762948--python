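"""Behavioural tests for the six DA testing methods on small fixtures."""

import numpy as np
import pandas as pd
import pytest

from dabench.bench import plant_and_assign, run_case
from dabench.evaluate import auroc, score_result
from dabench.methods import (
    Cna,
    Cydar,
    DASeq,
    Louvain,
    Meld,
    Milo,
    build_nam,
    cna_test,
)
from dabench.methods.cna import NamModel
from dabench.methods.base import group_design
from dabench.preprocess import build_knn_graph

SMALL_PARAMS = {
    "cydar": {},
    "daseq": {"n_permutations": 20},
    "meld": {},
    "cna": {"n_permutations": 200},
    "milo": {},
    "louvain": {},
}

ALL_METHODS = list(SMALL_PARAMS)


def _flip_conditions(ds):
    out = ds.copy()
    meta = out.cell_meta
    meta["condition"] = meta["condition"].map({"C1": "C2", "C2": "C1"})
    meta["sample"] = meta["condition"] + "_" + meta["replicate"]
    return out


@pytest.mark.parametrize("method", ALL_METHODS)
def test_parameter_recovery_on_cluster(cluster_base, method):
    """Planted cluster DA at ratio 0.95: target cells rank on top."""
    aucs = []
    for seed in (3, 4, 5):
        res, truth = run_case(
            cluster_base, method, "M1", 0.95, seed=seed, k=40,
            method_params=SMALL_PARAMS[method],
        )
        scores = res.scores.copy()
        scores[res.cell_table["not_assessed"].to_numpy()] = 0.0
        aucs.append(auroc(scores, truth.positive_mask()))
    assert np.median(aucs) > 0.9, f"{method} median AUROC {np.median(aucs)}"


@pytest.mark.parametrize("method", ALL_METHODS)
def test_condition_flip_preserves_score_negates_direction(cluster_case, method):
    ds, _, graph = cluster_case
    cls = {"cydar": Cydar, "daseq": DASeq, "meld": Meld,
           "cna": Cna, "milo": Milo, "louvain": Louvain}[method]
    params = dict(SMALL_PARAMS[method])
    a = cls(ds, graph, **params).fit()
    b = cls(_flip_conditions(ds), graph, **params).fit()
    tol = 0.05 if method == "daseq" else 1e-6  # solver tolerance
    np.testing.assert_allclose(a.scores, b.scores, atol=tol)
    active = (a.scores > tol) & (b.scores > tol)
    np.testing.assert_allclose(
        a.directions[active], -b.directions[active], atol=1e-12
    )


@pytest.mark.parametrize("method", ALL_METHODS)
def test_null_planting_flags_few_cells(cluster_base, method):
    """At DA ratio 0.5 no method may flag a large cell fraction."""
    res, _ = run_case(
        cluster_base, method, "M2", 0.5, seed=9, k=40,
        method_params=SMALL_PARAMS[method],
    )
    assert res.significant_cells.mean() <= 0.2


def test_summary_mentions_method_and_units(cluster_case):
    ds, _, graph = cluster_case
    res = Meld(ds, graph).fit()
    text = res.summary()
    assert "meld" in text
    assert "testing units" in text


class TestMeld:
    def test_likelihoods_are_probabilities(self, cluster_case):
        ds, _, graph = cluster_case
        res = Meld(ds, graph).fit()
        lik = res.cell_table["likelihood_c2"].to_numpy()
        assert np.all((lik >= 0) & (lik <= 1))
        np.testing.assert_allclose(res.scores, np.abs(lik - 0.5), atol=1e-12)

    def test_pure_component_gets_unit_likelihood(self, two_blob_dataset):
        ds = two_blob_dataset
        graph = build_knn_graph(ds.embeddings["pca"], k=5)
        res = Meld(ds, graph).fit()
        lik = res.cell_table["likelihood_c2"].to_numpy()
        blob_b = (ds.cell_meta["population"] == "B").to_numpy()
        np.testing.assert_allclose(lik[blob_b], 1.0, atol=1e-6)

    def test_symmetric_conditions_give_half(self):
        rng = np.random.default_rng(0)
        coords = rng.normal(size=(60, 3))
        counts = rng.poisson(4, (60, 8))
        # perfectly interleaved conditions: same cells support both
        meta = pd.DataFrame(
            {
                "population": ["P"] * 60,
                "condition": ["C1", "C2"] * 30,
                "replicate": ["R1"] * 60,
            },
            index=[f"c{i}" for i in range(60)],
        )
        meta["sample"] = meta["condition"] + "_" + meta["replicate"]
        from dabench.datasets import MultiSampleDataset

        ds = MultiSampleDataset(counts, meta, embeddings={"pca": coords})
        graph = build_knn_graph(coords, k=8)
        lik = Meld(ds, graph).fit().cell_table["likelihood_c2"].to_numpy()
        assert np.abs(lik - 0.5).max() < 0.2

    def test_rejects_bad_beta(self, cluster_case):
        ds, _, graph = cluster_case
        with pytest.raises(ValueError):
            Meld(ds, graph, beta=0.0)


class TestNam:
    def test_two_node_walk(self):
        from dabench.preprocess import CellGraph
        from scipy import sparse

        ds_meta = pd.DataFrame(
            {
                "population": ["P", "P"],
                "condition": ["C1", "C2"],
                "replicate": ["R1", "R1"],
                "sample": ["C1_R1", "C2_R1"],
            },
            index=["c0", "c1"],
        )
        from dabench.datasets import MultiSampleDataset

        ds = MultiSampleDataset(np.ones((2, 3)), ds_meta)
        adj = sparse.csr_matrix(np.array([[0.0, 1.0], [1.0, 0.0]]))
        graph = CellGraph(adj, k=1, kernel="binary",
                          knn_indices=np.array([[1], [0]]),
                          knn_distances=np.ones((2, 1)))
        nam = build_nam(ds, graph, steps=1)
        np.testing.assert_allclose(nam.markov.toarray(), [[0.5, 0.5], [0.5, 0.5]])
        # P_{1->2} after one step
        assert nam.markov[1, 0] == pytest.approx(0.5)
        np.testing.assert_allclose(nam.nam.sum(axis=1), 1.0)

    def test_zero_steps_counts_own_cells(self, cluster_case):
        ds, _, graph = cluster_case
        nam = build_nam(ds, graph, steps=0)
        design = group_design(ds)
        for g in range(design.n_groups):
            np.testing.assert_allclose(
                nam.arrivals[g], (design.codes == g).astype(float)
            )

    def test_markov_columns_and_nam_rows_stochastic(self, cluster_case):
        ds, _, graph = cluster_case
        nam = build_nam(ds, graph, steps=3)
        np.testing.assert_allclose(
            np.asarray(nam.markov.sum(axis=0)).ravel(), 1.0, atol=1e-10
        )
        np.testing.assert_allclose(nam.nam.sum(axis=1), 1.0, atol=1e-10)


class TestCna:
    def test_covariate_orthogonal_to_nam_is_null(self):
        # rank-2 NAM whose left singular vectors span a plane that the
        # covariate is constructed to be orthogonal to
        rng = np.random.default_rng(0)
        u1 = np.tile([1.0, -1.0], 3)
        u2 = np.array([1.0, 1.0, -1.0, -1.0, 1.0, -1.0])
        v1, v2 = rng.normal(size=(2, 30))
        Q = np.outer(u1, v1) + np.outer(u2, v2)
        Q = Q - Q.min() + 0.1
        Q = Q / Q.sum(axis=1, keepdims=True)
        nam = NamModel(markov=None, steps=0, arrivals=Q, nam=Q, design=None)
        Qc = Q - Q.mean(axis=0)
        U = np.linalg.svd(Qc, full_matrices=False)[0]
        y = rng.normal(size=6)
        y -= U[:, :5] @ (U[:, :5].T @ y)  # project out the NAM span
        if np.allclose(y, 0):
            pytest.skip("degenerate construction")
        gamma, k_star, p, _ = cna_test(nam, y + 1.0, max_k=2,
                                       n_permutations=0, fdr=0.05, seed=0)
        assert p > 0.9
        np.testing.assert_allclose(gamma, 0.0, atol=1e-8)

    def test_target_population_carries_top_gamma(self, cluster_case):
        ds, truth, graph = cluster_case
        res = Cna(ds, graph, n_permutations=100).fit()
        gamma = np.abs(res.cell_table["gamma"].to_numpy())
        target = (ds.cell_meta["population"] == "M1").to_numpy()
        # rank agreement: target cells dominate the top |gamma| decile
        top = gamma >= np.quantile(gamma, 0.9)
        assert target[top].mean() > 0.8

    def test_constant_covariate_rejected(self):
        nam = NamModel(markov=None, steps=0,
                       arrivals=np.ones((4, 5)) / 5, nam=np.ones((4, 5)) / 5,
                       design=None)
        with pytest.raises(ValueError):
            cna_test(nam, np.ones(4), max_k=2, n_permutations=0, fdr=0.05, seed=0)


class TestMilo:
    def test_default_sample_fraction(self, cluster_case):
        ds, _, graph = cluster_case
        assert Milo(ds, graph).sample_fraction == 0.1

    def test_uncovered_cells_flagged(self, cluster_case):
        ds, _, graph = cluster_case
        res = Milo(ds, graph, sample_fraction=0.02, seed=0).fit()
        na = res.cell_table["not_assessed"]
        assert na.any()
        assert (res.cell_table.loc[na, "score"] == 0).all()

    def test_zero_index_cells_rejected(self, cluster_case):
        ds, _, graph = cluster_case
        with pytest.raises(ValueError):
            Milo(ds, graph, sample_fraction=1e-6).fit()


class TestLouvain:
    def test_scores_piecewise_constant_on_clusters(self, cluster_case):
        ds, _, graph = cluster_case
        res = Louvain(ds, graph, seed=0).fit()
        frame = res.cell_table.copy()
        frame["pop"] = ds.cell_meta["population"]
        # at least as many testing units as populations; each unit one score
        assert len(res.unit_table) >= 3
        assert res.cell_table["score"].nunique() <= len(res.unit_table)

    def test_enriched_cluster_significant(self, cluster_case):
        ds, truth, graph = cluster_case
        res = Louvain(ds, graph, seed=0).fit()
        target = (ds.cell_meta["population"] == "M1").to_numpy()
        assert res.significant_cells[target].mean() > 0.9

    def test_tiny_resolution_gives_few_units(self, cluster_case):
        ds, _, graph = cluster_case
        res = Louvain(ds, graph, resolution=1e-4, seed=0).fit()
        assert len(res.unit_table) <= 3


class TestCydar:
    def test_target_hyperspheres_dominate_significant_set(self, cluster_case):
        ds, truth, graph = cluster_case
        res = Cydar(ds, graph, seed=0).fit()
        sig = res.unit_table[res.unit_table["significant"]]
        assert len(sig) > 0
        centers = sig["center_cell"].to_numpy()
        in_target = (ds.cell_meta["population"].to_numpy()[centers] == "M1")
        assert in_target.mean() > 0.8

    def test_invalid_radius(self, cluster_case):
        ds, _, graph = cluster_case
        with pytest.raises(ValueError):
            Cydar(ds, graph, radius=-1.0)

    def test_single_condition_rejected(self, cluster_case):
        ds, _, graph = cluster_case
        mono = ds.copy()
        mono.cell_meta["condition"] = "C2"
        mono.cell_meta["sample"] = "C2_" + mono.cell_meta["replicate"]
        with pytest.raises(ValueError):
            Cydar(mono, graph)


class TestDASeq:
    def test_saturated_neighbourhood_scores_near_one(self, two_blob_dataset):
        # blob B is pure C2: its cells see only C2 neighbours at every
        # scale, so the DA measure saturates towards +1
        ds = two_blob_dataset
        res = DASeq(ds, k_list=[5, 10, 20], n_permutations=10, seed=0).fit()
        blob_b = (ds.cell_meta["population"] == "B").to_numpy()
        lik = res.scores * res.directions
        assert lik[blob_b].min() > 0.8

    def test_k_list_validation(self, cluster_case):
        ds, _, graph = cluster_case
        with pytest.raises(ValueError):
            DASeq(ds, k_list=[50, 50])
        with pytest.raises(ValueError):
            DASeq(ds, k_list=[10, ds.n_cells])

    def test_balanced_exchangeable_cells_stay_null(self):
        rng = np.random.default_rng(1)
        n = 400
        coords = rng.normal(size=(n, 4))
        counts = rng.poisson(4, (n, 10))
        cond = np.where(rng.random(n) < 0.5, "C2", "C1")
        rep = rng.choice(["R1", "R2", "R3"], n)
        meta = pd.DataFrame(
            {"population": "P", "condition": cond, "replicate": rep},
            index=[f"c{i}" for i in range(n)],
        )
        meta["sample"] = meta["condition"] + "_" + meta["replicate"]
        from dabench.datasets import MultiSampleDataset

        ds = MultiSampleDataset(counts, meta, embeddings={"pca": coords})
        res = DASeq(ds, k_list=[20, 40, 60], n_permutations=30, seed=0).fit()
        assert res.significant_cells.mean() <= 0.05
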