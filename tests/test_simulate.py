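"""Simulation module: topologies, DA planting, labels, batches."""

import numpy as np
import pandas as pd
import pytest

from dabench.datasets import GroundTruth
from dabench.simulate import (
    BatchConfig,
    TopologyConfig,
    add_batch_effects,
    assign_conditions,
    default_config,
    ground_truth_labels,
    plant_da,
    simulate_scaling_series,
    simulate_topology,
    subsample_population,
)


def _truth(probs, p_da=0.8, target="T"):
    idx = pd.Index([f"c{i}" for i in range(len(probs))])
    return GroundTruth(
        p_da=p_da,
        prob_c2=pd.Series(probs, index=idx),
        w=pd.Series(np.arange(len(probs), dtype=float), index=idx),
        target_population=target,
    )


class TestTopology:
    def test_shipped_shapes(self):
        lin = default_config("linear")
        assert (lin.n_cells, lin.n_genes) == (7500, 500)
        clu = default_config("cluster")
        assert clu.n_cells == 2700
        assert clu.populations["M2"] == 2 * clu.populations["M1"]

    @pytest.mark.parametrize("kind,pops", [
        ("linear", {"L1", "L2", "L3", "L4", "L5"}),
        ("branch", {"T1", "T2", "A1", "A2", "B1", "B2"}),
        ("cluster", {"M1", "M2", "M3"}),
    ])
    def test_populations_present(self, kind, pops):
        cfg = TopologyConfig(kind=kind, n_cells=600, n_genes=40, seed=1)
        if kind == "cluster":
            cfg = TopologyConfig(
                kind="cluster", n_cells=600, n_genes=40,
                populations={"M1": 150, "M2": 300, "M3": 150}, seed=1,
            )
        ds = simulate_topology(cfg)
        assert ds.n_cells == 600 and ds.n_genes == 40
        assert set(ds.populations()) == pops
        assert np.issubdtype(ds.counts.dtype, np.integer)
        assert ds.counts.min() >= 0

    def test_deterministic_given_seed(self):
        cfg = TopologyConfig(kind="linear", n_cells=200, n_genes=30, seed=5)
        a = simulate_topology(cfg)
        b = simulate_topology(cfg)
        np.testing.assert_array_equal(a.counts, b.counts)
        assert (a.cell_meta["population"] == b.cell_meta["population"]).all()

    def test_invalid_configs(self):
        with pytest.raises(ValueError):
            TopologyConfig(kind="linear", n_cells=1, n_genes=10)
        with pytest.raises(ValueError):
            TopologyConfig(kind="spiral", n_cells=10, n_genes=10)
        with pytest.raises(ValueError):
            TopologyConfig(
                kind="cluster", n_cells=10, n_genes=5,
                populations={"A": 5, "B": 0, "C": 5},
            )
        with pytest.raises(ValueError):
            TopologyConfig(
                kind="cluster", n_cells=10, n_genes=5,
                populations={"A": 5, "B": 2},
            )


class TestPlanting:
    def test_bounds_attained_exactly(self, cluster_base):
        truth = plant_da(cluster_base.dataset, "M1", 0.95)
        prob = truth.prob_c2.to_numpy()
        assert prob.max() == pytest.approx(0.95, abs=1e-12)
        assert prob.min() == pytest.approx(0.5, abs=1e-12)

    def test_null_ratio_gives_flat_half(self, cluster_base):
        truth = plant_da(cluster_base.dataset, "M1", 0.5)
        np.testing.assert_allclose(truth.prob_c2.to_numpy(), 0.5)

    def test_monotone_in_w(self, cluster_base):
        truth = plant_da(cluster_base.dataset, "M2", 0.85)
        order = np.argsort(truth.w.to_numpy())
        prob_sorted = truth.prob_c2.to_numpy()[order]
        assert np.all(np.diff(prob_sorted) >= -1e-12)

    def test_depletion_ratio_flips_range(self, cluster_base):
        truth = plant_da(cluster_base.dataset, "M1", 0.25)
        prob = truth.prob_c2.to_numpy()
        assert prob.min() == pytest.approx(0.25, abs=1e-12)
        assert prob.max() == pytest.approx(0.5, abs=1e-12)
        # the target centroid is now depleted, not enriched
        m1 = (cluster_base.dataset.cell_meta["population"] == "M1").to_numpy()
        assert prob[m1].mean() < prob[~m1].mean()

    def test_errors(self, cluster_base):
        with pytest.raises(ValueError):
            plant_da(cluster_base.dataset, "M9", 0.9)
        with pytest.raises(ValueError):
            plant_da(cluster_base.dataset, "M1", 1.5)
        bare = cluster_base.dataset.copy()
        bare.embeddings.clear()
        with pytest.raises(ValueError):
            plant_da(bare, "M1", 0.9)


class TestLabels:
    def test_three_way_partition_at_known_threshold(self):
        # the derived t clips at 0.45 here, so the three branches of the
        # labelling rule are exercised at known boundaries
        truth = ground_truth_labels(_truth([0.25, 0.5, 0.75]), 0.5)
        assert truth.t == pytest.approx(0.45)
        assert list(truth.label) == ["NegLFC", "NotDA", "PosLFC"]

    def test_labels_partition_all_cells(self, cluster_base):
        truth = plant_da(cluster_base.dataset, "M1", 0.95)
        truth = ground_truth_labels(truth, 0.25)
        assert truth.label.isin(["NegLFC", "PosLFC", "NotDA"]).all()
        # enrichment-only planting cannot produce NegLFC
        assert (truth.label != "NegLFC").all()
        assert 0.05 <= truth.t <= 0.45

    def test_null_planting_is_all_notda(self, cluster_base):
        truth = plant_da(cluster_base.dataset, "M1", 0.5)
        truth = ground_truth_labels(truth, 0.25)
        assert (truth.label == "NotDA").all()

    def test_depletion_produces_neglfc(self, cluster_base):
        truth = plant_da(cluster_base.dataset, "M1", 0.15)
        truth = ground_truth_labels(truth, 0.25)
        assert (truth.label == "NegLFC").any()
        assert not (truth.label == "PosLFC").any()

    def test_invalid_proportion(self):
        with pytest.raises(ValueError):
            ground_truth_labels(_truth([0.5, 0.6]), 0.0)


class TestConditions:
    def test_six_samples_and_bernoulli_fraction(self, cluster_base):
        truth = plant_da(cluster_base.dataset, "M1", 0.5)
        ds = assign_conditions(cluster_base.dataset, truth, seed=0)
        assert ds.n_samples == 6
        tab = ds.sample_table()
        assert set(tab["condition"]) == {"C1", "C2"}
        assert set(tab["replicate"]) == {"R1", "R2", "R3"}
        # prob 0.5 everywhere: a 4-sigma binomial bound on the C2 share
        frac = (ds.cell_meta["condition"] == "C2").mean()
        assert abs(frac - 0.5) < 4 * 0.5 / np.sqrt(ds.n_cells)

    def test_forced_single_condition(self, cluster_base):
        n = cluster_base.dataset.n_cells
        truth = _truth(np.ones(n))
        truth.prob_c2.index = cluster_base.dataset.cell_ids
        ds = assign_conditions(cluster_base.dataset, truth, seed=0)
        assert (ds.cell_meta["condition"] == "C2").all()
        assert ds.n_samples == 3  # only C2 replicates exist

    def test_deterministic(self, cluster_base):
        truth = plant_da(cluster_base.dataset, "M2", 0.85)
        a = assign_conditions(cluster_base.dataset, truth, seed=11)
        b = assign_conditions(cluster_base.dataset, truth, seed=11)
        assert (a.cell_meta["sample"] == b.cell_meta["sample"]).all()


class TestBatch:
    def test_zero_sd_is_identity(self, cluster_case):
        ds, _, _ = cluster_case
        out = add_batch_effects(ds, BatchConfig(batch_sd=0.0, seed=1))
        np.testing.assert_array_equal(out.embeddings["pca"], ds.embeddings["pca"])
        assert "pca_original" in out.embeddings
        assert set(out.cell_meta["batch"]) == {"B1", "B2"}

    def test_one_shift_vector_per_batch(self, cluster_case):
        ds, _, _ = cluster_case
        out = add_batch_effects(ds, BatchConfig(batch_sd=1.0, seed=2))
        shift = out.embeddings["pca"] - out.embeddings["pca_original"]
        for b in ("B1", "B2"):
            rows = shift[(out.cell_meta["batch"] == b).to_numpy()]
            assert np.ptp(rows, axis=0).max() == pytest.approx(0.0, abs=1e-12)

    def test_shift_magnitude_matches_sd(self, cluster_case):
        # entries of the shift are iid N(0, 1.5^2); with d=50 the sample
        # sd lies within a chi-distribution confidence band
        ds, _, _ = cluster_case
        out = add_batch_effects(ds, BatchConfig(batch_sd=1.5, seed=3))
        shift = out.embeddings["pca"] - out.embeddings["pca_original"]
        b1 = shift[(out.cell_meta["batch"] == "B1").to_numpy()][0]
        assert 1.0 < b1.std() < 2.0

    def test_negative_sd_rejected(self):
        with pytest.raises(ValueError):
            BatchConfig(batch_sd=-0.1)


class TestSubsample:
    def test_counts(self, cluster_base):
        ds = cluster_base.dataset
        before = (ds.cell_meta["population"] == "M2").sum()
        out = subsample_population(ds, "M2", before // 2, seed=0)
        counts = out.cell_meta["population"].value_counts()
        assert counts["M2"] == before // 2
        assert counts["M1"] == (ds.cell_meta["population"] == "M1").sum()

    def test_full_size_is_identity(self, cluster_base):
        ds = cluster_base.dataset
        size = int((ds.cell_meta["population"] == "M1").sum())
        out = subsample_population(ds, "M1", size, seed=0)
        assert out.n_cells == ds.n_cells

    def test_empty_target_blocks_planting(self, cluster_base):
        out = subsample_population(cluster_base.dataset, "M3", 0, seed=0)
        assert "M3" not in out.populations()
        with pytest.raises(ValueError):
            plant_da(out, "M3", 0.9)

    def test_unknown_population(self, cluster_base):
        with pytest.raises(ValueError):
            subsample_population(cluster_base.dataset, "Mx", 10)


class TestScalingSeries:
    def test_sizes_and_independence(self):
        cfg = TopologyConfig(kind="linear", n_cells=100, n_genes=20, seed=3)
        series = simulate_scaling_series([50, 100], cfg)
        assert [d.n_cells for d in series] == [50, 100]
        solo = simulate_scaling_series([50], cfg)
        np.testing.assert_array_equal(series[0].counts, solo[0].counts)
        assert simulate_scaling_series([], cfg) == []
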