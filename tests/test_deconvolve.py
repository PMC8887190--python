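"""Tests of reference construction and cell-fraction estimation."""

import numpy as np
import pandas as pd
import pytest
import scipy.optimize

from cthbench import SimConfig
from cthbench.deconvolve import (
    ReferenceMatrix,
    build_reference,
    estimate_fractions_constrained,
    estimate_fractions_hierarchical,
    estimate_fractions_robust,
)
from cthbench.metrics import pooled_r2
from cthbench.simulate import generate_purified_profiles


def _mixture_from_reference(ref, weights, sample_ids=None):
    """Noise-free bulk built as convex combinations of reference columns."""
    W = np.atleast_2d(np.asarray(weights, dtype=float))
    bulk = ref.values.to_numpy() @ W.T
    cols = sample_ids or [f"S{i:03d}" for i in range(1, W.shape[0] + 1)]
    return pd.DataFrame(bulk, index=ref.values.index, columns=cols)


@pytest.fixture(scope="module")
def planted_reference(small_sim, small_reference):
    return small_reference


class TestBuildReference:
    def test_planted_markers_recovered(self, small_sim):
        """With markers planted at a 0.9 gap, selection at delta_min=0.7
        finds markers for every cell type, none from the reserved pool."""
        ref = build_reference(small_sim["spiked"], markers_per_type=20,
                              delta_min=0.7)
        ann = small_sim["spiked"].annotation
        assert not ann.loc[ref.values.index, "reserved"].any()
        for ct in small_sim["spiked"].cell_types:
            chosen = ref.marker_for[ref.marker_for == ct].index
            assert len(chosen) == 20
            # selected markers really are the planted ones for that type
            assert (ann.loc[chosen, "marker_for"] == ct).all()

    def test_gap_threshold_enforced(self, small_sim):
        ref = build_reference(small_sim["spiked"], markers_per_type=20,
                              delta_min=0.7)
        means = ref.values
        for cpg in means.index:
            ct = ref.marker_for[cpg]
            own = means.loc[cpg, ct]
            rest = means.loc[cpg].drop(ct)
            assert np.abs(own - rest).min() >= 0.7

    def test_impossible_threshold_errors(self, small_sim):
        with pytest.raises(ValueError, match="exceed"):
            build_reference(small_sim["spiked"], 10, delta_min=1.01)

    def test_row_and_column_counts(self):
        cfg = SimConfig(n_cpgs=2000, n_samples=20, n_cases=10, n_dmcs=50,
                        markers_per_type=50, seed=9)
        profiles = generate_purified_profiles(cfg)
        ref = build_reference(profiles, markers_per_type=50, delta_min=0.7)
        assert ref.values.shape == (150, 3)

    def test_direction_balance(self, planted_reference):
        counts = pd.crosstab(planted_reference.marker_for,
                             planted_reference.direction)
        assert (counts["hyper"] == counts["hypo"]).all()


class TestConstrainedEstimator:
    def test_exact_recovery_noise_free(self, planted_reference):
        W = np.array([[0.6, 0.3, 0.1], [0.2, 0.2, 0.6], [0.4, 0.4, 0.2]])
        bulk = _mixture_from_reference(planted_reference, W)
        est = estimate_fractions_constrained(bulk, planted_reference)
        np.testing.assert_allclose(est.fractions.to_numpy(), W, atol=1e-6)

    def test_pure_sample(self, planted_reference):
        bulk = _mixture_from_reference(planted_reference, [[0.0, 1.0, 0.0]])
        est = estimate_fractions_constrained(bulk, planted_reference)
        np.testing.assert_allclose(est.fractions.to_numpy(),
                                   [[0.0, 1.0, 0.0]], atol=1e-6)

    def test_contracts_on_noisy_data(self, small_sim, small_estimate):
        W = small_estimate.fractions.to_numpy()
        assert (W >= 0).all()
        assert (W.sum(axis=1) <= 1 + 1e-6).all()

    def test_recovery_r2_on_default_noise(self, small_sim, small_estimate):
        r2 = pooled_r2(small_estimate.fractions, small_sim["fractions"])
        assert r2 >= 0.8

    def test_matches_slsqp_oracle(self, planted_reference):
        """Cross-check against an independent constrained solver on noisy
        mixtures where the constraints are active."""
        rng = np.random.default_rng(0)
        R = planted_reference.values.to_numpy()
        for _ in range(5):
            b = rng.random(R.shape[0])
            x0 = np.full(R.shape[1], 1.0 / R.shape[1])
            res = scipy.optimize.minimize(
                lambda w: 0.5 * np.sum((R @ w - b) ** 2), x0,
                bounds=[(0, None)] * R.shape[1],
                constraints=[{"type": "ineq",
                              "fun": lambda w: 1.0 - w.sum()}],
                method="SLSQP", options={"ftol": 1e-14, "maxiter": 500},
            )
            bulk = pd.DataFrame(b[:, None], index=planted_reference.values.index,
                                columns=["s"])
            est = estimate_fractions_constrained(bulk, planted_reference)
            np.testing.assert_allclose(est.fractions.to_numpy()[0], res.x,
                                       atol=1e-5)

    def test_low_overlap_errors(self, planted_reference):
        bulk = _mixture_from_reference(planted_reference, [[0.5, 0.3, 0.2]])
        bulk = bulk.iloc[: int(0.5 * len(bulk))]
        with pytest.raises(ValueError, match="overlap|markers"):
            estimate_fractions_constrained(bulk, planted_reference)

    def test_partial_overlap_warns(self, planted_reference):
        bulk = _mixture_from_reference(planted_reference, [[0.5, 0.3, 0.2]])
        bulk = bulk.iloc[: int(0.9 * len(bulk))]
        with pytest.warns(UserWarning, match="missing"):
            est = estimate_fractions_constrained(bulk, planted_reference)
        np.testing.assert_allclose(est.fractions.to_numpy(),
                                   [[0.5, 0.3, 0.2]], atol=1e-6)

    def test_collinear_reference_errors(self):
        idx = pd.Index([f"c{i}" for i in range(10)], name="cpg_id")
        col = np.linspace(0.1, 0.9, 10)
        ref = ReferenceMatrix(
            values=pd.DataFrame({"a": col, "b": col}, index=idx),
            marker_for=pd.Series(["a"] * 5 + ["b"] * 5, index=idx),
            direction=pd.Series(["hyper"] * 10, index=idx),
        )
        bulk = pd.DataFrame({"s": col}, index=idx)
        with pytest.raises(ValueError, match="collinear"):
            estimate_fractions_constrained(bulk, ref)

    def test_permutation_equivariance(self, planted_reference, small_sim):
        bulk = small_sim["bulk"]
        ref = planted_reference
        est = estimate_fractions_constrained(bulk, ref)
        perm = ["monocyte", "neutrophil", "cd4t"]
        ref_perm = ReferenceMatrix(ref.values[perm], ref.marker_for,
                                   ref.direction)
        est_perm = estimate_fractions_constrained(bulk, ref_perm)
        pd.testing.assert_frame_equal(est.fractions[perm],
                                      est_perm.fractions)


class TestRobustEstimator:
    def test_noise_free_recovery(self, planted_reference):
        W = np.array([[0.6, 0.3, 0.1], [0.1, 0.5, 0.4]])
        bulk = _mixture_from_reference(planted_reference, W)
        est = estimate_fractions_robust(bulk, planted_reference)
        np.testing.assert_allclose(est.fractions.to_numpy(), W, atol=1e-4)

    def test_rows_sum_to_one(self, small_sim, planted_reference):
        est = estimate_fractions_robust(small_sim["bulk"], planted_reference)
        np.testing.assert_allclose(est.fractions.sum(axis=1), 1.0, atol=1e-12)

    def test_outperforms_constrained_under_corruption(self, planted_reference):
        """With 5% of marker CpGs corrupted in the bulk, Huber weighting
        yields no worse fraction RMSE than constrained least squares."""
        rng = np.random.default_rng(42)
        n = 30
        W = rng.dirichlet((21.0, 6.0, 3.0), size=n)
        bulk = _mixture_from_reference(planted_reference, W)
        n_corrupt = max(1, int(0.05 * len(bulk)))
        rows = rng.choice(len(bulk), n_corrupt, replace=False)
        bulk.iloc[rows] = rng.random((n_corrupt, n))
        est_r = estimate_fractions_robust(bulk, planted_reference)
        est_c = estimate_fractions_constrained(bulk, planted_reference)
        rmse_r = np.sqrt(np.mean((est_r.fractions.to_numpy() - W) ** 2))
        rmse_c = np.sqrt(np.mean((est_c.fractions.to_numpy() - W) ** 2))
        assert rmse_r <= rmse_c + 1e-9


class TestReferenceRobustness:
    def test_corrupted_reference_rows_tolerated(self, small_sim,
                                                planted_reference):
        """Up to 10% corrupted reference rows still give pooled R^2 >= 0.8
        against the true fractions on the default-noise simulation."""
        rng = np.random.default_rng(7)
        ref = planted_reference
        values = ref.values.copy()
        n_corrupt = int(0.10 * len(values))
        rows = rng.choice(len(values), n_corrupt, replace=False)
        values.iloc[rows] = rng.random((n_corrupt, values.shape[1]))
        corrupted = ReferenceMatrix(values, ref.marker_for, ref.direction)
        est = estimate_fractions_constrained(small_sim["bulk"], corrupted)
        assert pooled_r2(est.fractions, small_sim["fractions"]) >= 0.8


def _two_level_fixture(rng, n_markers=40, n_samples=25, noise=0.01):
    """Synthetic two-level tissue: epithelial + an immune lineage split
    into three subtypes with known ground truth."""
    idx1 = pd.Index([f"l1_{i}" for i in range(n_markers)], name="cpg_id")
    ref1 = ReferenceMatrix(
        values=pd.DataFrame({
            "epithelial": np.where(np.arange(n_markers) < n_markers // 2,
                                   0.95, 0.05),
            "immune": np.where(np.arange(n_markers) < n_markers // 2,
                               0.05, 0.95),
        }, index=idx1),
        marker_for=pd.Series(np.where(np.arange(n_markers) < n_markers // 2,
                                      "epithelial", "immune"), index=idx1),
        direction=pd.Series(["hyper"] * n_markers, index=idx1),
    )
    idx2 = pd.Index([f"l2_{i}" for i in range(3 * n_markers)], name="cpg_id")
    vals = np.full((3 * n_markers, 3), 0.05)
    marks = []
    for j in range(3):
        vals[j * n_markers:(j + 1) * n_markers, j] = 0.95
        marks += [f"immune{j}"] * n_markers
    ref2 = ReferenceMatrix(
        values=pd.DataFrame(vals, index=idx2,
                            columns=["immune0", "immune1", "immune2"]),
        marker_for=pd.Series(marks, index=idx2),
        direction=pd.Series(["hyper"] * len(idx2), index=idx2),
    )
    f_epi = rng.uniform(0.2, 0.8, n_samples)
    props = rng.dirichlet((5.0, 3.0, 2.0), size=n_samples)
    truth_sub = props * (1 - f_epi)[:, None]

    # level-2 markers behave like shared epithelial background (0.5) in
    # the epithelial compartment
    samples = [f"S{i:03d}" for i in range(1, n_samples + 1)]
    bulk1 = ref1.values.to_numpy() @ np.column_stack([f_epi, 1 - f_epi]).T
    epi_l2 = np.full((len(idx2), 1), 0.5)
    bulk2 = (epi_l2 * f_epi[None, :]
             + ref2.values.to_numpy() @ truth_sub.T)
    bulk = pd.DataFrame(
        np.vstack([bulk1, bulk2]) + rng.normal(0, noise,
                                               (len(idx1) + len(idx2),
                                                n_samples)),
        index=idx1.append(idx2), columns=samples,
    ).clip(0, 1)
    truth = pd.DataFrame(truth_sub, index=samples,
                         columns=["immune0", "immune1", "immune2"])
    truth["epithelial"] = f_epi
    return ref1, ref2, bulk, truth


class TestHierarchicalEstimator:
    def test_product_rule(self):
        rng = np.random.default_rng(1)
        ref1, ref2, bulk, truth = _two_level_fixture(rng, noise=0.0)
        est = estimate_fractions_hierarchical(bulk, ref1, ref2, "immune")
        # subset fractions are the parent fraction times within-parent
        # proportions, so they sum to the parent fraction
        sub = est.fractions[["immune0", "immune1", "immune2"]].sum(axis=1)
        parent = 1 - est.fractions["epithelial"]
        np.testing.assert_allclose(sub, parent, atol=1e-6)

    def test_zero_parent_gives_zero_subsets(self):
        rng = np.random.default_rng(2)
        ref1, ref2, bulk, _ = _two_level_fixture(rng, n_samples=5, noise=0.0)
        # make one sample purely epithelial
        pure = ref1.values["epithelial"].reindex(bulk.index)
        pure.loc[ref2.values.index] = 0.5
        bulk.iloc[:, 0] = pure
        est = estimate_fractions_hierarchical(bulk, ref1, ref2, "immune")
        assert est.fractions.iloc[0][["immune0", "immune1", "immune2"]].max() \
            <= 1e-6

    def test_two_level_recovery(self):
        rng = np.random.default_rng(3)
        ref1, ref2, bulk, truth = _two_level_fixture(rng)
        est = estimate_fractions_hierarchical(bulk, ref1, ref2, "immune")
        sub = est.fractions[["immune0", "immune1", "immune2"]].to_numpy()
        rmse = np.sqrt(np.mean(
            (sub - truth[["immune0", "immune1", "immune2"]].to_numpy()) ** 2))
        assert rmse <= 0.05

    def test_missing_parent_errors(self):
        rng = np.random.default_rng(4)
        ref1, ref2, bulk, _ = _two_level_fixture(rng, n_samples=5)
        with pytest.raises(ValueError, match="parent"):
            estimate_fractions_hierarchical(bulk, ref1, ref2, "stromal")
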