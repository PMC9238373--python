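import numpy as np
import pandas as pd
import pytest
from scipy.spatial import procrustes

from phylorpca import (
    SimulationConfig,
    ctf,
    knn_cv,
    masked_factorize,
    parse_newick,
    permanova,
    rank_loadings,
    rclr,
    rpca,
    simulate,
)
from phylorpca.transform import MaskedLogMatrix


def mlm_from(rows):
    rows = np.atleast_2d(np.asarray(rows, dtype=float))
    df = pd.DataFrame(
        rows,
        index=[f"s{i}" for i in range(rows.shape[0])],
        columns=[f"f{j}" for j in range(rows.shape[1])],
    )
    return MaskedLogMatrix.from_values(df)


class TestMaskedFactorize:
    def test_dense_rank1_exact(self):
        m = mlm_from([[1.0, 2.0], [2.0, 4.0]])
        fit = masked_factorize(m, rank=1, seed=0)
        from phylorpca import double_center

        centered = double_center(m).values.to_numpy()
        recon = fit.u @ np.diag(fit.s) @ fit.v.T
        np.testing.assert_allclose(recon, centered, atol=1e-8)

    def test_rank1_completion_recovers_missing_entry(self):
        m = mlm_from([[1.0, 2.0], [2.0, np.nan]])
        fit = masked_factorize(m, rank=1, seed=0, center=False, tol=1e-14)
        recon = fit.u @ np.diag(fit.s) @ fit.v.T
        assert recon[1, 1] == pytest.approx(4.0, abs=1e-6)

    def test_rank_too_large_rejected(self):
        m = mlm_from(np.ones((3, 4)))
        with pytest.raises(ValueError, match="rank"):
            masked_factorize(m, rank=5, seed=0)

    def test_empty_mask_row_rejected(self):
        m = mlm_from([[1.0, 2.0], [np.nan, np.nan]])
        with pytest.raises(ValueError, match="row with no observed"):
            masked_factorize(m, rank=1, seed=0)

    def test_dense_agrees_with_truncated_svd(self, rng):
        x = rng.normal(size=(8, 12))
        m = mlm_from(x)
        fit = masked_factorize(m, rank=3, seed=1, tol=1e-14)
        from phylorpca import double_center

        centered = double_center(m).values.to_numpy()
        u, s, vt = np.linalg.svd(centered, full_matrices=False)
        np.testing.assert_allclose(fit.s, s[:3], rtol=1e-6)
        truncated = u[:, :3] @ np.diag(s[:3]) @ vt[:3]
        recon = fit.u @ np.diag(fit.s) @ fit.v.T
        np.testing.assert_allclose(recon, truncated, atol=1e-6)

    def test_planted_rank2_recovered_with_20pct_mask(self, rng):
        u = rng.normal(size=(30, 2))
        v = rng.normal(size=(40, 2))
        x = u @ v.T
        mask = rng.random(size=x.shape) < 0.8
        vals = np.where(mask, x, np.nan)
        m = mlm_from(vals)
        fit = masked_factorize(m, rank=2, seed=3, center=False, tol=1e-14)
        recon = fit.u @ np.diag(fit.s) @ fit.v.T
        rel_err = np.linalg.norm(recon - x) / np.linalg.norm(x)
        assert rel_err <= 0.05

    def test_objective_monotone_and_deterministic(self, rng):
        x = rng.normal(size=(10, 15))
        x[rng.random(size=x.shape) < 0.2] = np.nan
        x[:, 0] = 1.0
        x[0, :] = 1.0
        m = mlm_from(x)
        fit1 = masked_factorize(m, rank=2, seed=7)
        fit2 = masked_factorize(m, rank=2, seed=7)
        obj = np.asarray(fit1.objective)
        assert (np.diff(obj) <= 1e-9 * np.maximum(obj[:-1], 1e-12)).all()
        np.testing.assert_array_equal(fit1.u, fit2.u)
        np.testing.assert_array_equal(fit1.s, fit2.s)
        np.testing.assert_array_equal(fit1.v, fit2.v)


class TestRpca:
    def test_duplicate_samples_have_zero_distance(self, rng):
        counts = rng.integers(1, 50, size=(5, 8)).astype(float)
        counts = np.vstack([counts, counts[0]])
        table = pd.DataFrame(
            counts, index=[f"s{i}" for i in range(6)],
            columns=[f"f{j}" for j in range(8)],
        )
        _, dm = rpca(table, rank=2, seed=0)
        assert dm["s0", "s5"] <= 1e-8

    def test_no_tree_equals_star_unit_tree(self, rng):
        features = [f"f{j}" for j in range(6)]
        table = pd.DataFrame(
            rng.integers(0, 40, size=(7, 6)).astype(float) + 1,
            index=[f"s{i}" for i in range(7)],
            columns=features,
        )
        star = parse_newick("(" + ",".join(f"{f}:1" for f in features) + ");")
        _, dm_star = rpca(table, tree=star, rank=2, seed=5)
        _, dm_none = rpca(table, tree=None, rank=2, seed=5)
        np.testing.assert_allclose(
            dm_star.data, dm_none.data, atol=1e-8
        )

    def test_three_block_simulation_fully_separated(self):
        cfg = SimulationConfig(
            features_per_block=20, samples_per_block=8, depth=2_000_000, seed=7
        )
        ds = simulate(cfg)
        ordination, _ = rpca(ds.counts, tree=ds.tree, rank=3, seed=0)
        pr_auc, roc_auc = knn_cv(ordination.samples, ds.sample_labels, seed=0)
        assert pr_auc == pytest.approx(1.0)
        assert roc_auc == pytest.approx(1.0)

    def test_sample_permutation_equivariance(self, small_dataset):
        table = small_dataset.counts
        perm = np.random.default_rng(0).permutation(len(table))
        shuffled = table.iloc[perm]
        _, dm1 = rpca(table, tree=small_dataset.tree, rank=2, seed=9, tol=1e-13)
        _, dm2 = rpca(shuffled, tree=small_dataset.tree, rank=2, seed=9, tol=1e-13)
        ids = list(table.index)
        np.testing.assert_allclose(
            dm1.filter(ids).data, dm2.filter(ids).data, atol=1e-6
        )

    def test_distance_matrix_metric_axioms(self, small_dataset):
        _, dm = rpca(small_dataset.counts, tree=small_dataset.tree, rank=3, seed=1)
        d = dm.data
        assert np.allclose(d, d.T)
        assert np.allclose(np.diag(d), 0.0)
        assert (d >= 0).all()
        n = d.shape[0]
        i, j, k = np.ix_(range(n), range(n), range(n))
        assert (d[i, j] <= d[i, k] + d[k, j] + 1e-8).all()

    def test_rank_clamped_when_few_samples(self, rng):
        table = pd.DataFrame(
            rng.integers(1, 9, size=(3, 6)).astype(float),
            index=list("abc"), columns=[f"f{j}" for j in range(6)],
        )
        with pytest.warns(RuntimeWarning, match="clamped"):
            ordination, _ = rpca(table, rank=3, seed=0)
        assert ordination.samples.shape[1] == 2

    def test_proportion_explained_valid(self, small_dataset):
        ordination, _ = rpca(small_dataset.counts, tree=small_dataset.tree, seed=0)
        pe = ordination.proportion_explained.to_numpy()
        assert ((pe >= 0) & (pe <= 1)).all()
        assert pe.sum() <= 1 + 1e-12
        eig = ordination.eigvals.to_numpy()
        assert (np.diff(eig) <= 1e-12).all()


class TestCtf:
    @staticmethod
    def _dense_table(rng, n, p):
        return pd.DataFrame(
            rng.integers(1, 100, size=(n, p)).astype(float),
            index=[f"s{i}" for i in range(n)],
            columns=[f"f{j}" for j in range(p)],
        )

    def test_single_state_matches_rpca_up_to_rotation(self, rng):
        table = self._dense_table(rng, 12, 20)
        meta = pd.DataFrame(
            {"subject": list(table.index), "state": ["one"] * 12},
            index=table.index,
        )
        ord_ctf, _, _ = ctf(
            table, None, meta, "subject", "state", rank=3, seed=0, tol=1e-14
        )
        ord_rpca, _ = rpca(table, rank=3, seed=0, tol=1e-14)
        scores_ctf = ord_ctf.samples.loc[list(table.index)].to_numpy()
        _, _, disparity = procrustes(ord_rpca.samples.to_numpy(), scores_ctf)
        assert disparity <= 1e-6

    def test_duplicate_subject_state_rejected(self, rng):
        table = self._dense_table(rng, 4, 5)
        meta = pd.DataFrame(
            {"subject": ["a", "a", "b", "b"], "state": ["x", "x", "x", "y"]},
            index=table.index,
        )
        with pytest.raises(ValueError, match="duplicated"):
            ctf(table, None, meta, "subject", "state", seed=0)

    def test_two_block_repeated_measures_separates(self):
        # two simulated blocks arranged as 2 timepoints per subject
        cfg = SimulationConfig(
            n_blocks=2, block_centers=(0.0, 5.0), features_per_block=20,
            samples_per_block=16, depth=50_000, seed=3,
        )
        ds = simulate(cfg)
        samples = list(ds.counts.index)
        block = ds.sample_labels
        meta = pd.DataFrame(index=samples, columns=["subject", "state", "block"], dtype=str)
        for b in ("block0", "block1"):
            ids = [s for s in samples if block[s] == b]
            for i, s in enumerate(ids):
                meta.loc[s] = [f"{b}_subj{i // 2}", f"t{i % 2}", b]
        ord_sub, dm_sub, state_loadings = ctf(
            ds.counts, ds.tree, meta, "subject", "state", rank=2, seed=0
        )
        subject_block = pd.Series(
            {f"{b}_subj{i}": b for b in ("block0", "block1") for i in range(8)}
        )
        f, p = permanova(dm_sub, subject_block, seed=0)
        assert p <= 0.01
        assert list(state_loadings.index) == ["t0", "t1"]


class TestRankLoadings:
    @staticmethod
    def _ordination(loadings):
        from skbio import OrdinationResults

        ids = list(loadings.keys())
        vals = np.array([[v] for v in loadings.values()], dtype=float)
        return OrdinationResults(
            "m", "m",
            eigvals=pd.Series([1.0], index=["PC1"]),
            samples=pd.DataFrame(np.zeros((2, 1)), index=["s1", "s2"], columns=["PC1"]),
            features=pd.DataFrame(vals, index=ids, columns=["PC1"]),
            proportion_explained=pd.Series([1.0], index=["PC1"]),
        )

    def test_top_positive_and_negative(self):
        ordination = self._ordination({"A": 2.0, "B": 0.0, "C": -2.0})
        positive, negative = rank_loadings(ordination, axis=1, top_k=1)
        assert positive == [("A", 2.0)]
        assert negative == [("C", -2.0)]

    def test_top_k_clamped_with_warning(self):
        ordination = self._ordination({"A": 1.0, "B": -1.0})
        with pytest.warns(RuntimeWarning, match="clamped"):
            positive, _ = rank_loadings(ordination, axis=1, top_k=10)
        assert len(positive) == 2

    @pytest.mark.parametrize("axis", [0, 2])
    def test_axis_out_of_range(self, axis):
        ordination = self._ordination({"A": 1.0, "B": -1.0})
        with pytest.raises(ValueError, match="axis"):
            rank_loadings(ordination, axis=axis, top_k=1)
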