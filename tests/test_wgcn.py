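"""Co-expression network contracts: TOM closed forms and triple-loop
equivalence, scale-free fit selection, dynamic-tree-cut module recovery,
eigengene SVD agreement, and eigengene-merge duality."""

import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from atheronet.data import DataValidationError
from atheronet.synth import SynthConfig, gen_expression
from atheronet.wgcn import (
    GREY,
    ModulePartition,
    WGCNConfig,
    adjacency_matrix,
    detect_modules,
    drop_unassigned,
    filter_noisy_genes,
    merge_close_modules,
    merge_height_to_correlation,
    module_eigengenes,
    pick_soft_threshold,
    scale_free_fit,
    tom_similarity,
)
from conftest import make_dataset, tom_oracle


def scale_free_cascade(seed: int, n_samples: int = 60):
    """Hub-structured expression data: module sizes halve while module
    counts double, giving a decreasing degree-frequency law."""
    rng = np.random.default_rng(seed)
    sizes = [100] + [50] * 2 + [25] * 4 + [12] * 8 + [6] * 16
    blocks = []
    for s in sizes:
        factor = rng.normal(0, 1, n_samples)
        blocks.append(2.0 * factor + rng.normal(0, 1, (s, n_samples)))
    blocks.append(rng.normal(0, 1, (60, n_samples)))
    return make_dataset(np.vstack(blocks))


class TestTOM:
    def test_complete_graph_closed_form(self):
        adj = np.ones((3, 3)) - np.eye(3)
        tom = tom_similarity(adj)
        # l=1, a=1, k=2: (1+1)/(2+1-1) = 1 for every pair
        np.testing.assert_allclose(tom, np.ones((3, 3)))

    def test_zero_adjacency(self):
        tom = tom_similarity(np.zeros((4, 4)))
        np.testing.assert_allclose(tom, np.eye(4))

    @pytest.mark.parametrize("n", [8, 20, 50])
    def test_matches_triple_loop_oracle(self, n, rng):
        a = rng.uniform(0, 1, size=(n, n))
        adj = (a + a.T) / 2
        np.fill_diagonal(adj, 0.0)
        tom = tom_similarity(adj)
        np.testing.assert_allclose(tom, tom_oracle(adj), atol=1e-12)
        assert tom.min() >= 0 and tom.max() <= 1 + 1e-12
        np.testing.assert_allclose(tom, tom.T, atol=1e-10)

    def test_invalid_adjacency_rejected(self):
        with pytest.raises(DataValidationError):
            tom_similarity(np.eye(3))  # nonzero diagonal
        bad = np.zeros((3, 3))
        bad[0, 1] = 2.0
        bad[1, 0] = 2.0
        with pytest.raises(DataValidationError):
            tom_similarity(bad)


class TestSoftThreshold:
    def test_selection_reproducible_and_fit_verified(self):
        """Selection is deterministic and the reported R^2 equals an
        independent least-squares fit of the binned log-log points."""
        ds = scale_free_cascade(1)
        r1 = pick_soft_threshold(ds)
        r2 = pick_soft_threshold(ds)
        assert r1.beta == r2.beta
        assert r1.table.equals(r2.table)
        # independent regression oracle on the same binned points
        adj = adjacency_matrix(ds, r1.beta)
        k = adj.sum(axis=1)
        k = k[k > 0]
        edges = np.linspace(k.min(), k.max(), 11)
        edges[-1] *= 1 + 1e-12
        xs, ys = [], []
        for b in range(10):
            m = (k >= edges[b]) & (k < edges[b + 1])
            if m.any():
                xs.append(np.log10(k[m].mean()))
                ys.append(np.log10(m.sum() / k.size))
        X = np.vstack([xs, np.ones(len(xs))]).T
        beta_hat, res_, *_ = np.linalg.lstsq(X, np.array(ys), rcond=None)
        ss_tot = np.sum((np.array(ys) - np.mean(ys)) ** 2)
        r2_oracle = 1 - res_[0] / ss_tot
        assert r1.r2 == pytest.approx(r2_oracle, abs=1e-10)

    def test_hub_structured_data_reaches_target(self):
        got = [pick_soft_threshold(scale_free_cascade(s)) for s in (1, 3)]
        assert all(r.reached_target and r.r2 >= 0.8 for r in got)

    def test_zero_target_selects_smallest_qualifying_power(self):
        ds = scale_free_cascade(2)
        cfg = WGCNConfig(r2_target=1e-9)
        res = pick_soft_threshold(ds, cfg)
        table = res.table
        negative = table[table["slope"] < 0]
        assert res.beta == int(negative["beta"].iloc[0])

    def test_constant_gene_rejected(self, rng):
        x = rng.normal(size=(30, 10))
        x[0] = 1.0
        with pytest.raises(DataValidationError, match="constant"):
            pick_soft_threshold(make_dataset(x))

    def test_degenerate_connectivity_rejected(self):
        with pytest.raises(DataValidationError, match="degenerate"):
            scale_free_fit(np.ones(50))


class TestFilterNoisyGenes:
    def test_independent_gene_dropped(self):
        rng = np.random.default_rng(3)
        factor = rng.normal(0, 1, 60)
        correlated = factor + rng.normal(0, 0.1, (3, 60))
        noise = rng.normal(0, 1, (1, 60))
        ds = make_dataset(np.vstack([correlated, noise]),
                          genes=["A", "B", "C", "NOISE"])
        out, dropped = filter_noisy_genes(ds, min_abs_cor=0.3)
        assert dropped == ["NOISE"]

    def test_zero_threshold_identity(self, rng):
        ds = make_dataset(rng.normal(size=(5, 10)))
        out, dropped = filter_noisy_genes(ds, min_abs_cor=0.0)
        assert dropped == [] and out.values.equals(ds.values)

    def test_duplicate_rows_never_dropped(self, rng):
        row = rng.normal(size=10)
        ds = make_dataset(np.vstack([row, row, rng.normal(size=(2, 10))]),
                          genes=["DUP1", "DUP2", "X", "Y"])
        _, dropped = filter_noisy_genes(ds, min_abs_cor=0.99)
        assert "DUP1" not in dropped and "DUP2" not in dropped


class TestDetectModules:
    def test_two_planted_blocks_recovered(self):
        """Within-block TOM far above between-block TOM: exactly two
        block-pure modules."""
        n = 100
        tom = np.full((n, n), 0.05)
        tom[:50, :50] = 0.6
        tom[50:, 50:] = 0.6
        np.fill_diagonal(tom, 1.0)
        genes = [f"G{i:03d}" for i in range(n)]
        part = detect_modules(tom, genes, WGCNConfig(min_module_size=20))
        sizes = part.sizes()
        assert len(part.modules()) == 2
        labels = part.labels()
        assert len(set(labels[:50])) == 1 and len(set(labels[50:])) == 1

    def test_identical_genes_single_module(self):
        n = 40
        tom = np.ones((n, n))
        genes = [f"G{i}" for i in range(n)]
        part = detect_modules(tom, genes, WGCNConfig(min_module_size=10))
        assert len(part.modules()) == 1
        assert part.sizes()[part.modules()[0]] == n

    def test_independent_noise_all_grey(self):
        cfg = SynthConfig(n_genes=100, n_samples_per_group=30, frac_de=0.0,
                          n_modules=0, seed=21)
        ds, _ = gen_expression(cfg)
        tom = tom_similarity(adjacency_matrix(ds, 10))
        # oracle: every dendrogram merge lies above the static cut
        part = detect_modules(tom, ds.gene_ids, WGCNConfig(min_module_size=10))
        assert part.modules() == []
        assert all(m == GREY for m in part.module_of.values())

    def test_planted_module_ari(self):
        """Five planted 40-gene modules at within-module correlation 0.8,
        60 samples: ARI of the detected non-grey partition vs truth is
        at least 0.8 for each of 10 seeds."""
        for seed in range(10):
            cfg = SynthConfig(n_genes=240, n_samples_per_group=30,
                              frac_de=0.0, n_modules=5, module_size=40,
                              module_cor=0.8, seed=seed)
            ds, truth = gen_expression(cfg)
            tom = tom_similarity(adjacency_matrix(ds, 6))
            part = detect_modules(tom, ds.gene_ids)
            non_grey = [g for g, m in part.module_of.items() if m != GREY]
            ari = adjusted_rand_score(
                [truth.module_of[g] for g in non_grey],
                [part.module_of[g] for g in non_grey],
            )
            assert ari >= 0.8, f"seed {seed}: ARI {ari:.3f}"


class TestEigengenes:
    def test_identical_profiles_give_profile_back(self):
        profile = np.array([1.0, -1.0, 2.0, -2.0, 0.5, -0.5])
        x = np.vstack([profile] * 5)
        ds = make_dataset(x)
        part = ModulePartition({g: "blue" for g in ds.gene_ids})
        eig = module_eigengenes(ds, part)
        me = eig.profiles["blue"].to_numpy()
        z = (profile - profile.mean()) / profile.std(ddof=1)
        np.testing.assert_allclose(me, z, atol=1e-10)
        assert eig.variance_explained["blue"] == pytest.approx(1.0)

    def test_two_gene_module_matches_svd_oracle(self, rng):
        x = rng.normal(size=(2, 12))
        ds = make_dataset(x)
        part = ModulePartition({g: "red" for g in ds.gene_ids})
        eig = module_eigengenes(ds, part)
        z = (x - x.mean(axis=1, keepdims=True)) / x.std(axis=1, ddof=1,
                                                        keepdims=True)
        _, _, vt = np.linalg.svd(z, full_matrices=False)
        me_oracle = vt[0] / vt[0].std(ddof=1)
        got = eig.profiles["red"].to_numpy()
        agree = np.allclose(got, me_oracle, atol=1e-8)
        flipped = np.allclose(got, -me_oracle, atol=1e-8)
        assert agree or flipped

    def test_sign_orientation_positive(self, rng):
        cfg = SynthConfig(n_genes=50, n_samples_per_group=20, frac_de=0.0,
                          n_modules=1, module_size=30, seed=2)
        ds, truth = gen_expression(cfg)
        part = ModulePartition(truth.module_of)
        part.module_of = {g: (m if m != "none" else GREY)
                          for g, m in part.module_of.items()}
        eig = module_eigengenes(ds, part)
        genes = [g for g, m in part.module_of.items() if m == "M1"]
        mean_profile = ds.values.loc[genes].mean(axis=0)
        c = np.corrcoef(eig.profiles["M1"], mean_profile)[0, 1]
        assert c > 0


class TestMergeModules:
    @staticmethod
    def _correlated_modules(target_cor: float, seed=0, n=200, size=30):
        """Two modules whose eigengenes correlate at roughly target_cor."""
        rng = np.random.default_rng(seed)
        shared = rng.normal(0, 1, n)
        mix = np.sqrt(target_cor)
        f1 = mix * shared + np.sqrt(1 - mix**2) * rng.normal(0, 1, n)
        f2 = mix * shared + np.sqrt(1 - mix**2) * rng.normal(0, 1, n)
        x = np.vstack([
            f1 + rng.normal(0, 0.05, (size, n)),
            f2 + rng.normal(0, 0.05, (size, n)),
        ])
        ds = make_dataset(x)
        part = ModulePartition(
            {g: ("blue" if i < size else "brown")
             for i, g in enumerate(ds.gene_ids)}
        )
        return ds, part

    def test_high_correlation_merges(self):
        ds, part = self._correlated_modules(0.85)
        merged, eig = merge_close_modules(ds, part, merge_height=0.25)
        assert len(merged.modules()) == 1

    def test_low_correlation_kept_separate(self):
        ds, part = self._correlated_modules(0.5)
        merged, _ = merge_close_modules(ds, part, merge_height=0.25)
        assert len(merged.modules()) == 2

    def test_three_modules_iterate_to_one(self):
        rng = np.random.default_rng(5)
        n, size = 300, 25
        shared = rng.normal(0, 1, n)
        x = np.vstack([
            shared + rng.normal(0, 0.3, (size, n)) for _ in range(3)
        ])
        ds = make_dataset(x)
        part = ModulePartition(
            {g: ["blue", "brown", "yellow"][i // size]
             for i, g in enumerate(ds.gene_ids)}
        )
        originals = module_eigengenes(ds, part)
        merged, eig = merge_close_modules(ds, part, merge_height=0.25)
        assert len(merged.modules()) == 1
        me = eig.profiles.iloc[:, 0]
        for m in originals.profiles:
            assert abs(np.corrcoef(me, originals.profiles[m])[0, 1]) >= 0.9

    def test_noop_when_all_dissimilar(self):
        ds, part = self._correlated_modules(0.1, seed=3)
        merged, _ = merge_close_modules(ds, part, merge_height=0.25)
        assert merged.module_of == part.module_of

    def test_height_correlation_duality(self):
        assert merge_height_to_correlation(0.25) == pytest.approx(0.75)
        for h in np.linspace(0.01, 0.99, 13):
            assert merge_height_to_correlation(h) == pytest.approx(1 - h)


class TestDropUnassigned:
    def test_grey_removed(self):
        part = ModulePartition({"A": "blue", "B": GREY, "C": "blue"})
        assert drop_unassigned(part) == ["A", "C"]

    def test_no_grey_keeps_all(self):
        part = ModulePartition({"A": "blue", "B": "brown"})
        assert drop_unassigned(part) == ["A", "B"]

    def test_all_grey_warns_empty(self):
        part = ModulePartition({"A": GREY})
        with pytest.warns(UserWarning):
            assert drop_unassigned(part) == []
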