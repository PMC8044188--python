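"""Admixture likelihood/EM, CV K-selection, Fst, the Fst tree, and PCA."""

import numpy as np
import pytest

from heteropop.admixture import (cv_error, fit_admixture, fst_matrix,
                                 fst_pairwise, fst_tree, loglik,
                                 pca_coordinates)
from heteropop.genotype_io import MISSING, GenotypeMatrix, alt_freq
from heteropop.simpop import SimConfig, simulate_panel


def naive_loglik(g, Q, P):
    total = 0.0
    for i in range(g.shape[0]):
        for j in range(g.shape[1]):
            if g[i, j] == MISSING:
                continue
            pi = min(max(float(Q[i] @ P[:, j]), 1e-6), 1 - 1e-6)
            total += g[i, j] * np.log(pi) + (2 - g[i, j]) * np.log(1 - pi)
    return total


class TestLoglik:
    def test_k1_collapses_to_binomial(self):
        rng = np.random.default_rng(0)
        g = rng.integers(0, 3, size=(10, 20)).astype(np.int8)
        p = rng.uniform(0.1, 0.9, 20)
        Q = np.ones((10, 1))
        P = p[None, :]
        expect = np.sum(g * np.log(p) + (2 - g) * np.log(1 - p))
        assert loglik(g, Q, P) == pytest.approx(expect)

    def test_single_entry(self):
        g = np.array([[2]], dtype=np.int8)
        assert loglik(g, np.array([[1.0]]), np.array([[0.5]])) == \
            pytest.approx(2 * np.log(0.5))

    def test_matches_naive_summation(self):
        rng = np.random.default_rng(1)
        g = rng.integers(-1, 3, size=(8, 15)).astype(np.int8)
        Q = rng.dirichlet(np.ones(3), size=8)
        P = rng.uniform(0.05, 0.95, size=(3, 15))
        assert loglik(g, Q, P) == pytest.approx(naive_loglik(g, Q, P))

    def test_shape_mismatch_errors(self):
        g = np.zeros((4, 5), dtype=np.int8)
        with pytest.raises(ValueError):
            loglik(g, np.ones((4, 2)) / 2, np.full((3, 5), 0.5))


class TestFitAdmixture:
    def test_k1_closed_form(self):
        rng = np.random.default_rng(2)
        g = (rng.random((20, 50)) < 0.3).astype(np.int8) * 2
        Q, P, trace = fit_admixture(g, 1)
        assert np.allclose(Q, 1.0)
        assert np.allclose(P[0], alt_freq(g), atol=1e-6)

    def test_monotone_loglik_trace(self):
        cfg = SimConfig(n_lines=60, n_loci=300, K_true=2,
                        divergence_F=(0.3,), pure_fraction=1.0, seed=4)
        G, *_ = simulate_panel(cfg)
        _, _, trace = fit_admixture(G, 2, seed=0, n_restarts=1,
                                    max_iter=200)
        assert np.all(np.diff(trace) >= -1e-8)

    def test_pure_panel_recovery_k2(self):
        cfg = SimConfig(n_lines=200, n_loci=2000, K_true=2,
                        divergence_F=(0.3,), pure_fraction=1.0, seed=6)
        G, _, _, truth = simulate_panel(cfg)
        Q, _, _ = fit_admixture(G, 2, seed=0, n_restarts=2, max_iter=400)
        err = min(np.abs(Q - truth.true_Q).mean(),
                  np.abs(Q[:, ::-1] - truth.true_Q).mean())
        assert err < 0.05

    def test_k_exceeding_lines_errors(self):
        g = np.zeros((3, 5), dtype=np.int8)
        g[0] = 2
        with pytest.raises(ValueError):
            fit_admixture(g, 4)

    def test_deterministic_given_seed(self):
        cfg = SimConfig(n_lines=40, n_loci=200, K_true=2,
                        divergence_F=(0.3,), seed=5)
        G, *_ = simulate_panel(cfg)
        Q1, P1, _ = fit_admixture(G, 2, seed=3, n_restarts=2, max_iter=100)
        Q2, P2, _ = fit_admixture(G, 2, seed=3, n_restarts=2, max_iter=100)
        assert np.array_equal(Q1, Q2) and np.array_equal(P1, P2)


class TestCVError:
    def test_mask_rate_zero_errors(self):
        g = (np.random.default_rng(0).random((10, 20)) < 0.5
             ).astype(np.int8) * 2
        with pytest.raises(ValueError):
            cv_error(g, 2, mask_rate=0.0)

    def test_k1_worse_than_true_k(self):
        cfg = SimConfig(n_lines=100, n_loci=800, K_true=3,
                        divergence_F=(0.3,), seed=7)
        G, *_ = simulate_panel(cfg)
        assert cv_error(G, 1, seed=0) > cv_error(G, 3, seed=0)


class TestFst:
    def test_identical_groups_zero(self):
        p = np.array([0.2, 0.5, 0.8])
        assert fst_pairwise(p, p) == 0.0

    def test_opposite_fixation_one(self):
        a = np.ones(10)
        b = np.zeros(10)
        assert fst_pairwise(a, b) == pytest.approx(1.0)

    def test_printed_frequency_pair(self):
        # single locus, group frequencies 0.945 and 0.213:
        # HT = 0.48752, HS = 0.21961 -> Fst = 0.5495
        assert fst_pairwise([0.945], [0.213]) == pytest.approx(0.5495,
                                                               abs=1e-4)

    def test_monotone_in_divergence(self):
        means = []
        for F in (0.05, 0.1, 0.2, 0.3):
            vals = []
            for seed in range(3):
                cfg = SimConfig(n_lines=120, n_loci=2000, K_true=2,
                                divergence_F=(F,), pure_fraction=1.0,
                                residual_het_rate=0.0, missing_rate=0.0,
                                seed=seed)
                G, _, _, truth = simulate_panel(cfg)
                grp = truth.true_group
                vals.append(fst_pairwise(alt_freq(G.values[grp == 0]),
                                         alt_freq(G.values[grp == 1])))
            means.append(np.mean(vals))
        assert np.all(np.diff(means) > 0)

    def test_estimate_tracks_true_P_oracle(self):
        """Fst from sample frequencies stays within 25% of the value
        computed directly from the generating P matrix."""
        cfg = SimConfig(n_lines=400, n_loci=3000, K_true=2,
                        divergence_F=(0.2,), pure_fraction=1.0,
                        residual_het_rate=0.0, missing_rate=0.0, seed=10)
        G, _, _, truth = simulate_panel(cfg)
        grp = truth.true_group
        est = fst_pairwise(alt_freq(G.values[grp == 0]),
                           alt_freq(G.values[grp == 1]))
        oracle = fst_pairwise(truth.true_P[0], truth.true_P[1])
        assert abs(est - oracle) / oracle < 0.25

    def test_no_usable_loci_errors(self):
        with pytest.raises(ValueError):
            fst_pairwise([np.nan], [0.5])


class TestFstTree:
    def test_two_group_cherry(self):
        import pandas as pd
        fst = pd.DataFrame([[0.0, 0.3], [0.3, 0.0]],
                           index=["A", "B"], columns=["A", "B"])
        nwk = fst_tree(fst)
        assert nwk == "(A:0.150000,B:0.150000);"

    def test_closest_pair_joined_first(self):
        import pandas as pd
        m = np.array([[0.0, 0.1, 0.5], [0.1, 0.0, 0.5], [0.5, 0.5, 0.0]])
        fst = pd.DataFrame(m, index=list("ABC"), columns=list("ABC"))
        nwk = fst_tree(fst)
        assert "(A:0.050000,B:0.050000)" in nwk

    def test_ultrametric_heights(self):
        """UPGMA output is ultrametric: all leaves at equal depth."""
        import io

        import pandas as pd
        from Bio import Phylo

        rng = np.random.default_rng(1)
        k = 5
        m = rng.uniform(0.1, 0.4, (k, k))
        m = (m + m.T) / 2
        np.fill_diagonal(m, 0.0)
        labels = [f"G{i}" for i in range(k)]
        nwk = fst_tree(pd.DataFrame(m, index=labels, columns=labels))
        tree = Phylo.read(io.StringIO(nwk), "newick")
        depths = tree.depths()
        leaf_depths = [d for cl, d in depths.items() if cl.is_terminal()]
        assert len(leaf_depths) == k
        assert np.allclose(leaf_depths, leaf_depths[0], atol=1e-6)


class TestPCA:
    def test_two_clusters_separated_on_pc1(self):
        rng = np.random.default_rng(0)
        a = (rng.random(100) < 0.5).astype(np.int8) * 2
        b = (rng.random(100) < 0.5).astype(np.int8) * 2
        v = np.vstack([np.tile(a, (5, 1)), np.tile(b, (5, 1))])
        coords = pca_coordinates(GenotypeMatrix(v), 2)
        pc1 = coords["PC1"].to_numpy()
        assert (pc1[:5].mean() - pc1[5:].mean()) ** 2 > \
            4 * (pc1[:5].var() + pc1[5:].var() + 1e-12)

    def test_three_group_silhouette(self):
        from sklearn.metrics import silhouette_score
        cfg = SimConfig(n_lines=90, n_loci=1000, K_true=3,
                        divergence_F=(0.3,), pure_fraction=1.0, seed=12)
        G, _, _, truth = simulate_panel(cfg)
        coords = pca_coordinates(G, 2).to_numpy()
        assert silhouette_score(coords, truth.true_group) > 0.5

    def test_variance_ordering(self, small_panel):
        G, *_ = small_panel
        coords = pca_coordinates(G, 5).to_numpy()
        var = coords.var(axis=0)
        assert np.all(np.diff(var) <= 1e-9)
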