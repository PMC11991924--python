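"""Ordination: CCA against independent oracles and its invariances; trait
PCA closed forms; Ward clustering with the elbow rule."""

import shutil
import subprocess
import tempfile
from pathlib import Path

import numpy as np
import pandas as pd
import pytest
import scipy.linalg as sla

import phytoniche as pn


def cca_eigen_oracle(Y, X):
    """Canonical eigenvalues by the generalized-eigenproblem route: a
    q x q symmetric eigenproblem in the metric of the weighted constraints,
    independent of the SVD path used by the implementation."""
    Y = np.asarray(Y, dtype=float)
    X = np.asarray(X, dtype=float)
    P = Y / Y.sum()
    r, c = P.sum(1), P.sum(0)
    Q = (P - np.outer(r, c)) / np.sqrt(np.outer(r, c))
    Xc = X - r @ X
    Xw = np.sqrt(r)[:, None] * Xc
    Mi = sla.fractional_matrix_power(Xw.T @ Xw, -0.5)
    G = Mi @ Xw.T @ Q @ Q.T @ Xw @ Mi
    ev = np.sort(sla.eigh(G)[0].real)[::-1]
    return ev[ev > 1e-12]


class TestCCA:
    def toy(self):
        rng = np.random.default_rng(0)
        Y = rng.integers(1, 30, (4, 3)).astype(float)
        X = rng.normal(size=(4, 2))
        return Y, X

    def test_toy_matches_generalized_eigen_oracle(self):
        Y, X = self.toy()
        res = pn.cca(Y, X)
        oracle = cca_eigen_oracle(Y, X)
        np.testing.assert_allclose(res.eigenvalues, oracle[:len(
            res.eigenvalues)], atol=1e-8)

    def test_matches_vegan_on_random_table(self):
        if shutil.which("Rscript") is None:
            pytest.skip("Rscript unavailable")
        rng = np.random.default_rng(1)
        Y = rng.integers(1, 40, (10, 4)).astype(float)
        X = rng.normal(size=(10, 2))
        res = pn.cca(Y, X)
        with tempfile.TemporaryDirectory() as d:
            pd.DataFrame(Y).to_csv(f"{d}/Y.csv", index=False)
            pd.DataFrame(X, columns=["a", "b"]).to_csv(f"{d}/X.csv",
                                                       index=False)
            out = subprocess.run(
                ["Rscript", "-e",
                 f'suppressMessages(library(vegan));'
                 f'Y<-read.csv("{d}/Y.csv");X<-read.csv("{d}/X.csv");'
                 f'm<-cca(Y~.,data=X);'
                 f'cat(m$CCA$eig,"\\n",m$tot.chi,"\\n")'],
                capture_output=True, text=True, timeout=120)
        assert out.returncode == 0, out.stderr
        lines = out.stdout.strip().splitlines()
        vegan_eig = np.array([float(v) for v in lines[0].split()])
        vegan_tot = float(lines[1])
        np.testing.assert_allclose(res.eigenvalues, vegan_eig, rtol=1e-6)
        assert res.total_inertia == pytest.approx(vegan_tot, rel=1e-6)

    def test_constrained_inertia_bounded_by_total(self):
        rng = np.random.default_rng(2)
        for _ in range(10):
            Y = rng.uniform(0.1, 20, (8, 5))
            X = rng.normal(size=(8, 3))
            res = pn.cca(Y, X)
            assert res.eigenvalues.sum() <= res.total_inertia + 1e-10
            assert 0 <= res.proportion_explained <= 1
            assert (np.diff(res.eigenvalues) <= 1e-12).all()
            assert (res.eigenvalues >= 0).all()

    def test_saturating_constraints_reproduce_unconstrained_axis(self):
        # X spanning all site contrasts: first canonical eigenvalue equals
        # the first correspondence-analysis eigenvalue
        rng = np.random.default_rng(3)
        Y = rng.integers(1, 30, (5, 4)).astype(float)
        X = np.eye(5)[:, :4]  # full site indicators (one dropped)
        res = pn.cca(Y, X)
        P = Y / Y.sum()
        r, c = P.sum(1), P.sum(0)
        Q = (P - np.outer(r, c)) / np.sqrt(np.outer(r, c))
        ca_eig = np.linalg.svd(Q, compute_uv=False) ** 2
        assert res.eigenvalues[0] == pytest.approx(ca_eig[0], abs=1e-10)

    def test_noise_constraint_explains_little(self):
        rng = np.random.default_rng(4)
        n = 100
        grad = np.linspace(0, 1, n)
        Y = np.column_stack([np.exp(-((grad - m) ** 2) / 0.02)
                             for m in (0.2, 0.5, 0.8)]) + 0.01
        X = rng.normal(size=(n, 1))
        res = pn.cca(Y, X)
        assert res.proportion_explained < 0.05

    def test_row_permutation_invariance(self):
        Y, X = self.toy()
        perm = np.array([2, 0, 3, 1])
        a = pn.cca(Y, X)
        b = pn.cca(Y[perm], X[perm])
        np.testing.assert_allclose(a.eigenvalues, b.eigenvalues, atol=1e-12)

    def test_centering_and_scale_invariance(self):
        Y, X = self.toy()
        a = pn.cca(Y, X)
        b = pn.cca(Y, X + 17.0)          # constant shift of constraints
        c = pn.cca(3.5 * Y, X)           # positive rescale of community
        np.testing.assert_allclose(a.eigenvalues, b.eigenvalues, atol=1e-10)
        np.testing.assert_allclose(a.eigenvalues, c.eigenvalues, atol=1e-10)
        assert a.proportion_explained == pytest.approx(
            c.proportion_explained, abs=1e-12)

    def test_collinear_columns_dropped_with_warning(self):
        Y, X = self.toy()
        X2 = np.column_stack([X, X[:, 0] * 2.0])
        with pytest.warns(RuntimeWarning, match="aliased"):
            res = pn.cca(pd.DataFrame(Y), pd.DataFrame(
                X2, columns=["a", "b", "a_twice"]))
        assert res.aliased == ["a_twice"]
        np.testing.assert_allclose(res.eigenvalues,
                                   pn.cca(Y, X).eigenvalues, atol=1e-10)

    def test_zero_rows_dropped_with_notice(self):
        Y, X = self.toy()
        Y2 = np.vstack([Y, np.zeros(3)])
        X2 = np.vstack([X, [0.5, 0.5]])
        with pytest.warns(RuntimeWarning, match="all-zero"):
            res = pn.cca(Y2, X2)
        np.testing.assert_allclose(res.eigenvalues,
                                   pn.cca(Y, X).eigenvalues, atol=1e-12)


def _niche_table(trait_cols):
    """Build a tidy niche table whose pivoted trait columns equal the given
    dict of {column_name: values} (columns named mu_<v> / sigma_<v>)."""
    groups = [f"g{i}" for i in range(len(next(iter(trait_cols.values()))))]
    variables = sorted({name.split("_", 1)[1] for name in trait_cols})
    rows = []
    for i, g in enumerate(groups):
        for v in variables:
            rows.append({
                "group": g, "variable": v,
                "mu": trait_cols.get(f"mu_{v}", np.zeros(len(groups)))[i],
                "sigma": trait_cols.get(f"sigma_{v}",
                                        np.ones(len(groups)))[i]})
    return pd.DataFrame(rows)


class TestPCATraits:
    def test_two_perfectly_correlated_traits_load_on_pc1(self):
        base = np.array([1.0, 2.0, 4.0, 8.0, 9.0])
        tab = _niche_table({"mu_t": base, "sigma_t": 2 * base + 3})
        space = pn.pca_traits(tab)
        assert space.variance_fractions[0] == pytest.approx(1.0, abs=1e-10)

    def test_known_correlation_eigenvalues(self):
        # informative traits (t1, t1 copy, t2 orthogonal): correlation
        # eigenvalues {2, 1, 0} -> variance fractions {2/3, 1/3, 0};
        # the constant fourth trait is dropped with a warning
        t1 = np.array([1.0, -1.0, 1.0, -1.0])
        t2 = np.array([1.0, 1.0, -1.0, -1.0])
        tab = _niche_table({"mu_a": t1, "sigma_a": t1.copy(), "mu_b": t2,
                            "sigma_b": np.ones(4)})
        with pytest.warns(RuntimeWarning, match="constant"):
            space = pn.pca_traits(tab)
        np.testing.assert_allclose(space.variance_fractions,
                                   [2 / 3, 1 / 3, 0.0], atol=1e-10)

    def test_variance_fractions_sum_to_one(self):
        rng = np.random.default_rng(5)
        tab = _niche_table({f"mu_v{j}": rng.normal(size=6)
                            for j in range(4)})
        space = pn.pca_traits(tab)
        assert space.variance_fractions.sum() == pytest.approx(1.0)
        assert (space.traits.mean().abs() < 1e-9).all()
        assert (np.abs(space.traits.std(ddof=1) - 1) < 1e-9).all()

    def test_scores_orthogonal(self):
        rng = np.random.default_rng(6)
        tab = _niche_table({f"mu_v{j}": rng.normal(size=7)
                            for j in range(5)})
        space = pn.pca_traits(tab)
        G = space.scores.to_numpy().T @ space.scores.to_numpy()
        off = G - np.diag(np.diag(G))
        assert np.abs(off).max() < 1e-8


class TestClustering:
    def test_three_separated_triplets_recovered(self):
        # three tight triplets at the corners of a triangle
        rng = np.random.default_rng(7)
        centers = np.array([[0.0, 0.0], [10.0, 0.0], [5.0, 9.0]])
        pts = np.vstack([c + 0.05 * rng.normal(size=(3, 2))
                         for c in centers])
        space = pn.TraitSpace(
            traits=pd.DataFrame(), loadings=pd.DataFrame(),
            variance_fractions=np.array([0.7, 0.3]),
            scores=pd.DataFrame(pts, columns=["PC1", "PC2"],
                                index=[f"g{i}" for i in range(9)]))
        labels, scree = pn.cluster_trait_space(space, "auto")
        assert labels.nunique() == 3
        for i in range(3):
            assert labels.iloc[3 * i:3 * i + 3].nunique() == 1
        assert (scree["wss"].diff().dropna() <= 1e-9).all()

    def test_identical_points_single_cluster(self):
        pts = np.ones((5, 2))
        space = pn.TraitSpace(
            traits=pd.DataFrame(), loadings=pd.DataFrame(),
            variance_fractions=np.array([1.0]),
            scores=pd.DataFrame(pts, columns=["PC1", "PC2"]))
        labels, _ = pn.cluster_trait_space(space, "auto")
        assert labels.nunique() == 1

    def test_k_exceeding_groups_rejected(self):
        pts = np.random.default_rng(8).normal(size=(4, 2))
        space = pn.TraitSpace(
            traits=pd.DataFrame(), loadings=pd.DataFrame(),
            variance_fractions=np.array([0.6, 0.4]),
            scores=pd.DataFrame(pts, columns=["PC1", "PC2"]))
        with pytest.raises(ValueError):
            pn.cluster_trait_space(space, 9)

    def test_label_structure_invariant_to_row_order(self):
        rng = np.random.default_rng(9)
        pts = np.vstack([rng.normal(0, 0.1, (3, 2)),
                         rng.normal(5, 0.1, (3, 2))])
        names = [f"g{i}" for i in range(6)]
        space = pn.TraitSpace(
            traits=pd.DataFrame(), loadings=pd.DataFrame(),
            variance_fractions=np.array([0.5, 0.5]),
            scores=pd.DataFrame(pts, columns=["PC1", "PC2"], index=names))
        labels1, _ = pn.cluster_trait_space(space, 2)
        perm = [3, 1, 5, 0, 2, 4]
        space2 = pn.TraitSpace(
            traits=pd.DataFrame(), loadings=pd.DataFrame(),
            variance_fractions=np.array([0.5, 0.5]),
            scores=space.scores.iloc[perm])
        labels2, _ = pn.cluster_trait_space(space2, 2)
        # same partition up to relabeling
        for a in names:
            for b in names:
                assert (labels1[a] == labels1[b]) == \
                    (labels2[a] == labels2[b])


def test_default_niche_traits_cluster_into_ecological_groups():
    """The generator's trait structure: warm-eutrophic pair, cool pair and
    the distinct dinoflagellate group."""
    cfg = pn.default_scenario()
    rows = [(g, v, *cfg.true_niches[g][v])
            for g in cfg.groups for v in cfg.niche_variables]
    tab = pd.DataFrame(rows, columns=["group", "variable", "mu", "sigma"])
    space = pn.pca_traits(tab)
    labels, _ = pn.cluster_trait_space(space, "auto")
    assert labels.nunique() == 3
    assert labels["Chlorophyta"] == labels["Cyanophyta"]
    assert labels["Bacillariophyta"] == labels["Cryptophyta"]
    assert labels["Pyrrophyta"] not in (labels["Chlorophyta"],
                                        labels["Bacillariophyta"])
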