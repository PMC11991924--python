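"""Constrained and unconstrained ordination of community and niche data.

* :func:`cca` — canonical correspondence analysis by the weighted-averaging
  eigen formulation: the chi-square standardized community matrix is
  regressed on the environmental variables with row-mass weights and the
  fitted matrix is decomposed by SVD.  Canonical eigenvalues, total inertia
  and the proportion of community variance explained by the constraints are
  reported along with site scores, species scores and biplot arrows.
* :func:`pca_traits` — PCA of the z-scored niche traits (mu and sigma per
  variable) of the phytoplankton groups, via the correlation matrix.
* :func:`cluster_trait_space` — Ward hierarchical clustering on Euclidean
  distances of the standardized first two principal components, with the
  number of clusters chosen at the elbow (maximal second difference) of the
  within-cluster sum-of-squares scree curve.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage

__all__ = ["CCAResult", "TraitSpace", "cca", "pca_traits",
           "cluster_trait_space"]


@dataclass
class CCAResult:
    eigenvalues: np.ndarray
    total_inertia: float
    proportion_explained: float
    site_scores: pd.DataFrame
    species_scores: pd.DataFrame
    biplot_scores: pd.DataFrame
    aliased: list[str] = field(default_factory=list)
    dropped_sites: list = field(default_factory=list)


@dataclass
class TraitSpace:
    traits: pd.DataFrame              # z-scored trait matrix (groups x traits)
    scores: pd.DataFrame              # PC scores (groups x components)
    variance_fractions: np.ndarray
    loadings: pd.DataFrame
    dropped_traits: list[str] = field(default_factory=list)
    cluster_labels: pd.Series | None = None


def _as_frame(M, prefix: str) -> pd.DataFrame:
    if isinstance(M, pd.DataFrame):
        return M
    M = np.asarray(M, dtype=float)
    return pd.DataFrame(M, columns=[f"{prefix}{j}" for j in
                                    range(M.shape[1])])


def cca(Y, X) -> CCAResult:
    """Canonical correspondence analysis of community table Y on
    environmental matrix X.

    Y must be non-negative with positive grand total; all-zero rows
    (sites) and columns (species) are dropped with a notice.  Collinear X
    columns are detected by pivoted QR and dropped (reported in
    ``aliased``).  Species scores use species-focused (scaling-2)
    weighting; biplot arrows are weighted correlations of the variables
    with the constrained site scores.
    """
    Yf = _as_frame(Y, "sp")
    Xf = _as_frame(X, "env")
    if len(Yf) != len(Xf):
        raise ValueError("Y and X must have the same number of rows")
    Ym = Yf.to_numpy(dtype=float)
    if (Ym < 0).any():
        raise ValueError("community matrix must be non-negative")
    keep_rows = Ym.sum(axis=1) > 0
    dropped_sites = list(Yf.index[~keep_rows])
    if dropped_sites:
        warnings.warn(f"dropping {len(dropped_sites)} all-zero site(s)",
                      RuntimeWarning, stacklevel=2)
    keep_cols = Ym.sum(axis=0) > 0
    Ym = Ym[keep_rows][:, keep_cols]
    Xm = Xf.to_numpy(dtype=float)[keep_rows]
    site_index = Yf.index[keep_rows]
    species = list(Yf.columns[keep_cols])
    if not np.isfinite(Xm).all():
        raise ValueError("environmental matrix must be finite")

    total = Ym.sum()
    P = Ym / total
    r = P.sum(axis=1)
    c = P.sum(axis=0)
    E = np.outer(r, c)
    Qbar = (P - E) / np.sqrt(E)
    total_inertia = float((Qbar ** 2).sum())

    # weighted centering and scaling of constraints
    Xc = Xm - r @ Xm
    Xw = np.sqrt(r)[:, None] * Xc
    # collinearity: QR, drop later columns with negligible diagonal pivot
    Qx, Rx = np.linalg.qr(Xw, mode="reduced")
    diag = np.abs(np.diag(Rx))
    scale = diag.max() if diag.size and diag.max() > 0 else 1.0
    ok = diag > 1e-10 * scale
    aliased = [str(Xf.columns[j]) for j in np.where(~ok)[0]]
    if aliased:
        warnings.warn(f"dropping aliased variable(s): {aliased}",
                      RuntimeWarning, stacklevel=2)
        keep = [j for j in range(Xw.shape[1]) if str(Xf.columns[j])
                not in aliased]
        Xw = Xw[:, keep]
        Qx, Rx = np.linalg.qr(Xw, mode="reduced")
    # projection of Qbar onto the span of the weighted constraints
    Yhat = Qx @ (Qx.T @ Qbar)
    U, S, Vt = np.linalg.svd(Yhat, full_matrices=False)
    rank = int(np.sum(S > 1e-12 * (S[0] if S.size else 1.0)))
    rank = min(rank, Xw.shape[1], Ym.shape[1] - 1)
    U, S, Vt = U[:, :rank], S[:rank], Vt[:rank]
    eig = S ** 2
    constrained = float(eig.sum())
    axes = [f"CCA{j + 1}" for j in range(rank)]
    site = U / np.sqrt(r)[:, None]
    spp = (Vt.T / np.sqrt(c)[:, None]) * S  # scaling 2
    # biplot arrows: weighted correlation of each variable with site axes
    Xn = Xw / np.linalg.norm(Xw, axis=0, keepdims=True)
    bip = Xn.T @ U
    env_names = [str(n) for n in Xf.columns if str(n) not in aliased]
    return CCAResult(
        eigenvalues=eig,
        total_inertia=total_inertia,
        proportion_explained=constrained / total_inertia,
        site_scores=pd.DataFrame(site, index=site_index, columns=axes),
        species_scores=pd.DataFrame(spp, index=species, columns=axes),
        biplot_scores=pd.DataFrame(bip, index=env_names, columns=axes),
        aliased=aliased,
        dropped_sites=dropped_sites,
    )


def pca_traits(niches: pd.DataFrame) -> TraitSpace:
    """PCA of standardized niche traits.

    ``niches`` is the tidy NicheEstimate table (columns group, variable, mu,
    sigma); it is pivoted to one row per group with ``mu_<var>`` and
    ``sigma_<var>`` columns, each z-scored, and decomposed through the
    correlation matrix (SVD of the standardized matrix).  Groups with any
    missing trait are removed listwise; constant traits are dropped.
    """
    need = {"group", "variable", "mu", "sigma"}
    if not need.issubset(niches.columns):
        raise KeyError(f"niche table needs columns {sorted(need)}")
    wide_mu = niches.pivot(index="group", columns="variable", values="mu")
    wide_sd = niches.pivot(index="group", columns="variable", values="sigma")
    wide = pd.concat([wide_mu.add_prefix("mu_"),
                      wide_sd.add_prefix("sigma_")], axis=1)
    before = len(wide)
    wide = wide.dropna(axis=0)
    if len(wide) < before:
        warnings.warn(f"removed {before - len(wide)} group(s) with missing "
                      "traits", RuntimeWarning, stacklevel=2)
    if len(wide) < 2 or wide.shape[1] < 2:
        raise ValueError("need at least 2 groups and 2 traits")
    sd = wide.std(ddof=1)
    dropped = list(wide.columns[sd == 0])
    if dropped:
        warnings.warn(f"dropping constant trait(s): {dropped}",
                      RuntimeWarning, stacklevel=2)
        wide = wide.drop(columns=dropped)
        sd = sd.drop(index=dropped)
    Z = (wide - wide.mean()) / sd
    n, p = Z.shape
    U, S, Vt = np.linalg.svd(Z.to_numpy(dtype=float), full_matrices=False)
    eig = S ** 2 / (n - 1)            # eigenvalues of the correlation matrix
    fractions = eig / eig.sum()
    comps = [f"PC{j + 1}" for j in range(len(S))]
    scores = pd.DataFrame(U * S, index=Z.index, columns=comps)
    loadings = pd.DataFrame(Vt.T, index=Z.columns, columns=comps)
    return TraitSpace(traits=Z, scores=scores, variance_fractions=fractions,
                      loadings=loadings, dropped_traits=dropped)


def _wss(points: np.ndarray, labels: np.ndarray) -> float:
    tot = 0.0
    for lab in np.unique(labels):
        sub = points[labels == lab]
        tot += float(((sub - sub.mean(axis=0)) ** 2).sum())
    return tot


def cluster_trait_space(space: TraitSpace, k: int | str = "auto"
                        ) -> tuple[pd.Series, pd.DataFrame]:
    """Ward clustering of groups in standardized PC1-PC2 space.

    The scree data are the within-cluster sums of squares for every cut of
    the Ward tree; for ``k='auto'`` the cluster count is the elbow of that
    curve (the k maximising its second difference).  Returns the labels and
    the scree table, and stores the labels on ``space``.
    """
    if "PC2" not in space.scores.columns:
        raise ValueError("need at least two principal components")
    pts = space.scores[["PC1", "PC2"]].to_numpy(dtype=float)
    sd = pts.std(axis=0, ddof=1)
    pts = (pts - pts.mean(axis=0)) / np.where(sd > 0, sd, 1.0)
    n = len(pts)
    if isinstance(k, (int, np.integer)) and k > n:
        raise ValueError(f"k={k} exceeds the number of groups ({n})")
    Zl = linkage(pts, method="ward")
    wss = {1: _wss(pts, np.zeros(n, dtype=int))}
    labels_by_k = {1: np.ones(n, dtype=int)}
    for kk in range(2, n + 1):
        lab = fcluster(Zl, kk, criterion="maxclust")
        labels_by_k[kk] = lab
        wss[kk] = _wss(pts, lab)
    scree = pd.DataFrame({"k": sorted(wss), "wss": [wss[j] for j in
                                                    sorted(wss)]})
    if k == "auto":
        if wss[1] < 1e-12:          # all points coincide
            k = 1
        elif n <= 2:
            k = 1 if wss[1] < 1e-12 else min(n, 2)
        else:
            cand = range(2, n)
            second = {j: wss[j - 1] - 2 * wss[j] + wss[j + 1] for j in cand}
            k = max(second, key=second.get)
    labels = pd.Series(labels_by_k[int(k)], index=space.scores.index,
                       name="cluster")
    space.cluster_labels = labels
    return labels, scree
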