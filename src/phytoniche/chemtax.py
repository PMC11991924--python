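"""Pigment-based chemotaxonomic decomposition (CHEMTAX-style).

Given a samples x pigments concentration table and a groups x pigments
ratio matrix F (pigment : chlorophyll-a mass ratios, chlorophyll-a column
fixed at 1), the model is

    s_i  ~  c_i . F        c_i >= 0

where ``c_i`` is the vector of per-group chlorophyll-a contributions in
sample i.  Estimation alternates two exact steps:

* composition step — per-sample non-negative least squares at the current F;
* ratio step — each free (initially non-zero) entry of F is updated by
  exact coordinate descent with box constraints that keep it non-negative
  and within a configured fraction of its value at the start of the run.

Both steps minimise the same weighted squared residual, so the objective is
non-increasing by construction.  The successive-runs protocol re-feeds each
run's output matrix as the next run's input (and re-centres the ratio bounds
on it), which lets ratios drift further than a single bounded run allows
while recording the residual after every run.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import nnls

__all__ = [
    "DEFAULT_MARKERS",
    "ChemtaxResult",
    "column_weights",
    "solve_composition",
    "optimize_ratios",
    "successive_runs",
    "validate_against_markers",
]

#: Conventional diagnostic (marker) pigment of each group.
DEFAULT_MARKERS = {
    "Pyrrophyta": "peridinin",
    "Bacillariophyta": "fucoxanthin",
    "Cryptophyta": "alloxanthin",
    "Cyanophyta": "zeaxanthin",
    "Chlorophyta": "chlorophyll_b",
}

CHLA_ALIASES = ("tchla", "TChl a", "TChl_a", "chlorophyll_a", "chl_a")


def _chla_column(columns) -> str:
    for name in CHLA_ALIASES:
        if name in columns:
            return name
    raise KeyError(
        "no total chlorophyll a column found (expected one of "
        f"{CHLA_ALIASES})")


def _check_ratio_matrix(ratios: pd.DataFrame) -> str:
    if (ratios.to_numpy() < 0).any():
        raise ValueError("ratio matrix entries must be >= 0")
    chla = _chla_column(ratios.columns)
    if not np.allclose(ratios[chla], 1.0):
        raise ValueError("chlorophyll-a column of the ratio matrix must be 1")
    return chla


def column_weights(ratios: pd.DataFrame) -> np.ndarray:
    """Per-pigment weights: inverse of the column maximum of the initial
    ratio matrix, so that minor pigments are not swamped by total
    chlorophyll a.  Columns with an all-zero ratio get weight 1.
    """
    cmax = ratios.to_numpy(dtype=float).max(axis=0)
    return np.where(cmax > 0, 1.0 / np.where(cmax > 0, cmax, 1.0), 1.0)


@dataclass
class ChemtaxResult:
    """Outcome of a successive-runs chemotaxonomic fit."""

    ratios: pd.DataFrame
    composition: pd.DataFrame
    rmse_trajectory: list[float]
    n_runs: int
    warnings: list[str] = field(default_factory=list)


def _align(pigments: pd.DataFrame, ratios: pd.DataFrame):
    missing = [p for p in ratios.columns if p not in pigments.columns]
    if missing:
        raise KeyError(
            f"pigment column(s) missing from table: {missing}")
    S = pigments[list(ratios.columns)].to_numpy(dtype=float)
    if (S < 0).any():
        raise ValueError("pigment concentrations must be >= 0")
    return S


def solve_composition(pigments: pd.DataFrame, ratios: pd.DataFrame,
                      weights: np.ndarray | None = None) -> pd.DataFrame:
    """Per-sample non-negative least squares at a fixed ratio matrix.

    Returns a sample x group table of chlorophyll-a contributions (ng/L)
    plus an ``rmse`` column: the root-mean-square weighted pigment residual
    of each sample.  All-zero samples get a zero composition, zero residual
    and ``all_zero=True``.
    """
    chla = _check_ratio_matrix(ratios)
    del chla
    S = _align(pigments, ratios)
    F = ratios.to_numpy(dtype=float)
    w = column_weights(ratios) if weights is None else np.asarray(weights)
    A = (F * w).T  # pigments x groups design
    n, m = S.shape
    C = np.zeros((n, F.shape[0]))
    rmse = np.zeros(n)
    zero = np.zeros(n, dtype=bool)
    for i in range(n):
        s = S[i]
        if not s.any():
            zero[i] = True
            continue
        c, res = nnls(A, s * w)
        C[i] = c
        rmse[i] = res / np.sqrt(m)
    out = pd.DataFrame(C, columns=list(ratios.index))
    if "sample_id" in pigments.columns:
        out.insert(0, "sample_id", pigments["sample_id"].to_numpy())
    out["rmse"] = rmse
    out["all_zero"] = zero
    return out


def _total_rmse(S, F, C, w) -> float:
    R = (S - C @ F) * w
    return float(np.sqrt(np.mean(R ** 2)))


def _column_candidate(G, diag, b, f0, lo_p, hi_p, n_sweeps: int = 50,
                      tol: float = 1e-12) -> np.ndarray:
    """Box-constrained minimiser of ||s_p - C f||^2 over one pigment column
    by exact coordinate descent (each coordinate update is the
    unconstrained minimiser clipped to its box, so the objective never
    increases)."""
    f = f0.copy()
    for _ in range(n_sweeps):
        delta = 0.0
        for g in range(len(f)):
            if diag[g] <= 0 or lo_p[g] == hi_p[g]:
                continue
            new = (b[g] - G[g] @ f + diag[g] * f[g]) / diag[g]
            new = min(max(new, lo_p[g]), hi_p[g])
            delta = max(delta, abs(new - f[g]))
            f[g] = new
        if delta < tol * (1.0 + np.abs(f).max()):
            break
    return f


def _ratio_step(S, C, F, lo, hi, free_cols, w, greedy: bool) -> None:
    """Bounded update of the ratio matrix's free pigment columns given the
    current compositions.

    ``greedy=True`` updates only the single column whose bounded re-fit
    most reduces the weighted residual (the caller re-solves compositions
    in between), which keeps the alternating path anchored to the nearest
    coordinate-wise optimum when only a few entries are off: updating every
    column against one stale composition can wander along near-degenerate
    directions of the factorization in which several (composition, ratio)
    pairs fit equally well.  ``greedy=False`` updates all columns in one
    block sweep, which converges much faster once the fit is broadly wrong.
    Either way each column update is an exact bounded minimisation, so the
    objective never increases.
    """
    G = C.T @ C
    diag = np.diag(G)
    best_gain = 0.0
    best = None
    for p in free_cols:
        b = C.T @ S[:, p]
        f0 = F[:, p]
        f1 = _column_candidate(G, diag, b, f0, lo[:, p], hi[:, p])
        if not greedy:
            F[:, p] = f1
            continue
        # SSE difference: ||s - C f||^2 = s's - 2 f'b + f'Gf (s's cancels)
        sse0 = -2 * f0 @ b + f0 @ G @ f0
        sse1 = -2 * f1 @ b + f1 @ G @ f1
        gain = (sse0 - sse1) * w[p] ** 2
        if gain > best_gain:
            best_gain = gain
            best = (p, f1)
    if greedy and best is not None:
        p, f1 = best
        F[:, p] = f1


def optimize_ratios(pigments: pd.DataFrame, init: pd.DataFrame,
                    ratio_limit: float = 0.5, *, tol: float = 1e-6,
                    max_iter: int = 500,
                    weights: np.ndarray | None = None):
    """One bounded alternating-least-squares run.

    Alternates an exact per-sample non-negative least-squares composition
    step with a bounded update of the most-improving pigment column of the
    ratio matrix.  Entries may move within ``+/- ratio_limit`` (a fraction)
    of their initial value and must stay non-negative; the chlorophyll-a
    column and entries that start at zero are never updated.  Iterates until
    the relative RMSE improvement drops below ``tol`` or ``max_iter`` inner
    iterations.

    Returns ``(ratios, composition, rmse, n_iter, converged)``.
    """
    if ratio_limit <= 0:
        raise ValueError("ratio_limit must be > 0")
    chla = _check_ratio_matrix(init)
    S = _align(pigments, init)
    w = column_weights(init) if weights is None else np.asarray(weights)
    F0 = init.to_numpy(dtype=float)
    F = F0.copy()
    lo = np.clip(F0 * (1.0 - ratio_limit), 0.0, None)
    hi = F0 * (1.0 + ratio_limit)
    chla_j = list(init.columns).index(chla)
    lo[:, chla_j] = hi[:, chla_j] = 1.0
    free_cols = [j for j in range(F.shape[1])
                 if j != chla_j and (hi[:, j] > lo[:, j]).any()]

    comp = None
    prev = np.inf
    converged = False
    it = 0
    # Initial greedy phase: one best column per iteration with compositions
    # re-solved in between (as many iterations as free columns), then fast
    # block sweeps.
    n_greedy = len(free_cols)
    for it in range(1, max_iter + 1):
        comp = _nnls_matrix(S, F, w)
        _ratio_step(S, comp, F, lo, hi, free_cols, w, greedy=it <= n_greedy)
        rmse = _total_rmse(S, F, comp, w)
        if prev - rmse < tol * max(prev, 1e-30):
            converged = True
            break
        prev = rmse
    comp = _nnls_matrix(S, F, w)
    rmse = _total_rmse(S, F, comp, w)
    ratios = pd.DataFrame(F, index=init.index, columns=init.columns)
    composition = pd.DataFrame(comp, columns=list(init.index))
    if "sample_id" in pigments.columns:
        composition.insert(0, "sample_id", pigments["sample_id"].to_numpy())
    if not converged:
        warnings.warn("ratio optimization did not converge; returning "
                      "best-so-far", RuntimeWarning, stacklevel=2)
    return ratios, composition, rmse, it, converged


def _nnls_matrix(S: np.ndarray, F: np.ndarray, w: np.ndarray) -> np.ndarray:
    A = (F * w).T
    C = np.zeros((S.shape[0], F.shape[0]))
    for i in range(S.shape[0]):
        if S[i].any():
            C[i], _ = nnls(A, S[i] * w)
    return C


def successive_runs(pigments: pd.DataFrame, init: pd.DataFrame,
                    n_runs: int = 10, ratio_limit: float = 0.5, *,
                    tol: float = 1e-6, max_iter: int = 500) -> ChemtaxResult:
    """Chained bounded runs: each run starts from — and re-centres its ratio
    bounds on — the previous run's output matrix, and the residual after each
    run is recorded.  The RMSE trajectory is non-increasing because every run
    starts at the previous optimum.
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    F = init
    w = column_weights(init)  # fixed across runs so RMSEs are comparable
    trajectory = []
    notes: list[str] = []
    composition = None
    for run in range(n_runs):
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            F, composition, rmse, _, converged = optimize_ratios(
                pigments, F, ratio_limit, tol=tol, max_iter=max_iter,
                weights=w)
        for c in caught:
            notes.append(f"run {run + 1}: {c.message}")
        trajectory.append(rmse)
    comp = composition.copy()
    groups = list(init.index)
    S = _align(pigments, init)
    resid = (S - comp[groups].to_numpy() @ F.to_numpy(dtype=float)) * w
    comp["rmse"] = np.sqrt(np.mean(resid ** 2, axis=1))
    comp["all_zero"] = ~S.any(axis=1)
    return ChemtaxResult(ratios=F, composition=comp,
                         rmse_trajectory=trajectory, n_runs=n_runs,
                         warnings=notes)


def validate_against_markers(comp: pd.DataFrame, pigments: pd.DataFrame,
                             marker_map: dict[str, str] | None = None
                             ) -> pd.DataFrame:
    """Pearson correlation of each group's chlorophyll-a contribution with
    its diagnostic marker pigment across samples.

    Strong positive correlations indicate that the markers carry the group
    signal and the decomposition is internally consistent.  A constant column
    leaves the correlation undefined (reported as NaN).
    """
    marker_map = dict(DEFAULT_MARKERS if marker_map is None else marker_map)
    if "sample_id" in comp.columns and "sample_id" in pigments.columns:
        merged = comp.merge(pigments, on="sample_id",
                            suffixes=("", "_pigment"))
    else:
        if len(comp) != len(pigments):
            raise ValueError("tables differ in length and lack sample_id")
        merged = pd.concat([comp.reset_index(drop=True),
                            pigments.reset_index(drop=True)], axis=1)
    rows = []
    for group, marker in marker_map.items():
        if group not in comp.columns or marker not in pigments.columns:
            rows.append((group, marker, np.nan, 0))
            continue
        x = merged[group].to_numpy(dtype=float)
        y = merged[marker]
        if isinstance(y, pd.DataFrame):  # marker equal to a comp column name
            y = y.iloc[:, -1]
        y = y.to_numpy(dtype=float)
        ok = np.isfinite(x) & np.isfinite(y)
        x, y = x[ok], y[ok]
        if len(x) < 3 or np.ptp(x) == 0 or np.ptp(y) == 0:
            r = np.nan
        else:
            r = float(np.corrcoef(x, y)[0, 1])
        rows.append((group, marker, r, len(x)))
    return pd.DataFrame(rows, columns=["group", "marker", "r", "n"])
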