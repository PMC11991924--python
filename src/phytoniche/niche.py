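"""Realized-niche estimation along environmental gradients.

For each phytoplankton group and environmental variable the procedure is:

1. **Response curve** — a penalized cubic B-spline smooth ``f(x)`` of
   log(concentration + eps) on the variable, with the penalty weight chosen
   by generalized cross-validation (GCV).
2. **Maximum-entropy occupancy density** — ``p(x) = exp(f(x)) / Z`` over the
   observed range of the variable, the least-informative density consistent
   with the fitted log-response.  Normalising over the *observed* range makes
   this a realized (not fundamental) niche.
3. **Niche moments** — the mean realized niche ``mu = E_p[x]`` and niche
   breadth ``sigma = sd_p(x)`` by trapezoidal quadrature on the grid.
4. **Bootstrap** — percentile confidence intervals on ``mu`` and ``sigma``
   from case-resampled replicates of steps 1-3.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import BSpline

__all__ = ["ResponseCurve", "NicheEstimate", "PenalizedSpline",
           "fit_response", "maxent_density", "niche_moments",
           "bootstrap_niche", "estimate_all"]


@dataclass
class ResponseCurve:
    """A fitted response along one environmental variable."""

    variable: str
    grid: np.ndarray          # strictly increasing evaluation points
    f: np.ndarray             # fitted smooth on log-concentration scale
    p: np.ndarray | None = None  # normalized occupancy density


@dataclass
class NicheEstimate:
    """Realized-niche parameters of one group along one variable."""

    group: str
    variable: str
    mu: float
    sigma: float
    ci_mu_low: float = np.nan
    ci_mu_high: float = np.nan
    ci_sigma_low: float = np.nan
    ci_sigma_high: float = np.nan
    n_boot: int = 0
    n_failed: int = 0
    n_obs: int = 0
    stable: bool = True


class PenalizedSpline:
    """Cubic B-spline smoother with a second-order difference penalty.

    The basis has ``basis_dim`` functions (clamped cubic B-splines with
    interior knots at quantiles of x).  The penalty weight is selected by
    minimising GCV(lambda) = n * RSS / (n - edf)^2 over a log-spaced grid;
    with a handful of basis functions each candidate requires only a small
    dense solve, so no special decomposition is needed.
    """

    def __init__(self, basis_dim: int = 6, degree: int = 3,
                 lambdas: np.ndarray | None = None):
        if basis_dim < degree + 1:
            raise ValueError("basis_dim must be at least degree + 1")
        self.basis_dim = basis_dim
        self.degree = degree
        self.lambdas = np.logspace(-4, 6, 41) if lambdas is None else \
            np.asarray(lambdas, dtype=float)
        self.knots_: np.ndarray | None = None
        self.coef_: np.ndarray | None = None
        self.lambda_: float | None = None

    def _knots(self, x: np.ndarray, k: int) -> np.ndarray:
        lo, hi = float(x.min()), float(x.max())
        n_interior = self.basis_dim - self.degree - 1
        if n_interior > 0:
            probs = np.linspace(0, 1, n_interior + 2)[1:-1]
            interior = np.quantile(x, probs)
            span = hi - lo
            interior = np.clip(interior, lo + 1e-9 * span, hi - 1e-9 * span)
            interior = np.sort(interior)
        else:
            interior = np.array([])
        return np.concatenate([[lo] * (self.degree + 1), interior,
                               [hi] * (self.degree + 1)])

    def fit(self, x: np.ndarray, y: np.ndarray) -> "PenalizedSpline":
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        n = len(x)
        if np.ptp(x) == 0:
            raise ValueError("x is constant; cannot fit a response curve")
        k = self.basis_dim
        if n < k + 2:
            k = max(self.degree + 1, n - 2)
            warnings.warn(
                f"only {n} observations; basis reduced to {k}",
                RuntimeWarning, stacklevel=2)
            self.basis_dim = k
        self.knots_ = self._knots(x, k)
        B = BSpline.design_matrix(x, self.knots_, self.degree,
                                  extrapolate=True).toarray()
        D2 = np.diff(np.eye(B.shape[1]), n=2, axis=0)
        P = D2.T @ D2
        BtB = B.T @ B
        Bty = B.T @ y
        jitter = 1e-10 * (np.trace(BtB) / B.shape[1] + 1.0)
        BtB += jitter * np.eye(B.shape[1])
        best = (np.inf, None, None)
        for lam in self.lambdas:
            M = BtB + lam * P
            try:
                beta = np.linalg.solve(M, Bty)
                H_tr = float(np.trace(np.linalg.solve(M, BtB)))
            except np.linalg.LinAlgError:
                continue
            rss = float(np.sum((y - B @ beta) ** 2))
            denom = max(n - H_tr, 1e-8)
            gcv = n * rss / denom ** 2
            if gcv < best[0]:
                best = (gcv, beta, lam)
        if best[1] is None:
            raise np.linalg.LinAlgError("all candidate fits failed")
        self.coef_ = best[1]
        self.lambda_ = best[2]
        return self

    def predict(self, xg: np.ndarray) -> np.ndarray:
        B = BSpline.design_matrix(np.asarray(xg, dtype=float), self.knots_,
                                  self.degree, extrapolate=True).toarray()
        return B @ self.coef_


def fit_response(x, c, *, variable: str = "x", basis_dim: int = 6,
                 grid_size: int = 256, eps: float | None = None,
                 range_quantiles: tuple[float, float] = (0.005, 0.995)
                 ) -> ResponseCurve:
    """Penalized-spline smooth of log(c + eps) on x over the observed range.

    ``eps`` defaults to half the smallest positive concentration, keeping
    zeros finite without letting them dominate the log scale.  The
    evaluation grid spans the observed range trimmed to ``range_quantiles``:
    beyond the extreme half-percentiles the smooth is supported by a handful
    of points and exponentiating it would let edge wiggles dominate the
    occupancy density.
    """
    x = np.asarray(x, dtype=float)
    c = np.asarray(c, dtype=float)
    ok = np.isfinite(x) & np.isfinite(c)
    x, c = x[ok], c[ok]
    if (c < 0).any():
        raise ValueError("concentrations must be >= 0")
    if len(x) < 5:
        raise ValueError("need at least 5 paired observations")
    if np.ptp(x) == 0:
        raise ValueError(f"variable {variable!r} is constant")
    if eps is None:
        pos = c[c > 0]
        if len(pos) == 0:
            raise ValueError("all concentrations are zero")
        eps = 0.5 * float(pos.min())
    y = np.log(c + eps)
    spline = PenalizedSpline(basis_dim=basis_dim).fit(x, y)
    lo, hi = np.quantile(x, range_quantiles)
    if hi <= lo:
        lo, hi = x.min(), x.max()
    grid = np.linspace(lo, hi, grid_size)
    return ResponseCurve(variable=variable, grid=grid,
                         f=spline.predict(grid))


def maxent_density(curve: ResponseCurve) -> ResponseCurve:
    """Fill the occupancy density p(x) = exp(f(x)) / integral exp(f).

    The maximum of f is subtracted before exponentiation to guard against
    overflow; the trapezoidal integral of p over the grid is exactly 1.
    """
    f = np.asarray(curve.f, dtype=float)
    g = np.asarray(curve.grid, dtype=float)
    if np.any(np.diff(g) <= 0):
        raise ValueError("grid must be strictly increasing")
    w = np.exp(f - f.max())
    Z = np.trapezoid(w, g)
    if Z <= 0 or not np.isfinite(Z):
        raise FloatingPointError("degenerate response curve")
    return ResponseCurve(variable=curve.variable, grid=g, f=f, p=w / Z)


def niche_moments(curve: ResponseCurve) -> tuple[float, float]:
    """Mean realized niche and niche breadth of a normalized occupancy
    density, by trapezoidal quadrature on the curve's grid."""
    if curve.p is None:
        raise ValueError("density not computed; call maxent_density first")
    g, p = curve.grid, curve.p
    mu = float(np.trapezoid(g * p, g))
    var = float(np.trapezoid((g - mu) ** 2 * p, g))
    return mu, float(np.sqrt(max(var, 0.0)))


def _point_estimate(x, c, variable, basis_dim, grid_size):
    curve = maxent_density(fit_response(x, c, variable=variable,
                                        basis_dim=basis_dim,
                                        grid_size=grid_size))
    return niche_moments(curve)


def bootstrap_niche(x, c, n_boot: int = 100, level: float = 0.95,
                    seed=None, *, group: str = "", variable: str = "x",
                    basis_dim: int = 6, grid_size: int = 256
                    ) -> NicheEstimate:
    """Niche mean/breadth with percentile bootstrap confidence intervals.

    The point estimate uses the full data; each replicate case-resamples the
    (x, c) pairs and repeats the fit-normalise-moments chain.  Replicates
    that fail to fit (e.g. a resample with constant x) are dropped and
    counted; more than 20% failures flags the estimate as unstable.
    """
    x = np.asarray(x, dtype=float)
    c = np.asarray(c, dtype=float)
    ok = np.isfinite(x) & np.isfinite(c)
    x, c = x[ok], c[ok]
    mu, sigma = _point_estimate(x, c, variable, basis_dim, grid_size)
    est = NicheEstimate(group=group, variable=variable, mu=mu, sigma=sigma,
                        n_obs=len(x))
    if n_boot <= 0:
        return est
    rng = np.random.default_rng(seed)
    mus, sigmas = [], []
    failed = 0
    n = len(x)
    for _ in range(n_boot):
        idx = rng.integers(0, n, n)
        try:
            m, s = _point_estimate(x[idx], c[idx], variable, basis_dim,
                                   grid_size)
            mus.append(m)
            sigmas.append(s)
        except (ValueError, FloatingPointError, np.linalg.LinAlgError):
            failed += 1
    est.n_boot = len(mus)
    est.n_failed = failed
    est.stable = failed <= 0.2 * n_boot
    if mus:
        alpha = 100 * (1 - level) / 2
        est.ci_mu_low, est.ci_mu_high = np.percentile(mus,
                                                      [alpha, 100 - alpha])
        est.ci_sigma_low, est.ci_sigma_high = np.percentile(
            sigmas, [alpha, 100 - alpha])
    return est


def estimate_all(comp: pd.DataFrame, env: pd.DataFrame,
                 variables, groups=None, *, n_boot: int = 100,
                 level: float = 0.95, seed=None, basis_dim: int = 6,
                 grid_size: int = 256) -> pd.DataFrame:
    """NicheEstimate table for every group x variable combination.

    ``comp`` and ``env`` are aligned on ``sample_id`` when both carry it,
    otherwise row-by-row.  Rows with missing values of a variable are
    dropped for that variable only; variables absent from the environment
    table are skipped (reported in the ``note`` column of a one-row stub).
    """
    if "sample_id" in comp.columns and "sample_id" in env.columns:
        merged = comp.merge(env, on="sample_id", suffixes=("", "_env"))
    else:
        if len(comp) != len(env):
            raise ValueError("tables differ in length and lack sample_id")
        merged = pd.concat([comp.reset_index(drop=True),
                            env.reset_index(drop=True)], axis=1)
    if groups is None:
        skip = {"sample_id", "rmse", "all_zero"}
        groups = [c for c in comp.columns if c not in skip]
    ss = np.random.SeedSequence(seed)
    child_seeds = iter(ss.spawn(len(groups) * len(list(variables))))
    rows = []
    for g in groups:
        for v in variables:
            child = next(child_seeds)
            if v not in merged.columns:
                rows.append({"group": g, "variable": v, "mu": np.nan,
                             "sigma": np.nan, "note": "variable absent"})
                continue
            sub = merged[[v, g]].dropna()
            est = bootstrap_niche(sub[v], sub[g], n_boot=n_boot, level=level,
                                  seed=child, group=g, variable=v,
                                  basis_dim=basis_dim, grid_size=grid_size)
            d = est.__dict__.copy()
            d["note"] = "" if est.stable else "unstable"
            rows.append(d)
    return pd.DataFrame(rows)
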