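"""Empirical indicator semivariograms and automatic model fitting.

The spatial-correlation engine behind the kriging stage.  The empirical
semivariogram is the method-of-moments estimator

    gamma_hat(h) = 1 / (2 N(h)) * sum over pairs in lag bin h of (z_i - z_j)^2

over great-circle separations in km.  A parametric model
``gamma(h) = nugget + psill * f(h / range)`` is fitted to the binned
estimates by weighted least squares (weights N(h)/h^2 by default, the
lineage default for automatic variogram fitting), and automatic selection
fits a list of candidate families and keeps the converged fit with the
smallest weighted residual sum of squares.

Supported families: Spherical, Exponential, Gaussian, Matern, Stein's
parameterization of the Matern, Circular, Linear (bounded), Bessel and
Pentaspherical.  For binary indicator data the sill is at most p(1-p)
<= 0.25, so all semivariances live well below 0.5.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import optimize, special

from .grid import pairwise_haversine_km

MANDATORY_FAMILIES = ["Spherical", "Exponential", "Gaussian", "Matern"]
ALL_FAMILIES = MANDATORY_FAMILIES + ["SteinMatern", "Circular", "Linear", "Bessel", "Pentaspherical"]

#: discrete smoothness values tried when fitting the Matern families,
#: mirroring the discrete-kappa search of automatic fitting tools
KAPPA_GRID = (0.3, 0.5, 1.0, 1.5, 2.0, 2.5, 5.0, 10.0)

DEFAULT_N_LAGS = 15


@dataclass
class EmpiricalVariogram:
    lag_centers: np.ndarray   # km
    semivariance: np.ndarray  # per lag; NaN where the bin is empty
    n_pairs: np.ndarray
    cutoff: float             # km

    def nonempty(self) -> "EmpiricalVariogram":
        keep = self.n_pairs > 0
        return EmpiricalVariogram(
            self.lag_centers[keep], self.semivariance[keep], self.n_pairs[keep], self.cutoff
        )

    @property
    def n_nonempty(self) -> int:
        return int((self.n_pairs > 0).sum())


@dataclass
class VariogramModel:
    family: str
    nugget: float
    partial_sill: float
    range_km: float
    kappa: Optional[float] = None
    rss: float = math.nan          # weighted residual sum of squares of the fit
    converged: bool = True
    candidates: dict = field(default_factory=dict)  # family -> rss, filled by autofit

    @property
    def sill(self) -> float:
        return self.nugget + self.partial_sill

    def __call__(self, h):
        return model_semivariance(self, h)


def empirical_variogram(
    lats: Sequence[float],
    lons: Sequence[float],
    values: Sequence[float],
    n_lags: int = DEFAULT_N_LAGS,
    cutoff: Optional[float] = None,
) -> EmpiricalVariogram:
    """Binned method-of-moments semivariogram over great-circle lags.

    ``cutoff`` defaults to one third of the maximum pairwise distance.
    Empty bins carry NaN semivariance and zero pair count.
    """
    lats = np.asarray(lats, dtype=float)
    lons = np.asarray(lons, dtype=float)
    z = np.asarray(values, dtype=float)
    if len(z) < 2:
        raise ValueError("need at least two points")
    d = pairwise_haversine_km(lats, lons)
    iu = np.triu_indices(len(z), k=1)
    dist = d[iu]
    if dist.max() <= 0.0:
        raise ValueError("no spatial spread: all points coincident")
    sqdiff = (z[iu[0]] - z[iu[1]]) ** 2
    if cutoff is None:
        cutoff = dist.max() / 3.0
    edges = np.linspace(0.0, cutoff, n_lags + 1)
    which = np.digitize(dist, edges[1:-1], right=True)  # bin index; > cutoff excluded below
    in_range = dist <= cutoff
    gamma = np.full(n_lags, np.nan)
    npairs = np.zeros(n_lags, dtype=int)
    for b in range(n_lags):
        sel = in_range & (which == b)
        npairs[b] = int(sel.sum())
        if npairs[b]:
            gamma[b] = sqdiff[sel].sum() / (2.0 * npairs[b])
    centers = 0.5 * (edges[:-1] + edges[1:])
    return EmpiricalVariogram(centers, gamma, npairs, float(cutoff))


# -- model families ---------------------------------------------------------

def _f_spherical(u):
    return np.where(u < 1.0, 1.5 * u - 0.5 * u ** 3, 1.0)


def _f_exponential(u):
    return 1.0 - np.exp(-u)


def _f_gaussian(u):
    return 1.0 - np.exp(-u ** 2)


def _f_matern(u, kappa):
    # standard Matern correlation: 1 - u^k K_k(u) / (2^(k-1) Gamma(k))
    u = np.asarray(u, dtype=float)
    out = np.ones_like(u)
    pos = u > 0
    up = u[pos]
    out[pos] = 1.0 - (up ** kappa) * special.kv(kappa, up) / (2.0 ** (kappa - 1.0) * special.gamma(kappa))
    return np.clip(out, 0.0, 1.0)


def _f_stein_matern(u, kappa):
    # M. Stein's parameterization: argument rescaled by 2 sqrt(kappa)
    return _f_matern(2.0 * np.sqrt(kappa) * np.asarray(u, dtype=float), kappa)


def _f_circular(u):
    u = np.minimum(np.asarray(u, dtype=float), 1.0)
    return (2.0 / np.pi) * (u * np.sqrt(np.clip(1.0 - u ** 2, 0.0, 1.0)) + np.arcsin(u))


def _f_linear(u):
    return np.minimum(np.asarray(u, dtype=float), 1.0)


def _f_bessel(u):
    u = np.asarray(u, dtype=float)
    out = np.ones_like(u)
    pos = u > 0
    out[pos] = 1.0 - u[pos] * special.kv(1, u[pos])
    return np.clip(out, 0.0, 1.0)


def _f_pentaspherical(u):
    u = np.asarray(u, dtype=float)
    return np.where(u < 1.0, (15.0 / 8.0) * u - (5.0 / 4.0) * u ** 3 + (3.0 / 8.0) * u ** 5, 1.0)


_FAMILY_FUNCS = {
    "Spherical": lambda u, k: _f_spherical(u),
    "Exponential": lambda u, k: _f_exponential(u),
    "Gaussian": lambda u, k: _f_gaussian(u),
    "Matern": _f_matern,
    "SteinMatern": _f_stein_matern,
    "Circular": lambda u, k: _f_circular(u),
    "Linear": lambda u, k: _f_linear(u),
    "Bessel": lambda u, k: _f_bessel(u),
    "Pentaspherical": lambda u, k: _f_pentaspherical(u),
}

_NEEDS_KAPPA = {"Matern", "SteinMatern"}


def model_semivariance(model: VariogramModel, h):
    """gamma(h) for a fitted model; gamma(0) = 0 by definition."""
    if model.family not in _FAMILY_FUNCS:
        raise ValueError(f"unsupported variogram family: {model.family}")
    h = np.asarray(h, dtype=float)
    scalar = h.ndim == 0
    h = np.atleast_1d(h)
    u = h / model.range_km
    kappa = model.kappa if model.family in _NEEDS_KAPPA else None
    f = _FAMILY_FUNCS[model.family](u, kappa)
    gamma = model.nugget + model.partial_sill * f
    gamma = np.where(h == 0.0, 0.0, gamma)
    return float(gamma[0]) if scalar else gamma


# -- fitting ----------------------------------------------------------------

def _wls_objective(emp: EmpiricalVariogram, weights: str):
    e = emp.nonempty()
    h, g, n = e.lag_centers, e.semivariance, e.n_pairs
    if weights == "npairs_over_h2":
        w = n / np.maximum(h, 1e-12) ** 2
    elif weights == "npairs":
        w = n.astype(float)
    elif weights == "equal":
        w = np.ones_like(h)
    else:
        raise ValueError(f"unknown weighting scheme: {weights}")
    return h, g, w


def _auto_initials(emp: EmpiricalVariogram) -> tuple[float, float, float]:
    e = emp.nonempty()
    g = e.semivariance
    nugget0 = float(np.min(g))
    upper_half = g[e.lag_centers > e.lag_centers.max() / 2.0]
    sill0 = float(np.mean(upper_half)) if len(upper_half) else float(np.mean(g))
    psill0 = max(sill0 - nugget0, 1e-6)
    range0 = 0.1 * float(e.lag_centers.max())
    return nugget0, psill0, range0


def fit_variogram_wls(
    emp: EmpiricalVariogram,
    family: str,
    initial: Optional[tuple[float, float, float]] = None,
    kappa: Optional[float] = None,
    weights: str = "npairs_over_h2",
) -> VariogramModel:
    """Weighted-least-squares fit of one family to a binned variogram.

    ``initial`` is an optional (nugget, partial_sill, range_km) start —
    the manual-oversight pathway when automatic initials fail.  For the
    Matern families a fixed ``kappa`` fits that smoothness only; otherwise
    the discrete KAPPA_GRID is searched and the best kept.
    """
    if emp.n_nonempty < 3:
        raise ValueError("need at least 3 non-empty lag bins to fit a variogram")
    if family not in _FAMILY_FUNCS:
        raise ValueError(f"unsupported variogram family: {family}")
    h, g, w = _wls_objective(emp, weights)
    hmax = float(h.max())

    kappas = [kappa] if (family not in _NEEDS_KAPPA or kappa is not None) else list(KAPPA_GRID)
    starts = [_auto_initials(emp)]
    if initial is not None:
        starts.append(tuple(float(v) for v in initial))

    best: Optional[VariogramModel] = None
    for k in kappas:
        func = _FAMILY_FUNCS[family]

        def obj(theta, k=k):
            nugget, psill, rng = theta
            gamma = nugget + psill * func(h / rng, k)
            return float(np.sum(w * (g - gamma) ** 2))

        for start in starts:
            x0 = np.clip(np.asarray(start, dtype=float),
                         [0.0, 0.0, 1e-6 * hmax], [np.inf, np.inf, 100.0 * hmax])
            res = optimize.minimize(
                obj, x0,
                method="Nelder-Mead",
                bounds=[(0.0, None), (0.0, None), (1e-6 * hmax, 100.0 * hmax)],
                options={"xatol": 1e-10, "fatol": 1e-14, "maxiter": 4000},
            )
            cand = VariogramModel(
                family=family,
                nugget=float(max(res.x[0], 0.0)),
                partial_sill=float(max(res.x[1], 0.0)),
                range_km=float(res.x[2]),
                kappa=k if family in _NEEDS_KAPPA else None,
                rss=float(res.fun),
                converged=bool(res.success),
            )
            if best is None or cand.rss < best.rss:
                best = cand
    assert best is not None
    return best


def autofit_variogram(
    emp: EmpiricalVariogram,
    families: Sequence[str] = tuple(ALL_FAMILIES),
    initial: Optional[tuple[float, float, float]] = None,
    weights: str = "npairs_over_h2",
) -> VariogramModel:
    """Fit every candidate family; keep the converged fit with smallest RSS.

    Ties break in family list order.  Raises if no family converges,
    signalling the pipeline's 100%/0% fallback pathway.
    """
    if not families:
        raise ValueError("need at least one candidate family")
    # numerically equal fits (e.g. Matern kappa=0.5 vs Exponential, which are
    # the same model) must tie to list order, so "smaller" means smaller by
    # more than float noise relative to the data scale
    h, g, w = _wls_objective(emp, weights)
    tie_tol = 1e-9 * float(np.sum(w * g ** 2))
    candidates: dict[str, float] = {}
    best: Optional[VariogramModel] = None
    for fam in families:
        try:
            fit = fit_variogram_wls(emp, fam, initial=initial, weights=weights)
        except (ValueError, FloatingPointError):
            continue
        candidates[fam] = fit.rss
        if not fit.converged or not np.isfinite(fit.rss):
            continue
        if best is None or fit.rss < best.rss - tie_tol:
            best = fit
    if best is None:
        raise RuntimeError("variogram fitting failed: no candidate family converged")
    best.candidates = candidates
    return best
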