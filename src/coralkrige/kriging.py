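"""Ordinary (indicator) kriging with local neighborhoods.

Ordinary kriging predicts a field with unknown constant mean by solving,
for each target location, the augmented system

    [ Gamma  1 ] [ lambda ]   [ gamma_0 ]
    [ 1^T    0 ] [ mu     ] = [ 1       ]

where Gamma holds model semivariances between observations, gamma_0 the
semivariances between observations and the target, and the Lagrange
multiplier mu enforces the unit-sum weight (unbiasedness) constraint.
Applied to binary presence/absence indicators the prediction is the
probability of presence; raw predictions can leave [0, 1] slightly and
are clamped, with the raw value retained for diagnostics.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import linalg

from .grid import CellIndex, haversine_km, pairwise_haversine_km
from .variogram import VariogramModel

DEFAULT_N_MAX = 100


@dataclass(frozen=True)
class IndicatorObservation:
    """One binary observation at a cell center: 1 = presence, 0 = absence."""

    lat: float
    lon: float
    value: int
    cell: Optional[CellIndex] = None

    def __post_init__(self) -> None:
        if self.value not in (0, 1):
            raise ValueError(f"indicator value must be 0 or 1, got {self.value}")


@dataclass
class KrigingResult:
    lat: float
    lon: float
    estimate: float       # clamped to [0, 1]
    raw_estimate: float
    variance: float
    n_neighbors: int
    weights: Optional[np.ndarray] = None   # lambda, in neighbor order
    lagrange: float = 0.0

    @property
    def clamped(self) -> bool:
        return self.estimate != self.raw_estimate


def _check_duplicates(lats: np.ndarray, lons: np.ndarray) -> None:
    seen: dict[tuple[float, float], int] = {}
    for k, key in enumerate(zip(lats.tolist(), lons.tolist())):
        if key in seen:
            raise ValueError(
                f"duplicate observation locations at (lat={key[0]}, lon={key[1]}): "
                f"indices {seen[key]} and {k}; collapse to one observation per cell first"
            )
        seen[key] = k


def krige_point(
    obs: Sequence[IndicatorObservation],
    model: VariogramModel,
    target_lat: float,
    target_lon: float,
    n_max: Optional[int] = DEFAULT_N_MAX,
) -> KrigingResult:
    """Ordinary-kriging prediction at one location.

    Uses the ``n_max`` nearest observations (all when ``n_max`` is None or
    exceeds the observation count).  Weights sum to one by construction of
    the constrained system.
    """
    if len(obs) < 2:
        raise ValueError("ordinary kriging needs at least 2 observations")
    lats = np.array([o.lat for o in obs], dtype=float)
    lons = np.array([o.lon for o in obs], dtype=float)
    vals = np.array([o.value for o in obs], dtype=float)

    d_target = haversine_km(target_lat, target_lon, lats, lons)
    if n_max is not None and n_max < len(obs):
        # stable argsort keeps input order among equidistant neighbors
        idx = np.argsort(d_target, kind="stable")[:n_max]
        lats, lons, vals, d_target = lats[idx], lons[idx], vals[idx], d_target[idx]
    n = len(vals)
    _check_duplicates(lats, lons)

    gamma_mat = model(pairwise_haversine_km(lats, lons))
    np.fill_diagonal(gamma_mat, 0.0)
    gamma_0 = model(d_target)

    a = np.empty((n + 1, n + 1))
    a[:n, :n] = gamma_mat
    a[:n, n] = 1.0
    a[n, :n] = 1.0
    a[n, n] = 0.0
    b = np.concatenate([gamma_0, [1.0]])
    try:
        sol = linalg.solve(a, b, assume_a="sym")
    except linalg.LinAlgError as exc:
        raise ValueError(f"singular kriging system ({n} observations): {exc}") from exc
    if not np.all(np.isfinite(sol)):
        raise ValueError(f"singular kriging system ({n} observations)")
    lam, mu = sol[:n], sol[n]

    raw = float(lam @ vals)
    variance = float(lam @ gamma_0 + mu)
    return KrigingResult(
        lat=target_lat, lon=target_lon,
        estimate=float(min(1.0, max(0.0, raw))),
        raw_estimate=raw,
        variance=max(variance, 0.0),
        n_neighbors=n,
        weights=lam,
        lagrange=float(mu),
    )


def krige_grid(
    obs: Sequence[IndicatorObservation],
    model: VariogramModel,
    target_lats: Sequence[float],
    target_lons: Sequence[float],
    n_max: Optional[int] = DEFAULT_N_MAX,
) -> tuple[list[Optional[KrigingResult]], list[str]]:
    """krige_point over many targets; failed cells are masked, not fatal.

    Returns (results, errors) where results[k] is None for a failed target
    and errors collects one message per failure.
    """
    results: list[Optional[KrigingResult]] = []
    errors: list[str] = []
    for lat, lon in zip(target_lats, target_lons):
        try:
            results.append(krige_point(obs, model, float(lat), float(lon), n_max=n_max))
        except ValueError as exc:
            results.append(None)
            errors.append(f"target ({lat:.4f}, {lon:.4f}): {exc}")
    return results, errors
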