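"""Global 0.05-degree grid conventions and great-circle geometry.

Every stage of the pipeline shares one raster convention: a global
0.05-degree x 0.05-degree latitude-longitude grid with origin at
(lon, lat) = (-180, -90), columns ``i`` indexed eastward and rows ``j``
indexed northward.  Cells are half-open intervals ``[edge, edge + 0.05)``
and the representative point of a cell is its center, ``edge + 0.025``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator

import numpy as np
import pandas as pd

CELL_DEG: float = 0.05
N_COLS: int = 7200
N_ROWS: int = 3600
EARTH_RADIUS_KM: float = 6371.0


@dataclass(frozen=True, order=True)
class CellIndex:
    """Column/row index of one 0.05-degree grid cell.

    Ordering is (i, j) lexicographic by dataclass field order; the
    snapping tie-break sorts on (j, i) explicitly.
    """

    i: int
    j: int

    def __post_init__(self) -> None:
        if not (0 <= self.i < N_COLS and 0 <= self.j < N_ROWS):
            raise ValueError(f"cell index out of bounds: ({self.i}, {self.j})")


def latlon_to_cell(lat: float, lon: float) -> CellIndex:
    """Map a coordinate to its grid cell (half-open cell convention)."""
    if not (-90.0 <= lat <= 90.0):
        raise ValueError(f"latitude out of range: {lat}")
    if not (-180.0 <= lon < 180.0):
        raise ValueError(f"longitude out of range: {lon}")
    # nudge guards against float noise at exact cell edges (half-open cells:
    # a coordinate on an edge belongs to the cell above/right of it)
    i = int(np.floor((lon + 180.0) / CELL_DEG + 1e-9))
    j = int(np.floor((lat + 90.0) / CELL_DEG + 1e-9))
    # lat = +90 exactly falls on the closed upper edge of the top row
    j = min(j, N_ROWS - 1)
    return CellIndex(i, j)


def cell_center(cell: CellIndex) -> tuple[float, float]:
    """(lat, lon) of the cell center."""
    lon = -180.0 + (cell.i + 0.5) * CELL_DEG
    lat = -90.0 + (cell.j + 0.5) * CELL_DEG
    return lat, lon


def haversine_km(lat1, lon1, lat2, lon2):
    """Great-circle distance in km on a spherical Earth (R = 6371 km).

    Accepts scalars or broadcastable numpy arrays.
    """
    lat1, lon1, lat2, lon2 = (np.radians(np.asarray(x, dtype=float)) for x in (lat1, lon1, lat2, lon2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    a = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))


def pairwise_haversine_km(lats: np.ndarray, lons: np.ndarray) -> np.ndarray:
    """Full symmetric distance matrix between n points, in km."""
    lats = np.asarray(lats, dtype=float)
    lons = np.asarray(lons, dtype=float)
    return haversine_km(lats[:, None], lons[:, None], lats[None, :], lons[None, :])


class ReefMask:
    """The set of reef-bearing cells on the global 0.05-degree grid."""

    def __init__(self, cells: Iterable[CellIndex]):
        cell_list = list(cells)
        if not cell_list:
            raise ValueError("reef mask must be non-empty")
        if len(set(cell_list)) != len(cell_list):
            raise ValueError("reef mask contains duplicate cells")
        # stored sorted by (j, i) so nearest-cell ties resolve deterministically
        self._cells: tuple[CellIndex, ...] = tuple(sorted(cell_list, key=lambda c: (c.j, c.i)))
        self._cell_set = frozenset(self._cells)
        centers = np.array([cell_center(c) for c in self._cells], dtype=float)
        self._center_lats = centers[:, 0]
        self._center_lons = centers[:, 1]

    def __contains__(self, cell: CellIndex) -> bool:
        return cell in self._cell_set

    def __len__(self) -> int:
        return len(self._cells)

    def __iter__(self) -> Iterator[CellIndex]:
        return iter(self._cells)

    @property
    def cells(self) -> tuple[CellIndex, ...]:
        return self._cells

    def centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(lats, lons) arrays of all cell centers, in mask order."""
        return self._center_lats, self._center_lons

    def nearest_cell(self, lat: float, lon: float) -> tuple[CellIndex, float]:
        """Nearest reef cell center by great-circle distance, with distance km.

        Ties break to the lowest (j, i), which is the storage order.
        """
        d = haversine_km(lat, lon, self._center_lats, self._center_lons)
        k = int(np.argmin(d))  # argmin returns the first minimum: (j, i) order
        return self._cells[k], float(d[k])

    # -- serialization -----------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"i": [c.i for c in self._cells], "j": [c.j for c in self._cells]})

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ReefMask":
        return cls(CellIndex(int(r.i), int(r.j)) for r in df.itertuples())

    @classmethod
    def from_csv(cls, path) -> "ReefMask":
        df = pd.read_csv(path)
        df.columns = [c.strip().lower() for c in df.columns]
        if not {"i", "j"}.issubset(df.columns):
            raise ValueError("reef mask CSV requires columns i, j")
        return cls.from_frame(df)
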