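"""Track geometry, condition labels, and the spatial binning grids.

The apparatus is a 120 x 24 cm shuttle box whose floor can be tilted to
0, 15, or 25 degrees by pivoting around one end.  The central 103 cm of
the long axis is the running region of interest (ROI); the two ends are
rewarded endzones.  Rate maps live on a nominal 2.5 cm square grid over
the ROI; phase-precession field detection uses a coarser 4 x 20 grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np

UPHILL = "uphill"
DOWNHILL = "downhill"
DIRECTIONS = (UPHILL, DOWNHILL)
TILTS = (0, 15, 25)

NORTH = "north"  # x = long_axis_cm end
SOUTH = "south"  # x = 0 end


class Condition(NamedTuple):
    """A tilt angle (degrees) crossed with a slope direction."""

    tilt: int
    direction: str


CONDITIONS = tuple(Condition(t, d) for d in DIRECTIONS for t in TILTS)


def opposite_end(end: str) -> str:
    if end == NORTH:
        return SOUTH
    if end == SOUTH:
        return NORTH
    raise ValueError(f"unknown end {end!r}")


@dataclass(frozen=True)
class TrackGeometry:
    """Dimensions of the shuttle box and derived binning grids.

    ``bin_side_cm`` is the nominal side of the square rate-map bins; the
    ROI length (103 cm) and track width (24 cm) are not integer multiples
    of 2.5 cm, so the last bin along each axis absorbs the remainder.
    ``pivot_end`` is the end that stays on the ground when tilted.
    """

    long_axis_cm: float = 120.0
    short_axis_cm: float = 24.0
    roi_long_cm: float = 103.0
    endzone_south_cm: float = 8.5
    endzone_north_cm: float = 8.5
    bin_side_cm: float = 2.5
    pivot_end: str = SOUTH
    coarse_shape: tuple[int, int] = (4, 20)  # (short-axis, long-axis) bins

    def __post_init__(self) -> None:
        total = self.roi_long_cm + self.endzone_south_cm + self.endzone_north_cm
        if not np.isclose(total, self.long_axis_cm):
            raise ValueError(
                "ROI plus endzones must span the long axis: "
                f"{self.roi_long_cm} + {self.endzone_south_cm} + "
                f"{self.endzone_north_cm} != {self.long_axis_cm}"
            )
        if self.bin_side_cm <= 0:
            raise ValueError("bin_side_cm must be positive")

    # --- ROI boundaries (absolute cm along the long axis) ---

    @property
    def roi_start_cm(self) -> float:
        return self.endzone_south_cm

    @property
    def roi_end_cm(self) -> float:
        return self.long_axis_cm - self.endzone_north_cm

    @property
    def roi_mid_cm(self) -> float:
        return 0.5 * (self.roi_start_cm + self.roi_end_cm)

    def in_roi(self, x: np.ndarray) -> np.ndarray:
        return (np.asarray(x) >= self.roi_start_cm) & (np.asarray(x) < self.roi_end_cm)

    # --- fine grid (rate maps) ---

    @property
    def n_bins_long(self) -> int:
        return int(self.roi_long_cm // self.bin_side_cm)

    @property
    def n_bins_short(self) -> int:
        return int(self.short_axis_cm // self.bin_side_cm)

    @property
    def long_edges_cm(self) -> np.ndarray:
        edges = self.roi_start_cm + self.bin_side_cm * np.arange(self.n_bins_long + 1)
        edges[-1] = self.roi_end_cm  # last bin absorbs the remainder
        return edges

    @property
    def short_edges_cm(self) -> np.ndarray:
        edges = self.bin_side_cm * np.arange(self.n_bins_short + 1)
        edges[-1] = self.short_axis_cm
        return edges

    def long_bin_center_cm(self, col: int | np.ndarray) -> np.ndarray:
        edges = self.long_edges_cm
        col = np.asarray(col)
        return 0.5 * (edges[col] + edges[col + 1])

    def bin_indices(self, x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Map ROI coordinates to (row, col) fine-grid indices.

        Bins are half-open [edge_k, edge_{k+1}); callers must pre-filter
        to in-ROI samples.
        """
        col = np.clip(
            ((np.asarray(x) - self.roi_start_cm) // self.bin_side_cm).astype(int),
            0,
            self.n_bins_long - 1,
        )
        row = np.clip(
            (np.asarray(y) // self.bin_side_cm).astype(int), 0, self.n_bins_short - 1
        )
        return row, col

    # --- coarse grid (phase-precession field detection) ---

    @property
    def coarse_long_width_cm(self) -> float:
        return self.roi_long_cm / self.coarse_shape[1]

    @property
    def coarse_short_width_cm(self) -> float:
        return self.short_axis_cm / self.coarse_shape[0]

    def coarse_bin_indices(self, x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        n_rows, n_cols = self.coarse_shape
        col = np.clip(
            ((np.asarray(x) - self.roi_start_cm) / self.coarse_long_width_cm).astype(int),
            0,
            n_cols - 1,
        )
        row = np.clip(
            (np.asarray(y) / self.coarse_short_width_cm).astype(int), 0, n_rows - 1
        )
        return row, col

    def coarse_col_edge_cm(self, col: int) -> float:
        """Absolute long-axis coordinate of the left edge of a coarse column."""
        return self.roi_start_cm + col * self.coarse_long_width_cm

    def ground_end(self, elevated_end: str) -> str:
        return opposite_end(elevated_end)

    def end_x(self, end: str) -> float:
        return 0.0 if end == SOUTH else self.long_axis_cm
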