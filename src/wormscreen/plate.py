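"""Assay-plate geometry.

The screening assay runs on a 13 x 10 cm rectangular agar plate divided
into a grid of equal-area regions (default 4 columns x 2 rows = 8). Each
region holds one treatment group and is bounded by a glycerol margin that
worms avoid, so a region index is a treatment label for every animal on
the plate.

Coordinates are millimetres with the origin at the top-left corner,
x increasing rightward and y increasing downward.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["PlateLayout"]


@dataclass(frozen=True)
class PlateLayout:
    """Physical plate and region geometry.

    Parameters
    ----------
    width_mm, height_mm
        Outer plate dimensions. Default 130 x 100 mm.
    n_cols, n_rows
        Grid of equal-area regions; region index is ``row * n_cols + col``,
        row-major from the top-left. Default 4 x 2 = 8 regions.
    border_mm
        Width of the glycerol margin inset inside each region. Animals are
        confined to the region rectangle shrunk by this margin on all sides.
    """

    width_mm: float = 130.0
    height_mm: float = 100.0
    n_cols: int = 4
    n_rows: int = 2
    border_mm: float = 2.0

    def __post_init__(self) -> None:
        if self.width_mm <= 0 or self.height_mm <= 0:
            raise ValueError("plate dimensions must be positive")
        if self.n_cols < 1 or self.n_rows < 1:
            raise ValueError("region grid must be at least 1 x 1")
        if self.border_mm < 0:
            raise ValueError("border_mm must be non-negative")
        if 2 * self.border_mm >= min(self.region_width_mm, self.region_height_mm):
            raise ValueError("glycerol border leaves no interior in a region")

    @property
    def n_regions(self) -> int:
        return self.n_cols * self.n_rows

    @property
    def region_width_mm(self) -> float:
        return self.width_mm / self.n_cols

    @property
    def region_height_mm(self) -> float:
        return self.height_mm / self.n_rows

    def region_of(self, x_mm, y_mm):
        """Region index for plate coordinates; vectorized.

        Every interior point maps to exactly one region; points on an
        internal grid line belong to the region on their right/below
        (half-open cells), and the far plate edges fold into the last cell
        so the full closed plate is covered.

        Raises
        ------
        ValueError
            If any point lies outside the plate bounds.
        """
        x = np.asarray(x_mm, dtype=float)
        y = np.asarray(y_mm, dtype=float)
        if np.any(x < 0) or np.any(x > self.width_mm) or np.any(y < 0) or np.any(y > self.height_mm):
            raise ValueError("coordinates outside plate bounds")
        col = np.minimum((x / self.region_width_mm).astype(int), self.n_cols - 1)
        row = np.minimum((y / self.region_height_mm).astype(int), self.n_rows - 1)
        idx = row * self.n_cols + col
        return idx if idx.ndim else int(idx)

    def region_bounds(self, region: int) -> tuple[float, float, float, float]:
        """Outer bounds ``(xmin, ymin, xmax, ymax)`` of a region in mm."""
        if not 0 <= region < self.n_regions:
            raise ValueError(f"region index {region} out of range [0, {self.n_regions})")
        row, col = divmod(region, self.n_cols)
        return (
            col * self.region_width_mm,
            row * self.region_height_mm,
            (col + 1) * self.region_width_mm,
            (row + 1) * self.region_height_mm,
        )

    def region_inner_bounds(self, region: int) -> tuple[float, float, float, float]:
        """Bounds of the crawlable interior: region rectangle inset by the
        glycerol border. Confinement (and reflection in the simulator) acts
        on these walls."""
        xmin, ymin, xmax, ymax = self.region_bounds(region)
        b = self.border_mm
        return (xmin + b, ymin + b, xmax - b, ymax - b)

    def region_center(self, region: int) -> tuple[float, float]:
        xmin, ymin, xmax, ymax = self.region_bounds(region)
        return ((xmin + xmax) / 2.0, (ymin + ymax) / 2.0)
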