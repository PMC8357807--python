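"""Canonical plate layout and the mark-based similarity transform.

A rendered (or photographed) plate carries, in canonical coordinates:

* a horizontal barcode strip near the top edge,
* two filled registration discs flanking the strip — the left disc is
  drawn larger than the right so a 180-degree rotated image can still be
  oriented from the marks alone,
* the 8 x 12 well grid (rows A-H top to bottom, columns 1-12 left to
  right) below the strip.

Pixel coordinates are (x right, y down), origin at the top-left corner.
Well positions in an arbitrary image are obtained by the similarity
transform (rotation + isotropic scale + translation) that maps the two
canonical mark centers onto their measured centroids.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["PlateGeometry", "DEFAULT_GEOMETRY", "SimilarityTransform", "ROWS", "well_names"]

ROWS = "ABCDEFGH"
N_COLS = 12


def well_names() -> list[str]:
    """All 96 well addresses A1..H12, row-major."""
    return [f"{r}{c}" for r in ROWS for c in range(1, N_COLS + 1)]


@dataclass(frozen=True)
class PlateGeometry:
    """Canonical pixel layout of a rendered plate."""

    image_size: tuple[int, int] = (560, 430)  # (width, height)
    well_pitch: float = 38.0
    well_radius: float = 13.0
    grid_origin: tuple[float, float] = (65.0, 110.0)  # center of well A1
    barcode_box: tuple[float, float, float, float] = (120.0, 25.0, 456.0, 65.0)
    mark_left: tuple[float, float, float] = (72.0, 45.0, 15.0)  # (x, y, radius)
    mark_right: tuple[float, float, float] = (504.0, 45.0, 9.0)

    def __post_init__(self) -> None:
        if self.well_radius <= 0:
            raise ValueError("well_radius must be positive")
        w, h = self.image_size
        ox, oy = self.grid_origin
        x_max = ox + (N_COLS - 1) * self.well_pitch + self.well_radius
        y_max = oy + (len(ROWS) - 1) * self.well_pitch + self.well_radius
        x0, y0, x1, y1 = self.barcode_box
        if (
            x_max >= w
            or y_max >= h
            or x1 >= w
            or y1 >= h
            or ox - self.well_radius < 0
            or oy - self.well_radius <= y1
        ):
            raise ValueError(
                "image_size too small to place the well grid and barcode strip"
            )

    def well_center(self, row: int, col: int) -> tuple[float, float]:
        """Center of the well at 0-based (row, col)."""
        ox, oy = self.grid_origin
        return (ox + col * self.well_pitch, oy + row * self.well_pitch)

    def well_centers(self) -> dict[str, tuple[float, float]]:
        return {
            f"{ROWS[r]}{c + 1}": self.well_center(r, c)
            for r in range(len(ROWS))
            for c in range(N_COLS)
        }

    @property
    def mark_centers(self) -> tuple[np.ndarray, np.ndarray]:
        return (
            np.array(self.mark_left[:2], dtype=float),
            np.array(self.mark_right[:2], dtype=float),
        )


DEFAULT_GEOMETRY = PlateGeometry()


@dataclass(frozen=True)
class SimilarityTransform:
    """Map canonical coordinates to image coordinates: ``p -> A p + t``."""

    matrix: np.ndarray  # 2x2, rotation * scale
    offset: np.ndarray  # length 2

    @classmethod
    def from_marks(
        cls,
        measured_left: np.ndarray,
        measured_right: np.ndarray,
        geometry: PlateGeometry,
    ) -> "SimilarityTransform":
        ref_l, ref_r = geometry.mark_centers
        dv_ref = ref_r - ref_l
        dv_meas = np.asarray(measured_right, float) - np.asarray(measured_left, float)
        n_ref = np.hypot(*dv_ref)
        n_meas = np.hypot(*dv_meas)
        if n_meas == 0:
            raise ValueError("registration mark centroids coincide")
        scale = n_meas / n_ref
        ang = np.arctan2(dv_meas[1], dv_meas[0]) - np.arctan2(dv_ref[1], dv_ref[0])
        c, s = np.cos(ang), np.sin(ang)
        A = scale * np.array([[c, -s], [s, c]])
        t = np.asarray(measured_left, float) - A @ ref_l
        return cls(matrix=A, offset=t)

    @property
    def scale(self) -> float:
        return float(np.sqrt(abs(np.linalg.det(self.matrix))))

    def apply(self, points) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        out = pts @ self.matrix.T + self.offset
        return out[0] if np.asarray(points).ndim == 1 else out
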