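"""Contour geometry, myocardial annulus masks and AHA segment models.

Coordinates are 0-based (row, col) pixel indices.  Angles are measured
counter-clockwise (with the y axis pointing up, i.e. toward decreasing row)
from the RV-insertion reference angle stored on the contour set.  The
myocardial annulus is the pixel set between the endocardial and epicardial
contours; segment models follow the standard 16-segment short-axis layout
(basal 1-6, mid 7-12, apical 13-16; the apical cap, segment 17, is not
covered by a three-slice acquisition).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.draw import polygon2mask

__all__ = [
    "ContourSet",
    "SegmentModel",
    "circular_contours",
    "build_segments",
    "SLICE_SECTORS",
    "SLICE_SEGMENT_OFFSET",
]

#: angular sector count per slice position
SLICE_SECTORS = {"basal": 6, "mid": 6, "apical": 4}
#: first segment id minus one, per slice position
SLICE_SEGMENT_OFFSET = {"basal": 0, "mid": 6, "apical": 12}


def _polar(points: np.ndarray, center: np.ndarray):
    """Radii and absolute CCW angles of (row, col) points about a center."""
    d_row = points[..., 0] - center[0]
    d_col = points[..., 1] - center[1]
    radii = np.hypot(d_row, d_col)
    angles = np.arctan2(-d_row, d_col)  # y up = decreasing row
    return radii, angles


@dataclass
class ContourSet:
    """Closed endo- and epicardial polylines with an RV-insertion reference.

    Contours are (N, 2) arrays of sub-pixel (row, col) vertices, listed once
    (no repeated closing vertex).  Both contours must be star-shaped about
    the endocardial centroid, which holds for short-axis LV geometry.
    """

    endo: np.ndarray
    epi: np.ndarray
    reference_angle: float = 0.0

    def __post_init__(self):
        self.endo = np.asarray(self.endo, dtype=float)
        self.epi = np.asarray(self.epi, dtype=float)
        for name, c in (("endo", self.endo), ("epi", self.epi)):
            if c.ndim != 2 or c.shape[1] != 2 or c.shape[0] < 3:
                raise ValueError(f"{name} contour must be an (N>=3, 2) array")
            if not np.all(np.isfinite(c)):
                raise ValueError(f"{name} contour contains non-finite vertices")
        self.center = self.endo.mean(axis=0)
        self._endo_r, self._endo_a = self._sorted_polar(self.endo)
        self._epi_r, self._epi_a = self._sorted_polar(self.epi)
        # endocardial contour strictly inside epicardial, angle by angle
        epi_at_endo = self._interp_radius(self._endo_a, self._epi_a, self._epi_r)
        if not np.all(self._endo_r < epi_at_endo):
            raise ValueError("endocardial contour must lie strictly inside epicardial")

    def _sorted_polar(self, contour):
        radii, angles = _polar(contour, self.center)
        order = np.argsort(angles)
        return radii[order], angles[order]

    @staticmethod
    def _interp_radius(query, angles, radii):
        # periodic interpolation of contour radius vs angle
        return np.interp(query, angles, radii, period=2 * np.pi)

    def endo_radius_at(self, theta_abs) -> np.ndarray:
        """Endocardial radius at absolute angle(s)."""
        return self._interp_radius(np.asarray(theta_abs, float), self._endo_a, self._endo_r)

    def epi_radius_at(self, theta_abs) -> np.ndarray:
        """Epicardial radius at absolute angle(s)."""
        return self._interp_radius(np.asarray(theta_abs, float), self._epi_a, self._epi_r)

    def endo_mask(self, shape) -> np.ndarray:
        return polygon2mask(shape, self.endo)

    def epi_mask(self, shape) -> np.ndarray:
        return polygon2mask(shape, self.epi)

    def annulus_mask(self, shape) -> np.ndarray:
        """Pixels between the contours (the myocardium)."""
        mask = self.epi_mask(shape) & ~self.endo_mask(shape)
        if not mask.any():
            raise ValueError("annulus mask is empty for this shape")
        return mask

    def polar_coordinates(self, points: np.ndarray):
        """Relative CCW angle in [0, 2pi) and transmural depth of points.

        Depth is 0 at the endocardial contour and 1 at the epicardial one,
        linear in radius along the ray from the centroid.  Values are not
        clipped, so pixels marginally outside the band keep their geometric
        position.
        """
        points = np.asarray(points, dtype=float)
        radii, angles = _polar(points, self.center)
        rel = np.mod(angles - self.reference_angle, 2 * np.pi)
        r_endo = self.endo_radius_at(angles)
        r_epi = self.epi_radius_at(angles)
        depth = (radii - r_endo) / (r_epi - r_endo)
        return rel, depth

    def point_at(self, rel_angle, depth):
        """Inverse of :meth:`polar_coordinates`: (row, col) positions."""
        rel_angle = np.asarray(rel_angle, dtype=float)
        depth = np.asarray(depth, dtype=float)
        theta = rel_angle + self.reference_angle
        r = self.endo_radius_at(theta) + depth * (
            self.epi_radius_at(theta) - self.endo_radius_at(theta)
        )
        row = self.center[0] - r * np.sin(theta)
        col = self.center[1] + r * np.cos(theta)
        return np.stack([row, col], axis=-1)


def circular_contours(
    center,
    endo_radius: float,
    epi_radius: float,
    reference_angle: float = 0.0,
    n_points: int = 180,
) -> ContourSet:
    """Concentric circular contours (radii in pixels) about a center."""
    if not 0 < endo_radius < epi_radius:
        raise ValueError("need 0 < endo_radius < epi_radius")
    theta = np.linspace(0, 2 * np.pi, n_points, endpoint=False)
    center = np.asarray(center, dtype=float)

    def ring(r):
        return np.stack(
            [center[0] - r * np.sin(theta), center[1] + r * np.cos(theta)], axis=1
        )

    return ContourSet(endo=ring(endo_radius), epi=ring(epi_radius),
                      reference_angle=reference_angle)


@dataclass
class SegmentModel:
    """Per-pixel AHA segment labels for one short-axis slice.

    ``labels`` is 0 outside the myocardium and a global segment id (1-16)
    inside; ``segment_ids`` lists the ids present on this slice in sector
    order (counter-clockwise from the reference angle).
    """

    labels: np.ndarray
    slice_label: str
    segment_ids: tuple

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=int)


def build_segments(contours: ContourSet, slice_label: str, shape) -> SegmentModel:
    """Partition the annulus into equal angular sectors.

    Basal and mid slices get 6 sectors, the apical slice 4; numbering starts
    at the RV-insertion reference angle and proceeds counter-clockwise.
    """
    if slice_label not in SLICE_SECTORS:
        raise ValueError(f"unknown slice label {slice_label!r}")
    n_sectors = SLICE_SECTORS[slice_label]
    offset = SLICE_SEGMENT_OFFSET[slice_label]

    mask = contours.annulus_mask(shape)
    rows, cols = np.nonzero(mask)
    rel, _ = contours.polar_coordinates(np.stack([rows, cols], axis=1))
    sector = np.floor(rel / (2 * np.pi / n_sectors)).astype(int) % n_sectors

    labels = np.zeros(shape, dtype=int)
    labels[rows, cols] = offset + sector + 1
    ids = tuple(offset + i + 1 for i in range(n_sectors))
    for seg_id in ids:
        if not np.any(labels == seg_id):
            raise ValueError(f"segment {seg_id} is empty; contours too coarse")
    return SegmentModel(labels=labels, slice_label=slice_label, segment_ids=ids)
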