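"""Internal raster-geometry helpers shared by the phantom and quantification code.

Conventions
-----------
* Pixel coordinates are 0-based (row, col) pairs; a pixel's centre is at its
  integer index.
* Angles are measured counterclockwise (with the image displayed origin-upper,
  i.e. in the mathematical sense with y pointing up = decreasing row) starting
  from the ray that runs from the LV centre through the reference point placed
  below the inferior wall. All angles are reduced to [0, 2*pi).

Both the phantom generator and the segment-map builder rasterise contour
polygons through the same `polygon_mask` path, so ground-truth masks and
quantification masks agree pixel-for-pixel.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
from skimage.draw import polygon2mask

TWO_PI = 2.0 * np.pi


def circle_polygon(
    center: tuple[float, float], radius: float, n_vertices: int = 256
) -> np.ndarray:
    """Closed circular contour as an (n, 2) array of (row, col) vertices."""
    if radius <= 0:
        raise ValueError("radius must be positive")
    theta = np.linspace(0.0, TWO_PI, n_vertices, endpoint=False)
    rows = center[0] - radius * np.sin(theta)
    cols = center[1] + radius * np.cos(theta)
    return np.column_stack([rows, cols])


def polygon_mask(shape: tuple[int, int], vertices: np.ndarray) -> np.ndarray:
    """Boolean mask of pixels whose centres fall inside the polygon."""
    return polygon2mask(shape, np.asarray(vertices, dtype=float))


def pixel_angles(
    shape: tuple[int, int],
    center: tuple[float, float],
    reference_point: tuple[float, float],
) -> np.ndarray:
    """Per-pixel angle in [0, 2*pi), counterclockwise from the reference ray."""
    rows, cols = np.indices(shape)
    y = -(rows - center[0])  # y points up
    x = cols - center[1]
    ref_y = -(reference_point[0] - center[0])
    ref_x = reference_point[1] - center[1]
    if ref_x == 0 and ref_y == 0:
        raise ValueError("reference point coincides with the centre")
    ang = np.arctan2(y, x) - np.arctan2(ref_y, ref_x)
    return np.mod(ang, TWO_PI)


def point_angle(
    point: tuple[float, float],
    center: tuple[float, float],
    reference_point: tuple[float, float],
) -> float:
    """Angle of a single (row, col) point, same convention as pixel_angles."""
    y = -(point[0] - center[0])
    x = point[1] - center[1]
    ref_y = -(reference_point[0] - center[0])
    ref_x = reference_point[1] - center[1]
    return float(np.mod(np.arctan2(y, x) - np.arctan2(ref_y, ref_x), TWO_PI))


def pixel_radii(shape: tuple[int, int], center: tuple[float, float]) -> np.ndarray:
    rows, cols = np.indices(shape)
    return np.hypot(rows - center[0], cols - center[1])


def _freeze(a: np.ndarray) -> np.ndarray:
    a.flags.writeable = False
    return a


@lru_cache(maxsize=64)
def annulus_rasters(
    shape: tuple[int, int],
    center: tuple[float, float],
    endo_radius: float,
    epi_radius: float,
    n_vertices: int = 256,
):
    """Cached rasterisation of a circular annulus.

    Returns (endo_fill, epi_fill, annulus) read-only boolean masks. Cached
    because every slice of a phantom — and every patient of a cohort with a
    shared geometry template — reuses the same annulus.
    """
    if not 0 < endo_radius < epi_radius:
        raise ValueError("need 0 < endo_radius < epi_radius")
    endo = circle_polygon(center, endo_radius, n_vertices)
    epi = circle_polygon(center, epi_radius, n_vertices)
    endo_fill = polygon_mask(shape, endo)
    epi_fill = polygon_mask(shape, epi)
    annulus = epi_fill & ~endo_fill
    return _freeze(endo_fill), _freeze(epi_fill), _freeze(annulus)


def wedge_mask(
    shape: tuple[int, int],
    center: tuple[float, float],
    reference_point: tuple[float, float],
    start_rad: float,
    span_rad: float,
    r_inner: float,
    r_outer: float,
) -> np.ndarray:
    """Pixels inside an angular wedge between two radii (angles from reference ray)."""
    ang = pixel_angles(shape, center, reference_point)
    rad = pixel_radii(shape, center)
    in_span = np.mod(ang - start_rad, TWO_PI) < span_rad
    return in_span & (rad >= r_inner) & (rad <= r_outer)
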