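"""Enhancement quantification: AHA segments, 5-SD thresholding, mass.

The myocardium between manually drawn endo- and epicardial contours is
divided into equal angular sectors according to the American Heart
Association segment model — six for basal and mid-ventricular slices, four
for apical slices — numbered counterclockwise starting at the ray through a
reference point placed outside and below the inferior wall. With the
standard five-slice coverage (2 basal + 2 mid + 1 apical) a left ventricle
contributes 6+6+6+6+4 = 28 subsegments.

Scar pixels are those myocardial pixels whose signal lies strictly above
mean + n_sd x SD of a reference ROI drawn in normal myocardium (n_sd = 5 by
default; the ROI must contain at least 100 pixels). Pixel counts convert to
mass as  count x pixel_area(mm^2) x slice_thickness(mm) x density(g/ml) / 1000.
No morphological island filtering is applied by default; an optional
minimum-island size is available.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from shapely.geometry import Point, Polygon
from skimage.morphology import remove_small_objects

from . import _geometry as geo
from .core import MYOCARDIAL_DENSITY_G_PER_ML, SEGMENTS_PER_LEVEL, validate_slice_level


@dataclass
class LVGeometry:
    """Manually drawn LV contours plus the angular reference point."""

    endo_contour: np.ndarray  # (N, 2) (row, col)
    epi_contour: np.ndarray
    reference_point: tuple[float, float]
    slice_level: str
    pixel_spacing: float
    slice_thickness: float

    def __post_init__(self) -> None:
        self.endo_contour = np.asarray(self.endo_contour, dtype=float)
        self.epi_contour = np.asarray(self.epi_contour, dtype=float)
        validate_slice_level(self.slice_level)
        endo = Polygon(self.endo_contour)
        epi = Polygon(self.epi_contour)
        if not endo.is_valid or not epi.is_valid:
            raise ValueError("contours must be simple (non-self-intersecting) polygons")
        if endo.boundary.intersects(epi.boundary):
            raise ValueError("endo- and epicardial contours intersect")
        if not epi.contains(endo):
            raise ValueError("endocardial contour must lie strictly inside the epicardial one")
        if epi.contains(Point(self.reference_point)) or epi.boundary.contains(
            Point(self.reference_point)
        ):
            raise ValueError("reference point must lie outside the epicardial contour")

    @property
    def n_segments(self) -> int:
        return SEGMENTS_PER_LEVEL[self.slice_level]

    @property
    def center(self) -> tuple[float, float]:
        c = Polygon(self.epi_contour).centroid
        return (c.x, c.y)  # shapely x = our row coordinate (first column)


@dataclass
class SegmentMap:
    """Integer label image: 0 outside the myocardium, 1..n_segments inside."""

    labels: np.ndarray
    n_segments: int

    @property
    def annulus(self) -> np.ndarray:
        return self.labels > 0


def build_segment_map(geometry: LVGeometry, shape: tuple[int, int]) -> SegmentMap:
    """Rasterise the annulus and label it by equal angular sectors.

    Segment 1 starts at the inferior reference direction; numbering proceeds
    counterclockwise. Basal/mid slices get 6 sectors of 60 degrees, apical
    slices 4 sectors of 90 degrees.
    """
    endo_fill = geo.polygon_mask(shape, geometry.endo_contour)
    epi_fill = geo.polygon_mask(shape, geometry.epi_contour)
    annulus = epi_fill & ~endo_fill
    n_seg = geometry.n_segments
    width = geo.TWO_PI / n_seg
    angles = geo.pixel_angles(shape, geometry.center, geometry.reference_point)
    labels = np.zeros(shape, dtype=int)
    labels[annulus] = np.minimum((angles[annulus] // width).astype(int), n_seg - 1) + 1
    return SegmentMap(labels=labels, n_segments=n_seg)


def subsegment_count(slice_levels) -> int:
    """Total AHA subsegments contributed by a list of slice levels."""
    levels = list(slice_levels)
    if not levels:
        raise ValueError("need at least one slice level")
    return sum(SEGMENTS_PER_LEVEL[validate_slice_level(lev)] for lev in levels)


@dataclass(frozen=True)
class ROIStats:
    mean: float
    sd: float
    n_pixels: int


def reference_roi_stats(
    image: np.ndarray, roi_mask: np.ndarray, min_pixels: int = 100
) -> ROIStats:
    """Mean and sample SD (n-1 denominator) of the normal-myocardium ROI."""
    image = np.asarray(image, dtype=float)
    roi_mask = np.asarray(roi_mask, dtype=bool)
    if image.shape != roi_mask.shape:
        raise ValueError("image and ROI mask shapes differ")
    vals = image[roi_mask]
    n = vals.size
    if n < min_pixels:
        raise ValueError(
            f"reference ROI has {n} pixels, {min_pixels - n} short of the "
            f"required {min_pixels}"
        )
    return ROIStats(float(vals.mean()), float(vals.std(ddof=1)), int(n))


def mass_from_pixels(
    n_pixels: int,
    pixel_spacing: float,
    slice_thickness: float,
    density: float = MYOCARDIAL_DENSITY_G_PER_ML,
) -> float:
    """Tissue mass in grams from a pixel count (mm^3 -> ml -> g)."""
    if pixel_spacing <= 0 or slice_thickness <= 0 or density <= 0:
        raise ValueError("spacing, thickness and density must be positive")
    if n_pixels < 0:
        raise ValueError("pixel count cannot be negative")
    return n_pixels * pixel_spacing**2 * slice_thickness * density / 1000.0


@dataclass
class ScarQuantResult:
    """Per-slice quantification: threshold, masks, counts and masses."""

    threshold: float
    roi: ROIStats
    n_sd: float
    scar_mask: np.ndarray
    segment_map: SegmentMap
    scar_pixels_by_segment: np.ndarray  # length n_segments, index = label-1
    scar_mass_g_by_segment: np.ndarray
    pixel_spacing: float
    slice_thickness: float
    density: float

    @property
    def scar_pixels_total(self) -> int:
        return int(self.scar_pixels_by_segment.sum())

    @property
    def scar_mass_g(self) -> float:
        return float(self.scar_mass_g_by_segment.sum())


def segment_scar(
    image: np.ndarray,
    annulus_mask: np.ndarray,
    roi_stats: ROIStats,
    segment_map: SegmentMap,
    n_sd: float = 5.0,
    pixel_spacing: float = 1.65,
    slice_thickness: float = 8.0,
    density: float = MYOCARDIAL_DENSITY_G_PER_ML,
    min_island_pixels: int = 0,
) -> ScarQuantResult:
    """Threshold the myocardium at mean + n_sd x SD of the reference ROI.

    Pixels strictly above the threshold count as scar; ties do not. A
    constant image with sd = 0 therefore yields an empty mask, not an error.
    ``min_island_pixels`` > 0 enables optional removal of connected
    components smaller than that size (off by default).
    """
    image = np.asarray(image, dtype=float)
    annulus_mask = np.asarray(annulus_mask, dtype=bool)
    if image.shape != annulus_mask.shape or image.shape != segment_map.labels.shape:
        raise ValueError("image, annulus mask and segment map must be congruent")
    threshold = roi_stats.mean + n_sd * roi_stats.sd
    scar = annulus_mask & (image > threshold)
    if min_island_pixels > 0:
        scar = remove_small_objects(scar, min_size=min_island_pixels)
    n_seg = segment_map.n_segments
    counts = np.bincount(
        segment_map.labels[scar & segment_map.annulus].ravel(), minlength=n_seg + 1
    )[1 : n_seg + 1]
    masses = np.array(
        [mass_from_pixels(int(c), pixel_spacing, slice_thickness, density) for c in counts]
    )
    return ScarQuantResult(
        threshold=float(threshold),
        roi=roi_stats,
        n_sd=float(n_sd),
        scar_mask=scar,
        segment_map=segment_map,
        scar_pixels_by_segment=counts,
        scar_mass_g_by_segment=masses,
        pixel_spacing=pixel_spacing,
        slice_thickness=slice_thickness,
        density=density,
    )


def call_subsegments(result: ScarQuantResult, min_pixels: int = 1) -> np.ndarray:
    """Binary per-segment scar calls for one slice.

    A subsegment is positive when it contains at least ``min_pixels``
    supra-threshold pixels (default 1).
    """
    if min_pixels < 1:
        raise ValueError("min_pixels must be >= 1")
    return result.scar_pixels_by_segment >= min_pixels


def auto_reference_roi(
    image: np.ndarray, segment_map: SegmentMap, min_pixels: int = 100
) -> np.ndarray:
    """Heuristic normal-myocardium ROI: accumulate whole segments in
    ascending order of mean signal until at least ``min_pixels`` pixels are
    collected. Stands in for the study's manually drawn remote-myocardium
    ROI on phantom data."""
    image = np.asarray(image, dtype=float)
    means = []
    for lab in range(1, segment_map.n_segments + 1):
        m = segment_map.labels == lab
        means.append(image[m].mean() if m.any() else np.inf)
    order = np.argsort(means)
    roi = np.zeros(image.shape, dtype=bool)
    for lab_idx in order:
        roi |= segment_map.labels == lab_idx + 1
        if roi.sum() >= min_pixels:
            break
    return roi


@dataclass
class PatientScarQuant:
    """Whole-LV quantification: per-slice results plus the stacked calls."""

    slices: list[ScarQuantResult]
    calls: np.ndarray  # concatenated per-subsegment booleans (28 for 5 slices)

    @property
    def total_mass_g(self) -> float:
        return float(sum(s.scar_mass_g for s in self.slices))


def quantify_patient(
    images,
    geometries,
    roi_masks=None,
    n_sd: float = 5.0,
    min_pixels: int = 1,
    density: float = MYOCARDIAL_DENSITY_G_PER_ML,
    min_island_pixels: int = 0,
) -> PatientScarQuant:
    """Quantify every slice of one patient and stack the subsegment calls.

    ``roi_masks`` may be None (auto ROI per slice), a single mask applied to
    every slice, or one mask per slice.
    """
    images = list(images)
    geometries = list(geometries)
    if len(images) != len(geometries):
        raise ValueError("one geometry per image required")
    if roi_masks is None:
        roi_masks = [None] * len(images)
    elif isinstance(roi_masks, np.ndarray):
        roi_masks = [roi_masks] * len(images)
    results, calls = [], []
    for img, geom, roi in zip(images, geometries, roi_masks):
        seg_map = build_segment_map(geom, img.shape)
        if roi is None:
            roi = auto_reference_roi(img, seg_map)
        stats = reference_roi_stats(img, roi)
        res = segment_scar(
            img,
            seg_map.annulus,
            stats,
            seg_map,
            n_sd=n_sd,
            pixel_spacing=geom.pixel_spacing,
            slice_thickness=geom.slice_thickness,
            density=density,
            min_island_pixels=min_island_pixels,
        )
        results.append(res)
        calls.append(call_subsegments(res, min_pixels=min_pixels))
    return PatientScarQuant(slices=results, calls=np.concatenate(calls))
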