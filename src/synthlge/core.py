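"""Core in-memory containers shared across the pipeline.

The pipeline passes short-axis cardiac images between stages as small
dataclasses carrying the pixel data together with the geometry metadata
(in-plane pixel spacing and slice thickness in millimetres) needed to turn
pixel counts into tissue mass.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Short-axis slice levels and the number of AHA segments each contributes.
SEGMENTS_PER_LEVEL = {"basal": 6, "mid": 6, "apical": 4}

#: The standard five-slice short-axis coverage: two basal, two mid, one apical.
STANDARD_SLICE_LEVELS = ("basal", "basal", "mid", "mid", "apical")

#: Myocardial tissue density in g/ml, used to convert volume to mass.
MYOCARDIAL_DENSITY_G_PER_ML = 1.05


def validate_slice_level(level: str) -> str:
    if level not in SEGMENTS_PER_LEVEL:
        raise ValueError(
            f"unknown slice level {level!r}; expected one of {sorted(SEGMENTS_PER_LEVEL)}"
        )
    return level


@dataclass
class T1Map:
    """Per-pixel longitudinal relaxation time (ms) for one short-axis slice.

    Attributes
    ----------
    values : (H, W) float array of T1 in milliseconds. May contain NaN where a
        fit did not converge.
    pixel_spacing : in-plane pixel size in mm (isotropic).
    slice_thickness : slice thickness in mm.
    slice_level : "basal", "mid" or "apical".
    quality_mask : optional (H, W) boolean array, True where the value is
        trustworthy (e.g. the per-pixel fit converged).
    """

    values: np.ndarray
    pixel_spacing: float
    slice_thickness: float
    slice_level: str = "mid"
    quality_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("T1Map.values must be a 2-D array")
        if self.pixel_spacing <= 0 or self.slice_thickness <= 0:
            raise ValueError("pixel_spacing and slice_thickness must be positive")
        validate_slice_level(self.slice_level)
        if self.quality_mask is not None:
            self.quality_mask = np.asarray(self.quality_mask, dtype=bool)
            if self.quality_mask.shape != self.values.shape:
                raise ValueError("quality_mask shape must match values")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def pixel_area_mm2(self) -> float:
        return self.pixel_spacing**2


@dataclass
class MOLLISeries:
    """A stack of TI-tagged magnitude images from one MOLLI acquisition.

    images has shape (n_images, H, W); tis holds the matching effective
    inversion times in ms, sorted ascending.
    """

    images: np.ndarray
    tis: np.ndarray
    pixel_spacing: float
    slice_thickness: float
    slice_level: str = "mid"

    def __post_init__(self) -> None:
        self.images = np.asarray(self.images, dtype=float)
        self.tis = np.asarray(self.tis, dtype=float)
        if self.images.ndim != 3:
            raise ValueError("MOLLISeries.images must have shape (n, H, W)")
        if len(self.tis) != self.images.shape[0]:
            raise ValueError(
                f"{self.images.shape[0]} images but {len(self.tis)} inversion times"
            )
        validate_slice_level(self.slice_level)

    @property
    def n_images(self) -> int:
        return self.images.shape[0]

    @property
    def image_shape(self) -> tuple[int, int]:
        return self.images.shape[1:]
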