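"""Synthetic phase-sensitive inversion-recovery (PSIR) image computation.

Once a post-contrast T1 map exists, an IR image at *any* inversion time can
be computed retrospectively. Under full recovery between inversions and an
ideal inversion pulse, with equilibrium magnetisation normalised to 1, the
signed signal of a pixel with relaxation time T1 at inversion time TI is

    S(TI) = 1 - 2 exp(-TI / T1)

which is -1 at TI = 0, crosses zero at the null point TI = T1 ln 2 and
approaches 1 as TI grows. At a TI below both tissues' null points, shorter
T1 means larger signed signal — this is why post-gadolinium scar (short T1)
is hyperintense against remote myocardium on an enhancement image.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .core import T1Map

logger = logging.getLogger(__name__)

LN2 = float(np.log(2.0))


@dataclass(frozen=True)
class TIGrid:
    """Evenly spaced inversion-time grid; the default is the 40-image series
    starting at 200 ms in 25 ms steps (last TI 1175 ms)."""

    start: float = 200.0
    increment: float = 25.0
    count: int = 40

    def __post_init__(self) -> None:
        if self.start <= 0 or self.increment <= 0 or self.count < 1:
            raise ValueError("need start > 0, increment > 0, count >= 1")

    @property
    def tis(self) -> np.ndarray:
        return self.start + self.increment * np.arange(self.count)

    @property
    def last_ti(self) -> float:
        return self.start + (self.count - 1) * self.increment

    def nearest(self, ti: float) -> float:
        """Grid TI closest to ``ti`` (ties resolve to the lower TI)."""
        tis = self.tis
        return float(tis[np.argmin(np.abs(tis - ti))])


@dataclass
class SyntheticIRSeries:
    """Signed (or magnitude) IR images computed from a T1 map over a TI grid."""

    images: np.ndarray  # (n, H, W)
    tis: np.ndarray
    source_t1map: T1Map
    mode: str = "signed"

    def __post_init__(self) -> None:
        if self.mode not in ("signed", "magnitude"):
            raise ValueError("mode must be 'signed' or 'magnitude'")
        if self.images.shape[0] != len(self.tis):
            raise ValueError("one image per TI required")

    @property
    def n_images(self) -> int:
        return self.images.shape[0]


def ir_signal(t1, ti):
    """Signed PSIR signal 1 - 2 exp(-TI/T1); accepts scalars or arrays."""
    t1 = np.asarray(t1, dtype=float)
    ti = np.asarray(ti, dtype=float)
    if np.any(t1 <= 0):
        raise ValueError("t1 must be strictly positive")
    if np.any(ti < 0):
        raise ValueError("ti must be non-negative")
    out = 1.0 - 2.0 * np.exp(-ti / t1)
    return float(out) if out.ndim == 0 else out


def synthesize_series(
    t1map: T1Map, grid: TIGrid | None = None, mode: str = "signed"
) -> SyntheticIRSeries:
    """Apply :func:`ir_signal` pixel-wise at every TI of the grid.

    Non-positive (or NaN) T1 pixels are masked out (set to NaN) with a
    logged warning rather than raising; fitted maps legitimately contain
    unconverged pixels.
    """
    if grid is None:
        grid = TIGrid()
    t1 = t1map.values
    valid = np.isfinite(t1) & (t1 > 0)
    if not np.all(valid):
        logger.warning(
            "masking %d non-positive/undefined T1 pixels during IR synthesis",
            int((~valid).sum()),
        )
    safe = np.where(valid, t1, 1.0)
    tis = grid.tis
    images = 1.0 - 2.0 * np.exp(-tis[:, None, None] / safe[None, :, :])
    images[:, ~valid] = np.nan
    if mode == "magnitude":
        images = np.abs(images)
    elif mode != "signed":
        raise ValueError("mode must be 'signed' or 'magnitude'")
    return SyntheticIRSeries(images=images, tis=tis, source_t1map=t1map, mode=mode)


def optimal_ti(
    t1map: T1Map, myocardial_mask: np.ndarray, grid: TIGrid | None = None
) -> float:
    """Inversion time that nulls normal myocardium: ln2 x mean T1 in the mask.

    When a grid is supplied the result is snapped to the nearest grid TI.
    """
    mask = np.asarray(myocardial_mask, dtype=bool)
    if mask.shape != t1map.shape:
        raise ValueError("mask shape must match the T1 map")
    vals = t1map.values[mask]
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        raise ValueError("myocardial mask selects no valid pixels")
    ti = LN2 * float(vals.mean())
    if grid is not None:
        ti = grid.nearest(ti)
    return ti
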