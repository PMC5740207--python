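"""MOLLI acquisition timing and three-parameter inversion-recovery fitting.

The Modified Look-Locker Inversion recovery (MOLLI) sequence samples the
inversion-recovery curve of each pixel over several heartbeats. A scheme such
as 4(1)3(1)2 acquires blocks of 4, 3 and 2 images separated by 1-beat
recovery pauses: nine images in eleven heartbeats. Each inversion block k
uses an inversion delay ``initial_ti + k * ti_increment`` and the j-th image
within the block is read out j heartbeats later, so its effective inversion
time is ``delay + j * rr_interval``.

Per pixel the signed signal follows the three-parameter model

    S(t) = A - B * exp(-t / T1*)

where T1* is the apparent (Look-Locker-shortened) relaxation time. The true
T1 is recovered with the Look-Locker correction

    T1 = T1* * (B / A - 1).

Magnitude images lose the sign of the early samples; polarity is restored by
exhaustively trying every "flip the m earliest samples" hypothesis
(m = 0..n-1) and keeping the fit with the smallest residual.

Two fitting engines are provided:

* :func:`fit_molli` — scipy least-squares on a single curve (the reference
  path, used for per-curve work and as a cross-check).
* :func:`fit_t1_map` — a vectorised variable-projection solver that profiles
  the residual over T1* (the model is linear in A and B at fixed T1*), scans
  a log-spaced T1* grid and refines the winner by golden-section search, for
  all pixels and all polarity hypotheses simultaneously. This is how a whole
  map is fitted in reasonable time on one core.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
from scipy.optimize import least_squares

from .core import MOLLISeries, T1Map

T1_STAR_BOUNDS = (1.0, 5000.0)  # ms; physically plausible search window


@dataclass(frozen=True)
class SamplingScheme:
    """MOLLI sampling pattern, e.g. 4(1)3(1)2.

    blocks is a sequence of (images_in_block, recovery_beats_after_block);
    initial_ti and ti_increment set the per-block inversion delays; a fixed
    rr_interval (ms) models a constant heart rate (857 ms ~= 70 bpm).
    """

    blocks: tuple[tuple[int, int], ...] = ((4, 1), (3, 1), (2, 0))
    initial_ti: float = 100.0
    ti_increment: float = 80.0
    rr_interval: float = 857.0

    def __post_init__(self) -> None:
        if not self.blocks:
            raise ValueError("scheme must contain at least one block")
        for n_img, rec in self.blocks:
            if n_img < 1:
                raise ValueError("each block must acquire at least one image")
            if rec < 0:
                raise ValueError("recovery beats cannot be negative")
        if self.initial_ti <= 0 or self.ti_increment < 0 or self.rr_interval <= 0:
            raise ValueError("timing parameters must be positive")

    @classmethod
    def from_string(cls, pattern: str, **kwargs) -> "SamplingScheme":
        """Parse the compact notation, e.g. ``"4(1)3(1)2"``."""
        tokens = re.findall(r"(\d+)(?:\((\d+)\))?", pattern)
        if not tokens or "".join(t[0] + (f"({t[1]})" if t[1] else "") for t in tokens) != pattern:
            raise ValueError(f"cannot parse sampling scheme {pattern!r}")
        blocks = tuple((int(n), int(r) if r else 0) for n, r in tokens)
        return cls(blocks=blocks, **kwargs)

    @property
    def n_images(self) -> int:
        return sum(n for n, _ in self.blocks)

    @property
    def n_heartbeats(self) -> int:
        """Total acquisition duration in heartbeats (images + recovery pauses)."""
        return sum(n for n, _ in self.blocks) + sum(r for _, r in self.blocks)


class EffectiveTI(NamedTuple):
    ti: float
    block: int
    image_in_block: int


def effective_tis(scheme: SamplingScheme, return_provenance: bool = False):
    """Effective inversion time of every acquired image, sorted ascending.

    With ``return_provenance=True`` returns a list of :class:`EffectiveTI`
    records keeping each TI's (block, image-within-block) origin; otherwise a
    plain float array.
    """
    entries: list[EffectiveTI] = []
    for k, (n_img, _) in enumerate(scheme.blocks):
        delay = scheme.initial_ti + k * scheme.ti_increment
        for j in range(n_img):
            entries.append(EffectiveTI(delay + j * scheme.rr_interval, k, j))
    entries.sort(key=lambda e: e.ti)
    if return_provenance:
        return entries
    return np.array([e.ti for e in entries])


@dataclass
class IRFit:
    """Result of a three-parameter IR fit on one pixel/curve."""

    A: float
    B: float
    t1_star: float
    t1: float
    residual_rms: float
    converged: bool
    polarity_flips: int = 0  # number of earliest samples sign-flipped


def _model(t: np.ndarray, A: float, B: float, tau: float) -> np.ndarray:
    return A - B * np.exp(-t / tau)


def _ls_fit(tis: np.ndarray, signed: np.ndarray, bounds: tuple[float, float]):
    """Bounded least-squares fit of the signed three-parameter model."""
    a0 = float(np.max(np.abs(signed)))
    if a0 == 0.0:
        a0 = 1.0
    tau0 = float(np.clip(np.median(tis), bounds[0] + 1e-9, bounds[1] - 1e-9))
    x0 = np.array([a0, 2.0 * a0, tau0])

    def resid(p):
        return _model(tis, *p) - signed

    def jac(p):
        A, B, tau = p
        e = np.exp(-tis / tau)
        return np.column_stack([np.ones_like(tis), -e, -B * e * tis / tau**2])

    return least_squares(
        resid,
        x0,
        jac=jac,
        bounds=([-np.inf, 0.0, bounds[0]], [np.inf, np.inf, bounds[1]]),
        method="trf",
        xtol=1e-14,
        ftol=1e-14,
        gtol=1e-14,
        max_nfev=400,
    )


def fit_molli(
    tis: Sequence[float],
    magnitudes: Sequence[float],
    t1_star_bounds: tuple[float, float] = T1_STAR_BOUNDS,
) -> IRFit:
    """Fit the three-parameter IR model to one magnitude curve.

    Performs exhaustive polarity restoration (sign-flip the m earliest
    samples for m = 0..n-1, keep the lowest-residual fit), then applies the
    Look-Locker correction. Optimiser failure is reported via
    ``converged=False``, never as an exception.
    """
    tis = np.asarray(tis, dtype=float)
    mags = np.asarray(magnitudes, dtype=float)
    if tis.shape != mags.shape or tis.ndim != 1:
        raise ValueError("tis and magnitudes must be 1-D arrays of equal length")
    n = len(tis)
    if n < 4:
        raise ValueError(f"need at least 4 samples to fit 3 parameters, got {n}")
    if len(np.unique(tis)) != n:
        raise ValueError("inversion times must be distinct")
    order = np.argsort(tis)
    tis, mags = tis[order], mags[order]

    if np.ptp(mags) == 0.0:
        return IRFit(float(mags[0]), 0.0, np.nan, np.nan, 0.0, converged=False)

    best = None
    best_m = 0
    for m in range(n):
        signed = mags.copy()
        signed[:m] *= -1.0
        res = _ls_fit(tis, signed, t1_star_bounds)
        if best is None or res.cost < best.cost:
            best, best_m = res, m

    A, B, tau = best.x
    t1 = tau * (B / A - 1.0) if A != 0 else np.nan
    rms = float(np.sqrt(2.0 * best.cost / n))
    converged = bool(best.success) and A > 0 and B > A and np.isfinite(t1)
    return IRFit(float(A), float(B), float(tau), float(t1), rms, converged, best_m)


# ---------------------------------------------------------------------------
# Vectorised variable-projection engine
# ---------------------------------------------------------------------------


def _profiled_rss(tis: np.ndarray, S: np.ndarray, tau: np.ndarray):
    """Exact (A, B) linear solve and residual sum of squares at fixed T1*.

    S has shape (n, P); tau has shape (P,) (one candidate per column).
    Returns (rss, A, B). The residual is accumulated explicitly (not via the
    normal-equation identity), which keeps the RSS resolvable down to machine
    precision near the optimum.
    """
    n = len(tis)
    E = np.exp(-tis[:, None] / tau[None, :])  # (n, P)
    s1 = S.sum(axis=0)
    sE = (E * S).sum(axis=0)
    e1 = E.sum(axis=0)
    ee = (E * E).sum(axis=0)
    det = n * ee - e1 * e1
    bad = det <= 1e-30
    det = np.where(bad, 1.0, det)
    A = (ee * s1 - e1 * sE) / det
    B = (e1 * s1 - n * sE) / det
    r = A[None, :] - B[None, :] * E - S
    rss = (r * r).sum(axis=0)
    rss[bad] = np.inf
    return rss, A, B


def _fit_stack(
    tis: np.ndarray,
    data: np.ndarray,
    t1_star_bounds: tuple[float, float] = T1_STAR_BOUNDS,
    n_grid: int = 64,
    n_golden: int = 80,
):
    """Fit every column of ``data`` (n, P magnitudes) with polarity search.

    Returns dict of arrays (P,): A, B, t1_star, t1, rss, flips, converged.
    """
    n, P = data.shape
    # polarity hypotheses: flip the m earliest samples, m = 0..n-1
    signs = np.where(np.arange(n)[None, :] >= np.arange(n)[:, None], 1.0, -1.0)  # (n, n)
    S = (signs[:, :, None] * data[None, :, :]).transpose(1, 0, 2).reshape(n, n * P)

    lo_b, hi_b = t1_star_bounds
    grid = np.geomspace(max(lo_b, 2.0), hi_b, n_grid)
    best_rss = np.full(S.shape[1], np.inf)
    best_idx = np.zeros(S.shape[1], dtype=int)
    for g, tau_g in enumerate(grid):
        rss, _, _ = _profiled_rss(tis, S, np.full(S.shape[1], tau_g))
        better = rss < best_rss
        best_rss[better] = rss[better]
        best_idx[better] = g

    lo = grid[np.maximum(best_idx - 1, 0)]
    hi = grid[np.minimum(best_idx + 1, n_grid - 1)]

    invphi = (np.sqrt(5.0) - 1.0) / 2.0
    x1 = hi - invphi * (hi - lo)
    x2 = lo + invphi * (hi - lo)
    f1, _, _ = _profiled_rss(tis, S, x1)
    f2, _, _ = _profiled_rss(tis, S, x2)
    for _ in range(n_golden):
        take1 = f1 < f2
        hi = np.where(take1, x2, hi)
        lo = np.where(take1, lo, x1)
        x1_new = hi - invphi * (hi - lo)
        x2_new = lo + invphi * (hi - lo)
        # only one endpoint moved per column; recompute both (vector-cheap)
        f1, _, _ = _profiled_rss(tis, S, x1_new)
        f2, _, _ = _profiled_rss(tis, S, x2_new)
        x1, x2 = x1_new, x2_new
    tau = 0.5 * (lo + hi)
    rss, A, B = _profiled_rss(tis, S, tau)

    rss = rss.reshape(n, P)
    tau = tau.reshape(n, P)
    A = A.reshape(n, P)
    B = B.reshape(n, P)
    m_best = np.argmin(rss, axis=0)  # ties -> smallest flip count
    cols = np.arange(P)
    A, B, tau, rss = A[m_best, cols], B[m_best, cols], tau[m_best, cols], rss[m_best, cols]

    with np.errstate(divide="ignore", invalid="ignore"):
        t1 = tau * (B / A - 1.0)
    converged = (
        np.isfinite(t1)
        & (A > 0)
        & (B > A)
        & (tau > lo_b * (1 + 1e-6))
        & (tau < hi_b * (1 - 1e-6))
    )
    return {
        "A": A,
        "B": B,
        "t1_star": tau,
        "t1": t1,
        "rss": rss,
        "flips": m_best,
        "converged": converged,
    }


def fit_t1_map(
    series: MOLLISeries,
    mask: np.ndarray | None = None,
    t1_star_bounds: tuple[float, float] = T1_STAR_BOUNDS,
) -> T1Map:
    """Fit the IR model per pixel of a MOLLI series to produce a T1 map.

    Pixels where the fit does not converge (e.g. flat or all-zero signal) are
    flagged False in the returned map's quality_mask and set to NaN. An
    optional boolean ``mask`` restricts fitting to a region; pixels outside
    it are NaN and flagged.
    """
    shapes = {im.shape for im in series.images}
    if len(shapes) != 1:
        raise ValueError("all images in the series must share one shape")
    n, H, W = series.images.shape
    if n < 4:
        raise ValueError("need at least 4 TI samples to fit a map")

    if mask is None:
        sel = np.ones(H * W, dtype=bool)
    else:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != (H, W):
            raise ValueError("mask shape must match the image shape")
        sel = mask.ravel()

    data = series.images.reshape(n, H * W)[:, sel]
    values = np.full(H * W, np.nan)
    quality = np.zeros(H * W, dtype=bool)
    if data.shape[1]:
        out = _fit_stack(series.tis, data, t1_star_bounds)
        vals = np.where(out["converged"], out["t1"], np.nan)
        values[sel] = vals
        quality[sel] = out["converged"]
    return T1Map(
        values.reshape(H, W),
        pixel_spacing=series.pixel_spacing,
        slice_thickness=series.slice_thickness,
        slice_level=series.slice_level,
        quality_mask=quality.reshape(H, W),
    )
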