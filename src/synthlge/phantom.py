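"""Synthetic left-ventricle phantoms and cohort datasets.

The phantom is a concentric-annulus short-axis LV: a blood pool inside the
endocardial contour, a myocardial annulus between the contours and
background outside, each assigned a post-gadolinium T1. Scar is inserted as
angular wedges of configurable span and transmurality; post-gadolinium scar
retains more contrast agent than remote myocardium and therefore has a
*shorter* T1. A reference point placed below the inferior wall anchors the
angular convention used by the AHA segment model.

Everything downstream (MOLLI simulation, IR synthesis, 5-SD quantification,
cohort agreement statistics) can be exercised on these phantoms without any
external data. Ground-truth scar masses come from exact pixel counts of the
inserted wedges, rasterised through the same polygon path the
quantification module uses, so the two stay pixel-consistent.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import _geometry as geo
from .core import (
    MYOCARDIAL_DENSITY_G_PER_ML,
    SEGMENTS_PER_LEVEL,
    STANDARD_SLICE_LEVELS,
    MOLLISeries,
    T1Map,
)
from .relaxometry import SamplingScheme, effective_tis


class PhantomConfigError(ValueError):
    """Raised when a phantom configuration is internally inconsistent."""


@dataclass(frozen=True)
class ScarSpec:
    """One scar wedge: slice index, angular placement (degrees,
    counterclockwise from the inferior reference direction) and
    transmurality (fraction of the wall thickness, from the endocardium
    outward, 0 < f <= 1)."""

    slice_index: int
    start_deg: float
    span_deg: float
    transmurality: float

    def __post_init__(self) -> None:
        if not 0 < self.transmurality <= 1:
            raise PhantomConfigError("transmurality must be in (0, 1]")
        if not 0 < self.span_deg <= 360:
            raise PhantomConfigError("span_deg must be in (0, 360]")


@dataclass(frozen=True)
class PhantomConfig:
    """Geometry, tissue T1s and noise for one synthetic LV.

    Post-gadolinium T1 defaults (myocardium 500 ms, scar 300 ms, blood
    350 ms) are literature-informed round numbers chosen so that scar is
    hyperintense relative to myocardium on an IR image at TI 300 ms.
    noise_sd is Gaussian noise (ms) added to the T1 map.
    """

    image_size: int = 64
    pixel_spacing: float = 1.65  # mm
    slice_thickness: float = 8.0  # mm
    n_slices: int = 5
    slice_levels: tuple[str, ...] | None = None
    t1_myocardium: float = 500.0
    t1_scar: float = 300.0
    t1_blood: float = 350.0
    t1_background: float = 1200.0
    endo_radius_mm: float = 12.0
    epi_radius_mm: float = 22.0
    scar_specs: tuple[ScarSpec, ...] = ()
    noise_sd: float = 0.0
    density: float = MYOCARDIAL_DENSITY_G_PER_ML
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("t1_myocardium", "t1_scar", "t1_blood", "t1_background"):
            if getattr(self, name) <= 0:
                raise PhantomConfigError(f"{name} must be strictly positive")
        if self.t1_scar >= self.t1_myocardium:
            raise PhantomConfigError(
                "post-gadolinium scar must have shorter T1 than remote myocardium"
            )
        if not 0 < self.endo_radius_mm < self.epi_radius_mm:
            raise PhantomConfigError("need 0 < endo_radius_mm < epi_radius_mm")
        if self.pixel_spacing <= 0 or self.slice_thickness <= 0 or self.density <= 0:
            raise PhantomConfigError("spacing, thickness and density must be positive")
        if self.n_slices < 1:
            raise PhantomConfigError("n_slices must be >= 1")
        levels = self.slice_levels
        if levels is None:
            if self.n_slices == 5:
                levels = STANDARD_SLICE_LEVELS
            else:
                raise PhantomConfigError(
                    "slice_levels must be given explicitly when n_slices != 5"
                )
        if len(levels) != self.n_slices:
            raise PhantomConfigError("slice_levels length must equal n_slices")
        for lev in levels:
            if lev not in SEGMENTS_PER_LEVEL:
                raise PhantomConfigError(f"unknown slice level {lev!r}")
        object.__setattr__(self, "slice_levels", tuple(levels))
        object.__setattr__(self, "scar_specs", tuple(self.scar_specs))
        for spec in self.scar_specs:
            if not 0 <= spec.slice_index < self.n_slices:
                raise PhantomConfigError(
                    f"scar spec references slice {spec.slice_index} but the "
                    f"phantom has {self.n_slices} slices"
                )
        margin = self.epi_radius_mm / self.pixel_spacing + 4
        if (self.image_size - 1) / 2 < margin - 3:
            raise PhantomConfigError("image_size too small for the epicardial radius")

    @property
    def center(self) -> tuple[float, float]:
        c = (self.image_size - 1) / 2.0
        return (c, c)

    @property
    def endo_radius_px(self) -> float:
        return self.endo_radius_mm / self.pixel_spacing

    @property
    def epi_radius_px(self) -> float:
        return self.epi_radius_mm / self.pixel_spacing

    @property
    def reference_point(self) -> tuple[float, float]:
        # outside and below the inferior wall (larger row = lower on screen)
        return (min(self.center[0] + self.epi_radius_px + 3.0,
                    self.image_size - 1.0), self.center[1])

    @property
    def pixel_area_mm2(self) -> float:
        return self.pixel_spacing**2


@dataclass
class GroundTruth:
    """Exact per-slice scar masks, masses and subsegment labelling."""

    scar_masks: list[np.ndarray]
    scar_mass_g: np.ndarray  # per slice
    subsegment_labels: list[np.ndarray]  # global labels 1..total_subsegments
    myocardium_masks: list[np.ndarray]
    endo_contour: np.ndarray
    epi_contour: np.ndarray
    reference_point: tuple[float, float]
    slice_levels: tuple[str, ...]

    @property
    def total_scar_mass_g(self) -> float:
        return float(self.scar_mass_g.sum())

    @property
    def n_subsegments(self) -> int:
        return sum(SEGMENTS_PER_LEVEL[lev] for lev in self.slice_levels)

    def subsegment_calls(self) -> np.ndarray:
        """Boolean per-subsegment scar presence (>= 1 scar pixel)."""
        calls = np.zeros(self.n_subsegments, dtype=bool)
        for labels, scar in zip(self.subsegment_labels, self.scar_masks):
            present = np.unique(labels[scar & (labels > 0)])
            calls[present - 1] = True
        return calls


def pixels_to_grams(
    n_pixels: int, pixel_spacing: float, slice_thickness: float, density: float
) -> float:
    return n_pixels * pixel_spacing**2 * slice_thickness * density / 1000.0


def make_lv_phantom(config: PhantomConfig) -> tuple[list[T1Map], GroundTruth]:
    """Build the T1 maps and exact ground truth for one synthetic LV.

    Deterministic for a fixed ``config.seed``.
    """
    shape = (config.image_size, config.image_size)
    center = config.center
    ref = config.reference_point
    endo_fill, epi_fill, annulus = geo.annulus_rasters(
        shape, center, config.endo_radius_px, config.epi_radius_px
    )
    angles = geo.pixel_angles(shape, center, ref)
    radii = geo.pixel_radii(shape, center)

    rng = np.random.default_rng(config.seed)
    maps: list[T1Map] = []
    scar_masks: list[np.ndarray] = []
    masses = np.zeros(config.n_slices)
    labels_per_slice: list[np.ndarray] = []
    offset = 0
    for s, level in enumerate(config.slice_levels):
        t1 = np.full(shape, config.t1_background)
        t1[epi_fill] = config.t1_myocardium
        t1[endo_fill] = config.t1_blood

        scar = np.zeros(shape, dtype=bool)
        for spec in config.scar_specs:
            if spec.slice_index != s:
                continue
            start = np.deg2rad(spec.start_deg)
            span = np.deg2rad(spec.span_deg)
            r_out = config.endo_radius_px + spec.transmurality * (
                config.epi_radius_px - config.endo_radius_px
            )
            in_span = np.mod(angles - start, geo.TWO_PI) < span
            scar |= annulus & in_span & (radii <= r_out)
        t1[scar] = config.t1_scar

        if config.noise_sd > 0:
            t1 = t1 + rng.normal(0.0, config.noise_sd, shape)
            t1 = np.clip(t1, 1.0, None)

        n_seg = SEGMENTS_PER_LEVEL[level]
        width = geo.TWO_PI / n_seg
        seg = np.zeros(shape, dtype=int)
        seg[annulus] = np.minimum((angles[annulus] // width).astype(int), n_seg - 1) + 1
        labels = np.where(seg > 0, seg + offset, 0)
        offset += n_seg

        maps.append(
            T1Map(
                t1,
                pixel_spacing=config.pixel_spacing,
                slice_thickness=config.slice_thickness,
                slice_level=level,
            )
        )
        scar_masks.append(scar)
        labels_per_slice.append(labels)
        masses[s] = pixels_to_grams(
            int(scar.sum()), config.pixel_spacing, config.slice_thickness, config.density
        )

    truth = GroundTruth(
        scar_masks=scar_masks,
        scar_mass_g=masses,
        subsegment_labels=labels_per_slice,
        myocardium_masks=[annulus.copy() for _ in range(config.n_slices)],
        endo_contour=geo.circle_polygon(center, config.endo_radius_px),
        epi_contour=geo.circle_polygon(center, config.epi_radius_px),
        reference_point=ref,
        slice_levels=config.slice_levels,
    )
    return maps, truth


def simulate_molli(
    t1_map: T1Map,
    scheme: SamplingScheme | None = None,
    noise_sd: float = 0.0,
    seed: int | None = None,
    inversion_efficiency: float = 1.0,
    equilibrium: float = 1.0,
) -> MOLLISeries:
    """Simulate a MOLLI magnitude-image stack from a T1 map.

    Per pixel the signed recovery S(t) = A - B exp(-t/T1*) is sampled at the
    scheme's effective inversion times with A = ``equilibrium``,
    B = A (1 + ``inversion_efficiency``) and T1* chosen so the Look-Locker
    correction returns the map's T1 exactly: T1* = T1 / (B/A - 1). Zero-mean
    Gaussian noise is added to the signed signal before taking the
    magnitude (a Rician-like noise model).
    """
    if scheme is None:
        scheme = SamplingScheme()
    if not 0 < inversion_efficiency <= 1.0:
        raise ValueError("inversion_efficiency must be in (0, 1]")
    t1 = t1_map.values
    bad = np.argwhere(~(t1 > 0))
    if bad.size:
        r, c = bad[0]
        raise ValueError(f"non-positive T1 at pixel (row={r}, col={c})")

    tis = effective_tis(scheme)
    a = equilibrium
    b = a * (1.0 + inversion_efficiency)
    t1_star = t1 / inversion_efficiency  # T1 = T1* (B/A - 1)
    signal = a - b * np.exp(-tis[:, None, None] / t1_star[None, :, :])
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        signal = signal + rng.normal(0.0, noise_sd, signal.shape)
    return MOLLISeries(
        np.abs(signal),
        tis,
        pixel_spacing=t1_map.pixel_spacing,
        slice_thickness=t1_map.slice_thickness,
        slice_level=t1_map.slice_level,
    )


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CohortSpec:
    """Structure of a synthetic patient cohort.

    Defaults mirror a 214-patient cohort with 23 scar-positive patients.
    Positive patients carry 1-3 scar wedges (span 45-120 degrees,
    transmurality 0.4-0.9). The two quantification channels (early synthetic
    vs conventional late enhancement) are the ground-truth masses perturbed
    by independent zero-mean reader jitter of ``reader_jitter_sd`` grams.

    ``n_false_negative_patients`` / ``n_false_positive_patients`` optionally
    inject index-channel discordance: an FN patient carries one small
    single-subsegment wedge that the index channel misses entirely; an FP
    patient is scar-free but the index channel calls
    ``fp_subsegments`` subsegments positive.
    """

    n_patients: int = 214
    n_positive: int = 23
    phantom: PhantomConfig = field(default_factory=PhantomConfig)
    wedges_per_positive: tuple[int, int] = (1, 3)
    span_deg_range: tuple[float, float] = (45.0, 120.0)
    transmurality_range: tuple[float, float] = (0.4, 0.9)
    reader_jitter_sd: float = 0.1  # grams
    n_false_negative_patients: int = 0
    n_false_positive_patients: int = 0
    fp_subsegments: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_positive > self.n_patients:
            raise PhantomConfigError("n_positive cannot exceed n_patients")
        if self.n_false_negative_patients > self.n_positive:
            raise PhantomConfigError("more FN patients than positives")
        if self.n_false_positive_patients > self.n_patients - self.n_positive:
            raise PhantomConfigError("more FP patients than negatives")
        if self.reader_jitter_sd < 0:
            raise PhantomConfigError("reader_jitter_sd must be >= 0")


@dataclass
class PatientRecord:
    patient_id: int
    config: PhantomConfig
    is_positive: bool
    gt_mass_g: float
    calls_index: np.ndarray  # ESGE channel, per subsegment
    calls_reference: np.ndarray  # conventional LGE channel (ground truth)
    mass_index_g: float
    mass_reference_g: float


@dataclass
class CohortDataset:
    spec: CohortSpec
    patients: list[PatientRecord]

    @property
    def n_subsegments_per_patient(self) -> int:
        return sum(SEGMENTS_PER_LEVEL[lev] for lev in self.spec.phantom.slice_levels)

    def calls_matrix(self, channel: str) -> np.ndarray:
        attr = "calls_index" if channel == "index" else "calls_reference"
        return np.array([getattr(p, attr) for p in self.patients])

    def masses(self, channel: str) -> np.ndarray:
        attr = "mass_index_g" if channel == "index" else "mass_reference_g"
        return np.array([getattr(p, attr) for p in self.patients])

    def build_phantom(self, patient_id: int) -> tuple[list[T1Map], GroundTruth]:
        """Materialise the full image stack for one patient on demand."""
        return make_lv_phantom(self.patients[patient_id].config)


def _random_scar_specs(rng: np.random.Generator, spec: CohortSpec) -> tuple[ScarSpec, ...]:
    lo, hi = spec.wedges_per_positive
    n_wedges = int(rng.integers(lo, hi + 1))
    out = []
    for _ in range(n_wedges):
        out.append(
            ScarSpec(
                slice_index=int(rng.integers(0, spec.phantom.n_slices)),
                start_deg=float(rng.uniform(0.0, 360.0)),
                span_deg=float(rng.uniform(*spec.span_deg_range)),
                transmurality=float(rng.uniform(*spec.transmurality_range)),
            )
        )
    return tuple(out)


def _single_subsegment_spec(rng: np.random.Generator, spec: CohortSpec) -> ScarSpec:
    """A small wedge confined strictly inside one basal/mid 60-degree sector."""
    slice_index = 0  # basal by construction of the standard level set
    sector = int(rng.integers(0, 6))
    return ScarSpec(
        slice_index=slice_index,
        start_deg=sector * 60.0 + 15.0,
        span_deg=30.0,
        transmurality=0.5,
    )


def make_cohort(spec: CohortSpec) -> CohortDataset:
    """Generate a whole cohort with paired quantification channels.

    Deterministic for fixed ``spec.seed``; all per-patient randomness is
    split from a single root SeedSequence.
    """
    root = np.random.SeedSequence(spec.seed)
    structure_rng = np.random.default_rng(root.spawn(1)[0])
    patient_seeds = root.spawn(spec.n_patients)

    n_sub = sum(SEGMENTS_PER_LEVEL[lev] for lev in spec.phantom.slice_levels)
    patients: list[PatientRecord] = []
    # deterministic layout: positives first, FN patients among positives,
    # FP patients among negatives
    for pid in range(spec.n_patients):
        rng = np.random.default_rng(patient_seeds[pid])
        is_positive = pid < spec.n_positive
        is_fn = pid < spec.n_false_negative_patients
        is_fp = (
            not is_positive
            and pid - spec.n_positive < spec.n_false_positive_patients
        )

        if is_positive:
            scar_specs = (
                (_single_subsegment_spec(rng, spec),)
                if is_fn
                else _random_scar_specs(rng, spec)
            )
        else:
            scar_specs = ()
        cfg = replace(spec.phantom, scar_specs=scar_specs, seed=int(rng.integers(2**31)))
        _, truth = make_lv_phantom(cfg)

        calls_ref = truth.subsegment_calls()
        if is_fn:
            calls_idx = np.zeros(n_sub, dtype=bool)
        elif is_fp:
            calls_idx = np.zeros(n_sub, dtype=bool)
            calls_idx[: spec.fp_subsegments] = True
        else:
            calls_idx = calls_ref.copy()

        gt_mass = truth.total_scar_mass_g
        jitter = rng.normal(0.0, spec.reader_jitter_sd, 2) if spec.reader_jitter_sd else (0.0, 0.0)
        patients.append(
            PatientRecord(
                patient_id=pid,
                config=cfg,
                is_positive=is_positive,
                gt_mass_g=gt_mass,
                calls_index=calls_idx,
                calls_reference=calls_ref,
                mass_index_g=gt_mass + float(jitter[0]),
                mass_reference_g=gt_mass + float(jitter[1]),
            )
        )
    return CohortDataset(spec=spec, patients=patients)
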