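"""Synthetic PET phantoms and cohorts with known ground truth.

Real PSMA PET scans of the kind this pipeline targets are not publicly
deposited, so the package ships a generator that emulates the features the
pipeline actually consumes: a 3D SUV grid with background noise, a liver
region and a descending-aorta region whose statistics drive the
segmentation threshold, spherical lesions with a smooth intensity taper,
follow-up volumes derived from baseline by per-lesion response factors
(including vanished and newly appearing lesions), and PSA changes
rank-coupled to the true tumor-volume change.

Lesion intensity profile
------------------------
Each lesion is a sphere of radius R whose SUV falls off as a truncated
paraboloid from the configured peak at the center to the background mean at
the boundary::

    SUV(r) = bg_mean + (peak - bg_mean) * (1 - (r/R)^2),   r <= R

so SUVmax is well defined and the suprathreshold fraction of the analytic
sphere volume at threshold T is ``(1 - (T - bg_mean)/(peak - bg_mean))^(3/2)``
— threshold choice controls recovered volume predictably (see
:func:`analytic_suprathreshold_volume_ml`).

PSA coupling
------------
Only the *rank* structure of the PSA/tumor-volume relationship is asserted
by the downstream analysis, so the generator couples them through a
Gaussian copula: the normal scores of the true delta-TV are mixed with
independent noise using a latent Pearson coefficient ``rho_p = 2 sin(pi *
rho_s / 6)`` (the bivariate-normal Spearman relation), and delta-PSA is a
fixed monotone transform of the latent score. With target coupling 1 and
zero noise the ranks coincide exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import ndtri
from scipy.stats import rankdata

from .exceptions import CouplingError, PhantomConfigError
from .io import PETVolume
from .keyhole import relative_change
from .segmentation import (
    AORTA_CYLINDER_DIAMETER_MM,
    AORTA_CYLINDER_ZLENGTH_MM,
    LIVER_SPHERE_DIAMETER_MM,
    ReferenceROISpec,
)

__all__ = [
    "LesionSpec",
    "PhantomConfig",
    "ResponseScenario",
    "GroundTruth",
    "CohortConfig",
    "PatientCase",
    "CohortSpec",
    "generate_phantom",
    "apply_response",
    "followup_config",
    "generate_cohort",
    "sphere_volume_ml",
    "analytic_suprathreshold_volume_ml",
    "make_structural_mirror_cohort",
    "make_adversarial_new_lesion_patient",
]

logger = logging.getLogger(__name__)

_SEED_MODULUS = 2**31 - 1


@dataclass(frozen=True)
class LesionSpec:
    """A spherical lesion: center (world mm), radius (mm), peak SUV."""

    center_mm: tuple[float, float, float]
    radius_mm: float
    peak_suv: float


@dataclass(frozen=True)
class PhantomConfig:
    """Geometry and intensity parameters of one synthetic scan.

    The default grid is a scaled-down torso: 40^3 voxels at 4 mm isotropic
    spacing (160 mm field of view) with a liver sphere and a z-aligned
    descending-aorta cylinder placed clear of each other. The default liver
    mean/SD (5.0/0.5) put the liver threshold (1.5*5 + 2*0.5 = 8.5 SUV)
    between the background (1.0) and typical lesion peaks (15-40), so the
    default configuration segments lesions and only lesions. Liver/aorta
    regions may be set to None for pure-lesion phantoms.
    """

    grid_shape: tuple[int, int, int] = (40, 40, 40)
    voxel_spacing_mm: tuple[float, float, float] = (4.0, 4.0, 4.0)
    background_suv_mean: float = 1.0
    background_suv_sd: float = 0.25
    liver_center_mm: tuple[float, float, float] | None = (48.0, 48.0, 112.0)
    liver_radius_mm: float = 18.0
    aorta_center_mm: tuple[float, float, float] | None = (112.0, 112.0, 80.0)
    aorta_radius_mm: float = 7.0
    aorta_zlength_mm: float = 60.0
    liver_suv_mean: float = 5.0
    liver_suv_sd: float = 0.5
    aorta_suv_mean: float = 1.8
    aorta_suv_sd: float = 0.3
    lesions: tuple[LesionSpec, ...] = ()
    seed: int = 0

    @property
    def extent_mm(self) -> np.ndarray:
        """World coordinate of the last voxel center along each axis."""
        return (np.asarray(self.grid_shape) - 1) * np.asarray(self.voxel_spacing_mm)

    def reference_rois(self) -> dict[str, ReferenceROISpec]:
        rois: dict[str, ReferenceROISpec] = {}
        if self.liver_center_mm is not None:
            rois["liver"] = ReferenceROISpec("liver_sphere", self.liver_center_mm)
        if self.aorta_center_mm is not None:
            rois["aorta"] = ReferenceROISpec("aorta_cylinder", self.aorta_center_mm)
        return rois


@dataclass(frozen=True)
class ResponseScenario:
    """Therapy effect between baseline and follow-up for one patient.

    ``volume_scales[i]`` multiplies the *volume* of baseline lesion i
    (radius scales by its cube root); 0 means the lesion vanished.
    ``intensity_scales[i]`` multiplies its peak SUV (default 1 for all).
    ``new_lesions`` appear only at follow-up.
    """

    volume_scales: tuple[float, ...]
    intensity_scales: tuple[float, ...] | None = None
    new_lesions: tuple[LesionSpec, ...] = ()
    psa_baseline: float | None = None

    def __post_init__(self) -> None:
        if any(s < 0 for s in self.volume_scales):
            raise ValueError("volume scale factors must be >= 0")
        if self.intensity_scales is not None:
            if len(self.intensity_scales) != len(self.volume_scales):
                raise ValueError("intensity_scales length must match volume_scales")
            if any(s < 0 for s in self.intensity_scales):
                raise ValueError("intensity scale factors must be >= 0")
        if self.psa_baseline is not None and self.psa_baseline <= 0:
            raise ValueError("psa_baseline must be positive")


@dataclass(frozen=True)
class GroundTruth:
    """Per-lesion analytic truth at both timepoints plus the true changes.

    Volumes are analytic sphere volumes (4/3 pi R^3, mL); the true relative
    tumor-volume change is computed with the same relative-change formula
    as the pipeline. ``true_delta_psa_pct`` is filled by the cohort
    generator (None for single-phantom use).
    """

    lesion_ids: tuple[int, ...]
    volumes_baseline_ml: tuple[float, ...]
    volumes_followup_ml: tuple[float, ...]
    peaks_baseline: tuple[float, ...]
    peaks_followup: tuple[float, ...]
    true_delta_tv_pct: float
    true_delta_psa_pct: float | None = None


def sphere_volume_ml(radius_mm: float) -> float:
    """Analytic sphere volume in mL (radius in mm)."""
    return 4.0 / 3.0 * np.pi * radius_mm**3 / 1000.0


def analytic_suprathreshold_volume_ml(
    radius_mm: float, peak_suv: float, background_mean: float, threshold: float
) -> float:
    """Volume of the paraboloid lesion profile strictly above ``threshold``.

    The infinite-resolution limit of the voxelized recovered volume; equals
    the full sphere volume for thresholds at or below the background mean.
    """
    if threshold >= peak_suv:
        return 0.0
    frac = 1.0 - max(0.0, threshold - background_mean) / (peak_suv - background_mean)
    return sphere_volume_ml(radius_mm) * frac**1.5


def _sphere_inside_grid(center, radius, extent) -> bool:
    c = np.asarray(center, dtype=float)
    return bool(np.all(c - radius >= 0.0) and np.all(c + radius <= extent))


def _lesion_roi_overlap(les: LesionSpec, config: PhantomConfig) -> str | None:
    """Return the name of a reference ROI the lesion sphere intersects, if any."""
    c = np.asarray(les.center_mm, dtype=float)
    if config.liver_center_mm is not None:
        liver_c = np.asarray(config.liver_center_mm, dtype=float)
        if np.linalg.norm(c - liver_c) < les.radius_mm + LIVER_SPHERE_DIAMETER_MM / 2:
            return "liver"
    if config.aorta_center_mm is not None:
        aorta_c = np.asarray(config.aorta_center_mm, dtype=float)
        r_xy = np.linalg.norm(c[:2] - aorta_c[:2])
        dz = abs(c[2] - aorta_c[2])
        if (
            r_xy < les.radius_mm + AORTA_CYLINDER_DIAMETER_MM / 2
            and dz < les.radius_mm + AORTA_CYLINDER_ZLENGTH_MM / 2
        ):
            return "aorta"
    return None


def _validate_config(config: PhantomConfig) -> None:
    extent = config.extent_mm
    if config.background_suv_mean <= 0 or config.background_suv_sd < 0:
        raise PhantomConfigError("background mean must be > 0 and sd >= 0")
    if config.liver_center_mm is not None:
        if config.liver_radius_mm <= 0:
            raise PhantomConfigError("liver radius must be positive")
        if not _sphere_inside_grid(config.liver_center_mm, config.liver_radius_mm, extent):
            raise PhantomConfigError("liver region extends outside the grid")
    if config.aorta_center_mm is not None:
        if config.aorta_radius_mm <= 0 or config.aorta_zlength_mm <= 0:
            raise PhantomConfigError("aorta radius and z-length must be positive")
        c = np.asarray(config.aorta_center_mm, dtype=float)
        lo = c - np.array([config.aorta_radius_mm, config.aorta_radius_mm,
                           config.aorta_zlength_mm / 2])
        hi = c + np.array([config.aorta_radius_mm, config.aorta_radius_mm,
                           config.aorta_zlength_mm / 2])
        if np.any(lo < 0) or np.any(hi > extent):
            raise PhantomConfigError("aorta region extends outside the grid")
    for i, les in enumerate(config.lesions):
        if les.radius_mm <= 0:
            raise PhantomConfigError(f"lesion {i}: radius must be positive")
        if les.peak_suv <= config.background_suv_mean:
            raise PhantomConfigError(
                f"lesion {i}: peak SUV {les.peak_suv} must exceed background mean "
                f"{config.background_suv_mean}"
            )
        if not _sphere_inside_grid(les.center_mm, les.radius_mm, extent):
            raise PhantomConfigError(f"lesion {i} at {les.center_mm} extends outside the grid")
        roi = _lesion_roi_overlap(les, config)
        if roi is not None:
            raise PhantomConfigError(f"lesion {i} overlaps the {roi} reference ROI")


def _axis_coords(config: PhantomConfig):
    return [
        np.arange(config.grid_shape[ax]) * config.voxel_spacing_mm[ax] for ax in range(3)
    ]


def generate_phantom(
    config: PhantomConfig,
) -> tuple[PETVolume, dict[str, ReferenceROISpec], GroundTruth]:
    """Rasterize a phantom configuration into an SUV volume.

    Returns the volume, the reference-ROI placements, and a ground-truth
    fragment with each lesion's analytic volume and configured peak SUV
    (follow-up fields mirror baseline; :func:`apply_response` produces the
    two-timepoint truth).

    Background voxels are drawn from N(mean, sd) clipped at 0 (SUV is
    non-negative); liver and aorta voxels from their own clipped normals;
    lesion voxels take the deterministic paraboloid profile, combined with
    the underlying draw by voxelwise maximum. Geometry is therefore
    seed-independent: two seeds differ only in noise draws, and the same
    seed reproduces the volume bit for bit.
    """
    _validate_config(config)
    rng = np.random.default_rng(config.seed)
    shape = tuple(config.grid_shape)
    values = rng.normal(config.background_suv_mean, config.background_suv_sd, size=shape)
    np.clip(values, 0.0, None, out=values)

    coords = _axis_coords(config)

    def region_mask_sphere(center, radius):
        dx = coords[0][:, None, None] - center[0]
        dy = coords[1][None, :, None] - center[1]
        dz = coords[2][None, None, :] - center[2]
        return dx * dx + dy * dy + dz * dz <= radius * radius

    if config.liver_center_mm is not None:
        mask = region_mask_sphere(config.liver_center_mm, config.liver_radius_mm)
        draws = rng.normal(config.liver_suv_mean, config.liver_suv_sd, size=int(mask.sum()))
        values[mask] = np.clip(draws, 0.0, None)
    if config.aorta_center_mm is not None:
        c = config.aorta_center_mm
        dx = coords[0][:, None, None] - c[0]
        dy = coords[1][None, :, None] - c[1]
        dz = coords[2][None, None, :] - c[2]
        mask = (dx * dx + dy * dy <= config.aorta_radius_mm**2) & (
            np.abs(dz) <= config.aorta_zlength_mm / 2
        )
        draws = rng.normal(config.aorta_suv_mean, config.aorta_suv_sd, size=int(mask.sum()))
        values[mask] = np.clip(draws, 0.0, None)

    bg = config.background_suv_mean
    spacing = np.asarray(config.voxel_spacing_mm)
    for les in config.lesions:
        center = np.asarray(les.center_mm, dtype=float)
        lo_idx = np.maximum(0, np.floor((center - les.radius_mm) / spacing)).astype(int)
        hi_idx = np.minimum(
            np.asarray(shape) - 1, np.ceil((center + les.radius_mm) / spacing)
        ).astype(int)
        sub = tuple(slice(lo_idx[a], hi_idx[a] + 1) for a in range(3))
        dx = coords[0][sub[0]][:, None, None] - center[0]
        dy = coords[1][sub[1]][None, :, None] - center[1]
        dz = coords[2][sub[2]][None, None, :] - center[2]
        r2 = (dx * dx + dy * dy + dz * dz) / (les.radius_mm**2)
        profile = bg + (les.peak_suv - bg) * np.clip(1.0 - r2, 0.0, None)
        block = values[sub]
        np.maximum(block, profile, out=block)

    volume = PETVolume(values=values, spacing=tuple(config.voxel_spacing_mm))
    truth = GroundTruth(
        lesion_ids=tuple(range(len(config.lesions))),
        volumes_baseline_ml=tuple(sphere_volume_ml(l.radius_mm) for l in config.lesions),
        volumes_followup_ml=tuple(sphere_volume_ml(l.radius_mm) for l in config.lesions),
        peaks_baseline=tuple(l.peak_suv for l in config.lesions),
        peaks_followup=tuple(l.peak_suv for l in config.lesions),
        true_delta_tv_pct=0.0,
    )
    return volume, config.reference_rois(), truth


def followup_config(config: PhantomConfig, scenario: ResponseScenario) -> PhantomConfig:
    """The phantom configuration of the follow-up scan under a scenario.

    Radii scale by the cube root of the volume scale factor, peaks by the
    intensity scale; vanished lesions (scale 0) are removed and new lesions
    appended. The noise seed is re-derived so the two scans have independent
    noise but reproducible geometry.
    """
    if len(scenario.volume_scales) != len(config.lesions):
        raise ValueError(
            f"scenario has {len(scenario.volume_scales)} scale factors for "
            f"{len(config.lesions)} baseline lesions"
        )
    intensity = scenario.intensity_scales or tuple([1.0] * len(config.lesions))
    new_lesions = []
    for les, vs, js in zip(config.lesions, scenario.volume_scales, intensity):
        if vs == 0.0:
            continue
        new_lesions.append(
            LesionSpec(
                center_mm=les.center_mm,
                radius_mm=les.radius_mm * vs ** (1.0 / 3.0),
                peak_suv=les.peak_suv * js,
            )
        )
    new_lesions.extend(scenario.new_lesions)
    fu_seed = (config.seed * 48271 + 1) % _SEED_MODULUS
    return replace(config, lesions=tuple(new_lesions), seed=fu_seed)


def apply_response(
    config: PhantomConfig, scenario: ResponseScenario
) -> tuple[PETVolume, GroundTruth]:
    """Derive the follow-up volume and two-timepoint ground truth.

    The true relative tumor-volume change is computed by the pipeline's own
    relative-change formula applied to the summed analytic volumes.
    """
    fu_config = followup_config(config, scenario)
    volume, _, _ = generate_phantom(fu_config)

    intensity = scenario.intensity_scales or tuple([1.0] * len(config.lesions))
    n_base = len(config.lesions)
    n_new = len(scenario.new_lesions)
    vols_b = [sphere_volume_ml(l.radius_mm) for l in config.lesions] + [0.0] * n_new
    vols_f = [
        sphere_volume_ml(l.radius_mm) * vs
        for l, vs in zip(config.lesions, scenario.volume_scales)
    ] + [sphere_volume_ml(l.radius_mm) for l in scenario.new_lesions]
    peaks_b = [l.peak_suv for l in config.lesions] + [0.0] * n_new
    peaks_f = [
        l.peak_suv * js for l, js in zip(config.lesions, intensity)
    ] + [l.peak_suv for l in scenario.new_lesions]
    true_dtv = relative_change(sum(vols_b), sum(vols_f))
    truth = GroundTruth(
        lesion_ids=tuple(range(n_base + n_new)),
        volumes_baseline_ml=tuple(vols_b),
        volumes_followup_ml=tuple(vols_f),
        peaks_baseline=tuple(peaks_b),
        peaks_followup=tuple(peaks_f),
        true_delta_tv_pct=true_dtv,
    )
    return volume, truth


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CohortConfig:
    """Distributional settings of the cohort generator.

    Defaults describe a scaled-down metastatic-prostate-cancer cohort:
    1-15 lesions per patient (so the <5-lesion case occurs regularly),
    lesion radii 4-10 mm, peaks 15-40 SUV (all above the default liver
    threshold of 8.5), a log-normal patient response factor with median
    ~0.74 (mix of responders, stable patients and progressors), mild
    per-lesion heterogeneity, occasional vanished lesions and, for
    progressing patients, a Poisson number of new follow-up lesions.
    """

    phantom: PhantomConfig = field(default_factory=PhantomConfig)
    lesion_count_range: tuple[int, int] = (1, 15)
    lesion_radius_range_mm: tuple[float, float] = (4.0, 10.0)
    lesion_peak_range: tuple[float, float] = (15.0, 40.0)
    response_log_mean: float = -0.3
    response_log_sd: float = 0.6
    lesion_scale_jitter_sd: float = 0.15  # log-scale per-lesion jitter
    intensity_jitter_sd: float = 0.05     # log-scale jitter of peak SUV
    vanish_scale: float = 0.05            # scales below this become 0 (vanished)
    new_lesion_rate: float = 1.0          # Poisson mean when patient progresses
    progression_threshold: float = 1.1    # patient factor above which new lesions may appear
    psa_log_median: float = np.log(60.0)  # baseline PSA ~ lognormal, ng/mL
    psa_log_sd: float = 1.0
    placement_margin_mm: float = 2.0
    max_placement_tries: int = 500
    #: volume scale factors are clipped here so grown follow-up lesions
    #: (radius x scale^(1/3)) stay inside the headroom reserved at placement
    max_volume_scale: float = 3.375  # radius growth capped at 1.5x

    @property
    def radius_headroom(self) -> float:
        return self.max_volume_scale ** (1.0 / 3.0)


@dataclass(frozen=True)
class PatientCase:
    patient_id: str
    baseline_config: PhantomConfig
    scenario: ResponseScenario
    truth: GroundTruth


@dataclass(frozen=True)
class CohortSpec:
    """A generated cohort: per-patient cases plus the PSA table.

    ``psa_table`` has columns patient_id, psa_baseline, psa_followup.
    """

    patients: tuple[PatientCase, ...]
    psa_table: pd.DataFrame
    target_rank_coupling: float
    seed: int

    def truth_table(self) -> pd.DataFrame:
        rows = [
            {
                "patient_id": p.patient_id,
                "n_lesions_baseline": sum(v > 0 for v in p.truth.volumes_baseline_ml),
                "n_lesions_followup": sum(v > 0 for v in p.truth.volumes_followup_ml),
                "true_tv_baseline_ml": sum(p.truth.volumes_baseline_ml),
                "true_tv_followup_ml": sum(p.truth.volumes_followup_ml),
                "true_delta_tv_pct": p.truth.true_delta_tv_pct,
                "true_delta_psa_pct": p.truth.true_delta_psa_pct,
            }
            for p in self.patients
        ]
        return pd.DataFrame(rows)


def _place_lesions(
    rng: np.random.Generator, config: CohortConfig, n_lesions: int
) -> tuple[LesionSpec, ...]:
    """Rejection-sample non-overlapping lesion spheres clear of the ROIs."""
    phantom = config.phantom
    extent = phantom.extent_mm
    margin = config.placement_margin_mm
    grow = config.radius_headroom
    placed: list[LesionSpec] = []
    for _ in range(n_lesions):
        r_lo, r_hi = config.lesion_radius_range_mm
        radius = float(rng.uniform(r_lo, r_hi))
        peak = float(rng.uniform(*config.lesion_peak_range))
        for attempt in range(config.max_placement_tries):
            r_eff = radius * grow  # headroom for follow-up growth
            center = tuple(
                float(rng.uniform(r_eff + margin, extent[a] - r_eff - margin))
                for a in range(3)
            )
            cand = LesionSpec(center_mm=center, radius_mm=radius, peak_suv=peak)
            if _lesion_roi_overlap(
                LesionSpec(center, r_eff, peak), phantom
            ) is not None:
                continue
            c = np.asarray(center)
            clash = any(
                np.linalg.norm(c - np.asarray(p.center_mm))
                < (radius + p.radius_mm) * grow + margin
                for p in placed
            )
            if not clash:
                placed.append(cand)
                break
            if attempt and attempt % 100 == 0:
                radius = max(r_lo, radius * 0.8)  # shrink to find room
        else:
            raise PhantomConfigError(
                f"could not place {n_lesions} non-overlapping lesions "
                f"in a {tuple(extent)} mm grid"
            )
    return tuple(placed)


def _place_new_lesions(
    rng: np.random.Generator,
    config: CohortConfig,
    existing: Sequence[LesionSpec],
    n_new: int,
    radius_range: tuple[float, float] | None = None,
) -> tuple[LesionSpec, ...]:
    phantom = config.phantom
    extent = phantom.extent_mm
    margin = config.placement_margin_mm
    r_range = radius_range or config.lesion_radius_range_mm
    grow = config.radius_headroom
    placed = list(existing)
    out = []
    for _ in range(n_new):
        radius = float(rng.uniform(*r_range))
        peak = float(rng.uniform(*config.lesion_peak_range))
        for _try in range(config.max_placement_tries):
            center = tuple(
                float(rng.uniform(radius + margin, extent[a] - radius - margin))
                for a in range(3)
            )
            cand = LesionSpec(center, radius, peak)
            if _lesion_roi_overlap(cand, phantom) is not None:
                continue
            c = np.asarray(center)
            if all(
                np.linalg.norm(c - np.asarray(p.center_mm))
                >= radius + p.radius_mm * grow + margin
                for p in placed
            ):
                placed.append(cand)
                out.append(cand)
                break
        else:
            break  # grid full; fewer new lesions than requested
    return tuple(out)


def rank_coupled_delta_psa(
    true_delta_tv: np.ndarray,
    target_rank_coupling: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Generate delta-PSA (%) rank-coupled to the true delta-TV.

    Gaussian-copula construction: normal scores of delta-TV are mixed with
    independent N(0,1) noise at latent Pearson ``rho_p = 2 sin(pi*rho_s/6)``,
    then pushed through a fixed monotone transform to a plausible percent
    scale (always > -100). The expected sample Spearman correlation equals
    the target up to O(1/n) finite-sample bias.
    """
    if not -1.0 <= target_rank_coupling <= 1.0:
        raise CouplingError(
            f"target rank coupling must be in [-1, 1], got {target_rank_coupling}"
        )
    x = np.asarray(true_delta_tv, dtype=float)
    n = x.size
    rho_p = 2.0 * np.sin(np.pi * target_rank_coupling / 6.0)
    u = (rankdata(x, method="average") - 0.5) / n
    z_tv = ndtri(u)
    noise_coef = np.sqrt(max(0.0, 1.0 - rho_p**2))
    z = rho_p * z_tv + noise_coef * rng.standard_normal(n)
    # monotone map latent score -> percent change; median ~ -22%, range (-100, inf)
    return 100.0 * (np.exp(0.9 * z - 0.25) - 1.0)


def generate_cohort(
    n_patients: int,
    seed: int,
    target_rank_coupling: float = 0.6,
    config: CohortConfig | None = None,
) -> CohortSpec:
    """Generate a full synthetic cohort with known ground truth.

    Per patient: a lesion count drawn uniformly from the configured range
    (so patients with fewer than 5 lesions occur), placed non-overlapping
    and clear of the reference ROIs; a log-normal patient response factor
    with per-lesion jitter; vanished lesions for near-zero scales; new
    follow-up lesions for progressing patients; and a PSA pair whose
    relative change is rank-coupled to the true tumor-volume change at the
    requested Spearman coupling.
    """
    if n_patients < 2:
        raise ValueError(f"n_patients must be >= 2, got {n_patients}")
    if config is None:
        config = CohortConfig()
    if not -1.0 <= target_rank_coupling <= 1.0:
        raise CouplingError(
            f"target rank coupling must be in [-1, 1], got {target_rank_coupling}"
        )
    rng = np.random.default_rng(seed)
    cases = []
    for i in range(n_patients):
        pid = f"P{i+1:03d}"
        n_lesions = int(rng.integers(config.lesion_count_range[0],
                                     config.lesion_count_range[1] + 1))
        lesions = _place_lesions(rng, config, n_lesions)
        phantom_seed = int(rng.integers(0, _SEED_MODULUS))
        baseline = replace(config.phantom, lesions=lesions, seed=phantom_seed)

        s_patient = float(np.exp(rng.normal(config.response_log_mean,
                                            config.response_log_sd)))
        scales = s_patient * np.exp(
            rng.normal(0.0, config.lesion_scale_jitter_sd, size=n_lesions)
        )
        scales = np.minimum(scales, config.max_volume_scale)
        scales[scales < config.vanish_scale] = 0.0
        intensity = np.exp(rng.normal(0.0, config.intensity_jitter_sd, size=n_lesions))

        new_specs: tuple[LesionSpec, ...] = ()
        if s_patient > config.progression_threshold and config.new_lesion_rate > 0:
            n_new = int(rng.poisson(config.new_lesion_rate))
            if n_new:
                new_specs = _place_new_lesions(rng, config, lesions, n_new)

        scenario = ResponseScenario(
            volume_scales=tuple(float(s) for s in scales),
            intensity_scales=tuple(float(j) for j in intensity),
            new_lesions=new_specs,
        )
        _, truth = apply_response(baseline, scenario)
        cases.append(PatientCase(pid, baseline, scenario, truth))

    dtv = np.array([c.truth.true_delta_tv_pct for c in cases])
    dpsa = rank_coupled_delta_psa(dtv, target_rank_coupling, rng)
    psa_baseline = np.exp(rng.normal(config.psa_log_median, config.psa_log_sd,
                                     size=n_patients))
    psa_followup = psa_baseline * (1.0 + dpsa / 100.0)
    cases = [
        replace(
            c,
            truth=replace(c.truth, true_delta_psa_pct=float(d)),
            scenario=replace(c.scenario, psa_baseline=float(pb)),
        )
        for c, d, pb in zip(cases, dpsa, psa_baseline)
    ]
    psa_table = pd.DataFrame(
        {
            "patient_id": [c.patient_id for c in cases],
            "psa_baseline": psa_baseline,
            "psa_followup": psa_followup,
        }
    )
    logger.info(
        "generated cohort: n=%d, target coupling %.2f, lesion counts %s",
        n_patients, target_rank_coupling,
        [len(c.baseline_config.lesions) for c in cases],
    )
    return CohortSpec(
        patients=tuple(cases),
        psa_table=psa_table,
        target_rank_coupling=target_rank_coupling,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# constructed study cohorts
# ---------------------------------------------------------------------------

def make_structural_mirror_cohort(seed: int, n_patients: int = 16) -> CohortSpec:
    """A cohort in which the top-10 lesions dominate every patient's change.

    Every lesion of a patient scales by one common factor, no lesions appear
    or vanish, and the factors are chosen clear of the ±30% classification
    boundaries, so whole-body and reduced metrics must agree: the keyhole
    assessment is concordant for every patient by construction. Mirrors the
    mechanism behind a treatment-naive cohort with no relevant deviations.
    """
    config = CohortConfig(
        lesion_count_range=(1, 12),
        lesion_scale_jitter_sd=0.0,
        intensity_jitter_sd=0.0,
        new_lesion_rate=0.0,
    )
    rng = np.random.default_rng(seed)
    # global response factors spread over strong response .. clear progression,
    # avoiding the bands around s=0.7 (PR boundary) and s=1.3 (PD boundary)
    allowed = np.concatenate(
        [
            np.linspace(0.20, 0.60, 8),
            np.linspace(0.80, 1.15, 4),
            np.linspace(1.45, 2.2, 4),
        ]
    )
    factors = rng.choice(allowed, size=n_patients, replace=True)

    base = generate_cohort(n_patients, seed=int(rng.integers(0, _SEED_MODULUS)),
                           target_rank_coupling=0.6, config=config)
    cases = []
    for case, s in zip(base.patients, factors):
        n = len(case.baseline_config.lesions)
        scenario = ResponseScenario(
            volume_scales=tuple([float(s)] * n),
            intensity_scales=tuple([1.0] * n),
            new_lesions=(),
            psa_baseline=case.scenario.psa_baseline,
        )
        _, truth = apply_response(case.baseline_config, scenario)
        truth = replace(truth, true_delta_psa_pct=case.truth.true_delta_psa_pct)
        cases.append(replace(case, scenario=scenario, truth=truth))
    dtv = np.array([c.truth.true_delta_tv_pct for c in cases])
    rng2 = np.random.default_rng((seed + 7919) % _SEED_MODULUS)
    dpsa = rank_coupled_delta_psa(dtv, 0.6, rng2)
    psa_baseline = base.psa_table["psa_baseline"].to_numpy()
    psa_table = pd.DataFrame(
        {
            "patient_id": [c.patient_id for c in cases],
            "psa_baseline": psa_baseline,
            "psa_followup": psa_baseline * (1.0 + dpsa / 100.0),
        }
    )
    cases = [
        replace(c, truth=replace(c.truth, true_delta_psa_pct=float(d)))
        for c, d in zip(cases, dpsa)
    ]
    return CohortSpec(tuple(cases), psa_table, 0.6, seed)


def make_adversarial_new_lesion_patient(
    seed: int,
) -> tuple[PhantomConfig, ResponseScenario]:
    """A patient whose progression is carried entirely by many small new lesions.

    Baseline: five large lesions. Follow-up: the same five, unchanged, plus
    twelve new lesions, each smaller than any baseline lesion. The summed
    whole-body volume rises well past +30% (PD) while the five largest
    follow-up lesions are exactly the unchanged baseline lesions (SD) — the
    failure mode the keyhole reduction can exhibit.
    """
    config = CohortConfig(
        lesion_count_range=(5, 5),
        lesion_radius_range_mm=(8.0, 9.0),
    )
    rng = np.random.default_rng(seed)
    # one common peak SUV so the threshold cuts the same volume fraction from
    # every lesion and measured volumes compare like analytic ones
    big = tuple(
        replace(l, peak_suv=30.0) for l in _place_lesions(rng, config, 5)
    )
    baseline = replace(config.phantom, lesions=big, seed=int(rng.integers(0, _SEED_MODULUS)))
    new = tuple(
        replace(l, peak_suv=30.0)
        for l in _place_new_lesions(rng, config, big, 12, radius_range=(5.0, 6.0))
    )
    if len(new) < 11:
        raise PhantomConfigError("could not place enough new lesions for the scenario")
    scenario = ResponseScenario(
        volume_scales=tuple([1.0] * 5),
        intensity_scales=tuple([1.0] * 5),
        new_lesions=new,
        psa_baseline=50.0,
    )
    return baseline, scenario
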