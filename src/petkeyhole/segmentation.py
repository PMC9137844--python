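"""Reference-ROI statistics, segmentation thresholds and lesion extraction.

The segmentation follows the PERCIST/PROMISE convention used for PSMA PET:
a reference region — a 3 cm sphere in healthy liver, or a 1 cm diameter,
2 cm long cylinder in the descending thoracic aorta when the liver carries
metastases — provides a mean and standard deviation of physiologic uptake,
from which a whole-body SUV threshold is derived:

* liver mode:  ``threshold = 1.5 * mean + 2 * SD``
* aorta mode:  ``threshold = 2.0 * mean + 2 * SD``

Lesions are maximal 3D connected components of strictly suprathreshold
voxels (``SUV > threshold``), outside any exclusion mask. For each lesion
the maximum SUV (SUVmax) and the PSMA-positive tumor volume (voxel count ×
voxel volume, mL) are reported; whole-body sums over all lesions give
SUVmax_all and PSMA-TV_all.

Numerical conventions (see docs/methods.md): sample SD (ddof=1) by default;
26-connectivity by default (6/18/26 configurable); lesions ordered by
descending SUVmax with centroid-lexicographic tie-breaking, which defines
the deterministic ``lesion_id`` assignment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .exceptions import ROIError
from .io import LESION_TABLE_COLUMNS, PETVolume

__all__ = [
    "LIVER_SPHERE_DIAMETER_MM",
    "AORTA_CYLINDER_DIAMETER_MM",
    "AORTA_CYLINDER_ZLENGTH_MM",
    "MIN_ROI_VOXELS",
    "ReferenceROISpec",
    "SegmentationThreshold",
    "Lesion",
    "LesionSet",
    "reference_roi_stats",
    "compute_threshold",
    "segment_lesions",
    "roi_mask",
    "label_map",
]

logger = logging.getLogger(__name__)

# Reference-ROI geometry fixed by the PERCIST-style protocol.
LIVER_SPHERE_DIAMETER_MM = 30.0
AORTA_CYLINDER_DIAMETER_MM = 10.0
AORTA_CYLINDER_ZLENGTH_MM = 20.0

#: Below this voxel count the ROI mean/SD are considered unstable.
MIN_ROI_VOXELS = 10

_THRESHOLD_COEFFS = {"liver": (1.5, 2.0), "aorta": (2.0, 2.0)}
_CONNECTIVITY_RANK = {6: 1, 18: 2, 26: 3}


@dataclass(frozen=True)
class ReferenceROISpec:
    """Placement of a reference ROI in world coordinates (mm).

    ``kind`` selects the geometry: ``'liver_sphere'`` is a sphere of
    diameter 30 mm; ``'aorta_cylinder'`` a z-aligned cylinder of diameter
    10 mm extending 20 mm along the third axis.
    """

    kind: str
    center_mm: tuple[float, float, float]
    diameter_mm: float = field(default=None)  # type: ignore[assignment]
    z_extent_mm: float = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.kind not in ("liver_sphere", "aorta_cylinder"):
            raise ValueError(f"unknown ROI kind {self.kind!r}")
        if self.diameter_mm is None:
            d = (
                LIVER_SPHERE_DIAMETER_MM
                if self.kind == "liver_sphere"
                else AORTA_CYLINDER_DIAMETER_MM
            )
            object.__setattr__(self, "diameter_mm", d)
        if self.z_extent_mm is None and self.kind == "aorta_cylinder":
            object.__setattr__(self, "z_extent_mm", AORTA_CYLINDER_ZLENGTH_MM)
        if self.diameter_mm <= 0:
            raise ValueError("ROI diameter must be positive")
        object.__setattr__(self, "center_mm", tuple(float(c) for c in self.center_mm))


@dataclass(frozen=True)
class SegmentationThreshold:
    """An SUV segmentation threshold with its provenance.

    The value is tied to the reference statistics on construction:
    liver mode enforces ``value == 1.5*mean + 2*sd``, aorta mode
    ``value == 2*mean + 2*sd``.
    """

    value: float
    mode: str
    ref_mean: float
    ref_sd: float

    def __post_init__(self) -> None:
        if self.mode not in _THRESHOLD_COEFFS:
            raise ValueError(f"mode must be 'liver' or 'aorta', got {self.mode!r}")
        a, b = _THRESHOLD_COEFFS[self.mode]
        expected = a * self.ref_mean + b * self.ref_sd
        if not np.isclose(self.value, expected, rtol=1e-12, atol=1e-12):
            raise ValueError(
                f"threshold value {self.value} inconsistent with {self.mode} formula "
                f"({a}*{self.ref_mean} + {b}*{self.ref_sd} = {expected})"
            )


def compute_threshold(mean: float, sd: float, mode: str = "liver") -> SegmentationThreshold:
    """Segmentation threshold from reference-ROI statistics.

    Liver mode: ``1.5*mean + 2*sd``. Aorta mode (used in patients with known
    liver metastases): ``2*mean + 2*sd``.
    """
    if mean < 0 or sd < 0:
        raise ValueError(f"mean and sd must be non-negative, got ({mean}, {sd})")
    if mode not in _THRESHOLD_COEFFS:
        raise ValueError(f"mode must be 'liver' or 'aorta', got {mode!r}")
    a, b = _THRESHOLD_COEFFS[mode]
    value = a * float(mean) + b * float(sd)
    return SegmentationThreshold(value=value, mode=mode, ref_mean=float(mean), ref_sd=float(sd))


def roi_mask(volume: PETVolume, spec: ReferenceROISpec) -> np.ndarray:
    """Boolean mask of voxels whose centers lie inside the ROI.

    Raises :class:`ROIError` if the ROI's bounding box extends beyond the
    voxel-center lattice, or if fewer than ``MIN_ROI_VOXELS`` centers fall
    inside the ROI.
    """
    low, high = volume.world_extent()
    center = np.asarray(spec.center_mm, dtype=float)
    radius = spec.diameter_mm / 2.0
    if spec.kind == "liver_sphere":
        lo_req = center - radius
        hi_req = center + radius
    else:
        half_z = spec.z_extent_mm / 2.0
        lo_req = center - np.array([radius, radius, half_z])
        hi_req = center + np.array([radius, radius, half_z])
    if np.any(lo_req < low) or np.any(hi_req > high):
        raise ROIError(
            f"{spec.kind} ROI at {spec.center_mm} (extent {lo_req}..{hi_req}) "
            f"exceeds volume extent {low}..{high}"
        )
    coords = [
        volume.origin[ax] + np.arange(volume.shape[ax]) * volume.spacing[ax]
        for ax in range(3)
    ]
    dx = coords[0][:, None, None] - center[0]
    dy = coords[1][None, :, None] - center[1]
    dz = coords[2][None, None, :] - center[2]
    if spec.kind == "liver_sphere":
        mask = dx**2 + dy**2 + dz**2 <= radius**2
    else:
        half_z = spec.z_extent_mm / 2.0
        mask = (dx**2 + dy**2 <= radius**2) & (np.abs(dz) <= half_z)
    n = int(mask.sum())
    if n < MIN_ROI_VOXELS:
        raise ROIError(
            f"{spec.kind} ROI contains only {n} voxel(s); "
            f"at least {MIN_ROI_VOXELS} required for stable statistics"
        )
    return mask


def reference_roi_stats(
    volume: PETVolume, spec: ReferenceROISpec, *, ddof: int = 1
) -> tuple[float, float]:
    """Mean and SD of SUV over the reference ROI.

    Sample SD (``ddof=1``) is the default convention; pass ``ddof=0`` for the
    population SD.
    """
    vals = volume.values[roi_mask(volume, spec)]
    mean = float(vals.mean())
    sd = float(vals.std(ddof=ddof))
    logger.info(
        "reference ROI %s at %s: n=%d mean=%.4f sd=%.4f",
        spec.kind, spec.center_mm, vals.size, mean, sd,
    )
    return mean, sd


@dataclass(frozen=True)
class Lesion:
    """One connected suprathreshold component."""

    lesion_id: int
    suvmax: float
    volume_ml: float
    centroid_mm: tuple[float, float, float]
    n_voxels: int
    voxel_indices: np.ndarray | None = None  # (n, 3) int array, optional


@dataclass(frozen=True)
class LesionSet:
    """All lesions of one scan plus the threshold that produced them."""

    lesions: tuple[Lesion, ...]
    threshold: float

    @property
    def n_lesions(self) -> int:
        return len(self.lesions)

    @property
    def suvmax_all(self) -> float:
        """Whole-body SUVmax: sum of per-lesion SUVmax over all lesions."""
        return float(sum(les.suvmax for les in self.lesions))

    @property
    def tv_all_ml(self) -> float:
        """Whole-body PSMA-positive tumor volume (mL)."""
        return float(sum(les.volume_ml for les in self.lesions))

    @property
    def hottest_suvmax(self) -> float:
        """SUVmax of the hottest lesion (0 if no lesions)."""
        return max((les.suvmax for les in self.lesions), default=0.0)

    def to_table(self, patient_id: str, timepoint: str) -> pd.DataFrame:
        rows = [
            {
                "patient_id": patient_id,
                "timepoint": timepoint,
                "lesion_id": les.lesion_id,
                "suvmax": les.suvmax,
                "volume_ml": les.volume_ml,
                "centroid_x_mm": les.centroid_mm[0],
                "centroid_y_mm": les.centroid_mm[1],
                "centroid_z_mm": les.centroid_mm[2],
            }
            for les in self.lesions
        ]
        return pd.DataFrame(rows, columns=LESION_TABLE_COLUMNS)


def segment_lesions(
    volume: PETVolume,
    threshold: SegmentationThreshold | float,
    exclusion_mask: np.ndarray | None = None,
    *,
    connectivity: int = 26,
    min_voxels: int = 1,
    keep_voxel_indices: bool = False,
) -> LesionSet:
    """Extract lesions as connected components of strictly suprathreshold voxels.

    Parameters
    ----------
    volume
        SUV volume.
    threshold
        A :class:`SegmentationThreshold` or a plain SUV value.
    exclusion_mask
        Boolean mask of voxels to exclude before labeling (reference regions
        and, on real data, physiologic-uptake masks — the programmatic
        stand-in for manual reader correction).
    connectivity
        3D voxel connectivity: 6, 18 or 26 (default 26).
    min_voxels
        Components smaller than this are dropped (default 1 = keep all).
    keep_voxel_indices
        Attach each lesion's voxel index array (for label maps / oracles).

    Lesions are ordered by descending SUVmax, ties broken by lexicographic
    centroid order; ``lesion_id`` is 1-based in that order.
    """
    thr_value = threshold.value if isinstance(threshold, SegmentationThreshold) else float(threshold)
    if thr_value < 0:
        raise ValueError(f"threshold must be non-negative, got {thr_value}")
    if connectivity not in _CONNECTIVITY_RANK:
        raise ValueError(f"connectivity must be 6, 18 or 26, got {connectivity}")
    mask = volume.values > thr_value  # strict inequality by convention
    if exclusion_mask is not None:
        mask &= ~exclusion_mask
    structure = ndimage.generate_binary_structure(3, _CONNECTIVITY_RANK[connectivity])
    labels, n_comp = ndimage.label(mask, structure=structure)
    if n_comp == 0:
        return LesionSet(lesions=(), threshold=thr_value)

    index = np.arange(1, n_comp + 1)
    counts = np.bincount(labels.ravel(), minlength=n_comp + 1)[1:]
    suvmax = ndimage.maximum(volume.values, labels=labels, index=index)
    centroids = ndimage.center_of_mass(mask, labels=labels, index=index)
    voxel_ml = volume.voxel_volume_ml

    records = []
    for lab, cnt, smax, cen in zip(index, counts, suvmax, centroids):
        if cnt < min_voxels:
            continue
        world = tuple(volume.index_to_world(np.asarray(cen)).tolist())
        records.append((lab, int(cnt), float(smax), world))
    # deterministic ordering: hottest first, centroid-lexicographic ties
    records.sort(key=lambda r: (-r[2], r[3]))

    voxel_lookup = None
    if keep_voxel_indices:
        voxel_lookup = ndimage.value_indices(labels, ignore_value=0)

    lesions = []
    for new_id, (lab, cnt, smax, world) in enumerate(records, start=1):
        vox = None
        if voxel_lookup is not None:
            vox = np.stack(voxel_lookup[lab], axis=1)
        lesions.append(
            Lesion(
                lesion_id=new_id,
                suvmax=smax,
                volume_ml=cnt * voxel_ml,
                centroid_mm=world,
                n_voxels=cnt,
                voxel_indices=vox,
            )
        )
    logger.info(
        "segmented %d lesion(s) at threshold %.4f (connectivity %d)",
        len(lesions), thr_value, connectivity,
    )
    return LesionSet(lesions=tuple(lesions), threshold=thr_value)


def label_map(volume: PETVolume, lesion_set: LesionSet) -> np.ndarray:
    """Integer label map (0 = background) from a LesionSet that kept voxel indices."""
    out = np.zeros(volume.shape, dtype=np.int32)
    for les in lesion_set.lesions:
        if les.voxel_indices is None:
            raise ValueError(
                "lesion voxel indices not retained; re-run segment_lesions with "
                "keep_voxel_indices=True"
            )
        idx = les.voxel_indices
        out[idx[:, 0], idx[:, 1], idx[:, 2]] = les.lesion_id
    return out
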