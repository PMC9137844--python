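"""Segmentation: reference-ROI statistics, threshold formulas, connected
components against a naive flood-fill oracle, and the partition/monotonicity
invariants."""

import numpy as np
import pytest

from petkeyhole.exceptions import ROIError
from petkeyhole.io import PETVolume
from petkeyhole.segmentation import (
    Lesion,
    ReferenceROISpec,
    SegmentationThreshold,
    compute_threshold,
    reference_roi_stats,
    roi_mask,
    segment_lesions,
)

# ---------------------------------------------------------------------------
# naive flood-fill oracle (independent of scipy.ndimage)
# ---------------------------------------------------------------------------

def neighbor_offsets(connectivity):
    offs = []
    for di in (-1, 0, 1):
        for dj in (-1, 0, 1):
            for dk in (-1, 0, 1):
                if (di, dj, dk) == (0, 0, 0):
                    continue
                manhattan = abs(di) + abs(dj) + abs(dk)
                if connectivity == 6 and manhattan > 1:
                    continue
                if connectivity == 18 and manhattan > 2:
                    continue
                offs.append((di, dj, dk))
    return offs


def flood_fill_components(binary, connectivity):
    """BFS flood fill; returns a set of frozensets of voxel index triples."""
    offsets = neighbor_offsets(connectivity)
    fg = {tuple(idx) for idx in np.argwhere(binary)}
    seen = set()
    components = set()
    for start in fg:
        if start in seen:
            continue
        comp = set()
        stack = [start]
        seen.add(start)
        while stack:
            v = stack.pop()
            comp.add(v)
            for off in offsets:
                nb = (v[0] + off[0], v[1] + off[1], v[2] + off[2])
                if nb in fg and nb not in seen:
                    seen.add(nb)
                    stack.append(nb)
        components.add(frozenset(comp))
    return components


def lesion_components(lesion_set):
    return {
        frozenset(map(tuple, les.voxel_indices.tolist()))
        for les in lesion_set.lesions
    }


# ---------------------------------------------------------------------------
# threshold formulas
# ---------------------------------------------------------------------------

class TestComputeThreshold:
    @pytest.mark.parametrize(
        "mean, sd, mode, expected",
        [
            (4.0, 1.0, "liver", 8.0),
            (4.0, 1.0, "aorta", 10.0),
            (0.0, 0.0, "liver", 0.0),
            (2.5, 0.5, "liver", 4.75),
            (2.5, 0.5, "aorta", 6.0),
        ],
    )
    def test_formula(self, mean, sd, mode, expected):
        thr = compute_threshold(mean, sd, mode)
        assert thr.value == pytest.approx(expected)
        assert thr.mode == mode

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            compute_threshold(-1.0, 0.5, "liver")
        with pytest.raises(ValueError):
            compute_threshold(1.0, -0.5, "aorta")

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError, match="mode"):
            compute_threshold(1.0, 0.5, "brain")

    def test_threshold_object_checks_consistency(self):
        with pytest.raises(ValueError, match="inconsistent"):
            SegmentationThreshold(value=9.0, mode="liver", ref_mean=4.0, ref_sd=1.0)


# ---------------------------------------------------------------------------
# reference ROI statistics
# ---------------------------------------------------------------------------

def uniform_volume(value=5.0, shape=(40, 40, 40), spacing=2.0):
    return PETVolume(np.full(shape, value), spacing=(spacing,) * 3)


class TestReferenceROIStats:
    def test_constant_region_mean_sd(self):
        vol = uniform_volume(5.0)
        spec = ReferenceROISpec("liver_sphere", (40.0, 40.0, 40.0))
        mean, sd = reference_roi_stats(vol, spec)
        assert mean == pytest.approx(5.0)
        assert sd == pytest.approx(0.0)

    def test_liver_sphere_voxel_count_near_analytic(self):
        # 30 mm sphere at 2 mm spacing: analytic count 4/3*pi*15^3/8 = 1767
        vol = uniform_volume()
        spec = ReferenceROISpec("liver_sphere", (39.0, 39.0, 39.0))
        mask = roi_mask(vol, spec)
        analytic = 4 / 3 * np.pi * 15.0**3 / 8.0
        assert abs(mask.sum() - analytic) / analytic < 0.15
        # brute-force voxel enumeration oracle
        count = 0
        for i in range(vol.shape[0]):
            for j in range(vol.shape[1]):
                for k in range(vol.shape[2]):
                    d2 = (2 * i - 39) ** 2 + (2 * j - 39) ** 2 + (2 * k - 39) ** 2
                    if d2 <= 15.0**2:
                        count += 1
        assert mask.sum() == count

    def test_cylinder_z_extent_outside_grid_errors(self):
        vol = uniform_volume(shape=(20, 20, 8))  # z extent 14 mm < 20 mm cylinder
        spec = ReferenceROISpec("aorta_cylinder", (20.0, 20.0, 7.0))
        with pytest.raises(ROIError, match="exceeds"):
            reference_roi_stats(vol, spec)

    def test_too_few_voxels_errors(self):
        vol = uniform_volume(spacing=8.0, shape=(20, 20, 20))
        spec = ReferenceROISpec("aorta_cylinder", (80.0, 80.0, 80.0))
        with pytest.raises(ROIError, match="voxel"):
            reference_roi_stats(vol, spec)

    def test_sd_convention_sample_vs_population(self):
        vol = PETVolume(
            np.fromfunction(lambda i, j, k: (i + j + k) % 7 + 1.0, (40, 40, 40)),
            spacing=(2.0, 2.0, 2.0),
        )
        spec = ReferenceROISpec("liver_sphere", (40.0, 40.0, 40.0))
        _, sd_sample = reference_roi_stats(vol, spec, ddof=1)
        _, sd_pop = reference_roi_stats(vol, spec, ddof=0)
        assert sd_sample > sd_pop


# ---------------------------------------------------------------------------
# lesion extraction
# ---------------------------------------------------------------------------

def binary_volume(binary, spacing=2.0):
    return PETVolume(binary.astype(float), spacing=(spacing,) * 3)


class TestSegmentLesions:
    def test_two_disjoint_spheres(self):
        vals = np.zeros((30, 30, 30))
        vals[5:9, 5:9, 5:9] = 10.0
        vals[20:26, 20:26, 20:26] = 8.0
        vol = PETVolume(vals, spacing=(2.0, 2.0, 2.0))
        ls = segment_lesions(vol, 5.0)
        assert ls.n_lesions == 2
        assert ls.tv_all_ml == pytest.approx((4**3 + 6**3) * 0.008)
        assert ls.suvmax_all == pytest.approx(18.0)
        assert ls.hottest_suvmax == pytest.approx(10.0)
        # deterministic ordering: hottest first
        assert ls.lesions[0].suvmax == pytest.approx(10.0)
        assert ls.lesions[0].lesion_id == 1

    def test_threshold_above_max_gives_empty_set(self, rng):
        vol = PETVolume(rng.uniform(0, 5, (10, 10, 10)), spacing=(2, 2, 2))
        ls = segment_lesions(vol, 10.0)
        assert ls.n_lesions == 0
        assert ls.tv_all_ml == 0.0
        assert ls.suvmax_all == 0.0

    def test_exclusion_mask_removes_voxels(self):
        vals = np.zeros((10, 10, 10))
        vals[2:4, 2:4, 2:4] = 10.0
        vol = PETVolume(vals, spacing=(2, 2, 2))
        excl = np.zeros((10, 10, 10), dtype=bool)
        excl[2:4, 2:4, 2:4] = True
        assert segment_lesions(vol, 5.0, excl).n_lesions == 0

    def test_min_voxels_drops_speckles(self):
        vals = np.zeros((10, 10, 10))
        vals[1, 1, 1] = 10.0  # single-voxel speckle
        vals[5:8, 5:8, 5:8] = 10.0
        vol = PETVolume(vals, spacing=(2, 2, 2))
        assert segment_lesions(vol, 5.0).n_lesions == 2
        assert segment_lesions(vol, 5.0, min_voxels=2).n_lesions == 1

    @pytest.mark.parametrize("connectivity", [6, 18, 26])
    def test_matches_flood_fill_oracle_on_random_grids(self, rng, connectivity):
        for _ in range(20):
            shape = tuple(rng.integers(4, 14, size=3))
            binary = rng.random(shape) < rng.uniform(0.2, 0.7)
            vol = binary_volume(binary)
            ls = segment_lesions(vol, 0.5, connectivity=connectivity,
                                 keep_voxel_indices=True)
            assert lesion_components(ls) == flood_fill_components(binary, connectivity)

    def test_partition_invariant(self, rng):
        vol = PETVolume(rng.uniform(0, 10, (16, 16, 16)), spacing=(2, 2, 2))
        thr = 6.0
        ls = segment_lesions(vol, thr, keep_voxel_indices=True)
        assert sum(l.n_voxels for l in ls.lesions) == int((vol.values > thr).sum())

    def test_threshold_monotonicity(self, rng):
        vol = PETVolume(rng.uniform(0, 10, (16, 16, 16)), spacing=(2, 2, 2))
        tvs = [segment_lesions(vol, t).tv_all_ml for t in (2.0, 4.0, 6.0, 8.0)]
        assert all(a >= b for a, b in zip(tvs, tvs[1:]))

    def test_idempotence(self, rng):
        vol = PETVolume(rng.uniform(0, 10, (12, 12, 12)), spacing=(2, 2, 2))
        a = segment_lesions(vol, 5.0)
        b = segment_lesions(vol, 5.0)
        assert [(l.lesion_id, l.suvmax, l.volume_ml, l.centroid_mm) for l in a.lesions] == [
            (l.lesion_id, l.suvmax, l.volume_ml, l.centroid_mm) for l in b.lesions
        ]

    def test_lesion_invariants(self, rng):
        vol = PETVolume(rng.uniform(0, 10, (14, 14, 14)), spacing=(2, 2, 2))
        ls = segment_lesions(vol, 5.0, keep_voxel_indices=True)
        for les in ls.lesions:
            suvs = vol.values[tuple(les.voxel_indices.T)]
            assert np.all(suvs > 5.0)
            assert les.suvmax == pytest.approx(suvs.max())
            assert les.volume_ml == pytest.approx(les.n_voxels * vol.voxel_volume_ml)
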