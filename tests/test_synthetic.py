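"""Phantom and cohort generator: determinism, geometry, response truth and
PSA rank-coupling calibration."""

import numpy as np
import pytest

from conftest import sphere_phantom_config
from petkeyhole.exceptions import CouplingError, PhantomConfigError
from petkeyhole.keyhole import relative_change
from petkeyhole.segmentation import segment_lesions
from petkeyhole.synthetic import (
    CohortConfig,
    LesionSpec,
    PhantomConfig,
    ResponseScenario,
    analytic_suprathreshold_volume_ml,
    apply_response,
    followup_config,
    generate_cohort,
    generate_phantom,
    rank_coupled_delta_psa,
    sphere_volume_ml,
)
from petkeyhole.cohort import spearman


class TestGeneratePhantom:
    def test_determinism_bit_identical(self):
        cfg = PhantomConfig(seed=42, lesions=(LesionSpec((80, 80, 40), 8.0, 20.0),))
        v1, _, _ = generate_phantom(cfg)
        v2, _, _ = generate_phantom(cfg)
        np.testing.assert_array_equal(v1.values, v2.values)

    def test_zero_lesions_segments_empty_above_liver_band(self):
        cfg = PhantomConfig(seed=7)
        vol, rois, truth = generate_phantom(cfg)
        thr = cfg.liver_suv_mean + 3 * cfg.liver_suv_sd
        from petkeyhole.segmentation import roi_mask

        excl = np.zeros(vol.shape, dtype=bool)
        for spec in rois.values():
            excl |= roi_mask(vol, spec)
        assert segment_lesions(vol, thr, excl).n_lesions == 0
        assert truth.lesion_ids == ()

    def test_geometry_is_seed_independent(self):
        from dataclasses import replace

        base = sphere_phantom_config(2.0, background_sd=0.3)
        sets = []
        for seed in (1, 2):
            cfg = replace(base, seed=seed)
            vol, _, _ = generate_phantom(cfg)
            ls = segment_lesions(vol, 5.0, keep_voxel_indices=True)
            sets.append(
                {frozenset(map(tuple, l.voxel_indices.tolist())) for l in ls.lesions}
            )
        assert sets[0] == sets[1]

    def test_sphere_recovery_within_15pct_of_analytic(self):
        cfg = sphere_phantom_config(2.0, radius_mm=10.0, peak_suv=20.0)
        vol, _, _ = generate_phantom(cfg)
        recovered = segment_lesions(vol, 1.2).tv_all_ml
        analytic = sphere_volume_ml(10.0)  # 4.19 mL
        assert abs(recovered - analytic) / analytic < 0.15

    def test_grid_refinement_converges_to_taper_volume(self):
        errors = []
        for spacing in (4.0, 2.0, 1.0):
            cfg = sphere_phantom_config(spacing)
            vol, _, _ = generate_phantom(cfg)
            recovered = segment_lesions(vol, 1.2).tv_all_ml
            target = analytic_suprathreshold_volume_ml(10.0, 20.0, 1.0, 1.2)
            errors.append(abs(recovered - target))
        assert errors[0] > errors[1] > errors[2]

    def test_suvmax_close_to_configured_peak(self):
        cfg = sphere_phantom_config(2.0, peak_suv=20.0, radius_mm=10.0)
        vol, _, _ = generate_phantom(cfg)
        ls = segment_lesions(vol, 5.0)
        # nearest voxel center can miss the lesion center by half a voxel
        # diagonal: worst-case profile drop (peak-bg)*3*(sp/2)^2/R^2
        worst = (20.0 - 1.0) * 3 * 1.0**2 / 10.0**2
        assert 20.0 - worst <= ls.lesions[0].suvmax <= 20.0

    def test_lesion_overlapping_reference_roi_rejected(self):
        cfg = PhantomConfig(lesions=(LesionSpec((48.0, 48.0, 112.0), 6.0, 20.0),))
        with pytest.raises(PhantomConfigError, match="liver"):
            generate_phantom(cfg)

    def test_lesion_outside_grid_rejected(self):
        cfg = PhantomConfig(lesions=(LesionSpec((158.0, 80.0, 80.0), 6.0, 20.0),))
        with pytest.raises(PhantomConfigError, match="outside"):
            generate_phantom(cfg)

    def test_background_clipped_at_zero(self):
        cfg = PhantomConfig(background_suv_mean=0.2, background_suv_sd=1.0, seed=3)
        vol, _, _ = generate_phantom(cfg)
        assert vol.values.min() >= 0.0


class TestApplyResponse:
    def base_config(self, n=1, radius=8.0):
        lesions = tuple(
            LesionSpec((30.0 + 30.0 * i, 100.0, 40.0), radius, 20.0) for i in range(n)
        )
        return PhantomConfig(lesions=lesions, seed=5)

    def test_no_change_scenario(self):
        cfg = self.base_config()
        _, truth = apply_response(cfg, ResponseScenario(volume_scales=(1.0,)))
        assert truth.true_delta_tv_pct == pytest.approx(0.0)

    def test_half_volume_is_minus_50(self):
        cfg = self.base_config()
        _, truth = apply_response(cfg, ResponseScenario(volume_scales=(0.5,)))
        assert truth.true_delta_tv_pct == pytest.approx(-50.0)

    def test_scale_130_is_pd_boundary(self):
        cfg = self.base_config()
        _, truth = apply_response(cfg, ResponseScenario(volume_scales=(1.3,)))
        assert truth.true_delta_tv_pct == pytest.approx(30.0)

    def test_truth_uses_pipeline_relative_change_formula(self):
        cfg = self.base_config(n=3)
        scen = ResponseScenario(volume_scales=(0.5, 2.0, 0.0))
        _, truth = apply_response(cfg, scen)
        expected = relative_change(
            sum(truth.volumes_baseline_ml), sum(truth.volumes_followup_ml)
        )
        assert truth.true_delta_tv_pct == pytest.approx(expected)

    def test_vanished_and_new_lesions(self):
        cfg = self.base_config(n=2)
        new = LesionSpec((120.0, 40.0, 120.0), 6.0, 25.0)
        scen = ResponseScenario(volume_scales=(0.0, 1.0), new_lesions=(new,))
        fu_cfg = followup_config(cfg, scen)
        assert len(fu_cfg.lesions) == 2  # one vanished, one new
        _, truth = apply_response(cfg, scen)
        assert truth.volumes_followup_ml[0] == 0.0
        assert truth.volumes_baseline_ml[2] == 0.0
        assert truth.volumes_followup_ml[2] == pytest.approx(sphere_volume_ml(6.0))

    def test_radius_scales_by_cube_root(self):
        cfg = self.base_config()
        fu = followup_config(cfg, ResponseScenario(volume_scales=(0.5,)))
        assert fu.lesions[0].radius_mm == pytest.approx(8.0 * 0.5 ** (1 / 3))

    def test_negative_scale_rejected(self):
        with pytest.raises(ValueError):
            ResponseScenario(volume_scales=(-0.1,))


class TestRankCoupling:
    def test_perfect_coupling_preserves_ranks_exactly(self, rng):
        dtv = rng.normal(size=50)
        dpsa = rank_coupled_delta_psa(dtv, 1.0, rng)
        assert spearman(dtv, dpsa).r == pytest.approx(1.0)

    def test_unreachable_coupling_rejected(self, rng):
        with pytest.raises(CouplingError):
            rank_coupled_delta_psa(rng.normal(size=10), 1.5, rng)

    def test_delta_psa_above_minus_100(self, rng):
        dpsa = rank_coupled_delta_psa(rng.normal(size=200), 0.3, rng)
        assert dpsa.min() > -100.0

    def test_calibration_mean_within_tolerance(self, rng):
        # Monte-Carlo check of the copula calibration at the truth level
        rs = []
        for _ in range(200):
            dtv = rng.normal(size=65)
            dpsa = rank_coupled_delta_psa(dtv, 0.6, rng)
            rs.append(spearman(dtv, dpsa).r)
        assert abs(np.mean(rs) - 0.6) < 0.05


class TestGenerateCohort:
    def test_determinism(self):
        a = generate_cohort(6, seed=9)
        b = generate_cohort(6, seed=9)
        assert a.psa_table.equals(b.psa_table)
        for ca, cb in zip(a.patients, b.patients):
            assert ca.baseline_config == cb.baseline_config
            assert ca.scenario == cb.scenario

    def test_minimal_cohort_of_two(self):
        spec = generate_cohort(2, seed=1)
        assert len(spec.patients) == 2
        assert set(spec.psa_table.columns) == {
            "patient_id", "psa_baseline", "psa_followup",
        }

    def test_single_patient_rejected(self):
        with pytest.raises(ValueError):
            generate_cohort(1, seed=1)

    def test_includes_patients_with_fewer_than_5_lesions(self):
        spec = generate_cohort(30, seed=4)
        counts = [len(p.baseline_config.lesions) for p in spec.patients]
        assert any(c < 5 for c in counts)
        assert any(c > 10 for c in counts)

    def test_lesions_clear_of_reference_rois(self):
        from petkeyhole.synthetic import _lesion_roi_overlap

        spec = generate_cohort(10, seed=12)
        for case in spec.patients:
            for les in case.baseline_config.lesions:
                assert _lesion_roi_overlap(les, case.baseline_config) is None

    def test_truth_delta_psa_matches_psa_table(self):
        spec = generate_cohort(8, seed=3)
        for case in spec.patients:
            row = spec.psa_table.set_index("patient_id").loc[case.patient_id]
            implied = relative_change(row["psa_baseline"], row["psa_followup"])
            assert implied == pytest.approx(case.truth.true_delta_psa_pct, abs=1e-9)
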