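import hashlib
from pathlib import Path

import numpy as np
import pytest

from lungdelta import synthetic as syn
from lungdelta.registration import apply_displacement
from lungdelta.volumes import load_cohort

from conftest import SMALL_EXTENT, SMALL_SPACING


class TestPlanningPhantom:
    def test_compartment_intensities(self, phantom):
        ct, lung = phantom["ct"], phantom["lung"]
        lung_hu = ct.values[lung.values]
        assert -900 <= lung_hu.mean() <= -700
        paren = lung.values & ~phantom["tumor"].values & ~phantom["vessels"].values
        assert ct.values[paren].max() < -500  # aerated parenchyma before noise
        vessel_hu = ct.values[phantom["vessels"].values]
        assert (vessel_hu > -300).all() and (vessel_hu < 0).all()
        assert ct.values[phantom["tumor"].values].min() >= 0

    def test_seed_determinism_and_sensitivity(self):
        a1 = syn.generate_planning_ct(SMALL_EXTENT, SMALL_SPACING, seed=1)
        a2 = syn.generate_planning_ct(SMALL_EXTENT, SMALL_SPACING, seed=1)
        b = syn.generate_planning_ct(SMALL_EXTENT, SMALL_SPACING, seed=2)
        np.testing.assert_array_equal(a1[0].values, a2[0].values)
        assert not np.array_equal(a1[0].values, b[0].values)

    def test_extent_too_small_rejected(self):
        with pytest.raises(ValueError, match="32"):
            syn.generate_planning_ct((16, 40, 40), SMALL_SPACING, seed=0)

    def test_masks_share_geometry(self, phantom):
        for key in ("lung", "tumor", "vessels"):
            assert phantom[key].same_geometry(phantom["ct"])


class TestDoseField:
    def test_prescription_met_at_target(self, phantom):
        ct = phantom["ct"]
        center = tuple(n / 2 * s for n, s in zip(ct.shape, ct.spacing))
        dose = syn.generate_dose_field(ct, center, 60.0)
        idx = tuple(int(n / 2) for n in ct.shape)
        assert dose.values[idx] == pytest.approx(60.0, abs=1.2)  # within 2%

    def test_monotone_falloff_along_ray(self, phantom_dose, phantom):
        ct = phantom["ct"]
        nz, ny, nx = ct.shape
        iz, iy = int(nz / 2), int(ny / 2)
        profile = phantom_dose.values[iz, iy, int(nx * 0.7):]
        assert (np.diff(profile) <= 1e-9).all()

    def test_lung_v20_sane(self, phantom, phantom_dose):
        lung_dose = phantom_dose.values[phantom["lung"].values]
        v20 = (lung_dose >= 20.0).mean()
        assert 0.0 < v20 < 1.0

    def test_nonpositive_prescription_rejected(self, phantom):
        with pytest.raises(ValueError, match="prescription"):
            syn.generate_dose_field(phantom["ct"], (10, 10, 10), 0.0)

    def test_target_outside_volume_rejected(self, phantom):
        with pytest.raises(ValueError, match="inside"):
            syn.generate_dose_field(phantom["ct"], (-50.0, 0.0, 0.0), 60.0)


class TestDeformation:
    def test_zero_amplitude_is_identity(self, phantom):
        field = syn.generate_deformation(phantom["ct"], 0.0, seed=0)
        assert field.max_magnitude_mm == 0.0

    def test_amplitude_bound_is_tight(self, phantom):
        field = syn.generate_deformation(phantom["ct"], 4.0, 24.0, seed=0)
        assert field.max_magnitude_mm == pytest.approx(4.0, abs=1e-9)
        assert field.jacobian_min() > 0

    def test_seed_determinism(self, phantom):
        f1 = syn.generate_deformation(phantom["ct"], 3.0, seed=5)
        f2 = syn.generate_deformation(phantom["ct"], 3.0, seed=5)
        np.testing.assert_array_equal(f1.vectors, f2.vectors)

    def test_folding_amplitude_rejected(self, phantom):
        with pytest.raises(ValueError, match="fold"):
            syn.generate_deformation(phantom["ct"], 80.0, 10.0, seed=0)


class TestFollowupSimulation:
    def test_linear_response_exact(self, phantom, phantom_dose):
        model = syn.ResponseModel(shape="linear", slope_b=2.0)
        fup = syn.simulate_followup(
            phantom["ct"], phantom_dose, phantom["lung"], phantom["tumor"],
            model, noise_sd=0.0, deformation=None, seed=0,
        )
        responding = phantom["lung"].values & ~phantom["tumor"].values
        delta = fup.values - phantom["ct"].values
        np.testing.assert_allclose(
            delta[responding], 2.0 * phantom_dose.values[responding], atol=1e-9
        )
        assert (delta[~responding] == 0).all()

    def test_null_model_returns_planning(self, phantom, phantom_dose):
        model = syn.ResponseModel(shape="linear", slope_b=0.0)
        fup = syn.simulate_followup(
            phantom["ct"], phantom_dose, phantom["lung"], phantom["tumor"],
            model, noise_sd=0.0, deformation=None, seed=0,
        )
        np.testing.assert_array_equal(fup.values, phantom["ct"].values)

    def test_sigmoid_half_maximum_at_d50(self):
        model = syn.ResponseModel(shape="sigmoid", delta_max=120.0, d50=40.0, steepness_k=8.0)
        assert model.response(np.array([40.0]))[0] == pytest.approx(60.0, abs=1e-12)

    def test_low_dose_dip_applies_below_10_gy(self):
        model = syn.ResponseModel(shape="linear", slope_b=1.0, low_dose_dip=20.0)
        r = model.response(np.array([5.0, 15.0]))
        assert r[0] == pytest.approx(5.0 - 20.0)
        assert r[1] == pytest.approx(15.0)


class TestCohortGeneration:
    def test_cohort_roundtrip_and_determinism(self, tmp_path):
        template = syn.CohortTemplate(
            extent=SMALL_EXTENT, noise_sd=0.0, deformation_amplitude_mm=0.0
        )
        m1, truth1 = syn.generate_cohort(tmp_path / "c1", 3, template, master_seed=7)
        assert len(m1.patient_ids) == 3
        assert m1.n_available("12w") == 3
        record = m1.load_patient(m1.patient_ids[0])
        assert record.dose_grid.values.max() <= 1.10 * record.prescription_dose

        m2, truth2 = syn.generate_cohort(tmp_path / "c2", 3, template, master_seed=7)
        for pid in m1.patient_ids:
            h1 = hashlib.sha256((tmp_path / "c1" / pid / "planning_ct.nii.gz").read_bytes())
            h2 = hashlib.sha256((tmp_path / "c2" / pid / "planning_ct.nii.gz").read_bytes())
            assert h1.hexdigest() == h2.hexdigest()
        assert truth1.models.keys() == truth2.models.keys()
        for pid in truth1.models:
            assert truth1.models[pid].slope_b == truth2.models[pid].slope_b

    def test_entity_mix_must_sum_to_one(self, tmp_path):
        template = syn.CohortTemplate(extent=SMALL_EXTENT, entity_mix={"NSCLC": 0.5})
        with pytest.raises(ValueError, match="sum to 1"):
            syn.generate_cohort(tmp_path / "c", 2, template, master_seed=0)

    def test_slope_distribution_matches_template(self, tmp_path):
        # cheap check on the slope draws: many patients, minimal volumes
        template = syn.CohortTemplate(
            extent=(32, 32, 32), noise_sd=0.0, deformation_amplitude_mm=0.0
        )
        _, truth = syn.generate_cohort(tmp_path / "c", 40, template, master_seed=3)
        slopes = np.array([m.slope_b for m in truth.models.values()])
        # 3-sigma band around mean 1.5 at sd 2.0, n=40
        assert abs(slopes.mean() - 1.5) < 3 * 2.0 / np.sqrt(40)
        assert 1.0 < slopes.std(ddof=1) < 3.0

    def test_truth_json_roundtrip(self, tmp_path):
        template = syn.CohortTemplate(
            extent=SMALL_EXTENT, noise_sd=0.0, deformation_amplitude_mm=0.0
        )
        _, truth = syn.generate_cohort(tmp_path / "c", 2, template, master_seed=1)
        back = syn.SyntheticTruth.from_json(tmp_path / "c" / "truth.json")
        assert back.models.keys() == truth.models.keys()
        for pid in truth.models:
            assert back.models[pid].slope_b == truth.models[pid].slope_b
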