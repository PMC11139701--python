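"""LDM voxel dose, partition doses, DVH, lung shunt, safety and comparisons."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp
from scipy.integrate import quad

from y90pet import (
    ActivityImage,
    DoseMap,
    DvhSummary,
    PhysicsConstants,
    PlanarImage,
    build_ground_truth,
    compartment_counts,
    compartment_masses_kg,
    compartment_partition_dose,
    density_map,
    dvh,
    lung_safety,
    lung_shunt,
    predicted_vs_actual,
    total_absorbed_energy_j,
    voxel_ldm_dose,
)

CONST = PhysicsConstants()


def decay_integral_oracle_s(constants: PhysicsConstants) -> float:
    """Residence time via numeric integration of the decay curve (independent
    of the closed form T½/ln 2)."""
    lam = math.log(2.0) / (constants.half_life_h * 3600.0)
    val, _ = quad(lambda t: math.exp(-lam * t), 0.0, 60.0 * constants.half_life_h * 3600.0)
    return val


class TestVoxelDose:
    def test_closed_form_against_decay_curve_integration(self):
        img = ActivityImage(np.full((4, 4, 4), 1000.0), (2, 2, 2))
        dose = voxel_ldm_dose(img, CONST, CONST.soft_tissue_density_g_ml)
        oracle = (
            1000.0e3 * decay_integral_oracle_s(CONST) * CONST.beta_energy_j
            / (CONST.soft_tissue_density_g_ml * 1e-3)
        )
        np.testing.assert_allclose(dose.voxels, oracle, rtol=1e-6)
        assert dose.voxels[0, 0, 0] == pytest.approx(47.9, abs=0.1)

    def test_zero_activity_zero_dose_and_linearity(self):
        img = ActivityImage(np.zeros((3, 3, 3)), (1, 1, 1))
        assert not voxel_ldm_dose(img, CONST, 1.0).voxels.any()
        a = ActivityImage(np.arange(27, dtype=float).reshape(3, 3, 3), (1, 1, 1))
        b = a.with_voxels(2.0 * a.voxels)
        np.testing.assert_allclose(
            voxel_ldm_dose(b, CONST, 1.0).voxels,
            2.0 * voxel_ldm_dose(a, CONST, 1.0).voxels,
        )

    def test_lung_density_amplifies_dose(self):
        img = ActivityImage(np.full((2, 2, 2), 10.0), (1, 1, 1))
        soft = voxel_ldm_dose(img, CONST, CONST.soft_tissue_density_g_ml)
        lung = voxel_ldm_dose(img, CONST, CONST.lung_density_g_ml)
        assert lung.voxels[0, 0, 0] / soft.voxels[0, 0, 0] == pytest.approx(
            CONST.soft_tissue_density_g_ml / CONST.lung_density_g_ml
        )

    def test_bad_density_rejected(self):
        img = ActivityImage(np.ones((2, 2, 2)), (1, 1, 1))
        with pytest.raises(ValueError, match="positive, finite density"):
            voxel_ldm_dose(img, CONST, 0.0)
        with pytest.raises(ValueError, match="does not match"):
            voxel_ldm_dose(img, CONST, np.ones((3, 3, 3)))

    def test_energy_conservation_on_phantom(self, small_truth):
        truth, segs = small_truth
        rho = density_map(segs, CONST)
        dose = voxel_ldm_dose(truth, CONST, rho)
        energy = total_absorbed_energy_j(dose, rho)
        expected = truth.total_activity_kbq * 1e-6 * CONST.gy_kg_per_gbq
        assert energy == pytest.approx(expected, rel=1e-9)


class TestPartitionDose:
    MASSES = {"tumor": 1.0, "liver_normal": 1.0, "lung": 1.0}

    def test_all_counts_in_one_kg_tumor(self):
        doses = compartment_partition_dose(
            {"tumor": 100.0, "liver_normal": 0.0}, 1.0, 0.0, self.MASSES, CONST
        )
        oracle = 1e9 * decay_integral_oracle_s(CONST) * CONST.beta_energy_j
        assert doses["tumor"] == pytest.approx(oracle, rel=1e-6)
        assert doses["tumor"] == pytest.approx(49.4, abs=0.05)
        assert doses["liver_normal"] == 0.0

    def test_ten_percent_shunt_lung_dose(self):
        doses = compartment_partition_dose(
            {"tumor": 100.0, "liver_normal": 0.0}, 1.0, 0.1, self.MASSES, CONST
        )
        assert doses["lung"] == pytest.approx(4.94, abs=0.01)
        assert doses["tumor"] == pytest.approx(0.9 * 49.39, abs=0.05)

    def test_symmetric_split_gives_equal_doses(self):
        doses = compartment_partition_dose(
            {"tumor": 50.0, "liver_normal": 50.0}, 2.0, 0.0, self.MASSES, CONST
        )
        assert doses["tumor"] == pytest.approx(doses["liver_normal"])

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError, match="mass"):
            compartment_partition_dose(
                {"tumor": 1.0, "liver_normal": 1.0}, 1.0, 0.0,
                {"tumor": 0.0, "liver_normal": 1.0, "lung": 1.0}, CONST,
            )
        with pytest.raises(ValueError, match="sum to zero"):
            compartment_partition_dose(
                {"tumor": 0.0, "liver_normal": 0.0}, 1.0, 0.0, self.MASSES, CONST
            )
        with pytest.raises(ValueError, match="shunt"):
            compartment_partition_dose(
                {"tumor": 1.0, "liver_normal": 0.0}, 1.0, 1.5, self.MASSES, CONST
            )

    def test_voxel_and_compartment_doses_agree_for_uniform_activity(self):
        # a uniform 1-compartment image must give identical mean doses by
        # the voxel (LDM) and partition routes
        img = ActivityImage(np.full((8, 8, 8), 500.0), (5.0, 5.0, 5.0))
        mask = np.ones(img.voxels.shape, dtype=bool)
        dose = voxel_ldm_dose(img, CONST, CONST.soft_tissue_density_g_ml)
        voxel_route = dvh(dose, mask, "tumor").dmean
        activity_gbq = img.total_activity_kbq * 1e-6
        mass = img.voxels.size * img.voxel_volume_ml * CONST.soft_tissue_density_g_ml * 1e-3
        partition_route = compartment_partition_dose(
            {"tumor": 1.0, "liver_normal": 0.0}, activity_gbq, 0.0,
            {"tumor": mass, "liver_normal": 1.0, "lung": 1.0}, CONST,
        )["tumor"]
        assert voxel_route == pytest.approx(partition_route, rel=1e-3)


class TestDvh:
    def test_uniform_region(self):
        dose = DoseMap(np.full((5, 5, 5), 100.0), (1, 1, 1))
        s = dvh(dose, np.ones((5, 5, 5), dtype=bool))
        assert s.d2 == s.d50 == s.d70 == s.dmean == 100.0

    def test_nearest_rank_worked_example(self):
        vals = np.array([10, 20, 30, 40, 50, 60, 70, 80, 90, 100], dtype=float)
        dose = DoseMap(vals.reshape(10, 1, 1), (1, 1, 1))
        s = dvh(dose, np.ones((10, 1, 1), dtype=bool))
        assert s.d2 == 100.0
        assert s.d50 == 60.0
        assert s.d70 == 40.0
        assert s.dmean == pytest.approx(55.0)

    def test_adding_cold_voxel_never_raises_summary(self):
        vals = np.array([10, 20, 30, 40, 50, 60, 70, 80, 90, 100], dtype=float)
        with_zero = np.append(vals, 0.0)
        d0 = dvh(DoseMap(vals.reshape(-1, 1, 1), (1, 1, 1)),
                 np.ones((10, 1, 1), dtype=bool))
        d1 = dvh(DoseMap(with_zero.reshape(-1, 1, 1), (1, 1, 1)),
                 np.ones((11, 1, 1), dtype=bool))
        assert d1.d50 <= d0.d50 and d1.d70 <= d0.d70 and d1.dmean < d0.dmean

    def test_empty_mask_rejected(self):
        dose = DoseMap(np.ones((2, 2, 2)), (1, 1, 1))
        with pytest.raises(ValueError, match="empty"):
            dvh(dose, np.zeros((2, 2, 2), dtype=bool))

    @given(
        vals=hnp.arrays(
            float, st.integers(1, 64),
            elements=st.floats(0, 1e4, allow_nan=False),
        )
    )
    def test_ordering_invariant(self, vals):
        dose = DoseMap(vals.reshape(-1, 1, 1), (1, 1, 1))
        s = dvh(dose, np.ones(dose.voxels.shape, dtype=bool))
        assert s.d2 >= s.d50 >= s.d70
        assert vals.min() * (1 - 1e-12) - 1e-12 <= s.dmean
        assert s.dmean <= vals.max() * (1 + 1e-12) + 1e-12

    def test_interpolated_variant_stays_ordered(self):
        vals = np.array([10, 20, 30, 40, 50, 60, 70, 80, 90, 100], dtype=float)
        dose = DoseMap(vals.reshape(10, 1, 1), (1, 1, 1))
        s = dvh(dose, np.ones((10, 1, 1), dtype=bool), interpolate=True)
        assert s.d2 >= s.d50 >= s.d70

    def test_inconsistent_summary_rejected(self):
        with pytest.raises(ValueError, match="ordering"):
            DvhSummary(d2=10.0, d50=20.0, d70=5.0, dmean=10.0,
                       compartment="tumor", voxel_count=3)


class TestLungShunt:
    def _planar(self, lung, liver):
        px = np.zeros((4, 4))
        px[0, 0] = lung
        px[2, 2] = liver
        return PlanarImage(px, (1, 1))

    @pytest.fixture()
    def rois(self):
        lung_roi = np.zeros((4, 4), dtype=bool)
        lung_roi[0, 0] = True
        liver_roi = np.zeros((4, 4), dtype=bool)
        liver_roi[2, 2] = True
        return lung_roi, liver_roi

    def test_ten_percent_shunt(self, rois):
        res = lung_shunt(self._planar(100, 900), self._planar(100, 900), *rois)
        assert res.lsf == pytest.approx(0.1)

    def test_reciprocal_attenuation_cancels(self, rois):
        k = 2.5
        res0 = lung_shunt(self._planar(100, 900), self._planar(100, 900), *rois)
        res1 = lung_shunt(self._planar(100 * k, 900 * k),
                          self._planar(100 / k, 900 / k), *rois)
        assert res1.lsf == pytest.approx(res0.lsf, rel=1e-12)

    def test_zero_lung_counts(self, rois):
        res = lung_shunt(self._planar(0, 900), self._planar(0, 900), *rois)
        assert res.lsf == 0.0

    def test_all_zero_undefined(self, rois):
        with pytest.raises(ValueError, match="undefined"):
            lung_shunt(self._planar(0, 0), self._planar(0, 0), *rois)

    def test_empty_roi_rejected(self, rois):
        lung_roi, liver_roi = rois
        with pytest.raises(ValueError, match="non-empty"):
            lung_shunt(self._planar(1, 1), self._planar(1, 1),
                       np.zeros((4, 4), dtype=bool), liver_roi)


class TestSafetyAndComparison:
    def test_lung_limit_flag(self):
        exceeded, margin = lung_safety(21.0)
        assert exceeded and margin == pytest.approx(-1.0)
        exceeded, margin = lung_safety(2.0)
        assert not exceeded and margin == pytest.approx(18.0)

    def test_identical_tables_give_zero_differences(self):
        s = DvhSummary(300.0, 200.0, 150.0, 180.0, "tumor", 100)
        table = predicted_vs_actual({"tumor": s}, {"tumor": s})
        assert (table["diff_gy"] == 0).all() and (table["pct_diff"] == 0).all()

    def test_percent_difference_worked_example(self):
        table = predicted_vs_actual({"tumor": 300.0}, {"tumor": 275.0})
        assert table["pct_diff"].iloc[0] == pytest.approx(-8.3, abs=0.05)

    def test_compartment_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            predicted_vs_actual({"tumor": 300.0}, {"lung": 2.0})

    def test_single_compartment_tables_join_on_name(self):
        table = predicted_vs_actual({"lung": 2.5}, {"lung": 2.0})
        assert len(table) == 1 and table["compartment"].iloc[0] == "lung"


def test_compartment_masses_and_counts_from_phantom(small_truth):
    truth, segs = small_truth
    counts = compartment_counts(truth, segs)
    assert counts["tumor"] == pytest.approx(
        6000.0 * segs.mask("tumor").sum()
    )
    masses = compartment_masses_kg(segs, truth.voxel_volume_ml, CONST)
    v_ml = truth.voxel_volume_ml
    assert masses["lung"] == pytest.approx(
        segs.lung_mask.sum() * v_ml * CONST.lung_density_g_ml * 1e-3
    )
    assert masses["tumor"] > 0 and masses["liver_normal"] > masses["tumor"]
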