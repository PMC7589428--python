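"""Dose engines: S values, LED, kernel construction/convolution, DVH."""

import itertools

import numpy as np
import pytest

from dosekit import (
    ImageVolume,
    LabelMap,
    Organ,
    SValueTable,
    build_water_kernel,
    dvh,
    dvk_dose,
    exponential_profile,
    led_dose,
    mean_organ_doses,
    svalue_dose,
)
from dosekit.errors import InvalidInputError, NormalizationError, TableLookupError

SPACING = (4.42, 4.42, 4.42)
VOXVOL_CM3 = 4.42 ** 3 / 1000.0


def toy_table():
    return SValueTable(
        nuclide_name="toy",
        s_Gy_per_MBqh={
            ("liver", "liver"): 1e-5,
            ("liver", "kidney"): 1e-7,
            ("kidney", "kidney"): 2e-5,
            ("kidney", "liver"): 1e-7,
        },
        ref_masses_g={"liver": 1800.0, "kidney": 300.0},
    )


class TestSvalueDose:
    def test_all_zero_tiacs(self):
        doses = svalue_dose(
            {"liver": 0.0, "kidney": 0.0}, 7000.0, toy_table(),
            {"liver": 1800.0, "kidney": 300.0},
        )
        assert doses == {"liver": 0.0, "kidney": 0.0}

    def test_hand_arithmetic_self_dose(self):
        """S=1e-5 Gy/MBq.h, TIAC 2 h, A0 7000 MBq, reference mass: 0.14 Gy."""
        doses = svalue_dose(
            {"liver": 2.0}, 7000.0, toy_table(), {"liver": 1800.0},
            targets=["liver"],
        )
        assert doses["liver"] == pytest.approx(0.14, rel=1e-12)

    def test_double_mass_halves_self_dose(self):
        doses = svalue_dose(
            {"liver": 2.0}, 7000.0, toy_table(), {"liver": 3600.0},
            targets=["liver"],
        )
        assert doses["liver"] == pytest.approx(0.07, rel=1e-12)

    def test_cross_dose_not_mass_scaled_by_default(self):
        d = svalue_dose(
            {"liver": 2.0}, 7000.0, toy_table(),
            {"liver": 1800.0, "kidney": 600.0}, targets=["kidney"],
        )
        # cross term uses adj=1 even though the patient kidney is 2x reference
        assert d["kidney"] == pytest.approx(7000.0 * 2.0 * 1e-7, rel=1e-12)

    def test_linear_in_tiac_and_a0(self):
        base = svalue_dose({"liver": 1.0}, 1000.0, toy_table(), {"liver": 1800.0})
        assert svalue_dose({"liver": 3.0}, 1000.0, toy_table(), {"liver": 1800.0})[
            "liver"
        ] == pytest.approx(3 * base["liver"], rel=1e-12)
        assert svalue_dose({"liver": 1.0}, 5000.0, toy_table(), {"liver": 1800.0})[
            "liver"
        ] == pytest.approx(5 * base["liver"], rel=1e-12)

    def test_missing_entry_names_pair(self):
        with pytest.raises(TableLookupError, match="spleen"):
            svalue_dose(
                {"spleen": 1.0}, 7000.0, toy_table(),
                {"spleen": 100.0, "liver": 1800.0}, targets=["liver"],
            )

    def test_csv_round_trip(self, tmp_path):
        path = tmp_path / "svalues.csv"
        toy_table().to_csv(path)
        back = SValueTable.from_csv(path)
        assert back.s_Gy_per_MBqh == toy_table().s_Gy_per_MBqh
        assert back.ref_masses_g == toy_table().ref_masses_g


class TestLedDose:
    def tia_one_voxel(self, value=1.0, shape=(5, 5, 5)):
        data = np.zeros(shape)
        data[2, 2, 2] = value
        return ImageVolume(data, SPACING, "TIA_MBqh")

    def density(self, value=1.0, shape=(5, 5, 5)):
        return ImageVolume(np.full(shape, value), SPACING, "density_gcc")

    def test_zero_tia_zero_dose(self, toy_nuclide):
        dose = led_dose(self.tia_one_voxel(0.0), self.density(), toy_nuclide)
        assert np.all(dose.data == 0.0)

    def test_hand_arithmetic(self, toy_nuclide):
        """1 MBq.h, E=1e-12 J, water voxel of (4.42mm)^3: ~41.69 Gy."""
        dose = led_dose(self.tia_one_voxel(1.0), self.density(1.0), toy_nuclide)
        expected = 3.6e9 * 1e-12 / (VOXVOL_CM3 * 1e-3)
        assert expected == pytest.approx(41.69, abs=5e-3)
        assert dose.data[2, 2, 2] == pytest.approx(expected, rel=1e-12)

    def test_density_halves_dose(self, toy_nuclide):
        d1 = led_dose(self.tia_one_voxel(), self.density(1.0), toy_nuclide)
        d2 = led_dose(self.tia_one_voxel(), self.density(2.0), toy_nuclide)
        assert d2.data[2, 2, 2] == pytest.approx(d1.data[2, 2, 2] / 2.0, rel=1e-12)

    def test_zero_density_with_tia_raises(self, toy_nuclide):
        with pytest.raises(InvalidInputError, match="voxel"):
            led_dose(self.tia_one_voxel(), self.density(0.0), toy_nuclide)


class TestBuildWaterKernel:
    def test_radius_zero_is_pure_led(self, toy_nuclide):
        k = build_water_kernel(toy_nuclide, SPACING, 0)
        assert k.values.shape == (1, 1, 1)
        assert k.energy_fraction == 1.0
        led_peak = 3.6e9 * 1e-12 / (VOXVOL_CM3 * 1e-3)
        assert k.values[0, 0, 0] == pytest.approx(led_peak, rel=1e-12)

    def test_energy_integral_within_truncation(self, toy_nuclide):
        """Radius-5 exponential kernel keeps the energy within 0.5%."""
        k = build_water_kernel(toy_nuclide, SPACING, 5, scale_mm=2.0)
        # direct summation oracle: sum(kernel) x voxel water mass = E fraction
        total_energy = k.values.sum() * VOXVOL_CM3 * 1e-3 / 3.6e9
        assert abs(total_energy - 1e-12) / 1e-12 <= 0.005
        assert k.energy_fraction == pytest.approx(1.0, abs=0.005)

    def test_symmetric_under_axis_permutations(self, toy_nuclide):
        k = build_water_kernel(toy_nuclide, SPACING, 2, scale_mm=2.0, truncation_tol=0.05)
        for perm in itertools.permutations((0, 1, 2)):
            assert np.allclose(k.values, np.transpose(k.values, perm), rtol=1e-10)
        assert k.values[2, 2, 2] == k.values.max()

    def test_excessive_truncation_rejected(self, toy_nuclide):
        with pytest.raises(NormalizationError, match="truncation"):
            build_water_kernel(toy_nuclide, SPACING, 1, scale_mm=30.0)

    def test_negative_profile_rejected(self, toy_nuclide):
        with pytest.raises(NormalizationError):
            build_water_kernel(
                toy_nuclide, SPACING, 2, profile=lambda r: np.cos(np.asarray(r))
            )


class TestDvkDose:
    def uniform_tia(self, shape=(20, 20, 20), value=0.5):
        return ImageVolume(np.full(shape, value), SPACING, "TIA_MBqh")

    def test_point_source_reproduces_kernel(self, toy_nuclide):
        k = build_water_kernel(toy_nuclide, SPACING, 2, scale_mm=2.0, truncation_tol=0.05)
        tia = np.zeros((11, 11, 11))
        tia[5, 5, 5] = 2.0
        dose = dvk_dose(ImageVolume(tia, SPACING, "TIA_MBqh"), k)
        assert np.allclose(dose.data[3:8, 3:8, 3:8], 2.0 * k.values, rtol=1e-9)

    def test_energy_conservation(self, toy_nuclide):
        """sum(dose x voxel mass) = sum(TIA) x kernel energy over the
        zero-padded field (sources keep a margin >= kernel radius)."""
        rng = np.random.default_rng(11)
        data = np.zeros((16, 16, 16))
        data[3:-3, 3:-3, 3:-3] = rng.random((10, 10, 10))
        tia = ImageVolume(data, SPACING, "TIA_MBqh")
        k = build_water_kernel(toy_nuclide, SPACING, 3, scale_mm=2.0, truncation_tol=0.05)
        dose = dvk_dose(tia, k)
        lhs = float(dose.data.sum()) * VOXVOL_CM3 * 1e-3
        rhs = float(tia.data.sum()) * 3.6e9 * 1e-12 * k.energy_fraction
        assert abs(lhs - rhs) / rhs <= 1e-6

    def test_radius_zero_equals_led_bit_for_bit(self, toy_nuclide):
        rng = np.random.default_rng(12)
        tia = ImageVolume(rng.random((9, 9, 9)), SPACING, "TIA_MBqh")
        density = ImageVolume(np.full((9, 9, 9), 1.0), SPACING, "density_gcc")
        k0 = build_water_kernel(toy_nuclide, SPACING, 0)
        assert np.array_equal(
            dvk_dose(tia, k0, density).data, led_dose(tia, density, toy_nuclide).data
        )

    def test_spacing_mismatch_is_hard_error(self, toy_nuclide):
        k = build_water_kernel(toy_nuclide, (2.0, 2.0, 2.0), 0)
        with pytest.raises(InvalidInputError, match="spacing"):
            dvk_dose(self.uniform_tia(), k)

    def test_engine_consistency_uniform_organ(self, toy_nuclide):
        """LED and compact-kernel DVK mean doses agree within 2% for a
        uniform organ more than 15 voxels across (interior dominance)."""
        shape = (24, 24, 24)
        grid = np.indices(shape).astype(float) + 0.5
        r2 = sum((g - 12.0) ** 2 for g in grid)
        mask = r2 <= 9.0 ** 2  # sphere 18 voxels across
        tia = np.where(mask, 0.3, 0.0)
        labels = LabelMap(mask.astype(np.int32), SPACING, {1: Organ(1, "blob", 1.0)})
        density = ImageVolume(np.ones(shape), SPACING, "density_gcc")
        tia_vol = ImageVolume(tia, SPACING, "TIA_MBqh")
        led = mean_organ_doses(led_dose(tia_vol, density, toy_nuclide), labels)[1]
        k = build_water_kernel(toy_nuclide, SPACING, 3)  # default compact profile
        dvk = mean_organ_doses(dvk_dose(tia_vol, k, density), labels)[1]
        assert abs(dvk - led) / led <= 0.02


class TestDvh:
    def label_all(self, shape):
        return LabelMap(np.ones(shape, dtype=np.int32), SPACING, {1: Organ(1, "voi", 1.0)})

    def test_uniform_voi(self):
        dose = ImageVolume(np.full((4, 4, 4), 2.0), SPACING, "dose_Gy")
        h, mean = dvh(dose, self.label_all((4, 4, 4)), 1)
        assert mean == 2.0
        assert h.at(0.0) == 1.0
        assert h.at(2.0) == 1.0
        assert h.at(2.01) == 0.0

    def test_two_voxel_brute_force(self):
        data = np.zeros((2, 1, 1))
        data[0, 0, 0], data[1, 0, 0] = 1.0, 3.0
        dose = ImageVolume(data, SPACING, "dose_Gy")
        h, mean = dvh(dose, self.label_all((2, 1, 1)), 1)
        assert mean == 2.0
        assert h.at(1.0) == 1.0
        assert h.at(3.0) == 0.5

    def test_monotone_non_increasing_random(self):
        rng = np.random.default_rng(13)
        dose = ImageVolume(rng.random((6, 6, 6)) * 5, SPACING, "dose_Gy")
        h, _ = dvh(dose, self.label_all((6, 6, 6)), 1)
        assert h.fraction[0] == 1.0
        assert np.all(np.diff(h.fraction) <= 1e-12)

    def test_empty_voi_raises(self):
        dose = ImageVolume(np.ones((3, 3, 3)), SPACING, "dose_Gy")
        labels = LabelMap(
            np.zeros((3, 3, 3), dtype=np.int32), SPACING, {1: Organ(1, "voi", 1.0)}
        )
        with pytest.raises(InvalidInputError):
            dvh(dose, labels, 1)
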