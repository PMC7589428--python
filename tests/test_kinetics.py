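"""TAC fitting families, trapezoid+tail integration, model selection."""

import math

import numpy as np
import pytest
from scipy import integrate

from dosekit import (
    FitModel,
    TimeActivityCurve,
    auto_select,
    fit_biexp,
    fit_monoexp,
    fit_powerexp,
    integrate_trapezoid_tail,
    voxel_tia_map,
)
from dosekit.errors import InsufficientDataError
from dosekit.kinetics import LU177_LAMBDA_PHYS_PER_H

T4 = np.array([4.0, 24.0, 72.0, 192.0])
A0 = 7200.0


def tac(times, activities, a0=A0):
    return TimeActivityCurve(1, "organ", np.asarray(times, float),
                             np.asarray(activities, float), a0)


class TestMonoexp:
    def test_noiseless_recovery(self):
        """A=50, lambda=0.02 sampled at the study times: exact recovery."""
        res = fit_monoexp(tac(T4, 50.0 * np.exp(-0.02 * T4)))
        assert res.parameters["A_MBq"] == pytest.approx(50.0, rel=1e-6)
        assert res.parameters["lambda_per_h"] == pytest.approx(0.02, rel=1e-6)
        assert res.tia_MBqh == pytest.approx(2500.0, rel=1e-6)
        assert res.converged

    def test_tiac_is_tia_over_a0(self):
        res = fit_monoexp(tac(T4, 50.0 * np.exp(-0.02 * T4)))
        assert res.tiac_h == res.tia_MBqh / A0
        assert res.tiac_h == pytest.approx(2500.0 / 7200.0, rel=1e-6)  # ~0.3472 h

    def test_two_points_exact_interpolation(self):
        res = fit_monoexp(tac([10.0, 50.0], [80.0, 20.0]))
        lam = math.log(80.0 / 20.0) / 40.0
        assert res.parameters["lambda_per_h"] == pytest.approx(lam, rel=1e-9)
        assert res.rss == pytest.approx(0.0, abs=1e-16)

    def test_single_point_insufficient(self):
        with pytest.raises(InsufficientDataError):
            fit_monoexp(tac([4.0], [90.0]))

    def test_non_decaying_flagged(self):
        res = fit_monoexp(tac(T4, [10.0, 20.0, 30.0, 40.0]))
        assert res.warnings

    def test_noisy_tiac_bias_small(self):
        """100 replicates of 5% multiplicative noise: TIAC bias within 2%."""
        rng = np.random.default_rng(2024)
        truth = 2500.0 / A0
        tiacs = []
        clean = 50.0 * np.exp(-0.02 * T4)
        for _ in range(100):
            noisy = clean * (1.0 + 0.05 * rng.standard_normal(4))
            tiacs.append(fit_monoexp(tac(T4, np.clip(noisy, 1e-6, None))).tiac_h)
        assert abs(np.mean(tiacs) - truth) / truth <= 0.02


class TestBiexp:
    def test_noiseless_recovery(self):
        """30 e^-0.1t + 20 e^-0.005t at 4 points: parameters and TIA ~exact."""
        y = 30.0 * np.exp(-0.1 * T4) + 20.0 * np.exp(-0.005 * T4)
        res = fit_biexp(tac(T4, y))
        assert res.parameters["A1_MBq"] == pytest.approx(30.0, rel=1e-4)
        assert res.parameters["lambda1_per_h"] == pytest.approx(0.1, rel=1e-4)
        assert res.parameters["A2_MBq"] == pytest.approx(20.0, rel=1e-4)
        assert res.parameters["lambda2_per_h"] == pytest.approx(0.005, rel=1e-4)
        assert res.tia_MBqh == pytest.approx(4300.0, rel=1e-4)
        assert res.converged

    def test_degenerate_single_rate_matches_monoexp(self):
        y = 50.0 * np.exp(-0.02 * T4)
        bi = fit_biexp(tac(T4, y))
        mono = fit_monoexp(tac(T4, y))
        assert bi.tia_MBqh == pytest.approx(mono.tia_MBqh, rel=1e-4)

    def test_three_points_insufficient(self):
        with pytest.raises(InsufficientDataError):
            fit_biexp(tac([4.0, 24.0, 72.0], [90.0, 70.0, 40.0]))

    def test_noisy_median_tia_within_5_percent(self):
        """2% Gaussian noise, 100 seeded replicates: median TIA error < 5%."""
        rng = np.random.default_rng(7)
        clean = 30.0 * np.exp(-0.1 * T4) + 20.0 * np.exp(-0.005 * T4)
        tias = []
        for _ in range(100):
            noisy = clean * (1.0 + 0.02 * rng.standard_normal(4))
            tias.append(fit_biexp(tac(T4, np.clip(noisy, 1e-6, None))).tia_MBqh)
        assert abs(np.median(tias) - 4300.0) / 4300.0 <= 0.05


class TestPowerexp:
    def test_nests_monoexp(self):
        """b=0, d=1 reduces to A e^-ct; TIA matches A/c."""
        y = 40.0 * np.exp(-0.03 * T4)
        res = fit_powerexp(tac(T4, y))
        assert res.tia_MBqh == pytest.approx(40.0 / 0.03, rel=1e-6)

    def test_parameter_recovery(self):
        y = 5.0 * np.power(T4, 0.5) * np.exp(-0.05 * T4)
        res = fit_powerexp(tac(T4, y))
        assert res.parameters["A"] == pytest.approx(5.0, rel=1e-3)
        assert res.parameters["b"] == pytest.approx(0.5, rel=1e-3)
        assert res.parameters["c_per_h"] == pytest.approx(0.05, rel=1e-3)
        assert res.parameters["d"] == pytest.approx(1.0, rel=1e-3)

    def test_tia_matches_quadrature_oracle(self):
        y = 5.0 * np.power(T4, 0.5) * np.exp(-0.05 * T4)
        res = fit_powerexp(tac(T4, y))
        a, b, c, d = (res.parameters[k] for k in ("A", "b", "c_per_h", "d"))
        # brute-force fine-grid quadrature on a log-spaced grid
        grid = np.logspace(-8, 3.5, 400_000)
        vals = a * grid ** b * np.exp(-c * grid ** d)
        oracle = np.trapezoid(vals, grid)
        assert res.tia_MBqh == pytest.approx(float(oracle), rel=1e-6)


class TestTrapezoidTail:
    def test_worked_four_point_curve(self, worked_tac):
        """Hand quadrature: 180 + 1600 + 2640 + 3000 + A_last/lambda_phys."""
        res = integrate_trapezoid_tail(worked_tac, head_rule="zero_line")
        tail = 10.0 / LU177_LAMBDA_PHYS_PER_H
        assert res.parameters["head_MBqh"] == pytest.approx(180.0, abs=1e-12)
        assert res.parameters["body_MBqh"] == pytest.approx(1600.0 + 2640.0 + 3000.0, abs=1e-9)
        assert res.tia_MBqh == pytest.approx(180.0 + 7240.0 + tail, rel=1e-12)
        assert res.tiac_h == pytest.approx(res.tia_MBqh / 7200.0, rel=1e-15)
        assert res.tiac_h == pytest.approx(1.350, abs=5e-4)

    def test_trapezoid_part_matches_piecewise_linear_oracle(self, worked_tac):
        """Independent oracle: dense piecewise-linear resampling + trapezoid."""
        t, y = worked_tac.times_h, worked_tac.activities_MBq
        grid = np.unique(np.concatenate([np.linspace(t[0], t[-1], 5000), t]))
        oracle = np.trapezoid(np.interp(grid, t, y), grid)
        res = integrate_trapezoid_tail(worked_tac)
        assert res.parameters["body_MBqh"] == pytest.approx(float(oracle), rel=1e-12)

    def test_constant_head_adds_half_t1_a1(self, worked_tac):
        zl = integrate_trapezoid_tail(worked_tac, head_rule="zero_line")
        ct = integrate_trapezoid_tail(worked_tac, head_rule="constant")
        assert ct.tia_MBqh - zl.tia_MBqh == pytest.approx(180.0, abs=1e-10)

    def test_single_point_closed_form(self):
        res = integrate_trapezoid_tail(
            tac([4.0], [100.0]), head_rule="constant", tail_rate_per_h=0.01
        )
        assert res.tia_MBqh == pytest.approx(400.0 + 100.0 / 0.01, rel=1e-12)

    def test_tail_equals_closed_form(self, worked_tac):
        res = integrate_trapezoid_tail(worked_tac, tail_rate_per_h=0.004)
        assert res.parameters["tail_MBqh"] == pytest.approx(10.0 / 0.004, rel=1e-15)


class TestLimitAgreement:
    def test_all_routes_converge_for_monoexp_truth(self):
        """monoexp fit, powerexp fit and fine trapezoid agree with A/lambda."""
        a_true, lam = 50.0, 0.02
        truth = a_true / lam
        y4 = a_true * np.exp(-lam * T4)
        assert fit_monoexp(tac(T4, y4)).tia_MBqh == pytest.approx(truth, rel=1e-3)
        assert fit_powerexp(tac(T4, y4)).tia_MBqh == pytest.approx(truth, rel=1e-3)
        t_fine = np.arange(0.1, 600.0, 0.1)
        fine = integrate_trapezoid_tail(
            tac(t_fine, a_true * np.exp(-lam * t_fine)),
            head_rule="constant",
            tail_rate_per_h=lam,
        )
        assert fine.tia_MBqh == pytest.approx(truth, rel=1e-3)


class TestGoodness:
    def test_spearman_one_for_exact_monotone_fit(self):
        res = fit_monoexp(tac(T4, 50.0 * np.exp(-0.02 * T4)))
        assert res.goodness_spearman == pytest.approx(1.0)
        trap = integrate_trapezoid_tail(tac(T4, [90.0, 70.0, 40.0, 10.0]))
        assert trap.goodness_spearman == pytest.approx(1.0)


class TestAutoSelect:
    def test_pure_monoexp_prefers_monoexp(self):
        res = auto_select(tac(T4, 50.0 * np.exp(-0.02 * T4)))
        assert res.model.family == "monoexp"

    def test_biphasic_prefers_biexp(self):
        y = 60.0 * np.exp(-0.5 * T4) + 20.0 * np.exp(-0.005 * T4)
        res = auto_select(tac(T4, y))
        assert res.model.family == "biexp"
        assert res.tia_MBqh == pytest.approx(60.0 / 0.5 + 20.0 / 0.005, rel=1e-3)

    def test_single_point_falls_back_to_trapezoid(self):
        res = auto_select(tac([4.0], [90.0]))
        assert res.model.family == "trapezoid_tail"
        assert res.warnings

    def test_criterion_comparison_is_reproducible(self):
        from dosekit.kinetics import _criterion

        y = 50.0 * np.exp(-0.02 * T4)
        mono = fit_monoexp(tac(T4, y))
        bi = fit_biexp(tac(T4, y))
        assert _criterion(mono) < _criterion(bi)


class TestVoxelTiaMap:
    def test_matches_organ_level_trapezoid(self):
        from dosekit import ImageVolume

        rng = np.random.default_rng(5)
        base = rng.random((4, 4, 4)) + 0.5
        vols = [
            ImageVolume(base * math.exp(-0.02 * t), (4.42,) * 3, "activity_MBq", t)
            for t in T4
        ]
        tia = voxel_tia_map(vols, head_rule="zero_line", tail_rate_per_h=0.004)
        i, j, k = 1, 2, 3
        one = integrate_trapezoid_tail(
            tac(T4, [v.data[i, j, k] for v in vols], a0=1.0),
            head_rule="zero_line",
            tail_rate_per_h=0.004,
        )
        assert tia.data[i, j, k] == pytest.approx(one.tia_MBqh, rel=1e-12)
        assert tia.kind == "TIA_MBqh"
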