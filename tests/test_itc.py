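"""Unit and property tests for the ITC module."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bindspec import itc
from conftest import ANS_WEAK, CAM1TNC_SEQ, CAM_ONE_SET


# ---------------------------------------------------------------------------
# Injection bookkeeping
# ---------------------------------------------------------------------------

class TestConcentrations:
    def test_no_injection_limit(self, peptide_schedule):
        sched = peptide_schedule
        m1, l1 = itc.concentrations_after_injection(sched, 1)
        # after one 10 uL injection into 1.4 mL, dilution is sub-1%
        assert m1 == pytest.approx(30e-6, rel=0.01)
        assert l1 == pytest.approx(1e-3 * 10e-6 / 1.4e-3, rel=0.01)

    def test_hand_evaluated_displacement(self):
        sched = itc.TitrationSchedule(1.4e-3, 30e-6, 1e-3, (10e-6,) * 10)
        v = 10 * 10e-6
        m, l = itc.concentrations_after_injection(sched, 10)
        denom = 1 + v / (2 * 1.4e-3)
        assert m == pytest.approx(30e-6 * (1 - v / (2 * 1.4e-3)) / denom, rel=1e-12)
        assert l == pytest.approx(1e-3 * (v / 1.4e-3) / denom, rel=1e-12)

    def test_series_matches_scalar(self, peptide_schedule):
        m, l = itc.concentration_series(peptide_schedule)
        for i in (1, 12, 25):
            mi, li = itc.concentrations_after_injection(peptide_schedule, i)
            assert m[i - 1] == pytest.approx(mi, rel=1e-14)
            assert l[i - 1] == pytest.approx(li, rel=1e-14)

    def test_out_of_range_rejected(self, peptide_schedule):
        with pytest.raises(IndexError):
            itc.concentrations_after_injection(peptide_schedule, 0)
        with pytest.raises(IndexError):
            itc.concentrations_after_injection(peptide_schedule, 26)


# ---------------------------------------------------------------------------
# Heat models
# ---------------------------------------------------------------------------

class TestHeatModels:
    def test_one_set_zero_ligand(self):
        assert itc.total_heat_one_set(30e-6, 0.0, 2.0, 1e6, -5.0, 1.4e-3) == 0.0

    def test_one_set_saturation_limit(self):
        q = itc.total_heat_one_set(30e-6, 1.0, 2.0, 1e6, -5.0, 1.4e-3)
        q_max = 2.0 * 30e-6 * -5.0 * 1.4e-3 * 1e9
        assert q == pytest.approx(q_max, rel=1e-3)

    def test_sequential_zero_and_saturation(self):
        assert itc.total_heat_sequential(30e-6, 0.0, 1e6, -5.0, 1e4, -3.0, 1.4e-3) == 0.0
        q = itc.total_heat_sequential(30e-6, 10.0, 1e6, -5.0, 1e4, -3.0, 1.4e-3)
        q_max = 30e-6 * 1.4e-3 * (-8.0) * 1e9
        assert q == pytest.approx(q_max, rel=1e-3)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(k=st.floats(1e3, 1e8), dh=st.floats(-10.0, -0.5),
           m=st.floats(1e-6, 1e-4), l=st.floats(1e-7, 1e-3))
    def test_statistical_factor_equivalence(self, k, dh, m, l):
        """One-set N=2 equals sequential (2k, k/2) with equal step enthalpies.

        The macroscopic constants of two identical independent sites carry
        statistical factors 2k and k/2; this links the two models through an
        entirely different code path (closed-form quadratic vs mass-balance
        solver + binding polynomial).
        """
        q1 = itc.total_heat_one_set(m, l, 2.0, k, dh, 1.4e-3)
        lf = itc.free_ligand_sequential(m, l, 2.0 * k, k / 2.0)
        q2 = itc.total_heat_sequential(m, lf, 2.0 * k, dh, k / 2.0, dh, 1.4e-3)
        assert q2 == pytest.approx(q1, rel=1e-9, abs=1e-12)


class TestFreeLigand:
    def test_no_macromolecule(self):
        assert itc.free_ligand_sequential(0.0, 1e-4, 1e6, 1e4) == 1e-4

    def test_k2_zero_reduces_to_single_site_quadratic(self):
        m, l, k = 30e-6, 4e-5, 8e5
        lf = itc.free_ligand_sequential(m, l, k, 0.0)
        # closed-form free ligand for one site: roots of K L^2 + (1 + K(M-Lt)) L - Lt = 0
        a, b, c = k, 1 + k * (m - l), -l
        lf_exact = (-b + math.sqrt(b * b - 4 * a * c)) / (2 * a)
        assert lf == pytest.approx(lf_exact, rel=1e-10)

    @pytest.mark.parametrize("m,l,k1,k2", [
        (30e-6, 2e-5, 7.57e5, 1.7e4),
        (30e-6, 1.5e-4, 7.57e5, 1.7e4),
        (5e-5, 1e-3, 2.1e3, 1e2),
        (1e-4, 1e-6, 1e8, 1e6),
    ])
    def test_against_grid_search_oracle(self, m, l, k1, k2):
        """Mass balance agrees with a dense brute-force grid search over L."""
        lf = itc.free_ligand_sequential(m, l, k1, k2)

        def total(L):
            p = 1 + k1 * L + k1 * k2 * L * L
            return L + m * (k1 * L + 2 * k1 * k2 * L * L) / p

        grid = np.linspace(0, l, 2_000_001)
        best = grid[np.argmin(np.abs(total(grid) - l))]
        assert lf == pytest.approx(best, abs=l / 1e6)  # grid spacing l/2e6
        # residual tolerance is much tighter than the grid
        assert abs(total(lf) - l) < 1e-12 * max(l, 1e-12)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(m=st.floats(1e-6, 1e-3), lo=st.floats(1e-8, 1e-3),
           frac=st.floats(0.1, 0.9), k1=st.floats(1e2, 1e8),
           r=st.floats(1e-4, 1.0))
    def test_monotone_in_total_ligand(self, m, lo, frac, k1, r):
        hi = lo * (1 + frac)
        k2 = k1 * r
        assert itc.free_ligand_sequential(m, hi, k1, k2) > \
            itc.free_ligand_sequential(m, lo, k1, k2)


class TestHeatPerInjection:
    def test_zero_volume_is_simple_difference(self):
        q = np.array([1.0, 3.0, 4.0])
        dv = np.array([1e-9, 1e-9, 1e-9])  # negligible
        dq = itc.heat_per_injection(q, dv, 1.4e-3)
        assert dq == pytest.approx([1.0, 2.0, 1.0], abs=1e-5)

    def test_constant_q_gives_displacement_term(self):
        q = np.array([7.0, 7.0, 7.0])
        dv = np.array([10e-6] * 3)
        dq = itc.heat_per_injection(q, dv, 1.4e-3)
        # first injection: Q0=0 -> dq = Q + dv/V0 * Q/2
        assert dq[1] == pytest.approx((10e-6 / 1.4e-3) * 7.0, rel=1e-12)
        assert dq[2] == pytest.approx((10e-6 / 1.4e-3) * 7.0, rel=1e-12)

    def test_heat_conservation_small_injection_limit(self, cam_model):
        """Sum of per-injection heats converges to the final heat content."""
        total_v = 100e-6
        errs = []
        for n in (10, 100, 1000):
            sched = itc.TitrationSchedule(1.4e-3, 30e-6, 1e-3,
                                          (total_v / n,) * n)
            m, l = itc.concentration_series(sched)
            q = itc.total_heat_one_set(m, l, cam_model.n_sites, cam_model.k_a,
                                       cam_model.dh, 1.4e-3)
            # without the displacement term the plain telescoping sum is Q_n
            dq = q - np.concatenate(([0.0], q[:-1]))
            errs.append(abs(dq.sum() - q[-1]))
        assert max(errs) < 1e-9


# ---------------------------------------------------------------------------
# Corrections and fitting
# ---------------------------------------------------------------------------

class TestDilutionCorrect:
    def test_zero_and_constant_blank(self, peptide_schedule, cam_model):
        tg = itc.model_thermogram(peptide_schedule, cam_model)
        zero = itc.Thermogram(np.zeros(25), tg.molar_ratios, peptide_schedule)
        assert itc.dilution_correct(tg, zero).heats_ucal == pytest.approx(tg.heats_ucal)
        const = itc.Thermogram(np.full(25, -0.5), tg.molar_ratios, peptide_schedule)
        assert itc.dilution_correct(tg, const).heats_ucal == \
            pytest.approx(tg.heats_ucal + 0.5)

    def test_mismatched_schedule_rejected(self, peptide_schedule, cam_model):
        tg = itc.model_thermogram(peptide_schedule, cam_model)
        other = itc.TitrationSchedule(1.4e-3, 30e-6, 1e-3, (10e-6,) * 10)
        blank = itc.model_thermogram(other, cam_model)
        with pytest.raises(ValueError):
            itc.dilution_correct(tg, blank)


class TestFitIsotherm:
    def test_one_set_noiseless_round_trip(self, peptide_schedule, cam_model):
        tg = itc.model_thermogram(peptide_schedule, cam_model)
        fit = itc.fit_isotherm(tg, itc.ONE_SET)
        assert fit.model.n_sites == pytest.approx(CAM_ONE_SET["n_sites"], rel=1e-4)
        assert fit.model.k_a == pytest.approx(CAM_ONE_SET["k_a"], rel=1e-4)
        assert fit.model.dh == pytest.approx(CAM_ONE_SET["dh"], rel=1e-4)

    def test_sequential_noiseless_round_trip(self, peptide_schedule, seq_model):
        tg = itc.model_thermogram(peptide_schedule, seq_model)
        fit = itc.fit_isotherm(tg, itc.SEQUENTIAL)
        assert fit.model.k_a1 == pytest.approx(CAM1TNC_SEQ["k_a1"], rel=1e-4)
        assert fit.model.k_a2 == pytest.approx(CAM1TNC_SEQ["k_a2"], rel=1e-4)
        assert fit.model.k_a1 >= fit.model.k_a2

    def test_weak_binding_low_noise_recovery(self, ans_schedule):
        """Incomplete-saturation regime (c ~ 0.5) still recovers K within 5%."""
        truth = itc.BindingModel.one_set(**ANS_WEAK)
        tg = itc.model_thermogram(ans_schedule, truth)
        rng = np.random.default_rng(7)
        noisy = itc.Thermogram(tg.heats_ucal + rng.normal(0, 0.05, len(tg.heats_ucal)),
                               tg.molar_ratios, ans_schedule)
        fit = itc.fit_isotherm(noisy, itc.ONE_SET, sigma_ucal=0.05)
        assert fit.model.k_a == pytest.approx(ANS_WEAK["k_a"], rel=0.05)

    def test_too_few_injections_rejected(self, cam_model):
        sched = itc.TitrationSchedule(1.4e-3, 30e-6, 1e-3, (10e-6,) * 5)
        tg = itc.model_thermogram(sched, cam_model)
        with pytest.raises(ValueError, match="6 informative"):
            itc.fit_isotherm(tg, itc.ONE_SET)

    def test_ci_coverage_near_nominal(self, peptide_schedule, cam_model):
        """95% asymptotic CIs cover the generating dH at about nominal rate."""
        tg0 = itc.model_thermogram(peptide_schedule, cam_model)
        rng = np.random.default_rng(11)
        hits = 0
        n_rep = 200
        for _ in range(n_rep):
            noisy = itc.Thermogram(
                tg0.heats_ucal + rng.normal(0, 0.2, len(tg0.heats_ucal)),
                tg0.molar_ratios, peptide_schedule)
            fit = itc.fit_isotherm(noisy, itc.ONE_SET, initial_guess=cam_model,
                                   sigma_ucal=0.2)
            se = fit.stderr["dh"]
            if se and abs(fit.model.dh - cam_model.dh) < 1.96 * se:
                hits += 1
        assert 0.88 <= hits / n_rep <= 0.99


# ---------------------------------------------------------------------------
# Thermodynamic linkage
# ---------------------------------------------------------------------------

class TestThermo:
    def test_cam_orai_entropy(self):
        state = itc.thermo_derive(8.92e5, -5.02, 298.15)
        assert round(state.ds_cal) == 10

    def test_unit_k_gives_zero_dg(self):
        state = itc.thermo_derive(1.0, -3.0, 300.0)
        assert state.dg_kcal == 0.0
        assert state.ds_cal == pytest.approx(-3.0 / 300.0 * 1000.0)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(k=st.floats(1e-3, 1e12), dh=st.floats(-50, 50),
           t=st.floats(270, 330))
    def test_linkage_identity(self, k, dh, t):
        s = itc.thermo_derive(k, dh, t)
        assert s.dg_kcal == pytest.approx(s.dh_kcal - t * s.ds_cal / 1000.0,
                                          rel=1e-9, abs=1e-9)


class TestBufferIonization:
    def test_no_protonation(self):
        out = itc.buffer_ionization_decompose([-5.0, -5.0, -5.0], [0.0, -11.0, 5.0])
        assert out["n_protons"] == pytest.approx(0.0, abs=1e-12)
        assert out["dh_b"] == pytest.approx(-5.0)

    def test_two_buffer_exact_solve(self):
        out = itc.buffer_ionization_decompose([-5.0, -16.0], [0.0, -11.0])
        assert out["n_protons"] == pytest.approx(1.0)
        assert out["dh_b"] == pytest.approx(-5.0)

    def test_three_buffers_matches_ols(self, rng):
        x = np.array([0.0, -5.0, -11.0])
        y = -4.0 + 0.7 * x + rng.normal(0, 0.05, 3)
        out = itc.buffer_ionization_decompose(y, x)
        slope, intercept = np.polyfit(x, y, 1)
        assert out["n_protons"] == pytest.approx(slope)
        assert out["dh_b"] == pytest.approx(intercept)

    def test_identical_buffers_rejected(self):
        with pytest.raises(ValueError):
            itc.buffer_ionization_decompose([-5.0, -6.0], [0.0, 0.0])
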