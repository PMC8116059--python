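"""Dimerization thermodynamics: binomial labeling statistics, the isotherm
against a mass-action oracle, F_Dimer estimation, and the titration fits."""

import numpy as np
import pytest
from scipy.optimize import brentq

from memsolv import thermo
from memsolv.thermo import (ControlBasis, StepDistribution,
                            expected_label_distribution, fit_fraction_dimer)


class TestLabelDistribution:
    @pytest.mark.parametrize("p,n,expect", [
        (1.0, 2, (0.0, 1.0, 0.0)),
        (0.3, 1, (1.0, 0.0, 0.0)),
        # direct binomial arithmetic at the wild-type labeling yield:
        # q=0.337, P1 = 2pq/(1-q^2), P2 = p^2/(1-q^2)
        (0.663, 2, (0.5041, 0.4959, 0.0)),
    ])
    def test_closed_forms(self, p, n, expect):
        d = expected_label_distribution(p, n)
        assert d.as_array() == pytest.approx(expect, abs=5e-5)

    def test_normalization_and_trimer_tail(self):
        d = expected_label_distribution(0.4, 5)
        assert d.p1 + d.p2 + d.p3plus == pytest.approx(1.0, abs=1e-12)
        assert d.p3plus > 0

    def test_p1_p2_crossover_at_two_thirds(self):
        d = expected_label_distribution(2 / 3, 2)
        assert d.p1 == pytest.approx(d.p2, abs=1e-12)
        assert expected_label_distribution(2 / 3 - 1e-6, 2).p1 > \
            expected_label_distribution(2 / 3 - 1e-6, 2).p2
        assert expected_label_distribution(2 / 3 + 1e-6, 2).p1 < \
            expected_label_distribution(2 / 3 + 1e-6, 2).p2

    def test_zero_labeling_rejected(self):
        with pytest.raises(ValueError, match="unobservable"):
            expected_label_distribution(0.0, 2)


def wt_basis():
    return ControlBasis(expected_label_distribution(0.663, 1),
                        expected_label_distribution(0.663, 2))


class TestFractionDimer:
    def test_controls_map_to_endpoints(self):
        b = wt_basis()
        assert fit_fraction_dimer(b.dimer, b).f_dimer == pytest.approx(1.0, abs=1e-12)
        assert fit_fraction_dimer(b.monomer, b).f_dimer == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("f", [0.05, 0.3, 0.77])
    def test_exact_on_noiseless_mixtures(self, f):
        b = wt_basis()
        mix = f * b.dimer.as_array() + (1 - f) * b.monomer.as_array()
        obs = StepDistribution(*mix)
        fit = fit_fraction_dimer(obs, b)
        assert fit.f_dimer == pytest.approx(f, abs=1e-9)
        assert fit.se == pytest.approx(0.0, abs=1e-9)
        assert not fit.clipped

    def test_permutation_equivariance(self):
        b = wt_basis()
        mix = 0.3 * b.dimer.as_array() + 0.7 * b.monomer.as_array()
        for perm in [(1, 0, 2), (2, 1, 0)]:
            bp = ControlBasis(StepDistribution(*b.monomer.as_array()[list(perm)]),
                              StepDistribution(*b.dimer.as_array()[list(perm)]))
            fp = fit_fraction_dimer(StepDistribution(*mix[list(perm)]), bp)
            assert fp.f_dimer == pytest.approx(0.3, abs=1e-9)

    def test_identical_basis_rejected(self):
        d = expected_label_distribution(0.5, 2)
        with pytest.raises(ValueError, match="unidentifiable"):
            ControlBasis(d, d)

    def test_out_of_segment_observation_clips(self):
        b = wt_basis()
        obs = StepDistribution(0.0, 0.2, 0.8)  # beyond the dimer control
        fit = fit_fraction_dimer(obs, b)
        assert fit.clipped and fit.f_dimer in (0.0, 1.0)


class TestIsotherm:
    def test_half_saturation_exact(self):
        assert thermo.isotherm(1.0, 1.0) == pytest.approx(0.5, abs=1e-15)

    def test_small_x_limit(self):
        x = 1e-12
        assert thermo.isotherm(x, 1.0) == pytest.approx(2 * x, rel=1e-9)

    def test_paper_scale_point(self):
        # Keq = 1/K_D at K_D = 2.5e-8 with chi* = 5e-7
        assert thermo.isotherm(4e7, 5e-7) == pytest.approx(0.8539, abs=5e-5)

    def test_matches_mass_action_oracle_over_12_decades(self):
        x = np.logspace(-6, 6, 121)
        f_iso = thermo.isotherm(x, 1.0)
        f_ma = np.array([thermo.mass_action_dimer_fraction(xi, 1.0) for xi in x])
        assert np.max(np.abs(f_iso - f_ma) / f_ma) < 1e-10
        assert (np.diff(f_iso) > 0).all()  # monotone in Keq*chi*

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            thermo.isotherm(-1.0, 1.0)
        with pytest.raises(ValueError):
            thermo.isotherm(1.0, 0.0)

    def test_single_point_inversion_vs_numeric(self):
        chi_star = 5e-7
        for f in (0.1, 0.5, 0.9):
            keq = thermo.invert_isotherm(f, chi_star)
            keq_num = brentq(lambda k: thermo.isotherm(k, chi_star) - f,
                             1e-3 / chi_star * f, 1e9 / chi_star)
            assert keq == pytest.approx(keq_num, rel=1e-9)
            assert thermo.isotherm(keq, chi_star) == pytest.approx(f, rel=1e-12)


class TestFreeEnergy:
    def test_unity_keq_is_zero(self):
        assert thermo.free_energy(1.0) == 0.0

    def test_printed_kd_conversion(self):
        # K_D = 4.2e-6 subunits/lipid at 298.15 K
        dg = thermo.free_energy(1 / 4.2e-6)
        assert dg == pytest.approx(-7.34, abs=0.005)

    def test_round_trip_bijection(self):
        for keq in (1e-3, 1.0, 4e7):
            dg = thermo.free_energy(keq)
            assert thermo.keq_from_free_energy(dg) == pytest.approx(keq, rel=1e-12)
        assert thermo.free_energy(1e8) < thermo.free_energy(1e6)  # decreasing

    def test_ddg_between_printed_states(self):
        ddg, se = thermo.delta_delta_g(-7.4, -10.9, 0.2, 0.1)
        assert ddg == pytest.approx(3.5)
        assert se == pytest.approx(np.hypot(0.2, 0.1))

    def test_invalid_temperature(self):
        with pytest.raises(ValueError):
            thermo.free_energy(1.0, t=0.0)


class TestIsothermFit:
    def test_noiseless_self_consistency(self):
        keq = 1e6
        chi = np.logspace(-8, -5, 8)
        pts = np.column_stack([chi, thermo.isotherm(keq, chi)])
        fit = thermo.fit_isotherm(pts)
        assert np.log10(fit.keq) == pytest.approx(6.0, abs=1e-6)
        assert fit.dg == pytest.approx(thermo.free_energy(keq), abs=1e-5)
        assert fit.r_squared > 1 - 1e-9

    def test_noisy_recovery_median_within_03_kcal(self):
        keq = 4e7
        chi = np.logspace(-9, -6, 8)
        truth_dg = thermo.free_energy(keq)
        rng = np.random.default_rng(2024)
        errs = []
        for _ in range(30):
            f = np.clip(thermo.isotherm(keq, chi) + rng.normal(0, 0.05, chi.size),
                        1e-4, 1 - 1e-4)
            fit = thermo.fit_isotherm(np.column_stack([chi, f, np.full(8, 0.05)]))
            errs.append(abs(fit.dg - truth_dg))
        assert np.median(errs) < 0.3

    def test_saturated_data_flagged_lower_limit(self):
        keq = 1e9
        chi = np.logspace(-7, -5, 6)
        pts = np.column_stack([chi, thermo.isotherm(keq, chi)])
        fit = thermo.fit_isotherm(pts)
        assert fit.lower_limit_only

    def test_degenerate_points_rejected(self):
        with pytest.raises(ValueError):
            thermo.fit_isotherm([(1e-6, 0.5)])
        with pytest.raises(ValueError, match="unidentifiable"):
            thermo.fit_isotherm([(1e-7, 0.0), (1e-6, 0.0)])


class TestTitration:
    def test_single_model_exact_recovery(self):
        dl = np.array([0.0, 5.0, 10.0, 20.0, 40.0])
        f = 0.86 * np.exp(-0.13 * dl)
        fit = thermo.fit_titration(np.column_stack([dl, f]), "single")
        assert fit.params["lam"] == pytest.approx(0.13, rel=1e-6)
        assert fit.f0 == pytest.approx(0.86, rel=1e-6)
        assert fit.r_squared > 1 - 1e-9

    def test_two_phase_slow_rate_recovered(self):
        dl = np.array([1e-4, 1e-3, 1e-2, 0.1, 1.0, 5.0, 10.0, 20.0, 40.0])
        truth = 0.86 * (0.3 * np.exp(-50.0 * dl) + 0.7 * np.exp(-0.09 * dl))
        fit = thermo.fit_titration(np.column_stack([dl, truth]), "two-phase",
                                   f0_fixed=0.86)
        assert fit.params["lam2"] == pytest.approx(0.09, rel=0.05)
        assert fit.params["lam1"] > fit.params["lam2"]

    def test_single_fit_on_two_phase_data_has_larger_residual(self):
        dl = np.array([1e-4, 1e-3, 1e-2, 0.1, 1.0, 5.0, 10.0, 20.0, 40.0])
        truth = 0.86 * (0.3 * np.exp(-50.0 * dl) + 0.7 * np.exp(-0.09 * dl))
        pts = np.column_stack([dl, truth])
        single = thermo.fit_titration(pts, "single", f0_fixed=0.86)
        two = thermo.fit_titration(pts, "two-phase", f0_fixed=0.86)
        assert single.residual_sum > two.residual_sum * 10

    def test_f0_fixed_is_respected(self):
        dl = np.array([0.0, 1.0, 2.0, 4.0, 8.0])
        f = 0.7 * np.exp(-0.2 * dl)
        fit = thermo.fit_titration(np.column_stack([dl, f]), "single", f0_fixed=0.86)
        assert fit.f0 == 0.86


class TestLinearDDG:
    def test_exact_line(self):
        x = np.array([2.0, 5.0, 10.0, 20.0, 40.0])
        y = 1.65 + 0.078 * x
        fit = thermo.fit_linear_ddg(np.column_stack([x, y]))
        assert fit.slope == pytest.approx(0.078, rel=1e-9)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)
        assert fit.per_10pct_dl == pytest.approx(0.78, rel=1e-9)
        lo, hi = fit.ci95_slope
        assert lo <= fit.slope <= hi and hi - lo < 1e-6

    def test_log_abscissa(self):
        dl = np.logspace(-6, 0, 7)
        y = 1.61 + 0.135 * np.log10(dl)
        fit = thermo.fit_linear_ddg(np.column_stack([dl, y]), "log10_pct_dl")
        assert fit.slope == pytest.approx(0.135, rel=1e-9)

    def test_standard_errors_match_bootstrap(self):
        rng = np.random.default_rng(7)
        x = np.linspace(1, 40, 12)
        y = 1.5 + 0.08 * x + rng.normal(0, 0.2, 12)
        fit = thermo.fit_linear_ddg(np.column_stack([x, y]))
        # residual bootstrap oracle (leverage-corrected residual scale)
        n = len(x)
        coef = np.polyfit(x, y, 1)
        resid = y - np.polyval(coef, x)
        resid = resid * np.sqrt(n / (n - 2))
        slopes = np.empty(10_000)
        for b in range(10_000):
            yb = np.polyval(coef, x) + rng.choice(resid, n, replace=True)
            slopes[b] = np.polyfit(x, yb, 1)[0]
        assert fit.se_slope == pytest.approx(slopes.std(ddof=1), rel=0.10)

    def test_degenerate_abscissa_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            thermo.fit_linear_ddg([(5.0, 1.0), (5.0, 2.0), (5.0, 3.0)])
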