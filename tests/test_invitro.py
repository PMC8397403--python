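"""Unit tests for the mechanistic hepatocyte uptake model."""
import numpy as np
import pytest
from scipy.linalg import expm

from gadopbpk import invitro as iv
from gadopbpk.invitro import (InVitroState, backextrapolate_c0, cl_active_u,
                              fit_invitro, fraction_active,
                              linear_uptake_clearance, lysate_to_conc,
                              protein_to_cells, simulate_uptake)
from gadopbpk.params import InVitroKineticParams, ParameterError

from conftest import ANIMAL1_TRUTH, relative_error


class TestNormalization:
    @pytest.mark.parametrize("mg,cells", [(1.0, 1.0), (0.0, 0.0),
                                          (0.24, 0.24)])
    def test_protein_to_cells(self, mg, cells):
        assert protein_to_cells(mg) == pytest.approx(cells)

    def test_protein_negative_rejected(self):
        with pytest.raises(ParameterError):
            protein_to_cells(-0.1)

    @pytest.mark.parametrize("pmol,cells,expect",
                             [(390.0, 1.0, 100.0), (0.0, 1.0, 0.0),
                              (7.8, 0.24, 8.333333333)])
    def test_lysate_to_conc(self, pmol, cells, expect):
        assert lysate_to_conc(pmol, cells, 3.9) == pytest.approx(expect)

    def test_lysate_zero_cells(self):
        with pytest.raises(ZeroDivisionError):
            lysate_to_conc(1.0, 0.0)


class TestBackExtrapolation:
    def test_exact_line_recovers_intercept(self):
        t = np.array([1.0, 5.0, 10.0])
        assert backextrapolate_c0(t, 2 + 3 * t) == pytest.approx(2.0)

    def test_constant_profile(self):
        t = np.array([1.0, 5.0, 20.0])  # t = 20 included (<= cutoff)
        assert backextrapolate_c0(t, np.full(3, 4.0)) == pytest.approx(4.0)

    def test_matches_closed_form_ols(self):
        t = np.array([1.0, 5.0, 10.0])
        c = np.array([3.1, 11.2, 20.4])
        # hand OLS: b = Sxy/Sxx, a = mean(c) - b mean(t)
        b = np.sum((t - t.mean()) * (c - c.mean())) / np.sum(
            (t - t.mean()) ** 2)
        a = c.mean() - b * t.mean()
        assert backextrapolate_c0(t, c) == pytest.approx(a, rel=1e-12)

    def test_negative_intercept_clipped_with_warning(self):
        t = np.array([1.0, 2.0, 3.0])
        with pytest.warns(UserWarning):
            assert backextrapolate_c0(t, 2.0 * t - 1.0) == 0.0

    def test_insufficient_points(self):
        with pytest.raises(ValueError):
            backextrapolate_c0([1.0, 30.0], [1.0, 2.0])


class TestSimulateUptake:
    times = np.array([1.0, 5.0, 20.0, 60.0, 150.0])

    def test_passive_equilibrium(self):
        """Without transport and with fu = 1, cell and medium equilibrate."""
        p = InVitroKineticParams(Vmax=0.0, Km_u=100.0, CLpassive_u=5.0,
                                 fu_cell=1.0)
        s0 = InVitroState(0.0, 100.0)
        c_cell, c_med = simulate_uptake(p, s0, np.array([1000.0, 2000.0]),
                                        n_cells=0.24)
        assert c_cell[-1] == pytest.approx(c_med[-1], rel=1e-6)
        total = 0.24 * s0.V_cell * c_cell + s0.V_medium * c_med
        assert total == pytest.approx(s0.V_medium * 100.0, rel=1e-6)

    def test_t0_returns_initial_state(self):
        p = ANIMAL1_TRUTH
        s0 = InVitroState(5.0, 100.0)
        c_cell, c_med = simulate_uptake(p, s0, np.array([0.0]), 0.24)
        assert c_cell[0] == 5.0 and c_med[0] == 100.0

    def test_passive_only_matches_linear_ode_solution(self):
        """Vmax = 0 makes the system linear; matrix exponential oracle."""
        p = InVitroKineticParams(Vmax=1e-12, Km_u=100.0, CLpassive_u=0.5,
                                 fu_cell=0.7)
        n_cells = 0.24
        s0 = InVitroState(0.0, 300.0)
        A = np.array([[-p.CLpassive_u * p.fu_cell / s0.V_cell,
                       p.CLpassive_u / s0.V_cell],
                      [n_cells * p.CLpassive_u * p.fu_cell / s0.V_medium,
                       -n_cells * p.CLpassive_u / s0.V_medium]])
        c_cell, c_med = simulate_uptake(p, s0, self.times, n_cells)
        for i, t in enumerate(self.times):
            exact = expm(A * t) @ np.array([0.0, 300.0])
            assert c_cell[i] == pytest.approx(exact[0], rel=1e-6)
            assert c_med[i] == pytest.approx(exact[1], rel=1e-6)

    def test_mass_conservation(self):
        s0 = InVitroState(0.0, 500.0)
        c_cell, c_med = simulate_uptake(ANIMAL1_TRUTH, s0, self.times, 0.24)
        total = 0.24 * s0.V_cell * c_cell + s0.V_medium * c_med
        initial = s0.V_medium * 500.0
        assert np.max(np.abs(total - initial)) / initial < 1e-6

    def test_increasing_vmax_never_decreases_uptake(self):
        s0 = InVitroState(0.0, 100.0)
        lo = ANIMAL1_TRUTH
        hi = InVitroKineticParams(Vmax=2 * lo.Vmax, Km_u=lo.Km_u,
                                  CLpassive_u=lo.CLpassive_u,
                                  fu_cell=lo.fu_cell)
        c_lo, _ = simulate_uptake(lo, s0, self.times, 0.24)
        c_hi, _ = simulate_uptake(hi, s0, self.times, 0.24)
        assert np.all(c_hi >= c_lo - 1e-9)


class TestDerivedClearances:
    @pytest.mark.parametrize("vmax,km,expect", [(350.4, 114.1, 3.07),
                                                (221.7, 79.8, 2.78),
                                                (0.0, 50.0, 0.0)])
    def test_cl_active_u_table_values(self, vmax, km, expect):
        assert cl_active_u(vmax, km) == pytest.approx(expect, abs=0.005)

    @pytest.mark.parametrize("cla,clp,expect", [(3.07, 0.091, 0.97),
                                                (1.0, 0.0, 1.0),
                                                (0.4, 0.4, 0.5)])
    def test_fraction_active(self, cla, clp, expect):
        assert fraction_active(cla, clp) == pytest.approx(expect, abs=0.005)

    def test_fraction_active_undefined(self):
        with pytest.raises(ParameterError):
            fraction_active(0.0, 0.0)

    def test_fractions_sum_to_one(self):
        fa = fraction_active(3.07, 0.091)
        assert fa + (1 - fa) == 1.0


class TestLinearUptakeClearance:
    def test_forced_arithmetic(self):
        t = np.array([0.5, 1.0, 2.0])
        assert linear_uptake_clearance(10.0 * t, t, 1.0, 0.2) == \
            pytest.approx(50.0)

    def test_zero_slope(self):
        t = np.array([0.5, 1.0, 2.0])
        assert linear_uptake_clearance(np.full(3, 7.0), t, 1.0, 0.2) == \
            pytest.approx(0.0, abs=1e-12)

    def test_matches_ols_slope(self):
        t = np.array([0.5, 1.0, 2.0])
        a = np.array([4.9, 10.3, 19.6])
        slope = np.sum((t - t.mean()) * (a - a.mean())) / np.sum(
            (t - t.mean()) ** 2)
        assert linear_uptake_clearance(a, t, 0.24, 0.2) == \
            pytest.approx(slope / 0.24 / 0.2, rel=1e-12)

    def test_nonpositive_concentration(self):
        with pytest.raises(ParameterError):
            linear_uptake_clearance([1, 2], [1, 2], 1.0, 0.0)


class TestFit:
    def test_objective_near_zero_at_truth(self, invitro_noisefree):
        """Residuals evaluated at the generating parameters vanish."""
        table, truth = invitro_noisefree
        from gadopbpk.invitro import _predict_c_cell, lysate_to_conc, \
            protein_to_cells
        adata = table.copy()
        cells = protein_to_cells(adata["protein_mg"].to_numpy())
        adata["c_cell_obs"] = lysate_to_conc(
            adata["lysate_pmol"].to_numpy(), cells)
        sq = 0.0
        for _, g in adata.groupby("nominal_conc_uM"):
            pred = _predict_c_cell(truth, g, 3.9, 500.0, 0.24)
            sq += float(np.sum((pred - g["c_cell_obs"]) ** 2))
        scale = float(np.sum(adata["c_cell_obs"] ** 2))
        assert sq / scale < 1e-10

    def test_noisy_km_recovery_median_within_25pct(self, invitro_noisefree):
        """10% proportional noise, duplicate wells: Km,u is recovered with
        moderate error (median over seeds)."""
        from gadopbpk.synthetic import InVitroDesign, \
            generate_invitro_dataset
        errors = []
        for seed in range(5):
            design = InVitroDesign(noise_cv=0.1, seed=1000 + seed)
            table = generate_invitro_dataset(ANIMAL1_TRUTH, design)
            res = fit_invitro(table, n_starts=1)[1]
            errors.append(relative_error(res.params.Km_u,
                                         ANIMAL1_TRUTH.Km_u))
        assert np.median(errors) < 0.25
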