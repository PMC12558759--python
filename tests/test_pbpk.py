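import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from _oracles import bateman_amount, literal_rhs, rk4_simulate
from matrine_pbpk import (
    DoseEvent,
    DoseRegimen,
    SimulationError,
    mass_balance_residual,
    rhs,
    simulate,
)
from matrine_pbpk.pbpk import STATES, system_matrix


def closed_system(params):
    """No elimination, full absorption, no protein binding."""
    return params.replace(k_e=0.0, Cl_renal=0.0, Pb=0.0, F=1.0)


class TestRHS:
    def test_zero_state_gives_zero_derivative(self, opt_params):
        assert np.all(rhs(np.zeros(8), 0.0, opt_params) == 0.0)

    def test_single_biliary_term_moves_liver_to_lumen(self, opt_params):
        p = opt_params.replace(Qcar=0.0, k_st=0.0, k_a=0.0, k_e=0.0,
                               Cl_renal=0.0, k_bi=0.25)
        y = np.zeros(8)
        y[STATES.index("A_l")] = 1.0
        dy = rhs(y, 0.0, p)
        assert dy[STATES.index("A_int")] == pytest.approx(0.25)
        assert dy[STATES.index("A_l")] == pytest.approx(-0.25)
        assert np.all(np.delete(dy, [1, 2]) == 0.0)

    @pytest.mark.parametrize("f_mode", ["systemic_scale", "dose_scale"])
    @pytest.mark.parametrize("pb_mode", ["free_uptake", "verbatim"])
    def test_matches_literal_transcription(self, opt_params, f_mode, pb_mode):
        """Term-by-term transcription of the published balances agrees."""
        p = opt_params.replace(f_mode=f_mode, pb_mode=pb_mode)
        y = np.zeros(8)
        y[STATES.index("A_int")] = 1000.0
        np.testing.assert_allclose(rhs(y, 0.0, p), literal_rhs(y, p), rtol=1e-12)
        y = np.array([50.0, 1000.0, 120.0, 300.0, 40.0, 5.0, 8.0, 2.0])
        np.testing.assert_allclose(rhs(y, 0.0, p), literal_rhs(y, p), rtol=1e-12)

    def test_negative_state_rejected(self, opt_params):
        y = np.zeros(8)
        y[1] = -1.0
        with pytest.raises(ValueError, match="non-negative"):
            rhs(y, 0.0, opt_params)


class TestSimulate:
    def test_zero_dose_gives_zero_trajectories(self, opt_params, exp1_grid):
        res = simulate(opt_params, DoseRegimen.single_oral(0.0, 27.0), exp1_grid)
        assert np.all(res.amounts == 0.0)
        assert np.all(res.residual == 0.0)

    def test_closed_system_conserves_mass(self, opt_params, exp1_grid):
        p = closed_system(opt_params)
        reg = DoseRegimen.single_oral(40.0, 27.0)
        res = simulate(p, reg, exp1_grid)
        dose = 40.0 * 27.0 * 1000.0
        np.testing.assert_allclose(res.total_amount, dose, rtol=1e-3)

    def test_adaptive_matches_fixed_step_rk4(self, opt_params, regimen40, exp1_grid):
        """Independent RK4 at dt = 0.001 h agrees within 0.5% everywhere."""
        res = simulate(opt_params, regimen40, exp1_grid)
        oracle = rk4_simulate(opt_params, regimen40, exp1_grid, dt=0.001)
        c_oracle = oracle[:, STATES.index("A_int")] / opt_params.V_int
        np.testing.assert_allclose(res.c_int, c_oracle, rtol=5e-3)

    def test_expm_propagator_matches_lsoda(self, opt_params, regimen40, exp1_grid):
        a = simulate(opt_params, regimen40, exp1_grid, method="lsoda")
        b = simulate(opt_params, regimen40, exp1_grid, method="expm")
        np.testing.assert_allclose(a.c_int, b.c_int, rtol=1e-6)

    def test_linearity_in_dose(self, opt_params, exp1_grid):
        lo = simulate(opt_params, DoseRegimen.single_oral(40.0, 27.0), exp1_grid)
        hi = simulate(opt_params, DoseRegimen.single_oral(80.0, 27.0), exp1_grid)
        np.testing.assert_allclose(hi.c_int, 2.0 * lo.c_int, rtol=1e-6)

    def test_superposition_of_repeated_doses(self, opt_params):
        grid = np.arange(0.0, 48.0 + 1e-9, 0.5)
        multi = simulate(opt_params,
                         DoseRegimen.repeated(40.0, 27.0, 8.0, 3), grid)
        total = np.zeros_like(grid)
        for shift in (0.0, 8.0, 16.0):
            single = simulate(
                opt_params, DoseRegimen((DoseEvent(shift, 40.0),), 27.0), grid)
            total += single.c_int
        np.testing.assert_allclose(multi.c_int, total, rtol=1e-5)

    def test_bateman_limit(self, opt_params):
        """With absorption and biliary return off, the lumen follows the
        two-step first-order chain in closed form."""
        p = opt_params.replace(k_a=0.0, k_bi=0.0)
        reg = DoseRegimen.single_oral(40.0, 27.0)
        grid = np.arange(0.25, 48.0, 0.25)
        res = simulate(p, reg, grid, rtol=1e-11, atol=1e-12)
        dose = reg.total_administered_ug
        exact = bateman_amount(grid, dose, p.k_st, p.k_e)
        err = np.abs(res.amount("A_int") - exact) / np.maximum(exact, 1e-9 * dose)
        assert err.max() < 1e-6

    def test_dose_beyond_horizon_raises(self, opt_params):
        reg = DoseRegimen.from_events([(0.0, 40.0), (200.0, 40.0)], 27.0)
        with pytest.raises(SimulationError, match="horizon"):
            simulate(opt_params, reg, np.array([0.0, 120.0]))

    def test_unsorted_grid_rejected(self, opt_params, regimen40):
        with pytest.raises(ValueError, match="sorted"):
            simulate(opt_params, regimen40, np.array([0.0, 2.0, 1.0]))

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(dose=st.floats(0.0, 500.0),
           scale_ka=st.floats(0.1, 5.0),
           scale_kbi=st.floats(0.1, 5.0))
    def test_trajectories_never_negative(self, opt_params, dose, scale_ka, scale_kbi):
        p = opt_params.replace(k_a=opt_params.k_a * scale_ka,
                               k_bi=opt_params.k_bi * scale_kbi)
        grid = np.array([0.0, 0.5, 2.0, 8.0, 24.0, 72.0, 120.0])
        res = simulate(p, DoseRegimen.single_oral(dose, 27.0), grid, method="expm")
        assert res.amounts.min() >= 0.0


class TestMassBalance:
    def test_zero_dose_residual_is_zero(self, opt_params, exp1_grid):
        res = simulate(opt_params, DoseRegimen.single_oral(0.0, 27.0), exp1_grid)
        assert np.all(mass_balance_residual(res) == 0.0)

    def test_unbound_free_uptake_conserves_even_with_binding(
            self, opt_params, regimen40, exp1_grid):
        res = simulate(opt_params, regimen40, exp1_grid)
        dose = regimen40.total_administered_ug
        assert np.abs(res.residual).max() < 1e-3 * dose

    def test_verbatim_binding_residual_matches_quadrature(self, opt_params):
        """Under the printed equations the system gains mass at rate
        Q_tot·Ca·Pb; the audit residual must equal minus its integral."""
        p = opt_params.replace(pb_mode="verbatim")
        reg = DoseRegimen.single_oral(40.0, 27.0)
        grid = np.arange(0.0, 24.0 + 1e-9, 0.005)
        res = simulate(p, reg, grid, method="expm")
        ca = res.c_b
        gain_rate = p.Q_tot * ca * p.Pb
        integral = np.concatenate(
            ([0.0], np.cumsum(0.5 * (gain_rate[1:] + gain_rate[:-1]) * np.diff(grid))))
        residual = mass_balance_residual(res)
        assert integral[-1] > 1e-2 * reg.total_administered_ug  # audit is non-trivial
        # atol covers the trapezoid quadrature's own early-time curvature error
        np.testing.assert_allclose(residual, -integral,
                                   rtol=5e-3, atol=1e-5 * reg.total_administered_ug)


def test_output_frame_has_interchange_columns(opt_params, regimen40, exp1_grid):
    df = simulate(opt_params, regimen40, exp1_grid).to_frame()
    for col in ["time_h", "A_st", "A_int", "A_l", "A_ot", "A_b",
                "C_int_ug_per_kg", "C_b_ug_per_L", "residual"]:
        assert col in df.columns
    assert len(df) == exp1_grid.size


def test_system_matrix_columns_sum_to_elimination(opt_params):
    """Free-uptake mode: every column of the full matrix (compartments +
    sinks) sums to zero, i.e. mass only moves, never appears."""
    M = system_matrix(opt_params)
    np.testing.assert_allclose(M.sum(axis=0), 0.0, atol=1e-12)
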