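"""Independent reference implementations used only as test oracles.

Everything here is written directly from the governing equations or
textbook formulas, term by term, deliberately avoiding the package's own
code paths (and, for the statistics, scipy's test functions).
"""

import numpy as np
from scipy.stats import t as t_dist


def literal_rhs(y, p):
    """Term-by-term transcription of the published mass balances.

    ``y`` = (A_st, A_int, A_l, A_ot, A_b, A_feces, A_urine, A_unabs) in μg.
    Written in the concentration form of the published table and converted
    to amount derivatives at the end.
    """
    A_st, A_int, A_l, A_ot, A_b = y[:5]
    BW = p.BW
    Q_l = p.Qc_l * p.Qcar * BW
    Q_ot = p.Qc_ot * p.Qcar * BW
    Q_tot = Q_l + Q_ot
    V_int, V_l, V_ot, V_b = (p.Vc_int * BW, p.Vc_l * BW,
                             p.Vc_ot * BW, p.Vc_b * BW)
    Ca = A_b / V_b
    C_l = A_l / V_l
    C_ot = A_ot / V_ot
    fu_t = (1.0 - p.Pb) if p.pb_mode == "free_uptake" else 1.0
    f_abs = p.F if p.f_mode == "systemic_scale" else 1.0

    dA_st = -p.k_st * A_st
    # V_int dC_int/dt = depot·k_st + amount_l·k_bi − amount_int·k_a − amount_int·k_e
    dC_int = (A_st * p.k_st + A_l * p.k_bi
              - A_int * p.k_a - A_int * p.k_e) / V_int
    # V_l dC_l/dt = Q_l (Ca − C_l/P_l) − amount_l·k_bi
    dC_l = (Q_l * (fu_t * Ca - C_l / p.P_l) - A_l * p.k_bi) / V_l
    # V_ot dC_ot/dt = Q_ot (Ca − C_ot/P_ot) − Ca·Cl_renal
    dC_ot = (Q_ot * (fu_t * Ca - C_ot / p.P_ot)
             - fu_t * Ca * p.Cl_renal * BW) / V_ot
    # V_b dC_b/dt = amount_int·k_a + Q_l C_l/P_l + Q_ot C_ot/P_ot − Q_tot Ca (1−Pb)
    dC_b = (f_abs * A_int * p.k_a + Q_l * C_l / p.P_l + Q_ot * C_ot / p.P_ot
            - Q_tot * Ca * (1.0 - p.Pb)) / V_b

    dA_feces = p.k_e * A_int
    dA_urine = fu_t * Ca * p.Cl_renal * BW
    dA_unabs = (1.0 - p.F) * p.k_a * A_int if p.f_mode == "systemic_scale" else 0.0
    return np.array([dA_st, dC_int * V_int, dC_l * V_l, dC_ot * V_ot,
                     dC_b * V_b, dA_feces, dA_urine, dA_unabs])


def rk4_simulate(params, regimen, t_grid, dt=0.001):
    """Naive fixed-step classical Runge-Kutta integration.

    Dose events must fall on multiples of ``dt``; states are recorded at
    the grid times (which must also be multiples of ``dt``).
    """
    t_grid = np.asarray(t_grid, dtype=float)
    n_steps = int(round(t_grid[-1] / dt))
    dose_steps = {}
    for e in regimen.events:
        k = int(round(e.time_h / dt))
        assert abs(k * dt - e.time_h) < 1e-12
        dose_steps[k] = dose_steps.get(k, 0.0) + regimen.amount_ug(e)
    record_steps = {int(round(t / dt)): i for i, t in enumerate(t_grid)}
    for k, t in zip(record_steps, t_grid):
        assert abs(k * dt - t) < 1e-9

    y = np.zeros(8)
    out = np.empty((t_grid.size, 8))

    def apply_dose(y, amt):
        if params.f_mode == "dose_scale":
            y[0] += params.F * amt
            y[7] += (1.0 - params.F) * amt
        else:
            y[0] += amt

    for step in range(n_steps + 1):
        if step in dose_steps:
            apply_dose(y, dose_steps[step])
        if step in record_steps:
            out[record_steps[step]] = y
        if step == n_steps:
            break
        k1 = literal_rhs(y, params)
        k2 = literal_rhs(y + 0.5 * dt * k1, params)
        k3 = literal_rhs(y + 0.5 * dt * k2, params)
        k4 = literal_rhs(y + dt * k3, params)
        y = y + (dt / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
    return out


def bateman_amount(t, dose, k1, k2):
    """Two-step first-order chain: amount in the second pool."""
    t = np.asarray(t, dtype=float)
    if np.isclose(k1, k2):
        return dose * k1 * t * np.exp(-k1 * t)
    return dose * k1 / (k2 - k1) * (np.exp(-k1 * t) - np.exp(-k2 * t))


def pearson_r_formula(x, y):
    """Covariance-formula correlation and its two-sided t-based p."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = x.size
    xm, ym = x - x.mean(), y - y.mean()
    r = np.sum(xm * ym) / np.sqrt(np.sum(xm ** 2) * np.sum(ym ** 2))
    t = r * np.sqrt((n - 2) / (1.0 - r ** 2))
    p = 2.0 * t_dist.sf(abs(t), n - 2)
    return r, p


def one_sample_t_formula(values, mu0):
    v = np.asarray(values, float)
    n = v.size
    sd = np.sqrt(np.sum((v - v.mean()) ** 2) / (n - 1))
    t = (v.mean() - mu0) / (sd / np.sqrt(n))
    return t, n - 1, 2.0 * t_dist.sf(abs(t), n - 1)


def two_sample_t_formula(a, b):
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    na, nb = a.size, b.size
    sp2 = (np.sum((a - a.mean()) ** 2) + np.sum((b - b.mean()) ** 2)) / (na + nb - 2)
    t = (a.mean() - b.mean()) / np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
    df = na + nb - 2
    return t, df, 2.0 * t_dist.sf(abs(t), df)
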