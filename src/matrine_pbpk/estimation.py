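"""Parameter estimation and local sensitivity analysis.

Estimation minimizes a Gaussian negative log-likelihood with the residual
standard deviation profiled out analytically.  The default error model is
log-normal (additive Gaussian on log concentration), appropriate for
intestinal profiles spanning several orders of magnitude; an additive
model on the raw scale is available.  Optimization is derivative-free
Nelder–Mead in a logit-transformed space so that every fitted parameter
respects its biological plausibility bounds, with a small number of
seeded random restarts.  Subsets of parameters can be fitted with the
rest held fixed, mirroring batched optimization of the sensitive
parameters.

Sensitivity uses normalized sensitivity coefficients (NSC): each
parameter is perturbed by ±0.1% and the central-difference derivative of
the intestinal concentration is normalized by parameter value and
response value at each time slice,

    NSC_i(t) = [R(p_i(1+δ)) − R(p_i(1−δ))] / (2δ · R(p_i, t)).

A parameter is classified sensitive when max over time of |NSC| exceeds
0.1.  The balancing entries of the parameter table are kept consistent
during perturbation: Qc_ot complements Qc_l and Vc_ot absorbs changes of
the other fractional volumes, so perturbed sets always satisfy the flow
and volume constraints.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .dosing import DoseRegimen
from .nca import ConcentrationTimeProfile
from .parameters import FITTABLE_PARAMETERS, ModelParameters
from .pbpk import simulate
from .schedules import EXPERIMENT_1_SCHEDULE_H

__all__ = [
    "EstimationError",
    "FitSpec",
    "FitResult",
    "SensitivityReport",
    "negative_log_likelihood",
    "fit_nelder_mead",
    "sensitivity_nsc",
    "pooled_geometric_mean",
    "NSC_THRESHOLD",
    "SENSITIVITY_PARAMETERS",
    "PLAUSIBLE_BOUNDS",
]

NSC_THRESHOLD = 0.1

#: independently perturbable parameters; Qc_ot and Vc_ot are balancing
#: terms ("by calculation") and are adjusted, not perturbed
SENSITIVITY_PARAMETERS = (
    "Qcar", "PCV", "Qc_l", "Vc_int", "Vc_l", "Vc_b",
    "k_st", "k_a", "F", "P_l", "P_ot", "k_e", "k_bi", "Pb", "Cl_renal",
)

_PENALTY = 1e8

#: biological plausibility boxes used when no study-specific limits are
#: supplied: first-order rates within (0.001, 10)/h, fractions inside the
#: open unit interval, partition coefficients and clearance around the
#: literature span
PLAUSIBLE_BOUNDS: Mapping[str, tuple[float, float]] = {
    "Qcar": (0.5, 20.0),
    "PCV": (0.1, 0.6),
    "Qc_l": (0.05, 0.95),
    "Qc_ot": (0.05, 0.95),
    "Vc_int": (0.001, 0.1),
    "Vc_l": (0.005, 0.1),
    "Vc_b": (0.01, 0.15),
    "Vc_ot": (0.5, 0.99),
    "k_st": (0.001, 10.0),
    "k_a": (0.001, 10.0),
    "F": (0.01, 1.0),
    "P_l": (0.1, 50.0),
    "P_ot": (0.1, 50.0),
    "k_e": (1e-4, 1.0),
    "k_bi": (1e-4, 1.0),
    "Pb": (0.0, 0.99),
    "Cl_renal": (0.001, 5.0),
}


class EstimationError(ValueError):
    """Raised for invalid estimation inputs."""


def pooled_geometric_mean(
        profiles: Sequence[ConcentrationTimeProfile],
) -> tuple[np.ndarray, np.ndarray]:
    """Per-time geometric mean over subjects, ignoring censored points.

    All profiles must share one sampling schedule.  Times at which every
    subject is censored (or at zero) are dropped.
    """
    if not profiles:
        raise EstimationError("no profiles supplied")
    t0 = profiles[0].time
    logs = []
    for p in profiles:
        if p.time.shape != t0.shape or not np.allclose(p.time, t0):
            raise EstimationError("profiles must share one sampling schedule")
        with np.errstate(divide="ignore"):
            lc = np.where(p.censored | (p.conc <= 0), np.nan, np.log(p.conc))
        logs.append(lc)
    logs = np.vstack(logs)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        mean_log = np.nanmean(logs, axis=0)
    keep = np.isfinite(mean_log)
    return t0[keep], np.exp(mean_log[keep])


def _profiled_gaussian_nll(residuals: np.ndarray) -> float:
    """NLL of iid N(0, σ²) residuals with σ² at its MLE."""
    n = residuals.size
    s2 = float(np.mean(residuals ** 2))
    if s2 <= 0:
        s2 = 1e-300  # exact fit: likelihood unbounded; report a floor
    return 0.5 * n * (np.log(2.0 * np.pi * s2) + 1.0)


def negative_log_likelihood(
        params: ModelParameters,
        observed: Sequence[ConcentrationTimeProfile],
        regimen: DoseRegimen,
        error_model: str = "lognormal",
        pooling: str = "geomean",
        method: str = "expm",
) -> float:
    """Profiled Gaussian NLL of the model against observed profiles.

    ``pooling="geomean"`` fits the group geometric-mean profile (one
    simulation per evaluation); ``pooling="pooled"`` accumulates
    per-subject residuals, simulating each subject at its own body
    weight when the profile carries one.  Non-positive predictions at
    uncensored observations under the log-normal model yield a large
    finite penalty rather than NaN.
    """
    if error_model not in ("lognormal", "additive"):
        raise EstimationError("error_model must be 'lognormal' or 'additive'")
    if pooling not in ("geomean", "pooled"):
        raise EstimationError("pooling must be 'geomean' or 'pooled'")
    if not observed:
        raise EstimationError("observed profiles must be non-empty")

    def residuals_for(t_obs, c_obs):
        # body weight is a covariate: it follows the regimen/subject
        sim = simulate(params.replace(BW=reg.bw_kg), reg, t_obs, method=method)
        pred = sim.c_int
        if error_model == "lognormal":
            if np.any(pred <= 0):
                return None
            return np.log(c_obs) - np.log(pred)
        return c_obs - pred

    all_res = []
    if pooling == "geomean":
        t_obs, c_obs = pooled_geometric_mean(observed)
        reg = regimen
        r = residuals_for(t_obs, c_obs)
        if r is None:
            return _PENALTY
        all_res.append(r)
    else:
        for p in observed:
            keep = ~p.censored & (p.conc > 0)
            if not keep.any():
                continue
            bw = p.bw_kg if np.isfinite(p.bw_kg) else regimen.bw_kg
            reg = DoseRegimen(regimen.events, bw)
            r = residuals_for(p.time[keep], p.conc[keep])
            if r is None:
                return _PENALTY
            all_res.append(r)
        if not all_res:
            raise EstimationError("no usable (uncensored) observations")
    return _profiled_gaussian_nll(np.concatenate(all_res))


@dataclass(frozen=True)
class FitSpec:
    """What to fit, from where, against which data."""

    param_names: tuple[str, ...]
    bounds: Mapping[str, tuple[float, float]]
    start: ModelParameters
    observed: tuple[ConcentrationTimeProfile, ...]
    regimen: DoseRegimen
    error_model: str = "lognormal"
    pooling: str = "geomean"
    max_restarts: int = 3
    seed: int = 0
    maxfev: int = 4000

    def __post_init__(self) -> None:
        for name in self.param_names:
            if name not in FITTABLE_PARAMETERS:
                raise EstimationError(f"{name!r} is not a fittable parameter")
            if name not in self.bounds:
                raise EstimationError(f"missing bounds for {name!r}")
            lo, hi = self.bounds[name]
            if not (np.isfinite(lo) and np.isfinite(hi) and lo < hi):
                raise EstimationError(f"bounds for {name!r} must be finite and ordered")
            v = getattr(self.start, name)
            if not (lo <= v <= hi):
                raise EstimationError(
                    f"start value {v} for {name!r} outside bounds ({lo}, {hi})")


@dataclass(frozen=True)
class FitResult:
    params: ModelParameters
    nll: float
    converged: bool
    n_fev: int
    n_restarts: int
    fitted: dict[str, float] = field(default_factory=dict)

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame({
            "parameter": list(self.fitted),
            "estimate": list(self.fitted.values()),
        })


def _to_unconstrained(v, lo, hi):
    frac = np.clip((v - lo) / (hi - lo), 1e-12, 1 - 1e-12)
    return np.log(frac / (1 - frac))


def _from_unconstrained(x, lo, hi):
    return lo + (hi - lo) / (1.0 + np.exp(-x))


def fit_nelder_mead(spec: FitSpec) -> FitResult:
    """Bounded Nelder–Mead maximum-likelihood fit of ``spec.param_names``.

    Parameters are logit-transformed to their bounds, so no candidate
    ever leaves the plausibility box.  After the initial run, up to
    ``spec.max_restarts`` seeded restarts from perturbed incumbents keep
    the best solution; non-convergence is flagged, never raised.
    """
    names = spec.param_names
    lohi = [spec.bounds[n] for n in names]

    def assemble(x):
        changes = {n: float(_from_unconstrained(xi, lo, hi))
                   for n, xi, (lo, hi) in zip(names, x, lohi)}
        return spec.start.replace(**changes), changes

    def objective(x):
        params, _ = assemble(x)
        try:
            return negative_log_likelihood(
                params, spec.observed, spec.regimen,
                error_model=spec.error_model, pooling=spec.pooling)
        except FloatingPointError:  # pragma: no cover - defensive
            return _PENALTY

    x0 = np.array([_to_unconstrained(getattr(spec.start, n), lo, hi)
                   for n, (lo, hi) in zip(names, lohi)])
    rng = np.random.default_rng(spec.seed)
    opts = dict(xatol=1e-8, fatol=1e-10, maxfev=spec.maxfev, adaptive=len(names) > 2)

    best, n_fev, restarts = None, 0, 0
    start_x = x0
    for attempt in range(1 + max(0, spec.max_restarts)):
        res = minimize(objective, start_x, method="Nelder-Mead", options=opts)
        n_fev += res.nfev
        if best is None or res.fun < best.fun:
            best = res
        restarts = attempt
        start_x = best.x + rng.normal(0.0, 1.0, size=len(names))
    params, changes = assemble(best.x)
    return FitResult(params=params, nll=float(best.fun),
                     converged=bool(best.success), n_fev=n_fev,
                     n_restarts=restarts, fitted=changes)


# ---- sensitivity ----------------------------------------------------------

def _perturbed(params: ModelParameters, name: str, factor: float) -> ModelParameters:
    """Scale one parameter, re-balancing the derived table entries."""
    value = getattr(params, name) * factor
    changes = {name: value}
    if name == "Qc_l":
        changes["Qc_ot"] = 1.0 - value
    elif name in ("Vc_int", "Vc_l", "Vc_b"):
        others = {"Vc_int", "Vc_l", "Vc_b"} - {name}
        changes["Vc_ot"] = 1.0 - value - sum(getattr(params, o) for o in others)
    return params.replace(**changes)


@dataclass(frozen=True)
class SensitivityReport:
    """Per-parameter, per-time NSC series plus the |NSC| > 0.1 flags."""

    param_names: tuple[str, ...]
    times: np.ndarray
    nsc: pd.DataFrame               # index = parameter, columns = time
    threshold: float = NSC_THRESHOLD

    @property
    def max_abs(self) -> pd.Series:
        return self.nsc.abs().max(axis=1)

    @property
    def sensitive(self) -> pd.Series:
        return self.max_abs > self.threshold

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame({
            "max_nsc": self.nsc.max(axis=1),
            "min_nsc": self.nsc.min(axis=1),
            "max_abs_nsc": self.max_abs,
            "sensitive": self.sensitive,
        })


def sensitivity_nsc(
        params: ModelParameters,
        regimen: DoseRegimen | None = None,
        response_fn: Callable[[ModelParameters], np.ndarray] | None = None,
        rel_step: float = 0.001,
        param_names: Sequence[str] = SENSITIVITY_PARAMETERS,
        times: np.ndarray | None = None,
) -> SensitivityReport:
    """Central-difference NSC of a response to each parameter.

    The default response is the intestinal-lumen concentration on the
    single-dose sampling schedule under ``regimen``.  Time slices where
    the baseline response vanishes are skipped with a warning (NSC is
    undefined there).
    """
    if times is None:
        times = EXPERIMENT_1_SCHEDULE_H
    times = np.asarray(times, dtype=float)
    if response_fn is None:
        if regimen is None:
            raise EstimationError("a regimen is required for the default response")

        def response_fn(p: ModelParameters) -> np.ndarray:
            return simulate(p, regimen, times, method="expm").c_int

    r0 = np.asarray(response_fn(params), dtype=float)
    usable = np.abs(r0) > 0
    if not usable.all():
        warnings.warn(
            f"{(~usable).sum()} time slice(s) with zero response skipped",
            RuntimeWarning, stacklevel=2)
    if times.size != r0.size:
        times = np.arange(r0.size, dtype=float)

    rows = {}
    for name in param_names:
        if getattr(params, name) == 0:
            rows[name] = np.zeros(usable.sum())
            continue
        r_up = np.asarray(response_fn(_perturbed(params, name, 1.0 + rel_step)))
        r_dn = np.asarray(response_fn(_perturbed(params, name, 1.0 - rel_step)))
        rows[name] = (r_up[usable] - r_dn[usable]) / (2.0 * rel_step * r0[usable])
    nsc = pd.DataFrame(rows, index=times[usable]).T
    return SensitivityReport(param_names=tuple(param_names),
                             times=times[usable], nsc=nsc)
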