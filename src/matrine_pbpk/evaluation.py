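"""Predicted-versus-observed performance statistics.

Model performance is summarized the way the pig studies were analysed:
ordinary least squares of observed on predicted concentrations with a
Pearson correlation test, a one-sample t test comparing predicted PK
parameters against the observed group values, and a two-sample t test
(pooled-variance by default, Welch optionally) for between-group PK
parameter comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .nca import ConcentrationTimeProfile
from .pbpk import SimulationResult

__all__ = [
    "EvaluationError",
    "RegressionReport",
    "TTestResult",
    "regress_pred_obs",
    "one_sample_t",
    "two_sample_t",
    "pair_by_time",
]


class EvaluationError(ValueError):
    """Raised for degenerate inputs (too few pairs, zero variance)."""


@dataclass(frozen=True)
class RegressionReport:
    """Observed ~ predicted regression plus Pearson correlation."""

    slope: float
    intercept: float
    r: float
    p_value: float
    n: int

    def to_dict(self) -> dict:
        return {"slope_m": self.slope, "intercept_b": self.intercept,
                "pearson_r": self.r, "p_value": self.p_value, "n": self.n}


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: int
    p_value: float


def regress_pred_obs(predicted, observed) -> RegressionReport:
    """OLS of observed on predicted with a two-sided Pearson test.

    Orientation follows the concentration-scale comparison convention:
    observed values regressed on model predictions.
    """
    x = np.asarray(predicted, dtype=float)
    y = np.asarray(observed, dtype=float)
    if x.size != y.size:
        raise EvaluationError("predicted and observed must pair one-to-one")
    if x.size < 3:
        raise EvaluationError("need at least 3 pairs")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise EvaluationError("pairs must be finite")
    if np.var(x) == 0 or np.var(y) == 0:
        raise EvaluationError("zero variance in predicted or observed values")
    fit = stats.linregress(x, y)
    r, p = stats.pearsonr(x, y)
    return RegressionReport(slope=float(fit.slope), intercept=float(fit.intercept),
                            r=float(r), p_value=float(p), n=int(x.size))


def one_sample_t(values, hypothesized_mean: float) -> TTestResult:
    """Two-sided one-sample t test, df = n − 1."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise EvaluationError("need at least 2 values")
    if np.std(v, ddof=1) == 0:
        raise EvaluationError("zero standard deviation")
    res = stats.ttest_1samp(v, hypothesized_mean)
    return TTestResult(t=float(res.statistic), df=int(v.size - 1),
                       p_value=float(res.pvalue))


def two_sample_t(group_a, group_b, equal_var: bool = True) -> TTestResult:
    """Two-sided two-sample t test (pooled variance; Welch via flag)."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise EvaluationError("both groups need at least 2 values")
    va, vb = np.var(a, ddof=1), np.var(b, ddof=1)
    if va == 0 and vb == 0:
        if np.mean(a) == np.mean(b):
            return TTestResult(t=0.0, df=int(a.size + b.size - 2), p_value=1.0)
        raise EvaluationError("zero variance in both groups")
    res = stats.ttest_ind(a, b, equal_var=equal_var)
    if equal_var:
        df = a.size + b.size - 2
    else:
        df = int(np.floor((va / a.size + vb / b.size) ** 2 / (
            (va / a.size) ** 2 / (a.size - 1) + (vb / b.size) ** 2 / (b.size - 1))))
    return TTestResult(t=float(res.statistic), df=int(df),
                       p_value=float(res.pvalue))


def pair_by_time(result: SimulationResult,
                 observed: list[ConcentrationTimeProfile],
                 ) -> tuple[np.ndarray, np.ndarray]:
    """Pair observed time-point means with predictions at the same times.

    Censored observations are excluded from the time-point means; times
    with no uncensored observation, or absent from the simulation grid,
    are dropped.
    """
    frames = [p.to_frame()[~p.censored] for p in observed]
    obs = pd.concat(frames, ignore_index=True)
    means = obs.groupby("time_h")["conc_ug_per_kg"].mean()
    sim = pd.Series(result.c_int, index=result.time)
    common = means.index.intersection(sim.index)
    if common.empty:
        raise EvaluationError("no common time points between model and data")
    return sim.loc[common].to_numpy(), means.loc[common].to_numpy()
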