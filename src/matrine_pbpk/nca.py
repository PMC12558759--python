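"""Non-compartmental analysis of intestinal concentration–time profiles.

Implements the standard model-free summary used for the pig studies:
Cmax/Tmax read directly off the curve, AUC by the linear trapezoidal
rule, the terminal elimination rate constant λz by log-linear regression
over an automatically selected terminal phase, t1/2 = 0.693/λz (the
conventional rounded constant, kept for comparability with the published
parameter tables), MRT = AUMC∞/AUC∞, and the apparent per-kg clearance
CL/F = dose/AUC∞ and volume V/F = (CL/F)/λz.

Censoring policy (the assay LLOQ is 2 μg/kg): below-LLOQ points before
Tmax are treated as zero concentration; below-LLOQ points after Tmax are
excluded from AUC and from the λz regression.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "NCAError",
    "ConcentrationTimeProfile",
    "NCAResult",
    "cmax_tmax",
    "auc_linear",
    "terminal_slope",
    "half_life",
    "nca_full",
    "read_profiles",
    "write_profiles",
    "nca_table",
]

#: the published convention, not ln(2)
HALF_LIFE_CONSTANT = 0.693


class NCAError(ValueError):
    """Raised when a profile cannot support the requested computation."""


@dataclass(frozen=True)
class ConcentrationTimeProfile:
    """One subject's (time, concentration) series in μg/kg (≡ μg/L)."""

    subject_id: str
    time: np.ndarray
    conc: np.ndarray
    censored: np.ndarray = None  # type: ignore[assignment]
    dose_mg_per_kg: float = float("nan")
    bw_kg: float = float("nan")

    def __post_init__(self) -> None:
        t = np.asarray(self.time, dtype=float)
        c = np.asarray(self.conc, dtype=float)
        cen = (np.zeros(t.size, dtype=bool) if self.censored is None
               else np.asarray(self.censored, dtype=bool))
        if t.size != c.size or t.size != cen.size:
            raise NCAError("time, conc and censored must have equal length")
        if np.any(np.diff(t) <= 0):
            raise NCAError("times must be strictly increasing")
        if np.any(c < 0):
            raise NCAError("concentrations must be non-negative")
        object.__setattr__(self, "time", t)
        object.__setattr__(self, "conc", c)
        object.__setattr__(self, "censored", cen)

    @property
    def n_uncensored(self) -> int:
        return int((~self.censored).sum())

    def working_series(self) -> tuple[np.ndarray, np.ndarray]:
        """(time, conc) after applying the censoring policy.

        Pre-Tmax censored points are kept at zero concentration;
        post-Tmax censored points are dropped.
        """
        if self.n_uncensored == 0:
            raise NCAError(f"profile {self.subject_id!r}: all points censored")
        tmax = self.time[~self.censored][np.argmax(self.conc[~self.censored])]
        keep = ~self.censored | (self.time <= tmax)
        c = np.where(self.censored, 0.0, self.conc)
        return self.time[keep], c[keep]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "subject_id": self.subject_id,
            "time_h": self.time,
            "conc_ug_per_kg": self.conc,
            "blq": self.censored.astype(int),
        })


def cmax_tmax(profile: ConcentrationTimeProfile) -> tuple[float, float]:
    """Observed maximum and its time; first occurrence breaks ties."""
    if profile.n_uncensored == 0:
        raise NCAError(f"profile {profile.subject_id!r}: all points censored")
    t = profile.time[~profile.censored]
    c = profile.conc[~profile.censored]
    i = int(np.argmax(c))
    return float(c[i]), float(t[i])


def auc_linear(profile: ConcentrationTimeProfile, t_end: float) -> float:
    """Linear-trapezoidal AUC from the first observation to ``t_end``.

    Observed points only; ``t_end`` beyond the last observation is
    truncated to it (no extrapolation), and a ``t_end`` interior to the
    grid is handled by linear interpolation.
    """
    t, c = profile.working_series()
    if t.size < 2:
        raise NCAError("need at least 2 points for AUC")
    if t_end <= t[1]:
        raise NCAError(f"t_end={t_end} precedes the second observation")
    t_stop = min(t_end, t[-1])
    mask = t <= t_stop
    tt, cc = t[mask], c[mask]
    if t_stop > tt[-1]:
        cc = np.append(cc, np.interp(t_stop, t, c))
        tt = np.append(tt, t_stop)
    return float(np.trapezoid(cc, tt))


def _adjusted_r2(r2: float, n: int) -> float:
    return 1.0 - (1.0 - r2) * (n - 1) / (n - 2)


def terminal_slope(profile: ConcentrationTimeProfile,
                   min_points: int = 3) -> tuple[float, np.ndarray, float]:
    """λz by OLS of ln(conc) on time over an automatic terminal phase.

    The phase is the suffix of ≥ ``min_points`` uncensored positive
    points strictly after Tmax maximizing the adjusted R² (ties go to the
    longer suffix).  Returns (λz, selected indices into the profile, R²).
    """
    cmax, tmax = cmax_tmax(profile)
    eligible = np.flatnonzero((profile.time > tmax) & ~profile.censored)
    if np.any(profile.conc[eligible] <= 0):
        raise NCAError("non-positive concentration in the terminal phase")
    if eligible.size < min_points:
        raise NCAError(
            f"need >= {min_points} uncensored points after Tmax, "
            f"got {eligible.size}")
    best = None
    for start in range(eligible.size - min_points + 1):
        idx = eligible[start:]
        x = profile.time[idx]
        y = np.log(profile.conc[idx])
        slope, intercept = np.polyfit(x, y, 1)
        ss_res = float(np.sum((y - (slope * x + intercept)) ** 2))
        ss_tot = float(np.sum((y - y.mean()) ** 2))
        r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
        adj = _adjusted_r2(r2, idx.size)
        if best is None or adj > best[0] + 1e-12:
            best = (adj, -slope, idx, r2)
    _, lambda_z, idx, r2 = best
    return float(lambda_z), idx, float(r2)


def half_life(lambda_z: float) -> float:
    """Terminal half-life, h: 0.693/λz."""
    if not lambda_z > 0:
        raise NCAError(f"lambda_z must be positive, got {lambda_z}")
    return HALF_LIFE_CONSTANT / lambda_z


@dataclass(frozen=True)
class NCAResult:
    """The full non-compartmental summary for one profile."""

    subject_id: str
    cmax: float                 # μg/L
    tmax: float                 # h
    auc_0_tlast: float          # h·μg/L, up to the requested t_end
    auc_0_inf: float            # h·μg/L
    aumc_0_inf: float           # h²·μg/L
    lambda_z: float             # 1/h
    t_half: float               # h
    mrt: float                  # h
    cl_f: float                 # L/h/kg
    v_f: float                  # L/kg
    terminal_indices: np.ndarray = field(repr=False, default=None)  # type: ignore[assignment]
    r_squared: float = float("nan")

    def to_dict(self) -> dict:
        # column order follows the published PK-parameter table
        return {
            "subject_id": self.subject_id,
            "Cmax_ug_per_L": self.cmax,
            "Tmax_h": self.tmax,
            "AUC_h_ug_per_L": self.auc_0_tlast,
            "V_F_L_per_kg": self.v_f,
            "MRT_h": self.mrt,
            "CL_F_L_per_h_per_kg": self.cl_f,
            "lambda_z_per_h": self.lambda_z,
            "t_half_h": self.t_half,
            "lambda_z_r_squared": self.r_squared,
        }


def nca_full(profile: ConcentrationTimeProfile,
             t_end: float | None = None) -> NCAResult:
    """Assemble the full NCA parameter set for one profile.

    ``t_end`` defaults to the last observation (120 h on the single-dose
    schedule).  The extrapolated tail uses C_last/λz for AUC and
    C_last·t_last/λz + C_last/λz² for AUMC.
    """
    t, c = profile.working_series()
    if t_end is None:
        t_end = float(t[-1])
    cmax, tmax = cmax_tmax(profile)
    auc_t = auc_linear(profile, t_end)
    lambda_z, idx, r2 = terminal_slope(profile)

    t_last, c_last = float(t[-1]), float(c[-1])
    auc_last = auc_linear(profile, t_last)
    auc_inf = auc_last + c_last / lambda_z
    aumc_last = float(np.trapezoid(t * c, t))
    aumc_inf = aumc_last + c_last * t_last / lambda_z + c_last / lambda_z ** 2
    mrt = aumc_inf / auc_inf

    dose_ug_per_kg = profile.dose_mg_per_kg * 1000.0
    cl_f = dose_ug_per_kg / auc_inf      # (μg/kg)/(h·μg/L) = L/h/kg
    v_f = cl_f / lambda_z
    return NCAResult(
        subject_id=profile.subject_id, cmax=cmax, tmax=tmax,
        auc_0_tlast=auc_t, auc_0_inf=auc_inf, aumc_0_inf=aumc_inf,
        lambda_z=lambda_z, t_half=half_life(lambda_z), mrt=mrt,
        cl_f=cl_f, v_f=v_f, terminal_indices=idx, r_squared=r2)


def nca_table(results: list[NCAResult]) -> pd.DataFrame:
    """One row per subject, columns in the published table order."""
    return pd.DataFrame([r.to_dict() for r in results])


# ---- delimited-text interchange -------------------------------------------

_COLUMNS = ["subject_id", "time_h", "conc_ug_per_kg", "blq"]


def write_profiles(profiles: list[ConcentrationTimeProfile],
                   path: str | Path) -> None:
    pd.concat([p.to_frame() for p in profiles], ignore_index=True).to_csv(
        path, index=False)


def read_profiles(path: str | Path, dose_mg_per_kg: float = float("nan"),
                  bw_kg: float = float("nan")) -> list[ConcentrationTimeProfile]:
    df = pd.read_csv(path)
    missing = [c for c in _COLUMNS if c not in df.columns]
    if missing:
        raise NCAError(f"{path}: missing columns {missing}")
    out = []
    for sid, grp in df.groupby("subject_id", sort=False):
        grp = grp.sort_values("time_h")
        out.append(ConcentrationTimeProfile(
            subject_id=str(sid),
            time=grp["time_h"].to_numpy(),
            conc=grp["conc_ug_per_kg"].to_numpy(),
            censored=grp["blq"].to_numpy().astype(bool),
            dose_mg_per_kg=dose_mg_per_kg, bw_kg=bw_kg))
    return out
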