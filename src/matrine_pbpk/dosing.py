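"""Oral dosing regimens.

Doses are stated per kilogram of body weight (mg/kg) as in veterinary
practice; the absolute depot load is dose_per_kg × BW × 1000 μg.  Feed
medication and gavage are both modelled as instantaneous loading of the
stomach depot.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

__all__ = ["DoseEvent", "DoseRegimen"]


@dataclass(frozen=True)
class DoseEvent:
    """A single oral dose: administration time (h) and dose (mg/kg)."""

    time_h: float
    dose_mg_per_kg: float

    def __post_init__(self) -> None:
        if self.time_h < 0:
            raise ValueError(f"dose time must be >= 0, got {self.time_h}")
        if self.dose_mg_per_kg < 0:
            raise ValueError(f"dose must be >= 0, got {self.dose_mg_per_kg}")


@dataclass(frozen=True)
class DoseRegimen:
    """An ordered sequence of oral dose events for one animal."""

    events: tuple[DoseEvent, ...]
    bw_kg: float

    def __post_init__(self) -> None:
        if self.bw_kg <= 0:
            raise ValueError(f"body weight must be positive, got {self.bw_kg}")
        times = [e.time_h for e in self.events]
        if any(t1 < t0 for t0, t1 in zip(times, times[1:])):
            raise ValueError("dose times must be non-decreasing")

    @classmethod
    def single_oral(cls, dose_mg_per_kg: float, bw_kg: float,
                    time_h: float = 0.0) -> "DoseRegimen":
        return cls((DoseEvent(time_h, dose_mg_per_kg),), bw_kg)

    @classmethod
    def repeated(cls, dose_mg_per_kg: float, bw_kg: float, interval_h: float,
                 n_doses: int, start_h: float = 0.0) -> "DoseRegimen":
        if interval_h <= 0:
            raise ValueError("dosing interval must be positive")
        events = tuple(
            DoseEvent(start_h + k * interval_h, dose_mg_per_kg)
            for k in range(n_doses)
        )
        return cls(events, bw_kg)

    @classmethod
    def from_events(cls, events: Iterable[tuple[float, float]],
                    bw_kg: float) -> "DoseRegimen":
        return cls(tuple(DoseEvent(t, d) for t, d in events), bw_kg)

    @property
    def times(self) -> np.ndarray:
        return np.array([e.time_h for e in self.events])

    def amount_ug(self, event: DoseEvent) -> float:
        """Absolute amount of one dose, μg."""
        return event.dose_mg_per_kg * self.bw_kg * 1000.0

    @property
    def total_administered_ug(self) -> float:
        return sum(self.amount_ug(e) for e in self.events)

    def administered_by(self, t: float | Sequence[float]) -> np.ndarray:
        """Cumulative administered amount (μg) at time(s) ``t``.

        A dose given exactly at ``t`` counts as administered.
        """
        t = np.atleast_1d(np.asarray(t, dtype=float))
        out = np.zeros_like(t)
        for e in self.events:
            out += np.where(t >= e.time_h, self.amount_ug(e), 0.0)
        return out
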