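"""Delimited-text interchange, collected in one namespace.

Dialect: comma-separated, UTF-8, '.' decimal, mandatory header row.
Times are in hours and concentrations in μg/kg (≡ μg/L under the
unit-density convention).
"""

from __future__ import annotations

from pathlib import Path

from .nca import nca_table, read_profiles, write_profiles
from .pbpk import SimulationResult
from .pkpd import metrics_table
from .synthetic import cohort_table

__all__ = [
    "read_profiles",
    "write_profiles",
    "write_simulation",
    "nca_table",
    "metrics_table",
    "cohort_table",
]


def write_simulation(result: SimulationResult, path: str | Path) -> None:
    """Write a simulation as time_h, amounts, concentrations, residual."""
    result.to_frame().to_csv(path, index=False)
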