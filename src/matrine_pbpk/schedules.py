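"""Sampling schedules of the two pig studies.

Study 1: T-cannulated pigs, single oral dose (40 or 70 mg/kg), intestinal
contents sampled 0.25–120 h post-dose.  Study 2: repeat dosing
(50 mg/kg/d × 5 d by gavage), five pigs sacrificed at each of 0.5, 1, 3,
6 and 12 d after the last dose (destructive sampling: one terminal lumen
concentration per pig).
"""

import numpy as np

__all__ = [
    "EXPERIMENT_1_SCHEDULE_H",
    "EXPERIMENT_2_DOSE_TIMES_H",
    "EXPERIMENT_2_SACRIFICE_H",
    "LLOQ_UG_PER_KG",
]

#: single-dose sampling times, h post-dose
EXPERIMENT_1_SCHEDULE_H = np.array(
    [0.25, 0.5, 1, 2, 3, 4, 5, 8, 12, 16, 24, 36, 48, 72, 120], dtype=float)

#: five once-daily doses, h
EXPERIMENT_2_DOSE_TIMES_H = np.array([0.0, 24.0, 48.0, 72.0, 96.0])

#: sacrifice times (0.5, 1, 3, 6, 12 d after the last dose), h on the
#: experiment clock
EXPERIMENT_2_SACRIFICE_H = EXPERIMENT_2_DOSE_TIMES_H[-1] + np.array(
    [12.0, 24.0, 72.0, 144.0, 288.0])

#: lower limit of quantification of the LC–MS/MS assay, μg/kg
LLOQ_UG_PER_KG = 2.0
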