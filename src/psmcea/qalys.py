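"""Quality-adjusted life years from state occupancy and adverse events.

QALYs are the utility-weighted, discounted areas under the occupancy layers
(PFS, second-line PPS, third-line PPS).  Adverse events subtract a
duration-weighted decrement per expected event; no disutility is attached to
brain metastases.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import UtilitySet
from .engine import ModelSettings, OccupancyTrace, present_value

__all__ = ["QalyResult", "compute_qalys"]


@dataclass
class QalyResult:
    """Discounted QALYs by state layer plus the adverse-event decrement."""

    pfs: float
    pps_second_line: float
    pps_third_line: float
    ae_decrement: float  # <= 0

    @property
    def total(self) -> float:
        return self.pfs + self.pps_second_line + self.pps_third_line + self.ae_decrement

    def as_dict(self) -> dict[str, float]:
        return {
            "pfs": self.pfs,
            "pps_second_line": self.pps_second_line,
            "pps_third_line": self.pps_third_line,
            "ae_decrement": self.ae_decrement,
            "total": self.total,
        }

    def to_series(self) -> pd.Series:
        return pd.Series(self.as_dict())


def compute_qalys(
    trace: OccupancyTrace,
    split: tuple[np.ndarray, np.ndarray],
    ae_events: dict[str, np.ndarray],
    utilities: UtilitySet,
    settings: ModelSettings,
) -> QalyResult:
    """Utility-weighted discounted time in state, minus AE decrements.

    ``split`` carries the second-/third-line PPS layers, which must add up to
    PPS occupancy; ``ae_events`` maps each AE label to its expected events
    per cycle on the grid.
    """
    second, third = split
    if second.shape != trace.pps.shape or third.shape != trace.pps.shape:
        raise ValueError("line layers on a different grid than the trace")
    if np.any(np.abs(second + third - trace.pps) > 1e-8):
        raise ValueError("second- plus third-line layers must equal PPS occupancy")

    wpy = settings.weeks_per_year
    q_pfs = present_value(trace.pfs * utilities.pfs, settings) / wpy
    q_pps2 = present_value(second * utilities.pps_second_line, settings) / wpy
    q_pps3 = present_value(third * utilities.pps_third_line, settings) / wpy

    dur_years = utilities.ae_disutility_duration_weeks / wpy
    decrement = 0.0
    for ae, rate in ae_events.items():
        expected_events = present_value(np.asarray(rate, dtype=float), settings)
        decrement -= expected_events * abs(utilities.disutility(ae)) * dur_years

    return QalyResult(
        pfs=q_pfs, pps_second_line=q_pps2, pps_third_line=q_pps3, ae_decrement=decrement
    )
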