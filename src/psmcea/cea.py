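"""Incremental cost-effectiveness outputs."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .costs import COST_CATEGORIES, CostBreakdown
from .qalys import QalyResult

__all__ = ["ArmResult", "CEResult", "icer", "summarize"]


@dataclass
class ArmResult:
    """Per-arm discounted outcomes plus undiscounted survival summaries."""

    arm: str
    life_years: float
    qalys: QalyResult
    costs: CostBreakdown
    mean_os_years: float
    mean_pfs_months: float


def icer(
    cost_new: float, cost_ref: float, eff_new: float, eff_ref: float
) -> tuple[float | None, str]:
    """Incremental ratio (cost per effect unit gained) and dominance label.

    Returns ``(ratio, "standard")`` in the north-east quadrant,
    ``(None, "dominant")`` when the new option is at least as effective and no
    more costly (not both ties), ``(None, "dominated")`` in the mirror case.
    A zero effect difference with a cost difference leaves the ratio
    undefined (None).
    """
    for v in (cost_new, cost_ref, eff_new, eff_ref):
        if not np.isfinite(v):
            raise ValueError("non-finite input")
    dc = cost_new - cost_ref
    de = eff_new - eff_ref
    if dc <= 0 and de >= 0 and not (dc == 0 and de == 0):
        return None, "dominant"
    if dc >= 0 and de <= 0 and not (dc == 0 and de == 0):
        return None, "dominated"
    if de == 0:
        return None, "undefined"
    return dc / de, "standard"


@dataclass
class CEResult:
    """Full incremental comparison of intervention vs comparator."""

    intervention: ArmResult
    comparator: ArmResult

    @property
    def delta_cost(self) -> float:
        return self.intervention.costs.total - self.comparator.costs.total

    @property
    def delta_ly(self) -> float:
        return self.intervention.life_years - self.comparator.life_years

    @property
    def delta_qaly(self) -> float:
        return self.intervention.qalys.total - self.comparator.qalys.total

    @property
    def cost_per_ly(self) -> float | None:
        return icer(
            self.intervention.costs.total,
            self.comparator.costs.total,
            self.intervention.life_years,
            self.comparator.life_years,
        )[0]

    @property
    def icer(self) -> float | None:
        return self._icer_label()[0]

    @property
    def dominance(self) -> str:
        return self._icer_label()[1]

    def _icer_label(self) -> tuple[float | None, str]:
        return icer(
            self.intervention.costs.total,
            self.comparator.costs.total,
            self.intervention.qalys.total,
            self.comparator.qalys.total,
        )

    def cost_table(self) -> pd.DataFrame:
        """Cost breakdown with a difference column (difference recomputed as
        column subtraction, so the table is internally consistent)."""
        a = self.intervention.costs.to_series()
        b = self.comparator.costs.to_series()
        df = pd.DataFrame({self.intervention.arm: a, self.comparator.arm: b})
        df["difference"] = df[self.intervention.arm] - df[self.comparator.arm]
        df.index.name = "category"
        return df.loc[list(COST_CATEGORIES) + ["total"]]

    def summary(self) -> dict:
        value, label = self._icer_label()
        return {
            "arms": {
                r.arm: {
                    "life_years_discounted": r.life_years,
                    "qalys": r.qalys.total,
                    "total_cost": r.costs.total,
                    "mean_os_years": r.mean_os_years,
                    "mean_pfs_months": r.mean_pfs_months,
                }
                for r in (self.intervention, self.comparator)
            },
            "delta_cost": self.delta_cost,
            "delta_ly": self.delta_ly,
            "delta_qaly": self.delta_qaly,
            "cost_per_ly_gained": self.cost_per_ly,
            "icer_per_qaly": value,
            "dominance": label,
        }


def summarize(intervention: ArmResult, comparator: ArmResult) -> CEResult:
    """Combine two arm results into the incremental comparison."""
    return CEResult(intervention=intervention, comparator=comparator)
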