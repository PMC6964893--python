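"""Cost accumulation along the treatment pathway.

Discounted costs are collected in six categories: treatment acquisition,
administration + monitoring, adverse-event management, disease management
during PFS, disease management during PPS, and brain-metastasis-associated
costs.  A cohort model does not track individual progression times, so the
second-/third-line split within PPS is obtained by convolving the per-cycle
progression inflow with a fixed-length second-line window.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import CostInputs, DrugSpec
from .engine import ModelSettings, OccupancyTrace, present_value
from .survival import ParametricFit, SurvivalCurve, build_hybrid_curve

__all__ = [
    "EventModel",
    "CostBreakdown",
    "COST_CATEGORIES",
    "monthly_to_weekly",
    "weekly_drug_cost",
    "weekly_ae_probability",
    "build_event_model",
    "build_bm_trace",
    "line_split",
    "ae_event_rates",
    "accumulate_costs",
]

COST_CATEGORIES = (
    "treatment_acquisition",
    "administration_monitoring",
    "ae_management",
    "management_pfs",
    "management_pps",
    "brain_metastases",
)


def monthly_to_weekly(cost: float) -> float:
    """Monthly euros to weekly euros at 52 weeks / 12 months."""
    if cost < 0:
        raise ValueError("negative cost")
    return cost * 12.0 / 52.0


def weekly_drug_cost(drug: DrugSpec, admin_per_session: float = 0.0) -> float:
    """Weekly acquisition cost of a drug; IV drugs include the per-session
    administration tariff, spread over the dosing interval."""
    if drug.kind == "oral":
        return monthly_to_weekly(drug.monthly_cost)
    return (drug.session_cost + admin_per_session) * 7.0 / drug.session_interval_days


def weekly_ae_probability(cum_incidence: float, mean_duration_months: float) -> float:
    """Weekly probability implied by a cumulative incidence spread linearly
    over the mean treatment duration: p = 1 - exp(-incidence / duration_weeks)."""
    if not 0 <= cum_incidence <= 1:
        raise ValueError("incidence outside [0, 1]")
    if mean_duration_months <= 0:
        raise ValueError("non-positive mean duration")
    rate = cum_incidence / (mean_duration_months * 52.0 / 12.0)
    return float(-np.expm1(-rate))


@dataclass
class EventModel:
    """Per-arm intercurrent-event machinery: weekly AE probabilities (with
    the arm's incidence re-weighting folded in) and BM prevalence."""

    weekly_ae_probs: dict[str, float]
    reweighting: float
    bm_prevalence: np.ndarray | None = None

    def __post_init__(self) -> None:
        for ae, p in self.weekly_ae_probs.items():
            if not 0 <= p <= 1:
                raise ValueError(f"weekly probability for {ae!r} outside [0, 1]")


def build_event_model(
    ae_incidences: dict[str, float],
    mean_duration_months: float,
    reweighting: float = 1.0,
    bm_prevalence: np.ndarray | None = None,
) -> EventModel:
    probs = {
        ae: weekly_ae_probability(inc, mean_duration_months)
        for ae, inc in ae_incidences.items()
    }
    return EventModel(weekly_ae_probs=probs, reweighting=reweighting, bm_prevalence=bm_prevalence)


def build_bm_trace(
    settings: ModelSettings,
    baseline: float,
    trial_bm_free: SurvivalCurve,
    tail_fit: ParametricFit | None,
    cutover: int,
) -> np.ndarray:
    """Per-cycle brain-metastasis prevalence among alive patients.

    ``baseline`` of the cohort has BM at entry; the remainder acquire it
    according to the within-trial BM-free curve up to the cutover and its
    parametric (exponential) continuation beyond.  BM is absorbing, so the
    prevalence is non-decreasing and capped at 1.
    """
    if not 0 <= baseline <= 1:
        raise ValueError("baseline prevalence outside [0, 1]")
    n = settings.n_weeks
    km = trial_bm_free.extended(max(cutover, trial_bm_free.n_weeks))
    if tail_fit is None:
        bm_free = km.extended(n)
    else:
        bm_free = build_hybrid_curve(km, tail_fit, cutover, n)
    prev = 1.0 - (1.0 - baseline) * bm_free.surv
    prev = np.clip(np.maximum.accumulate(prev), 0.0, 1.0)
    return prev


def line_split(
    trace: OccupancyTrace, second_line_weeks: float
) -> tuple[np.ndarray, np.ndarray]:
    """Split PPS occupancy into second- and third-line layers.

    Progression inflow during cycle i is the decrement of PFS occupancy.  A
    progressor is attributed to second line while the time since progression
    is below ``second_line_weeks`` (fractional last week handled pro rata)
    and to third line afterwards; the layers are rescaled so they always sum
    exactly to PPS occupancy.
    """
    if second_line_weeks <= 0:
        raise ValueError("non-positive second-line duration")
    pfs, pps = trace.pfs, trace.pps
    n = trace.n_weeks
    inflow = np.maximum(0.0, pfs[:-1] - pfs[1:])
    full = int(np.floor(second_line_weeks))
    frac = second_line_weeks - full
    kernel = np.ones(full + (1 if frac > 0 else 0))
    if frac > 0:
        kernel[-1] = frac
    conv = np.convolve(inflow, kernel)
    recent = np.zeros(n + 1)
    recent[1:] = conv[:n]
    total = np.zeros(n + 1)
    total[1:] = np.cumsum(inflow)
    with np.errstate(invalid="ignore", divide="ignore"):
        share = np.where(total > 0, recent / total, 0.0)
    share = np.clip(share, 0.0, 1.0)
    second = pps * share
    return second, pps - second


def ae_event_rates(
    on_treatment: np.ndarray, events: EventModel
) -> dict[str, np.ndarray]:
    """Expected AE events per cycle at each grid point, by AE label."""
    return {
        ae: on_treatment * p * events.reweighting
        for ae, p in events.weekly_ae_probs.items()
    }


@dataclass
class CostBreakdown:
    """Discounted euros in the six pathway categories."""

    treatment_acquisition: float
    administration_monitoring: float
    ae_management: float
    management_pfs: float
    management_pps: float
    brain_metastases: float

    @property
    def total(self) -> float:
        return (
            self.treatment_acquisition
            + self.administration_monitoring
            + self.ae_management
            + self.management_pfs
            + self.management_pps
            + self.brain_metastases
        )

    def as_dict(self) -> dict[str, float]:
        d = {cat: getattr(self, cat) for cat in COST_CATEGORIES}
        d["total"] = self.total
        return d

    def to_series(self) -> pd.Series:
        return pd.Series(self.as_dict())


def accumulate_costs(
    trace: OccupancyTrace,
    duration_curve: SurvivalCurve,
    arm: str,
    inputs: CostInputs,
    drugs: dict[str, DrugSpec],
    events: EventModel,
    settings: ModelSettings,
    split: tuple[np.ndarray, np.ndarray] | None = None,
) -> CostBreakdown:
    """Accumulate discounted pathway costs for one arm.

    First-line acquisition follows the on-treatment fraction (the treatment
    duration curve, capped by PFS occupancy); second line covers the first
    ``second_line_duration_weeks`` weeks of each progressor's PPS time at the
    arm's second-line drug mix; third line (pemetrexed + cisplatin, drug plus
    per-session administration) runs thereafter until death or the horizon.
    """
    n = settings.n_weeks
    if duration_curve.n_weeks < n:
        raise ValueError("duration curve does not cover the horizon")
    if events.bm_prevalence is None or events.bm_prevalence.size != n + 1:
        raise ValueError("event model carries no BM prevalence on the horizon grid")

    pfs, pps, alive = trace.pfs, trace.pps, trace.alive
    on1 = np.minimum(duration_curve.surv[: n + 1], pfs)
    if split is None:
        split = line_split(trace, inputs.second_line_duration_weeks)
    second, third = split

    admin = inputs.chemo_admin_per_session
    w1 = weekly_drug_cost(drugs[inputs.first_line_drug[arm]], admin)
    w2 = sum(
        share * weekly_drug_cost(drugs[d], admin)
        for d, share in inputs.second_line_mix[arm].items()
    )
    w3 = sum(
        share * weekly_drug_cost(drugs[d], admin)
        for d, share in inputs.third_line_mix[arm].items()
    )
    acquisition = present_value(on1 * w1 + second * w2 + third * w3, settings)

    monitoring = present_value(
        on1 * inputs.monitoring_first_line[arm]
        + second * inputs.monitoring_second_line
        + third * inputs.monitoring_third_line,
        settings,
    )

    per_event = {
        ae: (inputs.ae_event_costs[ae] + inputs.transport_round_trip)
        * inputs.ae_cost_multiplier[arm]
        for ae in events.weekly_ae_probs
    }
    ae_weekly = sum(
        p * events.reweighting * per_event[ae] for ae, p in events.weekly_ae_probs.items()
    )
    ae_cost = present_value(on1 * ae_weekly, settings)

    pfs_mgmt = present_value(pfs * inputs.management_weekly_pfs, settings)
    pps_mgmt = present_value(pps * inputs.management_weekly_pps, settings)
    bm_cost = present_value(events.bm_prevalence * alive * inputs.bm_weekly, settings)

    return CostBreakdown(
        treatment_acquisition=acquisition,
        administration_monitoring=monitoring,
        ae_management=ae_cost,
        management_pfs=pfs_mgmt,
        management_pps=pps_mgmt,
        brain_metastases=bm_cost,
    )
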