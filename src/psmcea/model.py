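"""End-to-end model assembly: fit survival inputs once, evaluate many times.

``CEModel`` holds the Kaplan-Meier curves and parametric tail fits estimated
from pseudo-individual-patient data, and re-evaluates the whole
partitioned-survival model under parameter overrides — the evaluation
closure that the deterministic, probabilistic and scenario sensitivity
analyses all drive.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cea import ArmResult, CEResult, summarize
from .config import ModelConfig, apply_overrides
from .costs import (
    accumulate_costs,
    ae_event_rates,
    build_bm_trace,
    build_event_model,
    line_split,
)
from .engine import compute_occupancy, discounted_time_in_state, yearly_snapshot
from .qalys import compute_qalys
from .survival import (
    ParametricFit,
    SurvivalCurve,
    apply_reference_hazards,
    build_hybrid_curve,
    family_table,
    fit_all_families,
    fit_parametric,
    kaplan_meier,
)
from .synthetic import TrialData

__all__ = ["CEModel", "ArmFits"]


@dataclass
class ArmFits:
    """Per-arm trial estimates: weekly KM curves and parametric tail fits."""

    km: dict[str, SurvivalCurve]
    fits: dict[str, ParametricFit]


class CEModel:
    """The assembled cost-effectiveness model.

    Parameters
    ----------
    config
        Validated model configuration.
    trial
        Generated (or loaded) pseudo-IPD the survival inputs are estimated
        from.
    """

    def __init__(self, config: ModelConfig, trial: TrialData):
        self.config = config
        self.trial = trial
        self._arm_fits: dict[str, ArmFits] | None = None
        self._base_curves: dict[str, dict] | None = None

    # -- estimation ---------------------------------------------------------

    def fit(self) -> "CEModel":
        """Estimate KM curves and the configured parametric tails per arm."""
        ex = self.config.extrapolation
        cut = ex.cutover_weeks
        fits_by_arm: dict[str, ArmFits] = {}
        for arm in self.config.arms:
            km: dict[str, SurvivalCurve] = {}
            fits: dict[str, ParametricFit] = {}
            for endpoint, label in (("pfs", "PFS"), ("os", "OS"), ("duration", "duration")):
                t, e = self.trial.endpoint(arm, label)
                km[endpoint] = kaplan_meier(t, e, n_weeks=max(cut, int(np.ceil(t.max()))))
            t, e = self._bm_onset_data(arm)
            km["bm_free"] = kaplan_meier(t, e, n_weeks=max(cut, int(np.ceil(t.max()))))

            t, e = self.trial.endpoint(arm, "PFS")
            fits["pfs"] = fit_parametric(t, e, ex.pfs_family)
            t, e = self.trial.endpoint(arm, "duration")
            fits["duration"] = fit_parametric(t, e, ex.duration_family)
            t, e = self.trial.endpoint(arm, "OS")
            fits["os"] = fit_parametric(t, e, ex.os_family)
            t, e = self._bm_onset_data(arm)
            if e.sum() > 0:
                fits["bm"] = fit_parametric(t, e, ex.bm_tail_family)
            fits_by_arm[arm] = ArmFits(km=km, fits=fits)
        self._arm_fits = fits_by_arm
        self._base_curves = None
        return self

    def _bm_onset_data(self, arm: str):
        """BM onset times excluding patients with BM at entry (time-0 events)."""
        t, e = self.trial.endpoint(arm, "BM")
        keep = ~((t == 0) & (e == 1))
        return t[keep], e[keep]

    @property
    def arm_fits(self) -> dict[str, ArmFits]:
        if self._arm_fits is None:
            raise RuntimeError("call fit() before evaluating the model")
        return self._arm_fits

    def selection_report(self) -> dict[tuple[str, str], pd.DataFrame]:
        """Information-criterion comparison of all candidate families per
        (arm, endpoint); diagnostic output, not used by evaluation."""
        tables = {}
        for arm in self.config.arms:
            for endpoint, label in (("pfs", "PFS"), ("os", "OS"), ("duration", "duration")):
                t, e = self.trial.endpoint(arm, label)
                fits = fit_all_families(t, e, self.config.extrapolation.candidate_families)
                tables[(arm, endpoint)] = family_table(fits)
        return tables

    # -- curve construction -------------------------------------------------

    def build_curves(
        self, survival_params: dict[tuple[str, str], np.ndarray] | None = None
    ) -> dict[str, dict]:
        """Hybrid KM + parametric-tail curves per arm on the horizon grid.

        ``survival_params`` substitutes unconstrained-scale parameters for a
        given (arm, endpoint) tail fit — the probabilistic sensitivity
        analysis's perturbation — leaving the KM portions untouched.  The
        non-reference arm's OS tail always follows the reference arm's
        extrapolated hazards (equal long-term efficacy assumption).
        """
        ex = self.config.extrapolation
        cut, n = ex.cutover_weeks, self.config.settings.n_weeks
        params = survival_params or {}

        def tail(arm: str, endpoint: str) -> ParametricFit:
            fit = self.arm_fits[arm].fits[endpoint]
            if (arm, endpoint) in params:
                fit = fit.with_params(params[(arm, endpoint)])
            return fit

        curves: dict[str, dict] = {}
        ref = ex.os_reference_arm
        ref_os = build_hybrid_curve(self.arm_fits[ref].km["os"], tail(ref, "os"), cut, n)
        for arm, af in self.arm_fits.items():
            c = {
                "pfs": build_hybrid_curve(af.km["pfs"], tail(arm, "pfs"), cut, n),
                "duration": build_hybrid_curve(af.km["duration"], tail(arm, "duration"), cut, n),
                "bm_free_km": af.km["bm_free"],
                "bm_tail": af.fits.get("bm"),
            }
            c["os"] = (
                ref_os if arm == ref else apply_reference_hazards(af.km["os"], ref_os, cut)
            )
            curves[arm] = c
        return curves

    def base_curves(self) -> dict[str, dict]:
        if self._base_curves is None:
            self._base_curves = self.build_curves()
        return self._base_curves

    # -- evaluation ---------------------------------------------------------

    def evaluate(
        self,
        overrides: dict[str, object] | None = None,
        survival_params: dict[tuple[str, str], np.ndarray] | None = None,
    ) -> CEResult:
        """Run the full model and return the incremental comparison.

        ``overrides`` are dotted configuration paths (utility values, unit
        costs, discount rate, ...); ``survival_params`` perturbs parametric
        tails.  The stored configuration is never mutated.
        """
        cfg = apply_overrides(self.config, overrides)
        settings = cfg.settings
        curves = (
            self.base_curves() if not survival_params else self.build_curves(survival_params)
        )
        cut = cfg.extrapolation.cutover_weeks

        arm_results: dict[str, ArmResult] = {}
        for arm, c in curves.items():
            profile = cfg.arms[arm]
            trace = compute_occupancy(c["pfs"], c["os"], settings)
            split = line_split(trace, cfg.costs.second_line_duration_weeks)
            bm_prev = build_bm_trace(
                settings, cfg.events.bm_baseline, c["bm_free_km"], c["bm_tail"], cut
            )
            events = build_event_model(
                profile.ae_incidences,
                profile.duration_mean_months,
                cfg.costs.ae_reweighting[arm],
                bm_prevalence=bm_prev,
            )
            costs = accumulate_costs(
                trace, c["duration"], arm, cfg.costs, cfg.drugs, events, settings, split=split
            )
            n = settings.n_weeks
            on1 = np.minimum(c["duration"].surv[: n + 1], trace.pfs)
            qalys = compute_qalys(
                trace, split, ae_event_rates(on1, events), cfg.utilities, settings
            )
            undisc = settings.model_copy(update={"discount_rate_annual": 0.0})
            arm_results[arm] = ArmResult(
                arm=arm,
                life_years=discounted_time_in_state(trace, "alive", settings),
                qalys=qalys,
                costs=costs,
                mean_os_years=discounted_time_in_state(trace, "alive", undisc),
                mean_pfs_months=discounted_time_in_state(trace, "pfs", undisc) * 12,
            )
        return summarize(arm_results[cfg.intervention], arm_results[cfg.comparator])

    def base_case(self) -> CEResult:
        return self.evaluate()

    def occupancy_tables(self) -> dict[str, pd.DataFrame]:
        """Yearly state-occupancy snapshots per arm (patient-flow shape)."""
        settings = self.config.settings
        out = {}
        for arm, c in self.base_curves().items():
            trace = compute_occupancy(c["pfs"], c["os"], settings)
            out[arm] = yearly_snapshot(trace, settings)
        return out
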