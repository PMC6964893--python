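"""Pseudo-individual-patient two-arm trial generator.

Stands in for the (undeposited) trial data the analysis assumes: per patient
it draws progression-free survival, overall survival, treatment duration and
brain-metastasis onset, with administrative censoring at the arm's data
cutoff, plus grade III/IV adverse events at the constant weekly probability
implied by the arm's cumulative incidences.

Overall survival is constructed as PFS plus an exponential post-progression
residual whose rate is calibrated so the survivor proportion at the trial
end matches the arm profile; the PFS <= OS invariant therefore holds by
construction.  Censoring is purely administrative.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import optimize

from .config import ArmProfile

__all__ = ["TrialData", "WEEKS_PER_MONTH", "generate_trial", "write_trial", "read_trial"]

WEEKS_PER_MONTH = 52.0 / 12.0

ENDPOINTS = ("PFS", "OS", "duration", "BM")


@dataclass
class TrialData:
    """Generated pseudo-IPD: endpoint records plus an adverse-event table.

    ``ipd`` has one row per (patient, endpoint): columns patient_id, arm,
    endpoint in {PFS, OS, duration, BM}, time_weeks, event.  ``ae_events``
    has one row per adverse-event occurrence (patient_id, arm, ae,
    week, in_trial); events beyond the administrative censoring time are kept
    with ``in_trial = 0`` so generator-level frequencies can be validated
    against the configured incidences.
    """

    ipd: pd.DataFrame
    ae_events: pd.DataFrame
    seed: int

    def arm(self, name: str) -> pd.DataFrame:
        return self.ipd[self.ipd["arm"] == name]

    def endpoint(self, arm: str, endpoint: str) -> tuple[np.ndarray, np.ndarray]:
        sub = self.ipd[(self.ipd["arm"] == arm) & (self.ipd["endpoint"] == endpoint)]
        return sub["time_weeks"].to_numpy(float), sub["event"].to_numpy(int)


def _os_residual_rate(pfs_rate: float, os_rate_at_end: float, trial_end_weeks: float) -> float:
    """Rate of the exponential post-progression residual such that
    P(PFS + residual > T) equals the target survivor proportion at T."""
    a, T = pfs_rate, trial_end_weeks
    s_pfs_T = np.exp(-a * T)
    if os_rate_at_end >= 1.0:
        raise ValueError("OS proportion of 1 is unattainable with exponential PFS")
    # b -> inf gives S_OS(T) -> S_PFS(T); target below that is infeasible
    if os_rate_at_end <= s_pfs_T:
        raise ValueError(
            f"OS proportion {os_rate_at_end} at trial end not reachable: "
            f"PFS alone leaves {s_pfs_T:.3f}"
        )

    def s_os(b: float) -> float:
        if abs(b - a) < 1e-12:
            return float(np.exp(-a * T) * (1 + a * T))
        return float((a * np.exp(-b * T) - b * np.exp(-a * T)) / (a - b))

    log_b = optimize.brentq(
        lambda lb: s_os(np.exp(lb)) - os_rate_at_end, -20.0, 8.0, xtol=1e-13
    )
    return float(np.exp(log_b))


def _generate_arm(profile: ArmProfile, rng: np.random.Generator):
    n = profile.n_patients
    T = profile.trial_end_months * WEEKS_PER_MONTH
    C = profile.censor_time_months * WEEKS_PER_MONTH
    pfs_rate = np.log(2.0) / (profile.pfs_median_months * WEEKS_PER_MONTH)

    pfs_t = rng.exponential(1.0 / pfs_rate, n)
    res_rate = _os_residual_rate(pfs_rate, profile.os_rate_at_end, T)
    os_t = pfs_t + rng.exponential(1.0 / res_rate, n)

    dur_mean_w = profile.duration_mean_months * WEEKS_PER_MONTH
    dur_t = rng.exponential(dur_mean_w, n)

    # BM: baseline prevalence at time 0, exponential onset among the rest
    baseline = rng.random(n) < profile.bm_baseline
    if profile.bm_cumulative >= 1.0:
        raise ValueError("bm_cumulative must be < 1")
    bm_rate = -np.log1p(-profile.bm_cumulative) / T
    onset = rng.exponential(1.0 / bm_rate, n) if bm_rate > 0 else np.full(n, np.inf)
    follow = np.minimum(os_t, C)
    bm_time = np.where(baseline, 0.0, np.where(onset <= follow, onset, follow))
    bm_event = np.where(baseline, 1, (onset <= follow).astype(int))

    rows = {
        "PFS": (np.minimum(pfs_t, C), (pfs_t <= C).astype(int)),
        "OS": (np.minimum(os_t, C), (os_t <= C).astype(int)),
        "duration": (np.minimum(dur_t, C), (dur_t <= C).astype(int)),
        "BM": (bm_time, bm_event),
    }

    # adverse events: per-cycle Bernoulli at the weekly probability implied by
    # the incidence over the mean duration, over each patient's (uncensored)
    # treatment duration, so events per patient is an unbiased frequency
    ae_rows = []
    for ae in sorted(profile.ae_incidences):
        inc = profile.ae_incidences[ae]
        if inc == 0:
            continue
        r = inc / dur_mean_w
        p = -np.expm1(-r)
        full_weeks = np.floor(dur_t).astype(int)
        counts = rng.binomial(full_weeks, p)
        counts += rng.random(n) < -np.expm1(-r * (dur_t - full_weeks))
        for pid in np.nonzero(counts)[0]:
            weeks = np.sort(rng.uniform(0.0, dur_t[pid], counts[pid]))
            for w in weeks:
                ae_rows.append((pid, ae, float(w), int(w <= C)))
    return rows, ae_rows


def generate_trial(
    profiles: dict[str, ArmProfile] | list[ArmProfile], seed: int
) -> TrialData:
    """Generate a two-arm pseudo-trial; identical seeds give identical output."""
    if seed is None:
        raise ValueError("a seed is required")
    if isinstance(profiles, dict):
        profiles = list(profiles.values())
    rng = np.random.default_rng(seed)
    ipd_parts, ae_parts = [], []
    offset = 0
    for profile in profiles:
        rows, ae_rows = _generate_arm(profile, rng)
        pids = np.arange(offset, offset + profile.n_patients)
        for endpoint in ENDPOINTS:
            t, e = rows[endpoint]
            ipd_parts.append(
                pd.DataFrame(
                    {
                        "patient_id": pids,
                        "arm": profile.name,
                        "endpoint": endpoint,
                        "time_weeks": t,
                        "event": e,
                    }
                )
            )
        if ae_rows:
            pid_idx, aes, weeks, in_trial = zip(*ae_rows)
            ae_parts.append(
                pd.DataFrame(
                    {
                        "patient_id": pids[list(pid_idx)],
                        "arm": profile.name,
                        "ae": aes,
                        "week": weeks,
                        "in_trial": in_trial,
                    }
                )
            )
        offset += profile.n_patients
    ipd = pd.concat(ipd_parts, ignore_index=True)
    ae = (
        pd.concat(ae_parts, ignore_index=True)
        if ae_parts
        else pd.DataFrame(columns=["patient_id", "arm", "ae", "week", "in_trial"])
    )
    return TrialData(ipd=ipd, ae_events=ae, seed=int(seed))


def write_trial(data: TrialData, directory: str | Path) -> dict[str, Path]:
    """Write the IPD and AE tables as CSV plus a JSON metadata sidecar."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "ipd": directory / "ipd.csv",
        "ae_events": directory / "ae_events.csv",
        "meta": directory / "ipd_meta.json",
    }
    data.ipd.to_csv(paths["ipd"], index=False)
    data.ae_events.to_csv(paths["ae_events"], index=False)
    paths["meta"].write_text(
        json.dumps({"seed": data.seed, "n_records": int(len(data.ipd))}, indent=2)
    )
    return paths


def read_trial(directory: str | Path) -> TrialData:
    directory = Path(directory)
    meta = json.loads((directory / "ipd_meta.json").read_text())
    return TrialData(
        ipd=pd.read_csv(directory / "ipd.csv"),
        ae_events=pd.read_csv(directory / "ae_events.csv"),
        seed=int(meta["seed"]),
    )
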