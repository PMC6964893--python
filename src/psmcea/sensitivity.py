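"""Deterministic, probabilistic and scenario sensitivity analyses.

The deterministic (one-way) analysis substitutes each parameter's low and
high bound in turn, re-evaluates the full model and reports the tornado
table.  The probabilistic analysis samples utilities from moment-matched
gamma distributions, costs from moment-matched log-normals, and parametric
survival tails from a multivariate normal on the unconstrained parameter
scale via the Cholesky factor of the fit covariance; each iteration
re-evaluates both arms.  The acceptability curve applies the net-monetary-
benefit rule, NMB(lambda) = lambda * dQALY - dCost > 0, which stays well
defined under dominance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cea import CEResult
from .config import PsaSettings
from .model import CEModel

__all__ = [
    "run_dsa",
    "sample_parameters",
    "run_psa",
    "PsaResult",
    "ceac",
    "run_scenario",
]

logger = logging.getLogger(__name__)


def _icer_or_nan(result: CEResult) -> float:
    v = result.icer
    return np.nan if v is None else float(v)


def run_dsa(model: CEModel, parameters=None) -> pd.DataFrame:
    """One-way (tornado) sensitivity analysis.

    Each parameter is set to its low and high bound with everything else at
    base; rows are sorted by bar width (|ICER_high - ICER_low|) descending.
    """
    if parameters is None:
        parameters = model.config.dsa
    base = model.base_case()
    base_icer = _icer_or_nan(base)
    rows = []
    for p in parameters:
        icer_low = _icer_or_nan(model.evaluate({p.path: p.low}))
        icer_high = _icer_or_nan(model.evaluate({p.path: p.high}))
        rows.append(
            {
                "parameter": p.name,
                "path": p.path,
                "low": p.low,
                "high": p.high,
                "icer_base": base_icer,
                "icer_at_low": icer_low,
                "icer_at_high": icer_high,
                "width": abs(icer_high - icer_low),
            }
        )
    df = pd.DataFrame(rows)
    return df.sort_values("width", ascending=False, kind="stable").reset_index(drop=True)


def _gamma_moments(mean: float, sd: float) -> tuple[float, float]:
    shape = (mean / sd) ** 2
    scale = sd**2 / mean
    return shape, scale


def _lognormal_moments(mean: float, sd: float) -> tuple[float, float]:
    sigma2 = np.log1p((sd / mean) ** 2)
    mu = np.log(mean) - 0.5 * sigma2
    return mu, float(np.sqrt(sigma2))


def sample_parameters(
    model: CEModel, psa: PsaSettings, rng: np.random.Generator
) -> tuple[dict[str, float], dict[tuple[str, str], np.ndarray]]:
    """Draw one PSA parameter set: config overrides + survival tail params.

    Gamma and log-normal draws are moment matched to the configured mean and
    standard deviation.  Survival tails are drawn jointly per (arm,
    endpoint) as mean + L z with L the Cholesky factor of the fit
    covariance; the reference-arm OS tail is shared by both arms through the
    hybrid construction.  Sampled utilities are truncated at 1.
    """
    overrides: dict[str, float] = {}
    for p in psa.parameters:
        if p.distribution == "gamma":
            shape, scale = _gamma_moments(p.mean, p.sd)
            value = float(rng.gamma(shape, scale))
        else:
            mu, sigma = _lognormal_moments(p.mean, p.sd)
            value = float(rng.lognormal(mu, sigma))
        if p.path.startswith("utilities."):
            value = min(value, 1.0)
        overrides[p.path] = value

    survival: dict[tuple[str, str], np.ndarray] = {}
    if psa.include_survival:
        ref = model.config.extrapolation.os_reference_arm
        for arm, af in model.arm_fits.items():
            for endpoint in ("pfs", "duration", "os"):
                if endpoint == "os" and arm != ref:
                    continue  # non-reference OS tail follows the reference arm
                fit = af.fits[endpoint]
                chol = np.linalg.cholesky(
                    fit.covariance + 1e-12 * np.eye(fit.covariance.shape[0])
                )
                z = rng.standard_normal(fit.params.size)
                survival[(arm, endpoint)] = fit.params + chol @ z
    return overrides, survival


@dataclass
class PsaResult:
    """Per-iteration increments plus summary statistics."""

    samples: pd.DataFrame
    n_failed: int
    seed: int

    def summary(self) -> dict:
        s = self.samples
        icers = s["icer"].dropna()
        return {
            "iterations": int(len(s)),
            "failed": self.n_failed,
            "mean_delta_cost": float(s["delta_cost"].mean()),
            "mean_delta_qaly": float(s["delta_qaly"].mean()),
            "median_delta_cost": float(s["delta_cost"].median()),
            "median_delta_qaly": float(s["delta_qaly"].median()),
            "median_icer": float(icers.median()) if len(icers) else None,
            "icer_of_means": float(s["delta_cost"].mean() / s["delta_qaly"].mean())
            if s["delta_qaly"].mean() != 0
            else None,
        }


def run_psa(model: CEModel, psa: PsaSettings | None = None, seed: int | None = None) -> PsaResult:
    """Monte-Carlo probabilistic sensitivity analysis.

    Reproducible from (settings, seed); iterations whose evaluation fails
    are logged, recorded as missing and excluded from summaries.
    """
    if psa is None:
        psa = model.config.psa
    if seed is None:
        seed = model.config.seeds.get("psa", 0)
    rng = np.random.default_rng(seed)
    rows = []
    n_failed = 0
    for it in range(psa.iterations):
        overrides, survival = sample_parameters(model, psa, rng)
        try:
            result = model.evaluate(overrides, survival_params=survival)
        except Exception as exc:  # pragma: no cover - defensive
            logger.warning("PSA iteration %d failed: %s", it, exc)
            n_failed += 1
            rows.append(
                {"iteration": it, "delta_cost": np.nan, "delta_qaly": np.nan,
                 "icer": np.nan, "dominance": "failed"}
            )
            continue
        rows.append(
            {
                "iteration": it,
                "delta_cost": result.delta_cost,
                "delta_qaly": result.delta_qaly,
                "icer": _icer_or_nan(result),
                "dominance": result.dominance,
            }
        )
    samples = pd.DataFrame(rows)
    ok = samples[samples["dominance"] != "failed"].reset_index(drop=True)
    if n_failed:
        logger.warning("PSA: %d of %d iterations failed", n_failed, psa.iterations)
    return PsaResult(samples=ok, n_failed=n_failed, seed=int(seed))


def ceac(samples: pd.DataFrame, wtp_grid) -> pd.DataFrame:
    """Cost-effectiveness acceptability curve.

    For each willingness-to-pay threshold, the fraction of iterations with
    positive net monetary benefit lambda * dQALY - dCost.
    """
    if len(samples) == 0:
        raise ValueError("empty PSA sample set")
    dq = samples["delta_qaly"].to_numpy(float)
    dc = samples["delta_cost"].to_numpy(float)
    wtp = np.asarray(list(wtp_grid), dtype=float)
    prob = [(lam * dq - dc > 0).mean() for lam in wtp]
    return pd.DataFrame({"wtp": wtp, "probability": prob})


def run_scenario(model: CEModel, second_line_mix: dict[str, dict[str, float]] | None = None) -> CEResult:
    """Re-evaluate under an alternative treatment pathway (second-line drug
    mixes per arm); the base engine, occupancies and utilities are unchanged."""
    if second_line_mix is None:
        second_line_mix = model.config.scenario.second_line_mix
    mix = dict(model.config.costs.second_line_mix)
    mix.update(second_line_mix)
    return model.evaluate({"costs.second_line_mix": mix})
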