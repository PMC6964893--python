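"""Survival curve estimation, parametric fitting, selection and extrapolation.

Within the trial window survival is summarised non-parametrically
(product-limit estimator on a weekly grid); beyond it, a parametric tail is
attached by conditional-survival scaling so that the hybrid curve is
continuous at the cutover and the post-cutover per-cycle death probability is
that of the parametric (or reference) extrapolation.

All parametric families are parameterised on an unconstrained scale
(logarithms of positive parameters; real-valued parameters kept as is) so
that multivariate-normal perturbation of the fitted parameters — as used in
probabilistic sensitivity analysis — never produces an invalid distribution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from scipy import optimize, stats
from statsmodels.tools.numdiff import approx_hess1

__all__ = [
    "SurvivalCurve",
    "ParametricFit",
    "PHDiagnostic",
    "FitError",
    "FAMILIES",
    "DEFAULT_FAMILIES",
    "kaplan_meier",
    "fit_parametric",
    "fit_all_families",
    "check_ph",
    "select_family",
    "family_table",
    "build_hybrid_curve",
    "apply_reference_hazards",
]

_TOL = 1e-9


class FitError(RuntimeError):
    """Raised when a parametric fit cannot be produced (no events, divergence)."""


# ---------------------------------------------------------------------------
# survival curve on the weekly grid
# ---------------------------------------------------------------------------


@dataclass
class SurvivalCurve:
    """Survival probability on a uniform weekly grid.

    ``surv[i]`` is S(t) at elapsed week ``i`` (left-closed convention;
    evaluation between grid points is last-value carry-forward).
    """

    surv: np.ndarray

    def __post_init__(self) -> None:
        self.surv = np.asarray(self.surv, dtype=float)
        if self.surv.ndim != 1 or self.surv.size < 1:
            raise ValueError("survival curve needs a 1-d grid of at least one point")
        if abs(self.surv[0] - 1.0) > _TOL:
            raise ValueError(f"S(0) must be 1, got {self.surv[0]!r}")
        if np.any(self.surv < -_TOL) or np.any(self.surv > 1 + _TOL):
            raise ValueError("survival values outside [0, 1]")
        if np.any(np.diff(self.surv) > _TOL):
            raise ValueError("survival curve must be non-increasing")
        self.surv = np.clip(self.surv, 0.0, 1.0)
        self.surv = np.minimum.accumulate(self.surv)

    @property
    def n_weeks(self) -> int:
        return self.surv.size - 1

    def __len__(self) -> int:
        return self.surv.size

    def at(self, week: int) -> float:
        """S at an integer week (carry-forward beyond the grid)."""
        return float(self.surv[min(int(week), self.n_weeks)])

    def extended(self, n_weeks: int) -> "SurvivalCurve":
        """Carry the last value forward to cover ``n_weeks`` weeks."""
        if n_weeks <= self.n_weeks:
            return SurvivalCurve(self.surv[: n_weeks + 1].copy())
        pad = np.full(n_weeks - self.n_weeks, self.surv[-1])
        return SurvivalCurve(np.concatenate([self.surv, pad]))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"week": np.arange(self.surv.size), "survival": self.surv})


def kaplan_meier(times, events, n_weeks: int | None = None) -> SurvivalCurve:
    """Product-limit estimator resampled onto the weekly grid.

    Parameters
    ----------
    times, events
        Equal-length vectors of follow-up times in weeks (>= 0) and event
        indicators (1 = event, 0 = right-censored).
    n_weeks
        Length of the output grid; defaults to ceil(max(times)).  Beyond the
        last observation the last estimate is carried forward.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if times.size == 0:
        raise ValueError("empty survival data")
    if times.shape != events.shape:
        raise ValueError("times and events must have equal length")
    if np.any(times < 0):
        raise ValueError("negative times")
    if n_weeks is None:
        n_weeks = int(np.ceil(times.max()))
    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events)
    grid = np.arange(n_weeks + 1, dtype=float)
    if np.any((times == 0) & (events == 1)):
        raise ValueError("events at time 0 are not representable on the weekly grid")
    surv = kmf.predict(grid).to_numpy(dtype=float)
    surv[0] = 1.0
    return SurvivalCurve(surv)


# ---------------------------------------------------------------------------
# parametric families on unconstrained parameter scales
# ---------------------------------------------------------------------------


def _exp_logsf(t, p):
    return -np.exp(p[0]) * t


def _exp_logpdf(t, p):
    return p[0] - np.exp(p[0]) * t


def _weibull_logsf(t, p):
    k, b = np.exp(p[0]), np.exp(p[1])
    return -((t / b) ** k)


def _weibull_logpdf(t, p):
    k, b = np.exp(p[0]), np.exp(p[1])
    return np.log(k / b) + (k - 1) * np.log(t / b) - (t / b) ** k


def _gamma_logsf(t, p):
    a, r = np.exp(p[0]), np.exp(p[1])
    return stats.gamma.logsf(t, a, scale=1.0 / r)


def _gamma_logpdf(t, p):
    a, r = np.exp(p[0]), np.exp(p[1])
    return stats.gamma.logpdf(t, a, scale=1.0 / r)


def _lognorm_logsf(t, p):
    mu, sigma = p[0], np.exp(p[1])
    return stats.lognorm.logsf(t, sigma, scale=np.exp(mu))


def _lognorm_logpdf(t, p):
    mu, sigma = p[0], np.exp(p[1])
    return stats.lognorm.logpdf(t, sigma, scale=np.exp(mu))


def _loglogistic_logsf(t, p):
    c, b = np.exp(p[0]), np.exp(p[1])
    return stats.fisk.logsf(t, c, scale=b)


def _loglogistic_logpdf(t, p):
    c, b = np.exp(p[0]), np.exp(p[1])
    return stats.fisk.logpdf(t, c, scale=b)


def _gompertz_cumhaz(t, p):
    b, eta = p[0], np.exp(p[1])  # shape b is real-valued (negative = decreasing hazard)
    t = np.asarray(t, dtype=float)
    if abs(b) < 1e-12:
        return eta * t
    return eta * np.expm1(b * t) / b


def _gompertz_logsf(t, p):
    return -_gompertz_cumhaz(t, p)


def _gompertz_logpdf(t, p):
    b, eta = p[0], np.exp(p[1])
    return np.log(eta) + b * np.asarray(t, dtype=float) - _gompertz_cumhaz(t, p)


def _gengamma_logsf(t, p):
    a, c, b = np.exp(p[0]), p[1], np.exp(p[2])
    return stats.gengamma.logsf(t, a, c, scale=b)


def _gengamma_logpdf(t, p):
    a, c, b = np.exp(p[0]), p[1], np.exp(p[2])
    return stats.gengamma.logpdf(t, a, c, scale=b)


FAMILIES: dict[str, dict] = {
    "exponential": {"k": 1, "logsf": _exp_logsf, "logpdf": _exp_logpdf},
    "weibull": {"k": 2, "logsf": _weibull_logsf, "logpdf": _weibull_logpdf},
    "gamma": {"k": 2, "logsf": _gamma_logsf, "logpdf": _gamma_logpdf},
    "log-normal": {"k": 2, "logsf": _lognorm_logsf, "logpdf": _lognorm_logpdf},
    "log-logistic": {"k": 2, "logsf": _loglogistic_logsf, "logpdf": _loglogistic_logpdf},
    "gompertz": {"k": 2, "logsf": _gompertz_logsf, "logpdf": _gompertz_logpdf},
    "generalized-gamma": {"k": 3, "logsf": _gengamma_logsf, "logpdf": _gengamma_logpdf},
}

#: Families entered in routine information-criterion selection.  The
#: generalized gamma is available but must be requested explicitly.
DEFAULT_FAMILIES = (
    "exponential",
    "weibull",
    "gamma",
    "log-normal",
    "log-logistic",
    "gompertz",
)


@dataclass
class ParametricFit:
    """Maximum-likelihood fit of one parametric survival family.

    ``params`` live on the family's unconstrained scale and ``covariance`` is
    the inverse observed information at the optimum on that same scale.
    """

    family: str
    params: np.ndarray
    loglik: float
    aic: float
    bic: float
    covariance: np.ndarray
    n: int
    n_events: int
    converged: bool = True
    message: str = ""

    @property
    def k(self) -> int:
        return self.params.size

    def logsf(self, t):
        return FAMILIES[self.family]["logsf"](np.asarray(t, dtype=float), self.params)

    def survival(self, t):
        return np.exp(self.logsf(t))

    def curve(self, n_weeks: int) -> SurvivalCurve:
        grid = np.arange(n_weeks + 1, dtype=float)
        return SurvivalCurve(np.exp(self.logsf(grid)))

    def with_params(self, params) -> "ParametricFit":
        """Same family with substituted parameters (PSA perturbation)."""
        params = np.asarray(params, dtype=float)
        if params.shape != self.params.shape:
            raise ValueError("parameter vector has wrong length")
        return ParametricFit(
            family=self.family,
            params=params,
            loglik=np.nan,
            aic=np.nan,
            bic=np.nan,
            covariance=self.covariance,
            n=self.n,
            n_events=self.n_events,
            converged=self.converged,
            message="parameters substituted",
        )

    def to_dict(self) -> dict:
        return {
            "family": self.family,
            "params": self.params.tolist(),
            "loglik": self.loglik,
            "aic": self.aic,
            "bic": self.bic,
            "covariance": self.covariance.tolist(),
            "n": self.n,
            "n_events": self.n_events,
            "converged": self.converged,
        }


def _neg_loglik(p, times, events, fam):
    with np.errstate(all="ignore"):
        ll = np.where(
            events == 1,
            fam["logpdf"](times, p),
            fam["logsf"](times, p),
        )
    if not np.all(np.isfinite(ll)):
        return 1e12
    return -float(ll.sum())


def _starts(family: str, times, events) -> list[np.ndarray]:
    total = times.sum()
    d = max(int(events.sum()), 1)
    rate = d / max(total, 1e-12)
    log_r = np.log(rate)
    et = times[events == 1]
    et = et[et > 0]
    med = np.median(et) if et.size else 1.0 / rate
    mu0 = float(np.mean(np.log(et))) if et.size else np.log(med)
    sd0 = float(np.std(np.log(et))) if et.size > 1 else 1.0
    sd0 = max(sd0, 0.1)
    if family == "exponential":
        return [np.array([log_r])]
    if family == "weibull":
        return [
            np.array([0.0, -log_r]),
            np.array([np.log(0.7), -log_r]),
            np.array([np.log(1.5), -log_r]),
        ]
    if family == "gamma":
        return [
            np.array([0.0, log_r]),
            np.array([np.log(2.0), np.log(2 * rate)]),
            np.array([np.log(0.5), np.log(0.5 * rate)]),
        ]
    if family == "log-normal":
        return [np.array([mu0, np.log(sd0)]), np.array([np.log(med), 0.0])]
    if family == "log-logistic":
        return [np.array([np.log(1.2), np.log(med)]), np.array([0.0, -log_r])]
    if family == "gompertz":
        return [
            np.array([1e-4, log_r]),
            np.array([0.01, log_r]),
            np.array([-0.01, log_r]),
        ]
    if family == "generalized-gamma":
        return [np.array([0.0, 1.0, -log_r]), np.array([0.0, -1.0, -log_r])]
    raise ValueError(f"unknown family {family!r}")


def fit_parametric(times, events, family: str) -> ParametricFit:
    """Fit a right-censored parametric survival model by maximum likelihood.

    Raises :class:`FitError` when there are no events or the optimiser fails
    from every start.
    """
    if family not in FAMILIES:
        raise ValueError(f"unknown family {family!r}; choose from {sorted(FAMILIES)}")
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if times.size == 0:
        raise ValueError("empty survival data")
    if np.any(times < 0):
        raise ValueError("negative times")
    if events.sum() < 1:
        raise FitError("no events: parametric fit is unidentified")
    # zero event times break log densities; nudge onto the open half-line
    times = np.where((times <= 0) & (events == 1), 1e-6, times)
    fam = FAMILIES[family]

    if family == "exponential":
        # closed form: rate = events / total exposure; information = events
        d, exposure = float(events.sum()), float(times.sum())
        rate = d / exposure
        loglik = d * np.log(rate) - rate * exposure
        return ParametricFit(
            family="exponential",
            params=np.array([np.log(rate)]),
            loglik=loglik,
            aic=2 - 2 * loglik,
            bic=np.log(times.size) - 2 * loglik,
            covariance=np.array([[1.0 / d]]),
            n=times.size,
            n_events=int(d),
        )

    best = None
    for x0 in _starts(family, times, events):
        res = optimize.minimize(
            _neg_loglik,
            x0,
            args=(times, events, fam),
            method="Nelder-Mead",
            options={"xatol": 1e-10, "fatol": 1e-10, "maxiter": 5000},
        )
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.isfinite(best.fun) or best.fun >= 1e11:
        raise FitError(f"optimiser failed for family {family!r}: {best}")

    params = np.asarray(best.x, dtype=float)
    loglik = -float(best.fun)
    k = params.size
    n = times.size
    aic = 2 * k - 2 * loglik
    bic = k * np.log(n) - 2 * loglik

    hess = approx_hess1(params, _neg_loglik, args=(times, events, fam))
    hess = 0.5 * (hess + hess.T)
    try:
        cov = np.linalg.inv(hess)
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(hess)
    cov = 0.5 * (cov + cov.T)
    # clip tiny negative eigenvalues so the PSA Cholesky never fails
    w, v = np.linalg.eigh(cov)
    cov = (v * np.maximum(w, 0.0)) @ v.T
    return ParametricFit(
        family=family,
        params=params,
        loglik=loglik,
        aic=aic,
        bic=bic,
        covariance=cov,
        n=n,
        n_events=int(events.sum()),
        converged=bool(best.success),
        message=str(best.message),
    )


def fit_all_families(times, events, families=DEFAULT_FAMILIES) -> list[ParametricFit]:
    """Fit every requested family, silently dropping ones that fail."""
    fits = []
    for fam in families:
        try:
            fits.append(fit_parametric(times, events, fam))
        except FitError:
            continue
    if not fits:
        raise FitError("no family could be fitted")
    return fits


def select_family(fits: list[ParametricFit]) -> str:
    """Family with minimal AIC; ties broken by fewer parameters, then name."""
    if not fits:
        raise ValueError("empty fit list")
    return min(fits, key=lambda f: (f.aic, f.k, f.family)).family


def family_table(fits: list[ParametricFit]) -> pd.DataFrame:
    """AIC/BIC comparison table (AIC order), with the BIC ranking alongside."""
    df = pd.DataFrame(
        {
            "family": [f.family for f in fits],
            "k": [f.k for f in fits],
            "loglik": [f.loglik for f in fits],
            "aic": [f.aic for f in fits],
            "bic": [f.bic for f in fits],
        }
    )
    df["bic_rank"] = df["bic"].rank(method="min").astype(int)
    return df.sort_values(["aic", "k", "family"]).reset_index(drop=True)


# ---------------------------------------------------------------------------
# proportional-hazards diagnostic
# ---------------------------------------------------------------------------


@dataclass
class PHDiagnostic:
    """Log-cumulative-hazard curves on log time, with a parallelism summary.

    Parallel straight lines (slope difference ~ 0) support proportional
    hazards between the arms; the accept/reject threshold is the caller's.
    """

    log_time_a: np.ndarray
    log_cum_haz_a: np.ndarray
    log_time_b: np.ndarray
    log_cum_haz_b: np.ndarray
    slope_a: float
    slope_b: float

    @property
    def slope_difference(self) -> float:
        return self.slope_b - self.slope_a


def _log_cum_haz(curve: SurvivalCurve):
    t = np.arange(len(curve), dtype=float)
    s = curve.surv
    mask = (t > 0) & (s > 0.0) & (s < 1.0)
    if mask.sum() < 2:
        raise ValueError("curve carries no usable hazard information (S stuck at 0 or 1)")
    return np.log(t[mask]), np.log(-np.log(s[mask]))


def check_ph(curve_a: SurvivalCurve, curve_b: SurvivalCurve) -> PHDiagnostic:
    """Log-cumulative transformation diagnostic for proportional hazards."""
    xa, ya = _log_cum_haz(curve_a)
    xb, yb = _log_cum_haz(curve_b)
    slope_a = float(np.polyfit(xa, ya, 1)[0])
    slope_b = float(np.polyfit(xb, yb, 1)[0])
    return PHDiagnostic(xa, ya, xb, yb, slope_a, slope_b)


# ---------------------------------------------------------------------------
# hybrid (trial + extrapolated tail) construction
# ---------------------------------------------------------------------------


def _scaled_tail(base_at_cut, tail_surv, tail_at_cut):
    return base_at_cut * tail_surv / tail_at_cut


def build_hybrid_curve(
    km: SurvivalCurve, fit: ParametricFit, cutover: int, n_weeks: int
) -> SurvivalCurve:
    """Trial curve up to ``cutover`` weeks, parametric tail beyond.

    The tail is attached by conditional-survival scaling,
    S(t) = S_km(c) * S_fit(t) / S_fit(c) for t > c, which is continuous at the
    cutover and inherits the parametric per-cycle hazard beyond it.
    """
    cutover = int(cutover)
    if cutover < 0 or cutover > km.n_weeks:
        raise ValueError("cutover outside the trial curve's grid")
    s_cut = km.at(cutover)
    if cutover > 0 and s_cut <= 0:
        raise ValueError("zero survival at the cutover: tail scaling undefined")
    grid = np.arange(n_weeks + 1, dtype=float)
    fit_surv = np.exp(fit.logsf(grid))
    if cutover == 0:
        return SurvivalCurve(fit_surv)
    if fit_surv[cutover] <= 0:
        raise ValueError("parametric survival vanishes at the cutover")
    out = np.empty(n_weeks + 1)
    head = min(cutover, n_weeks)
    out[: head + 1] = km.surv[: head + 1]
    if n_weeks > cutover:
        out[cutover + 1 :] = _scaled_tail(s_cut, fit_surv[cutover + 1 :], fit_surv[cutover])
    return SurvivalCurve(np.clip(out, 0.0, None))


def apply_reference_hazards(
    target: SurvivalCurve, reference: SurvivalCurve, cutover: int
) -> SurvivalCurve:
    """Continue ``target`` beyond ``cutover`` with the reference arm's hazards.

    For t > cutover the per-cycle death probability of the output equals the
    reference curve's, so the output equals
    S_target(c) * S_ref(t) / S_ref(c).  Used to impose equal long-term
    efficacy across arms.
    """
    cutover = int(cutover)
    if cutover < 0 or cutover > reference.n_weeks:
        raise ValueError("cutover outside the reference grid")
    s_ref_cut = reference.at(cutover)
    if s_ref_cut <= 0:
        raise ValueError("zero reference survival at the cutover")
    s_tgt_cut = target.at(cutover)
    n_weeks = reference.n_weeks
    out = np.empty(n_weeks + 1)
    head = target.extended(cutover).surv
    out[: cutover + 1] = head[: cutover + 1]
    out[cutover + 1 :] = _scaled_tail(s_tgt_cut, reference.surv[cutover + 1 :], s_ref_cut)
    return SurvivalCurve(np.clip(out, 0.0, None))
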