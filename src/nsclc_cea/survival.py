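"""Parametric survival curves, MLE fitting, Kaplan-Meier utilities, and
pseudo individual-patient-data (IPD) reconstruction from digitized curves.

Four families are supported, parameterized as they appear in the health
economic literature (time t in months):

* exponential   S(t) = exp(-rate * t)
* weibull       S(t) = exp(-(t / scale)^shape)
* loglogistic   S(t) = 1 / (1 + lambda * t^gamma)
* lognormal     S(t) = 1 - Phi((ln t - mu) / sigma)

Fitting maximises the right-censored log-likelihood
``sum_events log f(t) + sum_censored log S(t)`` (via lifelines), and model
selection uses AIC with BIC and a fixed family order as tie-breakers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from lifelines import (
    ExponentialFitter,
    KaplanMeierFitter,
    LogLogisticFitter,
    LogNormalFitter,
    WeibullFitter,
)
from lifelines.exceptions import ConvergenceError
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "FAMILIES",
    "ParametricSurvival",
    "FitResult",
    "FitConvergenceError",
    "KMCurve",
    "survival_at",
    "fit_mle",
    "fit_all_families",
    "select_best",
    "km_estimate",
    "reconstruct_ipd",
    "ipd_frame",
    "read_ipd",
    "write_ipd",
    "read_km_curve",
    "write_km_curve",
]

#: Fixed family order, also the model-selection tie-break order.
FAMILIES = ("exponential", "weibull", "loglogistic", "lognormal")

_REQUIRED_PARAMS = {
    "exponential": ("rate",),
    "weibull": ("shape", "scale"),
    "loglogistic": ("lambda", "gamma"),
    "lognormal": ("mu", "sigma"),
}


class FitConvergenceError(RuntimeError):
    """Raised when the likelihood optimiser fails to converge."""


@dataclass(frozen=True)
class ParametricSurvival:
    """A survival distribution family plus its parameters.

    Invariants: S(0) = 1, S non-increasing, S(t) in [0, 1].
    """

    family: str
    params: Mapping[str, float]

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}; expected one of {FAMILIES}")
        required = _REQUIRED_PARAMS[self.family]
        missing = [k for k in required if k not in self.params]
        if missing:
            raise ValueError(f"{self.family} requires params {required}, missing {missing}")
        positive = [k for k in required if k != "mu"]  # mu is a log-scale location
        for k in positive:
            if not np.isfinite(self.params[k]) or self.params[k] <= 0:
                raise ValueError(f"{self.family} param {k!r} must be > 0, "
                                 f"got {self.params[k]}")
        if not np.isfinite(self.params.get("mu", 0.0)):
            raise ValueError("lognormal mu must be finite")
        object.__setattr__(self, "params", dict(self.params))

    def _dist(self) -> stats.rv_continuous:
        p = self.params
        if self.family == "exponential":
            return stats.expon(scale=1.0 / p["rate"])
        if self.family == "weibull":
            return stats.weibull_min(c=p["shape"], scale=p["scale"])
        if self.family == "loglogistic":
            # scipy's fisk: S(t) = 1/(1+(t/s)^c)  =>  lambda = s^(-gamma)
            return stats.fisk(c=p["gamma"], scale=p["lambda"] ** (-1.0 / p["gamma"]))
        return stats.lognorm(s=p["sigma"], scale=np.exp(p["mu"]))

    def sf(self, t):
        """Survival probability S(t); accepts scalars or arrays, t >= 0."""
        t = np.asarray(t, dtype=float)
        if np.any(t < 0) or not np.all(np.isfinite(t)):
            raise ValueError("t must be finite and >= 0")
        return self._dist().sf(t)

    def ppf(self, q):
        """Event-time quantile: t such that F(t) = q."""
        return self._dist().ppf(q)

    @property
    def median(self) -> float:
        return float(self._dist().median())


def survival_at(model: ParametricSurvival, t) -> float:
    """Evaluate S(t) for the given parametric model (closed form)."""
    out = model.sf(t)
    return float(out) if np.ndim(out) == 0 else out


@dataclass(frozen=True)
class FitResult:
    model: ParametricSurvival
    loglik: float
    aic: float
    bic: float
    n: int


@dataclass(frozen=True)
class KMCurve:
    """A (possibly digitized) Kaplan-Meier step function.

    ``times`` are months (non-decreasing, starting at 0); ``surv`` the
    survival probabilities at those times; ``at_risk`` optional numbers at
    risk just before each time.
    """

    times: np.ndarray
    surv: np.ndarray
    at_risk: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        surv = np.asarray(self.surv, dtype=float)
        if times.shape != surv.shape or times.ndim != 1 or times.size == 0:
            raise ValueError("times and surv must be equal-length 1-D arrays")
        if np.any(np.diff(times) < 0):
            raise ValueError("times must be non-decreasing")
        if np.any(np.diff(surv) > 1e-12):
            raise ValueError("survival values must be non-increasing")
        if np.any((surv < -1e-12) | (surv > 1 + 1e-12)):
            raise ValueError("survival values must lie in [0, 1]")
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "surv", np.clip(surv, 0.0, 1.0))
        if self.at_risk is not None:
            ar = np.asarray(self.at_risk, dtype=float)
            if ar.shape != times.shape:
                raise ValueError("at_risk must align with times")
            object.__setattr__(self, "at_risk", ar)

    def step_interp(self, t) -> np.ndarray:
        """Right-continuous step interpolation S(t) (1.0 before first point)."""
        t = np.asarray(t, dtype=float)
        idx = np.searchsorted(self.times, t, side="right") - 1
        out = np.where(idx >= 0, self.surv[np.clip(idx, 0, None)], 1.0)
        return out


# ---------------------------------------------------------------------------
# IPD containers and I/O
# ---------------------------------------------------------------------------

def ipd_frame(times: Iterable[float], events: Iterable[int]) -> pd.DataFrame:
    """Build an IPD table with columns ``time_months`` / ``event`` (1 = event)."""
    df = pd.DataFrame({"time_months": np.asarray(list(times), dtype=float),
                       "event": np.asarray(list(events), dtype=int)})
    _check_ipd(df)
    return df


def _check_ipd(ipd: pd.DataFrame) -> pd.DataFrame:
    for col in ("time_months", "event"):
        if col not in ipd.columns:
            raise ValueError(f"IPD table must have a {col!r} column")
    t = ipd["time_months"].to_numpy(dtype=float)
    if t.size == 0:
        raise ValueError("IPD table is empty")
    if np.any(~np.isfinite(t)) or np.any(t <= 0):
        raise ValueError("times must be finite and > 0")
    ev = ipd["event"].to_numpy()
    if not np.isin(ev, (0, 1)).all():
        raise ValueError("event must be 0 (censored) or 1 (observed)")
    return ipd


def read_ipd(path) -> pd.DataFrame:
    return _check_ipd(pd.read_csv(path))


def write_ipd(ipd: pd.DataFrame, path) -> None:
    _check_ipd(ipd)[["time_months", "event"]].to_csv(path, index=False)


def read_km_curve(path, at_risk_path=None) -> KMCurve:
    df = pd.read_csv(path)
    at_risk = None
    if at_risk_path is not None:
        at_risk = pd.read_csv(at_risk_path)["at_risk"].to_numpy(dtype=float)
    return KMCurve(df["time_months"].to_numpy(dtype=float),
                   df["survival"].to_numpy(dtype=float), at_risk)


def write_km_curve(curve: KMCurve, path, at_risk_path=None) -> None:
    pd.DataFrame({"time_months": curve.times, "survival": curve.surv}).to_csv(
        path, index=False)
    if at_risk_path is not None and curve.at_risk is not None:
        pd.DataFrame({"time_months": curve.times, "at_risk": curve.at_risk}).to_csv(
            at_risk_path, index=False)


# ---------------------------------------------------------------------------
# Maximum-likelihood fitting and model selection
# ---------------------------------------------------------------------------

_FITTERS = {
    "exponential": ExponentialFitter,
    "weibull": WeibullFitter,
    "loglogistic": LogLogisticFitter,
    "lognormal": LogNormalFitter,
}


def _to_native(family: str, fitter) -> ParametricSurvival:
    if family == "exponential":
        return ParametricSurvival("exponential", {"rate": 1.0 / fitter.lambda_})
    if family == "weibull":
        return ParametricSurvival("weibull", {"shape": fitter.rho_, "scale": fitter.lambda_})
    if family == "loglogistic":
        # lifelines: S(t) = 1/(1+(t/alpha)^beta)
        return ParametricSurvival(
            "loglogistic",
            {"lambda": fitter.alpha_ ** (-fitter.beta_), "gamma": fitter.beta_})
    return ParametricSurvival("lognormal", {"mu": fitter.mu_, "sigma": fitter.sigma_})


def fit_mle(ipd: pd.DataFrame, family: str) -> FitResult:
    """Fit one family to right-censored IPD by maximum likelihood."""
    _check_ipd(ipd)
    if family not in FAMILIES:
        raise ValueError(f"unknown family {family!r}")
    if len(ipd) < 2:
        raise ValueError("need at least 2 records")
    n_events = int(ipd["event"].sum())
    if n_events < 1:
        raise ValueError("need at least 1 observed event to fit")
    fitter = _FITTERS[family]()
    try:
        fitter.fit(ipd["time_months"], event_observed=ipd["event"])
    except ConvergenceError as exc:  # pragma: no cover - data dependent
        raise FitConvergenceError(f"{family} fit failed to converge: {exc}") from exc
    n = len(ipd)
    k = len(_REQUIRED_PARAMS[family])
    loglik = float(fitter.log_likelihood_)
    return FitResult(model=_to_native(family, fitter), loglik=loglik,
                     aic=2 * k - 2 * loglik, bic=k * np.log(n) - 2 * loglik, n=n)


def fit_all_families(ipd: pd.DataFrame) -> list[FitResult]:
    """Fit all four families; skip (with a log line) any that fail."""
    out = []
    for family in FAMILIES:
        try:
            out.append(fit_mle(ipd, family))
        except FitConvergenceError:
            logger.warning("family %s did not converge; excluded from selection", family)
    if not out:
        raise FitConvergenceError("no family converged")
    return out


def select_best(fits: Sequence[FitResult]) -> FitResult:
    """Lowest AIC; ties broken by BIC, then by fixed family order."""
    fits = list(fits)
    if not fits:
        raise ValueError("empty collection of fits")
    return min(fits, key=lambda f: (f.aic, f.bic, FAMILIES.index(f.model.family)))


# ---------------------------------------------------------------------------
# Kaplan-Meier estimation and pseudo-IPD reconstruction
# ---------------------------------------------------------------------------

def km_estimate(ipd: pd.DataFrame) -> KMCurve:
    """Product-limit estimator (events precede censorings at tied times)."""
    _check_ipd(ipd)
    kmf = KaplanMeierFitter()
    kmf.fit(ipd["time_months"], event_observed=ipd["event"])
    sf = kmf.survival_function_
    times = sf.index.to_numpy(dtype=float)
    surv = sf.iloc[:, 0].to_numpy(dtype=float)
    at_risk = kmf.event_table["at_risk"].reindex(sf.index).to_numpy(dtype=float)
    return KMCurve(times=times, surv=surv, at_risk=at_risk)


def reconstruct_ipd(curve: KMCurve, total_n: int, censor_time: float) -> pd.DataFrame:
    """Allocate events to digitized KM coordinates to produce pseudo-IPD.

    Successive survival ratios fix the number of events per interval; events
    are placed at the midpoint of their interval (they occurred somewhere
    between two digitized coordinates, and the midpoint avoids a systematic
    right shift of the fitted time scale).  When ``curve.at_risk`` is
    supplied, interval censorings are additionally allocated so the at-risk
    counts are honoured, otherwise all censoring is administrative at
    ``censor_time``.  This is the simplified allocation scheme (not the full
    published reconstruction algorithm): its contract is that the KM
    estimate of the output matches the input coordinates.
    """
    if total_n <= 0:
        raise ValueError("total_n must be > 0")
    if censor_time <= 0:
        raise ValueError("censor_time must be > 0")
    times, surv = curve.times, curve.surv
    at_risk = curve.at_risk
    rec_t: list[float] = []
    rec_e: list[int] = []
    r = int(total_n)       # currently at risk
    s_model = 1.0          # KM value implied by allocations so far
    t_prev = 0.0
    for i, (ti, si) in enumerate(zip(times, surv)):
        if ti <= 0 or r <= 0 or s_model <= 0:
            continue
        d = int(round(r * (1.0 - si / s_model)))
        d = min(max(d, 0), r)
        if d > 0:
            t_event = 0.5 * (t_prev + float(ti))
            rec_t.extend([t_event] * d)
            rec_e.extend([1] * d)
            s_model *= 1.0 - d / r
            r -= d
        t_prev = float(ti)
        if at_risk is not None and i + 1 < len(times):
            c = int(round(r - at_risk[i + 1]))
            c = min(max(c, 0), r)
            if c > 0:
                tc = 0.5 * (ti + times[i + 1])
                rec_t.extend([float(tc)] * c)
                rec_e.extend([0] * c)
                r -= c
    if r > 0:
        rec_t.extend([float(censor_time)] * r)
        rec_e.extend([0] * r)
    return ipd_frame(rec_t, rec_e)
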