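"""Parametric accelerated-failure-time (AFT) survival laws for time to PONV.

Implements the four standard AFT families used for extrapolating the
postoperative-nausea-and-vomiting (PONV) incidence curve — exponential,
Weibull, log-logistic and log-normal — in the survreg-style location/scale
parameterisation: log event time = intercept (mu) + scale (sigma) x error,
with sigma = exp(log_scale).  For the Weibull family this gives

    S(t) = exp(-exp((ln t - mu) / sigma))

Maximum-likelihood fitting with right-censoring is delegated to lifelines;
fitted parameters are converted back into the location/scale convention.
Model selection uses AIC (ties broken by BIC, then by fewer parameters).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "AFT_FAMILIES",
    "AFTParameters",
    "EventTimeData",
    "FitResult",
    "survival_probability",
    "interval_event_probability",
    "fit_aft",
    "select_distribution",
    "information_criteria",
]

AFT_FAMILIES = ("exponential", "weibull", "loglogistic", "lognormal")

#: number of free parameters per family (exponential has sigma fixed at 1)
N_FREE_PARAMS = {"exponential": 1, "weibull": 2, "loglogistic": 2, "lognormal": 2}


@dataclass(frozen=True)
class AFTParameters:
    """A parametric AFT law: family, location mu on log-time, log sigma."""

    family: str
    intercept: float
    log_scale: float = 0.0

    def __post_init__(self) -> None:
        if self.family not in AFT_FAMILIES:
            raise ValueError(
                f"unsupported AFT family {self.family!r}; expected one of {AFT_FAMILIES}"
            )
        if self.family == "exponential" and self.log_scale != 0.0:
            raise ValueError("exponential family fixes log_scale at 0")

    @property
    def scale(self) -> float:
        return math.exp(self.log_scale)


@dataclass
class EventTimeData:
    """Right-censored event times: ``event[i] = 1`` means PONV observed."""

    times: np.ndarray
    event: np.ndarray
    unit: str = "days"

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.event = np.asarray(self.event, dtype=int)
        if self.times.shape != self.event.shape:
            raise ValueError("times and event must have equal length")
        if self.times.size and np.min(self.times) <= 0:
            raise ValueError("all event times must be positive")
        if self.event.size and not np.isin(self.event, (0, 1)).all():
            raise ValueError("event flags must be 0 (censored) or 1 (event)")

    def __len__(self) -> int:
        return self.times.size

    @property
    def n_events(self) -> int:
        return int(self.event.sum())

    def to_csv(self, path) -> None:
        import pandas as pd

        pd.DataFrame({"time": self.times, "event": self.event}).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, unit: str = "days") -> "EventTimeData":
        import pandas as pd

        df = pd.read_csv(path)
        return cls(df["time"].to_numpy(), df["event"].to_numpy(), unit=unit)


@dataclass
class FitResult:
    params: AFTParameters
    log_likelihood: float
    n: int
    k: int
    aic: float = field(init=False)
    bic: float = field(init=False)

    def __post_init__(self) -> None:
        self.aic, self.bic = information_criteria(self.log_likelihood, self.k, self.n)

    def to_json(self) -> str:
        return json.dumps(
            {
                "family": self.params.family,
                "intercept": self.params.intercept,
                "log_scale": self.params.log_scale,
                "log_likelihood": self.log_likelihood,
                "aic": self.aic,
                "bic": self.bic,
                "n": self.n,
                "k": self.k,
            }
        )


def _standardise(params: AFTParameters, t) -> np.ndarray:
    return (np.log(t) - params.intercept) / params.scale


def survival_probability(params: AFTParameters, t):
    """S(t) for the given AFT law; accepts scalars or arrays, t > 0."""
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr <= 0):
        raise ValueError("survival_probability requires t > 0")
    z = _standardise(params, t_arr)
    if params.family in ("exponential", "weibull"):
        s = np.exp(-np.exp(z))
    elif params.family == "loglogistic":
        s = 1.0 / (1.0 + np.exp(z))
    else:  # lognormal
        s = stats.norm.sf(z)
    return float(s) if np.isscalar(t) else s


def interval_event_probability(params: AFTParameters, t1: float, t2: float) -> float:
    """Probability of an event in (t1, t2]: S(t1) - S(t2), with S(0) = 1."""
    if t1 < 0:
        raise ValueError("t1 must be >= 0")
    if t2 <= t1:
        raise ValueError("interval requires t1 < t2")
    s1 = 1.0 if t1 == 0 else survival_probability(params, t1)
    s2 = 0.0 if math.isinf(t2) else survival_probability(params, t2)
    return s1 - s2


def information_criteria(log_likelihood: float, k: int, n: int) -> tuple[float, float]:
    """AIC = 2k - 2 logL; BIC = k ln(n) - 2 logL."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if k < 1:
        raise ValueError("k must be >= 1")
    aic = 2.0 * k - 2.0 * log_likelihood
    bic = k * math.log(n) - 2.0 * log_likelihood
    return aic, bic


def _lifelines_fitter(family: str):
    from lifelines import (
        ExponentialFitter,
        LogLogisticFitter,
        LogNormalFitter,
        WeibullFitter,
    )

    return {
        "exponential": ExponentialFitter,
        "weibull": WeibullFitter,
        "loglogistic": LogLogisticFitter,
        "lognormal": LogNormalFitter,
    }[family]()


def _to_location_scale(family: str, fitter) -> AFTParameters:
    # lifelines parameterisations -> survreg-style (mu, log sigma)
    if family == "exponential":
        return AFTParameters("exponential", math.log(fitter.lambda_), 0.0)
    if family == "weibull":
        return AFTParameters("weibull", math.log(fitter.lambda_), math.log(1.0 / fitter.rho_))
    if family == "loglogistic":
        return AFTParameters("loglogistic", math.log(fitter.alpha_), math.log(1.0 / fitter.beta_))
    return AFTParameters("lognormal", fitter.mu_, math.log(fitter.sigma_))


def fit_aft(data: EventTimeData, family: str) -> FitResult:
    """Maximum-likelihood AFT fit with right-censoring.

    Events contribute the density f(t), censored observations the survival
    S(t).  Raises if fewer than 2 uncensored events are available.
    """
    if family not in AFT_FAMILIES:
        raise ValueError(f"unsupported AFT family {family!r}")
    if len(data) == 0:
        raise ValueError("empty event-time data")
    if data.n_events < 2:
        raise ValueError("fit_aft requires at least 2 uncensored events")
    fitter = _lifelines_fitter(family)
    try:
        fitter.fit(data.times, event_observed=data.event)
    except Exception as exc:  # pragma: no cover - optimizer pathologies
        raise RuntimeError(f"AFT fit for family {family!r} did not converge: {exc}") from exc
    params = _to_location_scale(family, fitter)
    return FitResult(
        params=params,
        log_likelihood=float(fitter.log_likelihood_),
        n=len(data),
        k=N_FREE_PARAMS[family],
    )


def select_distribution(fits: list[FitResult]) -> str:
    """Family with minimal AIC; ties by minimal BIC, then fewer parameters."""
    if not fits:
        raise ValueError("select_distribution requires at least one fit")
    n_values = {f.n for f in fits}
    if len(n_values) > 1:
        raise ValueError(f"fits computed on differing data (n = {sorted(n_values)})")
    best = min(fits, key=lambda f: (f.aic, f.bic, f.k))
    return best.params.family


def censored_log_likelihood(params: AFTParameters, data: EventTimeData) -> float:
    """Closed-form censored log-likelihood of an AFT law (used as an oracle
    surface by callers; events contribute log f, censored log S)."""
    t = data.times
    z = _standardise(params, t)
    sigma = params.scale
    if params.family in ("exponential", "weibull"):
        log_f = z - np.exp(z) - np.log(sigma) - np.log(t)
        log_s = -np.exp(z)
    elif params.family == "loglogistic":
        log_s = -np.log1p(np.exp(z))
        log_f = z + 2.0 * log_s - np.log(sigma) - np.log(t)
    else:
        log_f = stats.norm.logpdf(z) - np.log(sigma) - np.log(t)
        log_s = stats.norm.logsf(z)
    return float(np.sum(np.where(data.event == 1, log_f, log_s)))
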