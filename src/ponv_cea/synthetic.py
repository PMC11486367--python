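"""Pseudo-trial data generation for the survival-fitting stage.

No patient-level time-to-PONV data are published; only summary proportions
at 24 and 48 hours and the fitted AFT laws are.  This module emulates the
missing inputs: inverse-CDF sampling of event times from any of the four
AFT families with administrative right-censoring (``simulate_event_times``),
expansion of interval summary proportions into pseudo individual-patient
data (``proportions_to_pseudo_ipd``), and frozen parameter-draw tables for
regression-testing the probabilistic sensitivity analysis.

Every operation takes an explicit seed and uses its own RNG stream; no
global random state is touched.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .econ import sample_parameter
from .params import ParameterSet
from .survival import AFT_FAMILIES, AFTParameters, EventTimeData

__all__ = [
    "SimulationSpec",
    "simulate_event_times",
    "proportions_to_pseudo_ipd",
    "fixture_parameter_draws",
]


@dataclass
class SimulationSpec:
    """Pseudo-trial design: AFT law, cohort size, censoring horizon, seed."""

    aft: AFTParameters
    n_patients: int
    censor_time: float
    seed: int

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        if self.censor_time <= 0:
            raise ValueError("censor_time must be positive")


def _quantile(aft: AFTParameters, u: np.ndarray) -> np.ndarray:
    """Event time T with S(T) = u, i.e. T = exp(mu + sigma w(u))."""
    if aft.family in ("exponential", "weibull"):
        w = np.log(-np.log(u))
    elif aft.family == "loglogistic":
        w = np.log((1.0 - u) / u)
    elif aft.family == "lognormal":
        w = stats.norm.isf(u)
    else:  # pragma: no cover - AFTParameters validates the family
        raise ValueError(f"unsupported family {aft.family!r}")
    return np.exp(aft.intercept + aft.scale * w)


def simulate_event_times(spec: SimulationSpec) -> EventTimeData:
    """Draw right-censored event times from the spec's AFT law.

    Uses inverse-CDF sampling (for the Weibull, T = exp(mu + sigma
    ln(-ln U)) so that S(T) = U); times beyond the censoring horizon are
    recorded as censored at that horizon.  Deterministic given the seed.
    """
    if spec.aft.family not in AFT_FAMILIES:
        raise ValueError(f"unsupported family {spec.aft.family!r}")
    rng = np.random.default_rng(spec.seed)
    u = rng.uniform(size=spec.n_patients)
    t = _quantile(spec.aft, u)
    event = (t <= spec.censor_time).astype(int)
    times = np.minimum(t, spec.censor_time)
    return EventTimeData(times=times, event=event, unit="days")


def proportions_to_pseudo_ipd(
    p24: float,
    p48: float,
    n: int,
    horizon: float,
    interval_bounds: tuple[float, float] = (24.0, 48.0),
    placement: str = "midpoint",
) -> EventTimeData:
    """Expand interval PONV proportions into pseudo patient-level data.

    ``round(n p24)`` events are placed in the first interval, ``round(n
    (p48 - p24))`` in the second, the remainder censored at the horizon.
    Events sit at interval midpoints by default (``placement='right'``
    uses the right endpoints instead).  Times share the unit of
    ``interval_bounds`` and ``horizon`` (hours by default).
    """
    if not (0.0 <= p24 <= 1.0 and 0.0 <= p48 <= 1.0):
        raise ValueError("proportions must lie in [0, 1]")
    if p48 < p24:
        raise ValueError("p48 must be >= p24 (cumulative proportions)")
    if n < 1:
        raise ValueError("n must be >= 1")
    b1, b2 = interval_bounds
    if not 0 < b1 < b2 <= horizon:
        raise ValueError("need 0 < first bound < second bound <= horizon")
    if placement == "midpoint":
        t1, t2 = b1 / 2.0, (b1 + b2) / 2.0
    elif placement == "right":
        t1, t2 = b1, b2
    else:
        raise ValueError(f"unknown placement {placement!r}")
    n1 = round(n * p24)
    n2 = round(n * (p48 - p24))
    n_censored = n - n1 - n2
    times = np.concatenate(
        [np.full(n1, t1), np.full(n2, t2), np.full(n_censored, float(horizon))]
    )
    event = np.concatenate([np.ones(n1 + n2, dtype=int), np.zeros(n_censored, dtype=int)])
    return EventTimeData(times=times, event=event, unit="hours")


def fixture_parameter_draws(params: ParameterSet, n: int, seed: int) -> pd.DataFrame:
    """A frozen table of n joint parameter draws (one column per parameter),
    for pinning PSA regression tests.  Deterministic given the seed."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    names = list(params.parameters)
    rows = [
        {name: sample_parameter(params.parameters[name], rng) for name in names}
        for _ in range(n)
    ]
    return pd.DataFrame(rows, columns=names)
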