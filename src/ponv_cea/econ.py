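"""Incremental cost-effectiveness, one-way and probabilistic sensitivity analyses.

The incremental cost-effectiveness ratio (ICER) is dC / dQ between the
intervention and the comparator; when the intervention is both cheaper and
more effective it is *dominant* and the (negative) ratio is reported with an
explicit label rather than left sign-ambiguous.  One-way analyses re-run
the model with one parameter at its low then high bound and feed a tornado
ranking; probabilistic sensitivity analysis (PSA) redraws every non-fixed
parameter per Monte-Carlo iteration (gamma for costs, beta for
probabilities and utilities, normal for times and counts, all
moment-matched to the stated mean and SE) and summarises draws as
cost-effectiveness-plane points, percentile intervals and the
cost-effectiveness acceptability curve (CEAC): the fraction of draws with
positive net monetary benefit, NMB = lambda dQ - dC, per willingness-to-pay
lambda.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd

from .calibration import calibrate
from .decision import ArmOutcome, evaluate_arm
from .params import ModelParameter, ParameterSet

__all__ = [
    "PERSPECTIVES",
    "IncrementalResult",
    "TornadoEntry",
    "PSAResult",
    "CEACPoint",
    "incremental_analysis",
    "net_monetary_benefit",
    "make_model",
    "one_way_sensitivity",
    "tornado",
    "sample_parameter",
    "sample_parameter_set",
    "run_psa",
    "ceac",
    "psa_percentile_ci",
    "default_wtp_grid",
]

PERSPECTIVES = ("payer", "societal")

DEFAULT_N_ITERATIONS = 1000
DEFAULT_SEED = 20241017
_REDRAW_CAP = 1000


@dataclass
class IncrementalResult:
    perspective: str
    delta_cost: float
    delta_qaly: float
    icer: float | None
    dominance: str  # intervention_dominant | comparator_dominant | none

    @property
    def quadrant(self) -> str:
        """CE-plane quadrant label (dominant ICERs are sign-ambiguous)."""
        if self.delta_qaly > 0:
            return "southeast (dominant)" if self.delta_cost < 0 else "northeast"
        if self.delta_qaly < 0:
            return "northwest (dominated)" if self.delta_cost > 0 else "southwest"
        return "boundary"


@dataclass
class TornadoEntry:
    parameter: str
    icer_at_low: float
    icer_at_high: float

    @property
    def bar_width(self) -> float:
        return abs(self.icer_at_high - self.icer_at_low)


@dataclass
class CEACPoint:
    wtp: float
    probability_cost_effective: float


@dataclass
class PSAResult:
    """Monte-Carlo draws of (dC, dQ) per perspective, plus summaries."""

    n_iterations: int
    seed: int
    draws: pd.DataFrame  # columns: iteration, perspective, delta_cost, delta_qaly
    summary: dict = field(default_factory=dict)

    def perspective_draws(self, perspective: str) -> pd.DataFrame:
        if perspective not in PERSPECTIVES:
            raise ValueError(f"unknown perspective {perspective!r}")
        return self.draws[self.draws["perspective"] == perspective]


def incremental_analysis(
    intervention: ArmOutcome, comparator: ArmOutcome, perspective: str
) -> IncrementalResult:
    """dC, dQ, ICER and dominance of intervention vs comparator."""
    if perspective not in PERSPECTIVES:
        raise ValueError(f"unknown perspective {perspective!r}")
    delta_cost = intervention.total(perspective) - comparator.total(perspective)
    delta_qaly = intervention.qaly - comparator.qaly
    icer = delta_cost / delta_qaly if delta_qaly != 0 else None
    if delta_cost < 0 and delta_qaly > 0:
        dominance = "intervention_dominant"
    elif delta_cost > 0 and delta_qaly < 0:
        dominance = "comparator_dominant"
    else:
        dominance = "none"
    return IncrementalResult(perspective, delta_cost, delta_qaly, icer, dominance)


def net_monetary_benefit(delta_cost: float, delta_qaly: float, wtp: float) -> float:
    """NMB = wtp x dQ - dC; positive means cost-effective at wtp."""
    return wtp * delta_qaly - delta_cost


Model = Callable[[ParameterSet], tuple[ArmOutcome, ArmOutcome]]


def make_model(
    base_params: ParameterSet, calibrated: bool = True, **cost_options
) -> Model:
    """An arm evaluator (intervention, comparator) with calibration frozen
    at the base case, so parameter variation propagates structurally."""
    cals = calibrate(base_params, **cost_options) if calibrated else None
    intervention, comparator = base_params.arm_labels

    def model(params: ParameterSet) -> tuple[ArmOutcome, ArmOutcome]:
        return (
            evaluate_arm(
                params,
                intervention,
                calibration=cals[intervention] if cals else None,
                **cost_options,
            ),
            evaluate_arm(
                params,
                comparator,
                calibration=cals[comparator] if cals else None,
                **cost_options,
            ),
        )

    return model


def one_way_sensitivity(
    params: ParameterSet, name: str, model: Model, perspective: str
) -> TornadoEntry:
    """ICER with one parameter at its low then high bound, others at base."""
    if name not in params.parameters:
        raise KeyError(f"unknown parameter {name!r}")
    p = params.parameters[name]
    if not p.is_bounded:
        raise ValueError(f"parameter {name!r} has no low/high bounds")
    icers = []
    for bound in (p.low, p.high):
        outcome_i, outcome_c = model(params.with_values({name: bound}))
        result = incremental_analysis(outcome_i, outcome_c, perspective)
        if result.icer is None:
            raise ZeroDivisionError(
                f"one-way analysis of {name!r}: dQALY is zero at bound {bound}"
            )
        icers.append(result.icer)
    return TornadoEntry(parameter=name, icer_at_low=icers[0], icer_at_high=icers[1])


def tornado(
    params: ParameterSet,
    model: Model,
    perspective: str,
    parameter_names: list[str] | None = None,
) -> list[TornadoEntry]:
    """One-way entries, widest bar first.

    By default only the bounded cost/time/count/utility inputs are varied
    (the parameters whose ranges the published input table prints); the
    panel-elicited proportion parameters enter the probabilistic analysis
    only.  Pass ``parameter_names`` to override.
    """
    if parameter_names is None:
        parameter_names = [
            name
            for name, p in params.parameters.items()
            if p.is_bounded and p.high > p.low and p.role != "probability"
        ]
    if not parameter_names:
        raise ValueError("tornado requires at least one bounded parameter")
    entries = [
        one_way_sensitivity(params, name, model, perspective) for name in parameter_names
    ]
    return sorted(entries, key=lambda e: (-e.bar_width, e.parameter))


# -- parameter sampling ----------------------------------------------------


def sample_parameter(p: ModelParameter, rng: np.random.Generator) -> float:
    """One draw from the parameter's distribution, moment-matched to
    (mean, SE); draws outside the natural support are redrawn."""
    if p.dist_family == "fixed":
        return p.point_value
    mean = p.point_value
    se = p.standard_error()
    if se == 0:
        return mean
    if p.dist_family == "gamma":
        shape = mean**2 / se**2
        scale = se**2 / mean
        draw = lambda: rng.gamma(shape, scale)  # noqa: E731
        ok = lambda x: x >= 0  # noqa: E731
    elif p.dist_family == "beta":
        nu = mean * (1.0 - mean) / se**2 - 1.0
        if nu <= 0:
            raise ValueError(
                f"parameter {p.name!r}: SE {se} too large for a beta with mean {mean}"
            )
        draw = lambda: rng.beta(mean * nu, (1.0 - mean) * nu)  # noqa: E731
        ok = lambda x: 0.0 <= x <= 1.0  # noqa: E731
    elif p.dist_family == "normal":
        draw = lambda: rng.normal(mean, se)  # noqa: E731
        # times/counts/costs cannot go negative; probabilities stay in [0,1]
        if p.role in ("probability", "utility"):
            ok = lambda x: 0.0 <= x <= 1.0  # noqa: E731
        else:
            ok = lambda x: x > 0  # noqa: E731
    else:  # pragma: no cover - validated upstream
        raise ValueError(f"unknown dist_family {p.dist_family!r}")
    for _ in range(_REDRAW_CAP):
        x = draw()
        if ok(x):
            return float(x)
    raise RuntimeError(f"parameter {p.name!r}: redraw cap exceeded")


def sample_parameter_set(params: ParameterSet, rng: np.random.Generator) -> ParameterSet:
    """A new ParameterSet with every non-fixed parameter redrawn once."""
    updates = {
        name: sample_parameter(p, rng)
        for name, p in params.parameters.items()
        if p.dist_family != "fixed"
    }
    return params.with_values(updates)


def run_psa(
    params: ParameterSet,
    model: Model | None = None,
    n_iterations: int = DEFAULT_N_ITERATIONS,
    seed: int = DEFAULT_SEED,
) -> PSAResult:
    """Probabilistic sensitivity analysis: n Monte-Carlo iterations, each
    redrawing all non-fixed parameters and evaluating both arms.

    Bit-reproducible for a given seed.  The summary holds per-perspective
    means and 2.5/97.5 percentile intervals of dC, dQ and the ICER.
    """
    if not isinstance(seed, (int, np.integer)) or isinstance(seed, bool):
        raise TypeError("seed must be an integer")
    if n_iterations < 1:
        raise ValueError("n_iterations must be >= 1")
    if model is None:
        model = make_model(params)
    rng = np.random.default_rng(seed)
    records = []
    for it in range(n_iterations):
        drawn = sample_parameter_set(params, rng)
        outcome_i, outcome_c = model(drawn)
        delta_qaly = outcome_i.qaly - outcome_c.qaly
        for perspective in PERSPECTIVES:
            records.append(
                {
                    "iteration": it,
                    "perspective": perspective,
                    "delta_cost": outcome_i.total(perspective)
                    - outcome_c.total(perspective),
                    "delta_qaly": delta_qaly,
                }
            )
    draws = pd.DataFrame.from_records(records)
    result = PSAResult(n_iterations=n_iterations, seed=int(seed), draws=draws)
    result.summary = {
        perspective: _summarise(result.perspective_draws(perspective))
        for perspective in PERSPECTIVES
    }
    return result


def _summarise(df: pd.DataFrame) -> dict:
    dc = df["delta_cost"].to_numpy()
    dq = df["delta_qaly"].to_numpy()
    out = {"mean_delta_cost": float(dc.mean()), "mean_delta_qaly": float(dq.mean())}
    if len(df) >= 40:
        ci = psa_percentile_arrays(dc, dq)
        out.update(ci)
    return out


def psa_percentile_arrays(dc: np.ndarray, dq: np.ndarray, level: float = 0.95) -> dict:
    alpha = (1.0 - level) / 2.0
    qs = [100 * alpha, 100 * (1 - alpha)]
    with np.errstate(divide="ignore", invalid="ignore"):
        icers = np.where(dq != 0, dc / dq, np.nan)
    out = {
        "delta_cost_ci": tuple(np.percentile(dc, qs)),
        "delta_qaly_ci": tuple(np.percentile(dq, qs)),
    }
    finite = icers[np.isfinite(icers)]
    out["icer_ci"] = tuple(np.percentile(finite, qs)) if finite.size else (np.nan, np.nan)
    return out


def psa_percentile_ci(psa: PSAResult, level: float = 0.95, perspective: str = "payer") -> dict:
    """Empirical percentile intervals (linear interpolation, numpy default)
    for dC, dQ and the per-draw ICER."""
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    df = psa.perspective_draws(perspective)
    if len(df) < 40:
        raise ValueError(
            f"{len(df)} draws are too few for a meaningful {level:.0%} percentile interval"
        )
    return psa_percentile_arrays(
        df["delta_cost"].to_numpy(), df["delta_qaly"].to_numpy(), level
    )


# -- acceptability ---------------------------------------------------------


def default_wtp_grid(
    wtp_min: float = -20000.0, wtp_max: float = 20000.0, step: float = 500.0
) -> np.ndarray:
    """Willingness-to-pay grid matching the published CEAC range."""
    if wtp_min >= wtp_max:
        raise ValueError("wtp_min must be below wtp_max")
    return np.arange(wtp_min, wtp_max + step / 2.0, step)


def ceac(psa: PSAResult, wtp_grid, perspective: str) -> list[CEACPoint]:
    """Fraction of PSA draws with positive net monetary benefit at each
    willingness-to-pay threshold."""
    wtp_grid = np.asarray(wtp_grid, dtype=float)
    if wtp_grid.size == 0:
        raise ValueError("wtp_grid must be non-empty")
    df = psa.perspective_draws(perspective)
    dc = df["delta_cost"].to_numpy()
    dq = df["delta_qaly"].to_numpy()
    points = []
    for wtp in wtp_grid:
        nmb = net_monetary_benefit(dc, dq, wtp)
        points.append(CEACPoint(float(wtp), float(np.mean(nmb > 0))))
    return points
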