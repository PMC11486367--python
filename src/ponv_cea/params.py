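"""Model inputs: named parameters, validation, currency conversion.

Every input of the cost-effectiveness model — drug unit costs, staff wages
and minutes, hospitalization and outpatient costs, wage losses, transport,
the analysis horizon, health-state utilities, severity splits and
service-use proportions — is a :class:`ModelParameter` with a point value,
an uncertainty range and/or standard error, and a sampling distribution
family for probabilistic sensitivity analysis.  The packaged fixture
``params_base_2024.csv`` carries the 2024 South-Korean base case (all
monetary values in USD, converted from KRW at 0.00073 USD/KRW).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from decimal import ROUND_HALF_UP, Decimal
from importlib import resources
from pathlib import Path

import pandas as pd

from .survival import AFTParameters

__all__ = [
    "ModelParameter",
    "ParameterSet",
    "ValidationError",
    "load_parameter_table",
    "default_parameter_set",
    "convert_currency",
    "DEFAULT_EXCHANGE_RATE",
    "ARM_INTERVENTION",
    "ARM_COMPARATOR",
]

DEFAULT_EXCHANGE_RATE = 0.00073  # USD per KRW

ARM_INTERVENTION = "ramosetron"
ARM_COMPARATOR = "no_antiemetic"

ROLES = ("cost", "probability", "utility", "time", "count", "rate")
DIST_FAMILIES = ("gamma", "beta", "normal", "fixed")

#: parameters the decision model cannot run without
MANDATORY_PARAMETERS = (
    "cost_ramosetron",
    "cost_metoclopramide",
    "cost_dexamethasone",
    "cost_palonosetron",
    "wage_physician_hourly",
    "minutes_physician",
    "wage_nurse_hourly",
    "minutes_nurse",
    "cost_hospital_day",
    "additional_hospital_days",
    "cost_outpatient_visit",
    "n_outpatient_visits",
    "wage_loss_per_visit",
    "wage_loss_per_day",
    "cost_transport_visit",
    "horizon_days",
    "utility_no_ponv",
    "utility_mild_ponv",
    "utility_mod_severe_ponv",
    "mild_share_ramosetron_acute",
    "mild_share_no_antiemetic_acute",
    "mild_share_ramosetron_delayed",
    "mild_share_no_antiemetic_delayed",
    "p_additional_stay_ramosetron",
    "p_additional_stay_no_antiemetic",
    "p_outpatient_ramosetron",
    "p_outpatient_no_antiemetic",
)


class ValidationError(ValueError):
    """A parameter table violated a structural invariant."""


def convert_currency(amount_krw: float, rate: float = DEFAULT_EXCHANGE_RATE) -> float:
    """KRW -> USD at the fixed study exchange rate, rounded half-up to cents."""
    if amount_krw < 0:
        raise ValueError("amount_krw must be non-negative")
    if rate <= 0:
        raise ValueError("rate must be positive")
    usd = Decimal(str(amount_krw)) * Decimal(str(rate))
    return float(usd.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


@dataclass
class ModelParameter:
    """One named model input with uncertainty metadata."""

    name: str
    role: str
    point_value: float
    low: float | None = None
    high: float | None = None
    se: float | None = None
    dist_family: str = "fixed"
    units: str = ""
    source_tag: str = ""

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.role not in ROLES:
            raise ValidationError(f"parameter {self.name!r}: unknown role {self.role!r}")
        if self.dist_family not in DIST_FAMILIES:
            raise ValidationError(
                f"parameter {self.name!r}: unknown dist_family {self.dist_family!r}"
            )
        if self.low is not None and self.high is not None and self.low > self.high:
            raise ValidationError(f"parameter {self.name!r}: low {self.low} > high {self.high}")
        if self.low is not None and self.point_value < self.low - 1e-12:
            raise ValidationError(f"parameter {self.name!r}: point value below low bound")
        if self.high is not None and self.point_value > self.high + 1e-12:
            raise ValidationError(f"parameter {self.name!r}: point value above high bound")
        if self.role in ("probability", "utility"):
            if not 0.0 <= self.point_value <= 1.0:
                raise ValidationError(
                    f"parameter {self.name!r}: {self.role} value "
                    f"{self.point_value} outside [0, 1]"
                )
            if self.dist_family not in ("beta", "fixed"):
                raise ValidationError(
                    f"parameter {self.name!r}: {self.role} must use beta or fixed distribution"
                )
        if self.role == "cost" and self.point_value < 0:
            raise ValidationError(f"parameter {self.name!r}: cost must be non-negative")
        if self.se is not None and self.se < 0:
            raise ValidationError(f"parameter {self.name!r}: se must be >= 0")

    def standard_error(self) -> float:
        """Stated SE, or the half-width of the 95% range over 1.96."""
        if self.se is not None:
            return self.se
        if self.low is not None and self.high is not None:
            return (self.high - self.low) / (2.0 * 1.96)
        raise ValidationError(
            f"parameter {self.name!r}: no se and no bounds to derive one from"
        )

    @property
    def is_bounded(self) -> bool:
        return self.low is not None and self.high is not None


@dataclass
class SeveritySplit:
    """Mild vs moderate-to-severe share among patients with PONV."""

    mild: float
    mod_severe: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.mild <= 1.0 and 0.0 <= self.mod_severe <= 1.0):
            raise ValidationError("severity shares must lie in [0, 1]")
        if abs(self.mild + self.mod_severe - 1.0) > 1e-9:
            raise ValidationError("severity shares must sum to 1")


@dataclass
class ParameterSet:
    """The full, validated input set of the decision model."""

    parameters: dict[str, ModelParameter]
    aft: dict[str, AFTParameters]
    arm_labels: tuple[str, str] = (ARM_INTERVENTION, ARM_COMPARATOR)
    exchange_rate_usd_per_krw: float = DEFAULT_EXCHANGE_RATE
    prophylaxis_cost_param: dict[str, str | None] = field(
        default_factory=lambda: {ARM_INTERVENTION: "cost_ramosetron", ARM_COMPARATOR: None}
    )

    def __post_init__(self) -> None:
        self.validate()

    # -- accessors ---------------------------------------------------------

    def value(self, name: str) -> float:
        return self.parameters[name].point_value

    @property
    def horizon_days(self) -> float:
        return self.value("horizon_days")

    def severity_split(self, arm: str, phase: str) -> SeveritySplit:
        """Severity split for ``phase`` in {'acute' (0-24 h), 'delayed' (24-48 h)}."""
        mild = self.value(f"mild_share_{arm}_{phase}")
        return SeveritySplit(mild=mild, mod_severe=1.0 - mild)

    def service_use(self, arm: str) -> dict[str, float]:
        return {
            "p_additional_stay": self.value(f"p_additional_stay_{arm}"),
            "p_outpatient_visit": self.value(f"p_outpatient_{arm}"),
        }

    def utilities(self) -> dict[str, float]:
        return {
            "u_no": self.value("utility_no_ponv"),
            "u_mild": self.value("utility_mild_ponv"),
            "u_sev": self.value("utility_mod_severe_ponv"),
        }

    # -- validation --------------------------------------------------------

    def validate(self) -> None:
        missing = [n for n in MANDATORY_PARAMETERS if n not in self.parameters]
        if missing:
            raise ValidationError(f"missing mandatory parameters: {', '.join(missing)}")
        for p in self.parameters.values():
            p.validate()
        if self.horizon_days <= 0:
            raise ValidationError("horizon_days must be positive")
        if self.exchange_rate_usd_per_krw <= 0:
            raise ValidationError("exchange rate must be positive")
        for arm in self.arm_labels:
            if arm not in self.aft:
                raise ValidationError(f"no AFT law for arm {arm!r}")
            for phase in ("acute", "delayed"):
                self.severity_split(arm, phase)  # raises if shares invalid
            for key, v in self.service_use(arm).items():
                if not 0.0 <= v <= 1.0:
                    raise ValidationError(f"{key} for arm {arm!r} outside [0, 1]")

    # -- functional updates ------------------------------------------------

    def with_values(self, updates: dict[str, float]) -> "ParameterSet":
        """A new set with point values replaced (ranges widened to keep the
        replaced value admissible; used by sampling and one-way analysis)."""
        new_params = dict(self.parameters)
        for name, value in updates.items():
            if name not in new_params:
                raise KeyError(f"unknown parameter {name!r}")
            p = new_params[name]
            low = None if p.low is None else min(p.low, value)
            high = None if p.high is None else max(p.high, value)
            new_params[name] = replace(p, point_value=value, low=low, high=high)
        return replace(self, parameters=new_params)

    # -- serialisation -----------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "name": p.name,
                "role": p.role,
                "value": p.point_value,
                "low": p.low,
                "high": p.high,
                "se": p.se,
                "dist": p.dist_family,
                "units": p.units,
                "source": p.source_tag,
            }
            for p in self.parameters.values()
        ]
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def _parameter_from_row(row: dict) -> ModelParameter:
    def _opt(key):
        v = row.get(key)
        if v is None or (isinstance(v, float) and pd.isna(v)) or v == "":
            return None
        return float(v)

    try:
        return ModelParameter(
            name=str(row["name"]),
            role=str(row["role"]),
            point_value=float(row["value"]),
            low=_opt("low"),
            high=_opt("high"),
            se=_opt("se"),
            dist_family=str(row.get("dist", "fixed")),
            units=str(row.get("units", "") or ""),
            source_tag=str(row.get("source", "") or ""),
        )
    except ValidationError:
        raise
    except (KeyError, TypeError, ValueError) as exc:
        raise ValidationError(f"malformed parameter row {row.get('name', '?')!r}: {exc}") from exc


def _default_aft() -> dict[str, AFTParameters]:
    text = resources.files("ponv_cea.data").joinpath("aft_weibull_2024.json").read_text()
    spec = json.loads(text)
    return {
        arm: AFTParameters(d["family"], d["intercept"], d["log_scale"])
        for arm, d in spec["arms"].items()
    }


def load_parameter_table(source, aft: dict[str, AFTParameters] | None = None) -> ParameterSet:
    """Load and validate a parameter table (CSV, or YAML/JSON with the same keys).

    The table must carry the header ``name,role,value,low,high,se,dist,units,
    source``.  A YAML/JSON config holds a list of row mappings under
    ``parameters`` and may override ``aft`` per arm.  Unknown roles or
    distribution families, bound violations and missing mandatory parameters
    are rejected with the offending row named.
    """
    path = Path(source)
    if path.suffix.lower() in (".yaml", ".yml", ".json"):
        import yaml

        config = yaml.safe_load(path.read_text())
        if not config or "parameters" not in config or not config["parameters"]:
            raise ValidationError(f"no parameters found in {path}")
        rows = config["parameters"]
        if aft is None and "aft" in config:
            aft = {
                arm: AFTParameters(d["family"], d["intercept"], d.get("log_scale", 0.0))
                for arm, d in config["aft"].items()
            }
    else:
        df = pd.read_csv(path, comment="#")
        if df.empty:
            raise ValidationError(f"no parameters found in {path}")
        rows = df.to_dict("records")
    parameters = {}
    for row in rows:
        p = _parameter_from_row(row)
        parameters[p.name] = p
    return ParameterSet(parameters=parameters, aft=aft if aft is not None else _default_aft())


def default_parameter_set() -> ParameterSet:
    """The packaged 2024 base case (all published inputs, USD)."""
    with resources.as_file(
        resources.files("ponv_cea.data").joinpath("params_base_2024.csv")
    ) as path:
        return load_parameter_table(path)
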