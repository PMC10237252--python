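"""The Modified Sick Neonatal Score (MSNS) rubric.

The MSNS grades eight admission physiological parameters of a neonate —
respiratory effort, heart rate, axillary temperature, capillary refill time,
random blood sugar, room-air SpO2, gestational age and birth weight — each on
a 0/1/2 band (0 = most deranged, 2 = normal), for a total of 0-16 where a
*lower* total means a sicker neonate.

The band constants live in ``data/rubric.csv`` shipped with the package, so
the rubric is data, not code.  Interval endpoints follow a fixed half-open
convention that makes the three bands of every parameter a true partition of
the admissible input space; two clinical presentations the band table leaves
unbanded are resolved explicitly and documented in ``docs/methods.md``:

* bradypnea (respiratory rate < 40/min without apnea or grunting) scores 0;
* fever (axillary temperature > 37.5 C) scores 1.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field, fields
from functools import lru_cache
from importlib import resources
from typing import Optional

from .errors import UnknownParameterError, ValidationError

#: The eight rubric parameters, in fixed reporting order.
PARAMETERS = (
    "respiratory_effort",
    "heart_rate",
    "axillary_temperature",
    "capillary_refill_time",
    "random_blood_sugar",
    "spo2",
    "gestational_age",
    "birth_weight",
)

#: Observation field each numeric parameter reads.
PARAMETER_FIELDS = {
    "respiratory_effort": "respiratory_rate",
    "heart_rate": "heart_rate",
    "axillary_temperature": "axillary_temperature",
    "capillary_refill_time": "capillary_refill_time",
    "random_blood_sugar": "random_blood_sugar",
    "spo2": "spo2_room_air",
    "gestational_age": "gestational_age",
    "birth_weight": "birth_weight",
}

MAX_TOTAL = 16

OUTCOMES = ("discharged", "expired")
SEXES = ("male", "female")
DELIVERY_MODES = ("vaginal", "caesarean")
PARITIES = ("primi", "multi")


def parse_gestational_age(value) -> float:
    """Convert a gestational age to decimal completed weeks.

    Accepts a plain number, or obstetric ``"weeks+days"`` notation
    (``"36+6"`` -> 36 + 6/7 = 36.857...).
    """
    if isinstance(value, str) and "+" in value:
        weeks_s, days_s = value.split("+", 1)
        weeks, days = float(weeks_s), float(days_s)
        if not 0 <= days < 7:
            raise ValueError(f"days part must be in [0, 7): {value!r}")
        return weeks + days / 7.0
    return float(value)


@dataclass(frozen=True)
class NeonateObservation:
    """One neonate's admission physiology, demographics and outcome."""

    id: str
    apnea_or_grunt: bool
    heart_rate: float
    axillary_temperature: float
    capillary_refill_time: float
    random_blood_sugar: float
    spo2_room_air: float
    gestational_age: float
    birth_weight: float
    sex: str
    mode_of_delivery: str
    parity: str
    outcome: str
    respiratory_rate: Optional[float] = None  # may be absent when apneic
    retractions: bool = False  # recorded but never score-determining
    clinical_diagnosis: Optional[str] = None

    def validation_issues(self) -> list[tuple[str, str, str]]:
        """All field-level problems as ``(id, field, message)`` tuples."""
        issues = []

        def bad(field_name, msg):
            issues.append((self.id, field_name, msg))

        if not self.apnea_or_grunt and self.respiratory_rate is None:
            bad("respiratory_rate", "required when apnea_or_grunt is false")
        nonneg = (
            "respiratory_rate", "heart_rate", "axillary_temperature",
            "capillary_refill_time", "random_blood_sugar",
            "gestational_age", "birth_weight",
        )
        for name in nonneg:
            v = getattr(self, name)
            if v is None:
                continue
            if not math.isfinite(v) or v < 0:
                bad(name, f"must be a finite non-negative number, got {v!r}")
        s = self.spo2_room_air
        if s is None or not math.isfinite(s) or not 0 <= s <= 100:
            bad("spo2_room_air", f"must lie in [0, 100], got {s!r}")
        for name, allowed in (
            ("outcome", OUTCOMES), ("sex", SEXES),
            ("mode_of_delivery", DELIVERY_MODES), ("parity", PARITIES),
        ):
            if getattr(self, name) not in allowed:
                bad(name, f"must be one of {allowed}, got {getattr(self, name)!r}")
        return issues

    def validate(self) -> "NeonateObservation":
        issues = self.validation_issues()
        if issues:
            raise ValidationError(issues)
        return self

    @classmethod
    def field_names(cls) -> tuple[str, ...]:
        return tuple(f.name for f in fields(cls))


@dataclass(frozen=True)
class RubricBand:
    """One scoring band of one parameter.

    Numeric bands are intervals with explicit open/closed endpoints;
    categorical bands carry a ``condition`` (currently only apnea/grunt).
    """

    parameter: str
    score: int
    label: str
    condition: Optional[str] = None
    lower: float = -math.inf
    lower_inclusive: bool = False
    upper: float = math.inf
    upper_inclusive: bool = False

    def contains(self, value: float) -> bool:
        if self.condition is not None:
            return False
        above = value >= self.lower if self.lower_inclusive else value > self.lower
        below = value <= self.upper if self.upper_inclusive else value < self.upper
        return above and below


@lru_cache(maxsize=1)
def load_rubric() -> tuple[RubricBand, ...]:
    """Load the shipped band table (cached)."""
    bands = []
    path = resources.files("msns").joinpath("data/rubric.csv")
    with path.open(newline="") as fh:
        for row in csv.DictReader(fh):
            cond = row["condition"] or None
            if cond is None:
                band = RubricBand(
                    parameter=row["parameter"],
                    score=int(row["score"]),
                    label=row["label"],
                    lower=float(row["lower"]),
                    lower_inclusive=row["lower_inclusive"] == "true",
                    upper=float(row["upper"]),
                    upper_inclusive=row["upper_inclusive"] == "true",
                )
            else:
                band = RubricBand(
                    parameter=row["parameter"], score=int(row["score"]),
                    label=row["label"], condition=cond,
                )
            bands.append(band)
    return tuple(bands)


def bands_for(parameter: str) -> tuple[RubricBand, ...]:
    if parameter not in PARAMETERS:
        raise UnknownParameterError(parameter)
    return tuple(b for b in load_rubric() if b.parameter == parameter)


@dataclass(frozen=True)
class MsnsResult:
    """Per-parameter subscores (each 0/1/2, fixed order) and their total."""

    subscores: dict[str, int] = field(default_factory=dict)
    total: int = 0

    def __post_init__(self):
        if tuple(self.subscores) != PARAMETERS:
            raise ValueError("subscores must cover all eight parameters in order")
        if any(s not in (0, 1, 2) for s in self.subscores.values()):
            raise ValueError("each subscore must be 0, 1 or 2")
        if self.total != sum(self.subscores.values()):
            raise ValueError("total must equal the sum of the subscores")

    def as_tuple(self) -> tuple[int, ...]:
        return tuple(self.subscores[p] for p in PARAMETERS)


def score_parameter(parameter: str, observation: NeonateObservation) -> int:
    """Score one rubric parameter for one observation.

    Deterministic band lookup: the apnea/grunt flag dominates respiratory
    effort; every numeric value falls in exactly one band.
    """
    bands = bands_for(parameter)
    if parameter == "respiratory_effort" and observation.apnea_or_grunt:
        return next(b.score for b in bands if b.condition == "apnea_or_grunt")
    field_name = PARAMETER_FIELDS[parameter]
    value = getattr(observation, field_name)
    if value is None:
        raise ValidationError([(observation.id, field_name,
                                f"required to score {parameter}")])
    if parameter == "gestational_age":
        value = parse_gestational_age(value)
    matches = [b for b in bands if b.contains(value)]
    if len(matches) != 1:  # cannot happen on validated input; guards the table
        raise ValidationError([(observation.id, field_name,
                                f"value {value!r} matches {len(matches)} bands")])
    return matches[0].score


def compute_msns(observation: NeonateObservation) -> MsnsResult:
    """Compute all eight MSNS subscores and the total for one neonate.

    Pure function of the observation; raises a single aggregated
    :class:`ValidationError` if the record is not scoreable.
    """
    observation.validate()
    subscores = {p: score_parameter(p, observation) for p in PARAMETERS}
    return MsnsResult(subscores=subscores, total=sum(subscores.values()))
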