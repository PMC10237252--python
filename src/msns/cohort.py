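"""Cohort tables: reading, validation, writing, and the reference fixture.

The canonical on-disk form is a comma-delimited UTF-8 table with one row per
neonate and a fixed header vocabulary (see :data:`CANONICAL_COLUMNS`); a
column-alias map absorbs dialects.  Reading never discards information
silently: rows that fail record validation are excluded from the cohort but
enumerated, field by field, in a :class:`ValidationReport`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterator, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import MsnsError, ValidationError
from .rubric import (
    MAX_TOTAL,
    PARAMETERS,
    MsnsResult,
    NeonateObservation,
    parse_gestational_age,
)

#: Fixed header vocabulary of a cohort table, in column order.
CANONICAL_COLUMNS = NeonateObservation.field_names()

#: Columns that may be empty (respiratory_rate only when apneic).
_OPTIONAL_COLUMNS = {"respiratory_rate", "clinical_diagnosis"}

_BOOL_VALUES = {"true": True, "false": False, "1": True, "0": False,
                "yes": True, "no": False}

_FLOAT_COLUMNS = ("respiratory_rate", "heart_rate", "axillary_temperature",
                  "capillary_refill_time", "random_blood_sugar",
                  "spo2_room_air", "birth_weight")


@dataclass
class Cohort:
    """An ordered collection of validated neonate records plus provenance."""

    records: list[NeonateObservation]
    provenance: str = "unknown"

    def __post_init__(self):
        ids = [r.id for r in self.records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError([(i, "id", "duplicate record id") for i in dupes])

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[NeonateObservation]:
        return iter(self.records)

    def outcomes(self) -> list[str]:
        return [r.outcome for r in self.records]

    def to_frame(self) -> pd.DataFrame:
        """The cohort as a DataFrame in canonical column order."""
        return pd.DataFrame([{c: getattr(r, c) for c in CANONICAL_COLUMNS}
                             for r in self.records], columns=list(CANONICAL_COLUMNS))


@dataclass
class ValidationReport:
    """Per-record field issues found while reading a cohort table."""

    issues: list[tuple[str, str, str]] = field(default_factory=list)
    n_read: int = 0
    n_accepted: int = 0

    @property
    def n_rejected(self) -> int:
        return self.n_read - self.n_accepted

    def to_dict(self) -> dict:
        return {
            "n_read": self.n_read,
            "n_accepted": self.n_accepted,
            "n_rejected": self.n_rejected,
            "issues": [{"id": i, "field": f, "issue": m} for i, f, m in self.issues],
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)


def _parse_row(raw: dict, row_number: int):
    """Turn one raw CSV row into an observation, or a list of issues."""
    rid = (raw.get("id") or "").strip() or f"row{row_number}"
    issues: list[tuple[str, str, str]] = []
    parsed: dict = {"id": rid}

    def get(col):
        v = raw.get(col)
        if v is None:
            return None
        v = str(v).strip()
        return v or None

    for col in ("apnea_or_grunt", "retractions"):
        v = get(col)
        if v is None:
            parsed[col] = False
        elif v.lower() in _BOOL_VALUES:
            parsed[col] = _BOOL_VALUES[v.lower()]
        else:
            issues.append((rid, col, f"not a boolean: {v!r}"))
    for col in _FLOAT_COLUMNS:
        v = get(col)
        if v is None:
            parsed[col] = None
            if col not in _OPTIONAL_COLUMNS:
                issues.append((rid, col, "missing value"))
        else:
            try:
                parsed[col] = float(v)
            except ValueError:
                issues.append((rid, col, f"not a number: {v!r}"))
    ga = get("gestational_age")
    if ga is None:
        issues.append((rid, "gestational_age", "missing value"))
    else:
        try:
            parsed["gestational_age"] = parse_gestational_age(ga)
        except ValueError:
            issues.append((rid, "gestational_age",
                           f"not a number or weeks+days value: {ga!r}"))
    for col in ("sex", "mode_of_delivery", "parity", "outcome"):
        v = get(col)
        if v is None:
            issues.append((rid, col, "missing value"))
        else:
            parsed[col] = v.lower()
    parsed["clinical_diagnosis"] = get("clinical_diagnosis")

    if issues:
        return None, issues
    obs = NeonateObservation(**parsed)
    issues = obs.validation_issues()
    if issues:
        return None, issues
    return obs, []


def read_cohort(
    path,
    *,
    column_aliases: Optional[dict[str, str]] = None,
    delimiter: str = ",",
) -> tuple[Cohort, ValidationReport]:
    """Read and validate a cohort table.

    ``column_aliases`` maps non-canonical header names found in the file to
    canonical ones.  Mandatory columns missing from the header raise
    :class:`MsnsError`; invalid *rows* are rejected individually and listed
    in the returned :class:`ValidationReport`.
    """
    try:
        frame = pd.read_csv(path, sep=delimiter, dtype=str, keep_default_na=False)
    except (OSError, pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise MsnsError(f"cannot read cohort table {path}: {exc}") from exc
    if column_aliases:
        frame = frame.rename(columns=column_aliases)
    mandatory = [c for c in CANONICAL_COLUMNS
                 if c not in _OPTIONAL_COLUMNS and c != "retractions"]
    missing = [c for c in mandatory if c not in frame.columns]
    if missing:
        raise MsnsError(f"cohort table {path} lacks mandatory columns: {missing}")

    report = ValidationReport(n_read=len(frame))
    records: list[NeonateObservation] = []
    seen: set[str] = set()
    for i, raw in enumerate(frame.to_dict("records")):
        obs, issues = _parse_row(raw, i + 1)
        if obs is not None and obs.id in seen:
            issues = [(obs.id, "id", "duplicate record id")]
            obs = None
        if obs is None:
            report.issues.extend(issues)
        else:
            seen.add(obs.id)
            records.append(obs)
    report.n_accepted = len(records)
    return Cohort(records=records, provenance=str(path)), report


def write_cohort(cohort: Cohort, path) -> None:
    """Write a cohort in canonical CSV form (round-trips through read_cohort)."""
    cohort.to_frame().to_csv(path, index=False)


def write_scored_cohort(
    cohort: Cohort, msns_results: Sequence[MsnsResult], path
) -> None:
    """Write the cohort with nine appended columns: the eight subscores
    (``msns_<parameter>``) and ``msns_total``."""
    if len(msns_results) != len(cohort):
        raise MsnsError(
            f"{len(msns_results)} score results for {len(cohort)} records")
    frame = cohort.to_frame()
    for p in PARAMETERS:
        frame[f"msns_{p}"] = [r.subscores[p] for r in msns_results]
    frame["msns_total"] = [r.total for r in msns_results]
    frame.to_csv(path, index=False)


# --------------------------------------------------------------------------
# the 71-neonate reference fixture
# --------------------------------------------------------------------------

#: Exact demographic marginals of the reference cohort (counts out of 71).
FIXTURE_MARGINALS = {
    "n": 71,
    "sex": {"male": 59, "female": 12},
    "gestational_age_group": {"preterm": 14, "term": 57},
    "mode_of_delivery": {"vaginal": 55, "caesarean": 16},
    "parity": {"primi": 58, "multi": 13},
    "outcome": {"discharged": 62, "expired": 9},
}


def _shuffled_labels(rng, counts: dict[str, int]) -> np.ndarray:
    labels = np.repeat(list(counts), list(counts.values()))
    return rng.permutation(labels)


def build_fixture_cohort(seed: int = 0) -> Cohort:
    """Build the 71-record reference cohort with exact demographic marginals.

    Marginal counts (sex 59/12, preterm/term 14/57, delivery 55/16, parity
    58/13, outcome 62/9) hold exactly for every seed; the joint assignment
    across fields is seeded-random, since only the marginals are known.
    Physiology is realised from per-group target MSNS totals (expired low,
    discharged high, the generator's default calibration), subject to the
    rubric's own feasibility constraints: a total of 16 forces term
    gestation, a total <= 1 forces preterm.
    """
    from .simulate import GeneratorConfig, generate_scores, observation_from_target_score

    n = FIXTURE_MARGINALS["n"]
    n_preterm = FIXTURE_MARGINALS["gestational_age_group"]["preterm"]
    rng = np.random.default_rng(seed)

    for _ in range(100):
        scores = generate_scores(GeneratorConfig(
            n_total=n, seed=int(rng.integers(2**31))))
        totals = scores["total_score"].to_numpy()
        forced_preterm = np.flatnonzero(totals <= 1)
        eligible = np.flatnonzero((totals >= 2) & (totals <= MAX_TOTAL - 1))
        if len(forced_preterm) <= n_preterm <= len(forced_preterm) + len(eligible):
            break
    else:  # pragma: no cover - measure-zero under the default calibration
        raise MsnsError("could not draw totals compatible with the preterm marginal")

    preterm = set(forced_preterm.tolist())
    extra = rng.choice(eligible, size=n_preterm - len(preterm), replace=False)
    preterm.update(extra.tolist())

    sexes = _shuffled_labels(rng, FIXTURE_MARGINALS["sex"])
    deliveries = _shuffled_labels(rng, FIXTURE_MARGINALS["mode_of_delivery"])
    parities = _shuffled_labels(rng, FIXTURE_MARGINALS["parity"])

    records = []
    for k in range(n):
        rng_k = np.random.default_rng([seed, k])
        records.append(observation_from_target_score(
            int(totals[k]),
            rng_k,
            ga_scores=(0, 1) if k in preterm else (2,),
            record_id=f"N{k + 1:02d}",
            sex=str(sexes[k]),
            mode_of_delivery=str(deliveries[k]),
            parity=str(parities[k]),
            outcome=str(scores["outcome"].iloc[k]),
        ))
    return Cohort(records=records, provenance="fixture")
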