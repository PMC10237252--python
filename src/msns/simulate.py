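"""Seeded synthetic neonatal cohorts calibrated to published group statistics.

The generator emulates a two-group NICU admission cohort in which the MSNS
total discriminates expired from discharged neonates: totals are integers on
the 0-16 grid, drawn per outcome group from a latent normal that is clipped
to [0, 16] and rounded.  Because clipping and rounding shift the mean of the
latent normal, the latent *location* is calibrated (closed-form discretized
mean, solved by Brent's method) so that the expected value of the emitted
integer scores equals the configured group mean exactly.  The default
configuration encodes the study conditions this package targets: group means
9.11 (expired) and 12.9 (discharged), mortality 9/71, and latent spreads
2.4 / 2.2 chosen so the binormal separation
``Phi((12.9 - 9.11) / sqrt(2.4^2 + 2.2^2)) ~= 0.878`` matches the reported
discrimination (AUC ~ 0.88).  The spreads are calibration constants of this
package, not published values.

Two output levels are supported: *score level* (total + outcome only, enough
for the ROC machinery) and *observation level*, where each drawn total is
realised as a full physiological record via :func:`observation_from_target_score`
— the exact inverse of the rubric, by construction.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, replace
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.stats import norm

from .cohort import Cohort
from .rubric import (
    MAX_TOTAL,
    PARAMETERS,
    NeonateObservation,
    compute_msns,
)

MODES = ("score_level", "observation_level")

#: Demographic proportions used when a synthetic cohort needs demographics
#: (male, vaginal delivery, primigravida fractions of the 71-neonate cohort).
DEMOGRAPHIC_PROPORTIONS = {"male": 59 / 71, "vaginal": 55 / 71, "primi": 58 / 71}

DIAGNOSES = (
    "birth asphyxia", "respiratory distress", "malformation",
    "meconium aspiration syndrome", "jaundice", "nonspecific", "sepsis",
)


@dataclass(frozen=True)
class GeneratorConfig:
    """Cohort size, outcome mix, per-group score calibration, and seed."""

    n_total: int = 71
    mortality_fraction: float = 9 / 71
    expired_mean: float = 9.11
    expired_sd: float = 2.4
    discharged_mean: float = 12.9
    discharged_sd: float = 2.2
    seed: int = 0
    mode: str = "score_level"

    def __post_init__(self):
        if self.n_total < 1:
            raise ValueError("n_total must be positive")
        if not 0 < self.mortality_fraction < 1:
            raise ValueError("mortality_fraction must lie strictly in (0, 1)")
        for name in ("expired_mean", "discharged_mean"):
            if not 0 <= getattr(self, name) <= MAX_TOTAL:
                raise ValueError(f"{name} must lie in [0, {MAX_TOTAL}]")
        for name in ("expired_sd", "discharged_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}")

    @property
    def n_expired(self) -> int:
        """Exact expired count: round(n * fraction), never Bernoulli."""
        return int(round(self.n_total * self.mortality_fraction))


# --------------------------------------------------------------------------
# score-level generation
# --------------------------------------------------------------------------

def score_distribution(mu: float, sd: float) -> np.ndarray:
    """PMF over {0..16} of round(clip(N(mu, sd), 0, 16))."""
    if sd == 0:
        p = np.zeros(MAX_TOTAL + 1)
        p[int(round(min(max(mu, 0), MAX_TOTAL)))] = 1.0
        return p
    edges = np.arange(0.5, MAX_TOTAL, 1.0)
    cdf = norm.cdf((edges - mu) / sd)
    p = np.empty(MAX_TOTAL + 1)
    p[0] = cdf[0]
    p[1:MAX_TOTAL] = np.diff(cdf)
    p[MAX_TOTAL] = 1.0 - cdf[-1]
    return p


@lru_cache(maxsize=64)
def latent_location(target_mean: float, sd: float) -> float:
    """Latent normal location whose clipped+rounded mean equals ``target_mean``.

    The discretized mean is continuous and strictly increasing in the
    location for sd > 0, so a bracketing root find is exact; with sd = 0 the
    distribution is degenerate and the location is the target itself.
    """
    if sd == 0:
        return target_mean
    grid = np.arange(MAX_TOTAL + 1)

    def gap(mu):
        return float(score_distribution(mu, sd) @ grid) - target_mean

    lo, hi = target_mean - 12 * sd - 1, target_mean + 12 * sd + 1
    return brentq(gap, lo, hi, xtol=1e-10)


def _draw_group_scores(rng, n, mean, sd):
    if sd == 0:
        return np.full(n, int(round(min(max(mean, 0), MAX_TOTAL))))
    mu = latent_location(mean, sd)
    latent = rng.normal(mu, sd, size=n)
    return np.rint(np.clip(latent, 0, MAX_TOTAL)).astype(int)


def generate_scores(config: GeneratorConfig) -> pd.DataFrame:
    """Draw a score-level cohort: one row per neonate, columns
    ``total_score`` (int, 0-16) and ``outcome``.

    The expired count is exact (``round(n * mortality_fraction)``); group
    scores are independent draws from the calibrated discretized normal.
    Rows are shuffled with the same seeded stream, so the output order
    carries no outcome information.
    """
    if config.mode != "score_level":
        raise ValueError("generate_scores requires mode='score_level'")
    rng = np.random.default_rng(config.seed)
    n_exp = config.n_expired
    n_dis = config.n_total - n_exp
    exp_scores = _draw_group_scores(rng, n_exp, config.expired_mean, config.expired_sd)
    dis_scores = _draw_group_scores(rng, n_dis, config.discharged_mean, config.discharged_sd)
    frame = pd.DataFrame({
        "total_score": np.concatenate([exp_scores, dis_scores]),
        "outcome": ["expired"] * n_exp + ["discharged"] * n_dis,
    })
    order = rng.permutation(len(frame))
    return frame.iloc[order].reset_index(drop=True)


# --------------------------------------------------------------------------
# observation-level generation (inverse of the rubric)
# --------------------------------------------------------------------------

# Sampling interval per (parameter, subscore): (lower, upper, decimals).
# Open-ended rubric bands use finite clinical caps so values stay plausible.
# Values are drawn in the interior, shrunk by one rounding quantum on each
# side, so the rounded value provably stays inside the band whatever the
# open/closed endpoint convention.
_BAND_RANGES = {
    "respiratory_effort": {1: (60.0, 90.0, 1), 2: (40.0, 60.0, 1)},
    "heart_rate": {0: (40.0, 100.0, 1), 1: (160.0, 220.0, 1),
                   2: (100.0, 160.0, 1)},
    "axillary_temperature": {0: (33.0, 36.0, 2), 1: (36.0, 36.5, 2),
                             2: (36.5, 37.5, 2)},
    "capillary_refill_time": {0: (5.0, 10.0, 1), 1: (3.0, 5.0, 1),
                              2: (1.0, 3.0, 1)},
    "random_blood_sugar": {0: (10.0, 40.0, 1), 1: (40.0, 60.0, 1),
                           2: (60.0, 200.0, 1)},
    "spo2": {0: (50.0, 85.0, 1), 1: (85.0, 92.0, 1),
             2: (92.0, 100.0, 1)},
    "gestational_age": {0: (24.0, 32.0, 3), 1: (32.0, 37.0, 3),
                        2: (37.0, 42.0, 3)},
    "birth_weight": {0: (0.5, 1.5, 3), 1: (1.5, 2.5, 3),
                     2: (2.5, 4.5, 3)},
}

_GA_INDEX = PARAMETERS.index("gestational_age")


@lru_cache(maxsize=None)
def _compositions(total: int) -> tuple[tuple[int, ...], ...]:
    """All ways to write ``total`` as eight ordered subscores in {0,1,2}."""
    return tuple(c for c in itertools.product((0, 1, 2), repeat=len(PARAMETERS))
                 if sum(c) == total)


def _sample_band_value(rng, lower, upper, decimals):
    q = 10.0 ** -decimals
    return round(float(rng.uniform(lower + q, upper - q)), decimals)


def observation_from_target_score(
    target_total: int,
    rng,
    *,
    ga_scores: tuple[int, ...] | None = None,
    record_id: str = "synthetic",
    sex: str = "male",
    mode_of_delivery: str = "vaginal",
    parity: str = "primi",
    outcome: str = "discharged",
    clinical_diagnosis: str | None = None,
) -> NeonateObservation:
    """Construct an observation whose MSNS total equals ``target_total`` exactly.

    A composition of the target into eight subscores (each <= 2) is chosen
    uniformly by direct enumeration, then each subscore is realised by a
    uniform draw inside its rubric band.  ``ga_scores`` optionally restricts
    the gestational-age subscore (used to pin term/preterm status); the
    restriction must leave at least one feasible composition.

    ``rng`` is a :class:`numpy.random.Generator` or an integer seed.
    """
    if not 0 <= target_total <= MAX_TOTAL:
        raise ValueError(f"target total must lie in [0, {MAX_TOTAL}]")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    comps = _compositions(target_total)
    if ga_scores is not None:
        allowed = set(ga_scores)
        comps = tuple(c for c in comps if c[_GA_INDEX] in allowed)
        if not comps:
            raise ValueError(
                f"no composition of total {target_total} with "
                f"gestational-age subscore in {sorted(allowed)}")
    comp = comps[rng.integers(len(comps))]

    values: dict[str, float] = {}
    apnea = False
    for param, sub in zip(PARAMETERS, comp):
        if param == "respiratory_effort" and sub == 0:
            apnea = True  # score-0 respiratory effort is realised as apnea/grunt
            continue
        values[param] = _sample_band_value(rng, *_BAND_RANGES[param][sub])

    obs = NeonateObservation(
        id=record_id,
        apnea_or_grunt=apnea,
        respiratory_rate=None if apnea else values["respiratory_effort"],
        retractions=bool(rng.integers(2)) if comp[0] == 1 else False,
        heart_rate=values["heart_rate"],
        axillary_temperature=values["axillary_temperature"],
        capillary_refill_time=values["capillary_refill_time"],
        random_blood_sugar=values["random_blood_sugar"],
        spo2_room_air=values["spo2"],
        gestational_age=values["gestational_age"],
        birth_weight=values["birth_weight"],
        sex=sex,
        mode_of_delivery=mode_of_delivery,
        parity=parity,
        outcome=outcome,
        clinical_diagnosis=clinical_diagnosis,
    )
    result = compute_msns(obs)
    if result.total != target_total:  # rounding a band value must not cross a boundary
        raise AssertionError(
            f"realised total {result.total} != target {target_total}")
    return obs


def generate_observation_cohort(config: GeneratorConfig) -> Cohort:
    """Draw a full observation-level cohort.

    Totals come from the score-level machinery; each total is realised as a
    physiological record using a sub-stream keyed by ``(seed, record index)``
    so a record's realisation does not depend on cohort size.  Demographics
    are seeded draws at the study cohort's proportions.
    """
    if config.mode != "observation_level":
        raise ValueError("generate_observation_cohort requires mode='observation_level'")
    scores = generate_scores(replace(config, mode="score_level"))
    width = len(str(config.n_total))
    records = []
    for k, row in enumerate(scores.itertuples(index=False)):
        rng_k = np.random.default_rng([config.seed, k])
        records.append(observation_from_target_score(
            int(row.total_score),
            rng_k,
            record_id=f"S{k + 1:0{width}d}",
            sex="male" if rng_k.random() < DEMOGRAPHIC_PROPORTIONS["male"] else "female",
            mode_of_delivery=("vaginal" if rng_k.random() < DEMOGRAPHIC_PROPORTIONS["vaginal"]
                              else "caesarean"),
            parity="primi" if rng_k.random() < DEMOGRAPHIC_PROPORTIONS["primi"] else "multi",
            outcome=row.outcome,
            clinical_diagnosis=DIAGNOSES[rng_k.integers(len(DIAGNOSES))],
        ))
    return Cohort(records=records, provenance=f"synthetic:{config.seed}")
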