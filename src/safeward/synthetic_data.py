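"""Synthetic ward injury records and staff questionnaires.

The generator emulates the statistical structure of a seven-year injury
surveillance window on a psychiatric inpatient ward with a dual
reporting stream: every injury can be self-reported by staff, and each
event independently enters the official accident register with a fixed
reporting probability (underreporting as non-reporting, a thinned
subset of true events). Causes follow the ward's observed causal-agent
mix, dominated by patient aggression; events are stamped with a uniform
month within the window. Questionnaires carry per-hazard exposure
perception as independent Bernoulli answers plus simple demographics.

All randomness flows through one :class:`numpy.random.Generator` seeded
from the config, so a fixed seed reproduces every output bit-for-bit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .records_io import CAUSES, HAZARDS

#: Observed causal-agent mix of the ward's self-reported injuries.
DEFAULT_CAUSE_PROBS: dict[str, float] = {
    "aggression": 0.46,
    "fall": 0.23,
    "sharp_object": 0.15,
    "commuting": 0.10,
    "ergonomic": 0.06,
}

#: Fraction of staff answering "exposed" per hazard category.
DEFAULT_HAZARD_PROBS: dict[str, float] = {
    "ergonomic": 1.0,
    "aggression": 1.0,
    "biological": 0.93,
    "chemical": 0.93,
    "noise": 0.714,
}

#: Ward staffing mix used for the occupation label (not printed in any
#: register; nursing technicians outnumber nurses on Brazilian wards).
DEFAULT_OCCUPATION_PROBS: dict[str, float] = {
    "nursing_technician": 0.7,
    "nurse": 0.3,
}


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of the synthetic surveillance window.

    Defaults reproduce the study ward: 93 self-reports expected over
    7 years of which 71 are expected to reach the official register,
    69% of injuries involving women, 25 staff questionnaires with the
    observed hazard-perception rates, mean age 36 and mean tenure 7.
    """

    n_years: int = 7
    annual_self_rate: float = 93.0 / 7.0
    cause_probs: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CAUSE_PROBS)
    )
    report_prob: float = 71.0 / 93.0
    n_staff: int = 25
    hazard_probs: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_HAZARD_PROBS)
    )
    female_prob: float = 0.69
    occupation_probs: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_OCCUPATION_PROBS)
    )
    mean_age: float = 36.0
    mean_tenure: float = 7.0
    ever_injured_prob: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_years < 1:
            raise ConfigurationError(f"n_years must be >= 1, got {self.n_years}")
        if self.n_staff < 1:
            raise ConfigurationError(f"n_staff must be >= 1, got {self.n_staff}")
        if self.annual_self_rate < 0:
            raise ConfigurationError("annual_self_rate must be >= 0")
        for name, p in [
            ("report_prob", self.report_prob),
            ("female_prob", self.female_prob),
            ("ever_injured_prob", self.ever_injured_prob),
            *((f"hazard_probs[{h}]", p) for h, p in self.hazard_probs.items()),
            *((f"cause_probs[{c}]", p) for c, p in self.cause_probs.items()),
            *((f"occupation_probs[{o}]", p) for o, p in self.occupation_probs.items()),
        ]:
            if not (0.0 <= p <= 1.0):
                raise ConfigurationError(f"{name} must be in [0, 1], got {p}")
        unknown = set(self.cause_probs) - set(CAUSES)
        if unknown:
            raise ConfigurationError(f"unknown cause categories {sorted(unknown)}")
        unknown = set(self.hazard_probs) - set(HAZARDS)
        if unknown:
            raise ConfigurationError(f"unknown hazard categories {sorted(unknown)}")
        if not math.isclose(sum(self.cause_probs.values()), 1.0, abs_tol=1e-9):
            raise ConfigurationError("cause_probs must sum to 1")
        if not math.isclose(sum(self.occupation_probs.values()), 1.0, abs_tol=1e-9):
            raise ConfigurationError("occupation_probs must sum to 1")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def gen_injury_records(cfg: GeneratorConfig) -> pd.DataFrame:
    """Draw the dual-stream injury register.

    True events form a Poisson stream at ``annual_self_rate`` over the
    window; every event appears as a self-report row, and each event is
    independently duplicated into the official register with probability
    ``report_prob``. The returned frame therefore holds both streams,
    distinguished by the ``source`` column, with official records a
    subset (by event) of the self-reports.
    """
    rng = cfg.rng()
    n_events = int(rng.poisson(cfg.annual_self_rate * cfg.n_years))
    causes = list(cfg.cause_probs)
    cause_draw = rng.choice(causes, size=n_events, p=list(cfg.cause_probs.values()))
    months = rng.integers(0, cfg.n_years * 12, size=n_events)
    occs = rng.choice(
        list(cfg.occupation_probs),
        size=n_events,
        p=list(cfg.occupation_probs.values()),
    )
    genders = np.where(rng.random(n_events) < cfg.female_prob, "female", "male")
    reported = rng.random(n_events) < cfg.report_prob

    base = pd.DataFrame(
        {
            "month": months.astype(int),
            "occupation": occs,
            "cause": cause_draw,
            "source": "self_report",
            "gender": genders,
        }
    )
    official = base.loc[reported].assign(source="official")
    frame = pd.concat([base, official], ignore_index=True)
    return frame


def gen_questionnaires(cfg: GeneratorConfig) -> pd.DataFrame:
    """Draw ``n_staff`` questionnaire rows.

    Hazard-perception answers are independent Bernoulli draws at the
    configured per-hazard rates; age and tenure are normal around the
    configured means (sd 8 and 4 years, floored at plausible minima);
    self-reported injury counts are shifted Poisson (always >= 1) for
    staff with an injury history, scaled so the expected total matches
    the self-report stream.
    """
    rng = np.random.default_rng(cfg.seed + 1)  # independent of the record stream
    n = cfg.n_staff
    age = np.clip(rng.normal(cfg.mean_age, 8.0, size=n), 20.0, 70.0)
    tenure = np.minimum(np.clip(rng.normal(cfg.mean_tenure, 4.0, size=n), 0.0, 45.0), age - 18.0)
    ever = rng.random(n) < cfg.ever_injured_prob

    # mean count among the injured so that the expected questionnaire
    # total matches the expected number of self-reported events
    expected_total = cfg.annual_self_rate * cfg.n_years
    mean_injured = expected_total / max(n * cfg.ever_injured_prob, 1e-12)
    counts = np.zeros(n, dtype=int)
    injured = np.flatnonzero(ever)
    if injured.size:
        # shifted Poisson: 1 + Poisson(mean - 1) keeps every injured
        # respondent at >= 1 report while matching the target mean
        counts[injured] = 1 + rng.poisson(max(mean_injured - 1.0, 0.0), size=injured.size)

    data: dict[str, object] = {
        "staff_id": [f"S{i + 1:03d}" for i in range(n)],
        "age": np.round(age, 1),
        "tenure": np.round(tenure, 1),
    }
    for hazard in HAZARDS:
        p = cfg.hazard_probs.get(hazard, 0.0)
        data[f"exposed_{hazard}"] = rng.random(n) < p
    data["ever_injured"] = ever
    data["n_self_reported"] = counts
    return pd.DataFrame(data)
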