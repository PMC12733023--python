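"""Injury-record and questionnaire I/O plus descriptive statistics.

The ward's injury surveillance has two streams: official accident
reports (CAT forms filed with the safety office) and staff self-reports
collected by questionnaire. Records are carried as pandas DataFrames
with one row per event; :class:`InjuryRecord` / :class:`QuestionnaireResponse`
give the typed row schema. Underreporting is measured by simple
differencing of the two stream totals — no record linkage is attempted,
because the streams share no linkage keys.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from ._rounding import round_half_away
from .errors import AnalysisError, DomainError, FormatError

#: Canonical causal-agent categories for ward injuries.
CAUSES: tuple[str, ...] = (
    "aggression",
    "fall",
    "sharp_object",
    "commuting",
    "ergonomic",
    "other",
)

#: Record provenance: official CAT register vs. questionnaire self-report.
SOURCES: tuple[str, ...] = ("official", "self_report")

GENDERS: tuple[str, ...] = ("female", "male", "unspecified")

#: Hazard categories probed by the risk-perception questionnaire.
HAZARDS: tuple[str, ...] = ("ergonomic", "aggression", "biological", "chemical", "noise")

RECORD_COLUMNS: tuple[str, ...] = ("month", "occupation", "cause", "source", "gender")

# Free-text cause labels seen in the wild, mapped onto the canonical enum.
_CAUSE_SYNONYMS: dict[str, str] = {
    "aggression": "aggression",
    "falls": "fall",
    "fall": "fall",
    "sharp": "sharp_object",
    "sharp_object": "sharp_object",
    "sharps": "sharp_object",
    "commuting": "commuting",
    "commute": "commuting",
    "ergonomic": "ergonomic",
    "ergonomics": "ergonomic",
    "other": "other",
}


@dataclass(frozen=True)
class InjuryRecord:
    """One injury event.

    ``month`` is a 0-based month index within the observation window.
    """

    month: int
    occupation: str
    cause: str
    source: str
    gender: str = "unspecified"

    def __post_init__(self) -> None:
        if self.month < 0:
            raise DomainError(f"month index must be >= 0, got {self.month}")
        if self.cause not in CAUSES:
            raise DomainError(f"unknown cause {self.cause!r}")
        if self.source not in SOURCES:
            raise DomainError(f"unknown source {self.source!r}")
        if self.gender not in GENDERS:
            raise DomainError(f"unknown gender {self.gender!r}")


@dataclass(frozen=True)
class QuestionnaireResponse:
    """One staff questionnaire row: demographics, hazard perception, history."""

    staff_id: str
    age: float
    tenure: float
    exposed: Mapping[str, bool] = field(default_factory=dict)
    ever_injured: bool = False
    n_self_reported: int = 0

    def __post_init__(self) -> None:
        if self.age <= 0:
            raise DomainError(f"age must be positive, got {self.age}")
        if self.tenure < 0:
            raise DomainError(f"tenure must be >= 0, got {self.tenure}")
        if self.n_self_reported < 0:
            raise DomainError("n_self_reported must be >= 0")


@dataclass(frozen=True)
class CauseBreakdown:
    """Per-cause counts and percentages of an injury-record collection."""

    counts: Mapping[str, int]
    percentages: Mapping[str, float]
    total: int
    decimals: int


def records_to_frame(records: Iterable[InjuryRecord]) -> pd.DataFrame:
    rows = [
        {f.name if f.name != "month" else "month": getattr(r, f.name) for f in fields(r)}
        for r in records
    ]
    if not rows:
        return pd.DataFrame(columns=list(RECORD_COLUMNS))
    return pd.DataFrame(rows, columns=list(RECORD_COLUMNS))


def frame_to_records(frame: pd.DataFrame) -> list[InjuryRecord]:
    return [
        InjuryRecord(
            month=int(row.month),
            occupation=str(row.occupation),
            cause=str(row.cause),
            source=str(row.source),
            gender=str(row.gender),
        )
        for row in frame.itertuples(index=False)
    ]


def normalize_cause(label: str) -> str:
    """Map a free-text cause label to the canonical enum (``other`` fallback)."""
    key = str(label).strip().lower().replace(" ", "_")
    if key in _CAUSE_SYNONYMS:
        return _CAUSE_SYNONYMS[key]
    warnings.warn(f"unknown cause label {label!r}; mapping to 'other'", stacklevel=2)
    return "other"


def read_records(path: str | Path) -> pd.DataFrame:
    """Read an injury-record CSV (columns month,occupation,cause,source,gender).

    Unknown cause labels are mapped to ``other`` with a warning; unknown
    source labels are a format error because the official/self-report
    distinction is what the underreporting analysis rests on.
    """
    path = Path(path)
    try:
        frame = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"{path}: empty records file") from exc
    missing = [c for c in RECORD_COLUMNS if c not in frame.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {', '.join(missing)}")
    if frame.empty:
        raise FormatError(f"{path}: no records")
    frame = frame.loc[:, list(RECORD_COLUMNS)].copy()
    frame["cause"] = frame["cause"].map(normalize_cause)
    bad_src = set(frame["source"].unique()) - set(SOURCES)
    if bad_src:
        raise FormatError(f"{path}: unknown source label(s) {sorted(bad_src)}")
    frame["gender"] = frame["gender"].fillna("unspecified")
    frame["month"] = frame["month"].astype(int)
    return frame


def write_records(frame: pd.DataFrame, path: str | Path) -> None:
    frame.loc[:, list(RECORD_COLUMNS)].to_csv(path, index=False)


def read_questionnaires(path: str | Path) -> pd.DataFrame:
    """Read a questionnaire CSV with one ``exposed_<hazard>`` column per hazard."""
    path = Path(path)
    try:
        frame = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"{path}: empty questionnaire file") from exc
    required = ["staff_id", "age", "tenure"] + [f"exposed_{h}" for h in HAZARDS]
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {', '.join(missing)}")
    if frame.empty:
        raise FormatError(f"{path}: no responses")
    return frame


def write_questionnaires(frame: pd.DataFrame, path: str | Path) -> None:
    frame.to_csv(path, index=False)


def _as_frame(records: pd.DataFrame | Sequence[InjuryRecord]) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        return records
    return records_to_frame(records)


def cause_breakdown(
    records: pd.DataFrame | Sequence[InjuryRecord], decimals: int = 0
) -> CauseBreakdown:
    """Count injuries per causal agent and express them as percentages.

    Percentages are ``100 * count / total`` rounded half-away-from-zero
    to ``decimals`` places, matching how surveillance tables are printed.
    """
    frame = _as_frame(records)
    if frame.empty:
        raise AnalysisError("cause_breakdown: empty record collection")
    counts = {c: int((frame["cause"] == c).sum()) for c in CAUSES}
    total = int(len(frame))
    pct = {c: round_half_away(100.0 * n / total, decimals) for c, n in counts.items()}
    return CauseBreakdown(counts=counts, percentages=pct, total=total, decimals=decimals)


def underreporting_count(self_total: int, official_total: int) -> int:
    """Number of self-reported injuries absent from the official register.

    Computed from stream totals as ``max(self - official, 0)``; the ward's
    two streams carry no keys that would allow event-level matching.
    """
    if self_total < 0 or official_total < 0:
        raise DomainError("totals must be non-negative")
    return max(self_total - official_total, 0)


def underreporting_fraction(self_total: int, official_total: int) -> float:
    """Unrecorded self-reports as a fraction of all self-reports."""
    n = underreporting_count(self_total, official_total)
    if self_total == 0:
        return 0.0
    return n / self_total


def annual_rate(
    records: pd.DataFrame | Sequence[InjuryRecord],
    years: float,
    source: str | None = None,
) -> float:
    """Events per year over the observation window, optionally by source."""
    if years <= 0:
        raise DomainError(f"years must be positive, got {years}")
    frame = _as_frame(records)
    if source is not None:
        if source not in SOURCES:
            raise DomainError(f"unknown source filter {source!r}")
        frame = frame[frame["source"] == source]
    return len(frame) / years


def perception_summary(responses: pd.DataFrame) -> dict[str, float]:
    """Per-hazard percentage of staff reporting exposure, to one decimal."""
    if responses.empty:
        raise AnalysisError("perception_summary: empty response collection")
    n = len(responses)
    out: dict[str, float] = {}
    for hazard in HAZARDS:
        col = f"exposed_{hazard}"
        if col not in responses.columns:
            raise FormatError(f"perception_summary: missing column {col}")
        out[hazard] = round_half_away(100.0 * responses[col].astype(bool).sum() / n, 1)
    return out
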