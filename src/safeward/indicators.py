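"""Ward safety indicators and their five-band traffic-light classification.

The hospital's safety performance is tracked by 23 ordinal indicators
(built with the constructivist multi-criteria methodology, MCDA-C,
phase 1), each scored 0-100. Scores are banded into five colour classes:

    very poor   0-20   red
    poor       21-40   orange
    intermediate 41-60 gray
    good       61-80   light green
    excellent  >= 81   dark green

Integer band edges belong to the band below them (a score of 20 is
"very poor", 40 is "poor", ...), matching how the ward's lowest-scoring
indicators are reported; non-integer scores follow the same
closed-upper-bound convention.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Sequence

import pandas as pd

from ._rounding import round_half_away
from .errors import AnalysisError, DomainError


class Band(enum.IntEnum):
    """Ordered indicator performance bands (worst to best)."""

    VERY_POOR = 0
    POOR = 1
    INTERMEDIATE = 2
    GOOD = 3
    EXCELLENT = 4

    @property
    def label(self) -> str:
        return self.name.lower()

    @property
    def color(self) -> str:
        return _BAND_COLORS[self]

    @property
    def score_range(self) -> tuple[float, float]:
        """Score interval (lower, upper] covered by this band.

        The lower edge is exclusive except at 0.
        """
        return _BAND_RANGES[self]


_BAND_COLORS = {
    Band.VERY_POOR: "red",
    Band.POOR: "orange",
    Band.INTERMEDIATE: "gray",
    Band.GOOD: "light green",
    Band.EXCELLENT: "dark green",
}

# upper edges are inclusive
_BAND_RANGES = {
    Band.VERY_POOR: (0.0, 20.0),
    Band.POOR: (20.0, 40.0),
    Band.INTERMEDIATE: (40.0, 60.0),
    Band.GOOD: (60.0, 80.0),
    Band.EXCELLENT: (80.0, 100.0),
}


@dataclass(frozen=True)
class Indicator:
    """One safety indicator with its measured 0-100 result."""

    id: int
    name: str
    description: str
    result: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.result <= 100.0):
            raise DomainError(
                f"indicator {self.id} result {self.result} outside [0, 100]"
            )

    @property
    def band(self) -> Band:
        return classify(self.result)


def classify(result: float) -> Band:
    """Band a 0-100 indicator result (upper edges inclusive)."""
    if not (0.0 <= result <= 100.0):
        raise DomainError(f"result {result} outside [0, 100]")
    if result <= 20.0:
        return Band.VERY_POOR
    if result <= 40.0:
        return Band.POOR
    if result <= 60.0:
        return Band.INTERMEDIATE
    if result <= 80.0:
        return Band.GOOD
    return Band.EXCELLENT


def band_summary(indicators: Sequence[Indicator]) -> pd.DataFrame:
    """Tally indicators per band with percentage of the collection.

    Returns a frame indexed by band label with ``count`` and ``percent``
    (percent rounded half-away-from-zero to whole points).
    """
    if not indicators:
        raise AnalysisError("band_summary: empty indicator collection")
    total = len(indicators)
    counts = {band: 0 for band in Band}
    for ind in indicators:
        counts[ind.band] += 1
    return pd.DataFrame(
        {
            "count": [counts[b] for b in Band],
            "percent": [round_half_away(100.0 * counts[b] / total) for b in Band],
        },
        index=pd.Index([b.label for b in Band], name="band"),
    )


def builtin_indicators() -> list[Indicator]:
    """The ward's 23 measured indicators, shipped as package data."""
    with resources.files("safeward.data").joinpath("indicators.csv").open() as fh:
        frame = pd.read_csv(fh)
    return [
        Indicator(
            id=int(r.id),
            name=str(r.name),
            description=str(r.description),
            result=float(r.result),
        )
        for r in frame.itertuples(index=False)
    ]


def read_indicators(path) -> list[Indicator]:
    frame = pd.read_csv(path)
    return [
        Indicator(int(r.id), str(r.name), str(r.description), float(r.result))
        for r in frame.itertuples(index=False)
    ]


def write_indicators(indicators: Iterable[Indicator], path) -> None:
    pd.DataFrame(
        [
            {
                "id": i.id,
                "name": i.name,
                "description": i.description,
                "result": i.result,
            }
            for i in indicators
        ]
    ).to_csv(path, index=False)
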