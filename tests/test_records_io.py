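"""Record I/O and descriptive statistics, checked against hand counts."""

import math

import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from safeward.errors import AnalysisError, DomainError, FormatError
from safeward.records_io import (
    CAUSES,
    InjuryRecord,
    annual_rate,
    cause_breakdown,
    frame_to_records,
    perception_summary,
    read_records,
    records_to_frame,
    underreporting_count,
    underreporting_fraction,
    write_records,
)
from safeward.synthetic_data import GeneratorConfig, gen_injury_records, gen_questionnaires


def _frame(cause_counts: dict[str, int], source: str = "official") -> pd.DataFrame:
    rows = []
    for cause, n in cause_counts.items():
        rows += [
            {"month": 0, "occupation": "nurse", "cause": cause, "source": source,
             "gender": "female"}
        ] * n
    return pd.DataFrame(rows)


# the ward's seven-year registers, by causal agent
OFFICIAL_COUNTS = {"aggression": 33, "fall": 16, "sharp_object": 11, "commuting": 7, "ergonomic": 4}
SELF_COUNTS = {"aggression": 58, "fall": 23, "other": 12}


def test_official_register_cause_percentages():
    breakdown = cause_breakdown(_frame(OFFICIAL_COUNTS), decimals=0)
    assert breakdown.total == 71
    assert breakdown.percentages["aggression"] == 46
    assert breakdown.percentages["fall"] == 23
    assert breakdown.percentages["sharp_object"] == 15
    assert breakdown.percentages["commuting"] == 10
    assert breakdown.percentages["ergonomic"] == 6


def test_self_report_cause_percentages_two_decimals():
    breakdown = cause_breakdown(_frame(SELF_COUNTS, "self_report"), decimals=2)
    assert breakdown.total == 93
    assert breakdown.percentages["aggression"] == 62.37
    assert breakdown.percentages["fall"] == 24.73


def test_single_record_is_its_whole_breakdown():
    breakdown = cause_breakdown(_frame({"fall": 1}), decimals=0)
    assert breakdown.percentages["fall"] == 100
    assert all(breakdown.percentages[c] == 0 for c in CAUSES if c != "fall")


def test_breakdown_counts_sum_exactly_and_percentages_nearly():
    frame = gen_injury_records(GeneratorConfig(seed=2))
    breakdown = cause_breakdown(frame, decimals=0)
    assert sum(breakdown.counts.values()) == breakdown.total == len(frame)
    assert abs(sum(breakdown.percentages.values()) - 100) <= len(CAUSES)


def test_empty_collection_is_an_analysis_error():
    with pytest.raises(AnalysisError):
        cause_breakdown(pd.DataFrame(columns=["cause"]))


def test_underreporting_difference_and_fraction():
    assert underreporting_count(93, 71) == 22
    assert underreporting_count(50, 50) == 0
    assert underreporting_count(10, 30) == 0  # floored, never negative
    assert underreporting_fraction(93, 71) == pytest.approx(22 / 93)
    with pytest.raises(DomainError):
        underreporting_count(-1, 3)


def test_underreporting_matches_thinning_expectation():
    cfg = GeneratorConfig(n_years=1, annual_self_rate=10_000, seed=23)
    frame = gen_injury_records(cfg)
    n_self = int((frame["source"] == "self_report").sum())
    n_official = int((frame["source"] == "official").sum())
    gap = underreporting_count(n_self, n_official)
    expected = (1 - cfg.report_prob) * n_self
    p = cfg.report_prob
    assert abs(gap - expected) <= 3 * math.sqrt(n_self * p * (1 - p))


def test_annual_rate_is_plain_division_and_matches_recount():
    official = _frame(OFFICIAL_COUNTS)
    assert annual_rate(official, 7, source="official") == pytest.approx(71 / 7)
    assert annual_rate(official.iloc[:0], 7) == 0.0
    frame = gen_injury_records(GeneratorConfig(seed=9))
    # independent counting oracle: iterate rows by hand
    by_hand = sum(1 for r in frame.itertuples() if r.source == "official")
    assert annual_rate(frame, 7, source="official") == pytest.approx(by_hand / 7)
    with pytest.raises(DomainError):
        annual_rate(frame, 0)


def test_roundtrip_write_read_preserves_records(tmp_path):
    frame = gen_injury_records(GeneratorConfig(seed=17)).head(500)
    path = tmp_path / "records.csv"
    write_records(frame, path)
    back = read_records(path)
    pd.testing.assert_frame_equal(
        frame.reset_index(drop=True), back, check_dtype=False
    )
    assert frame_to_records(back) == frame_to_records(frame)


def test_unknown_cause_label_maps_to_other_with_warning(tmp_path):
    path = tmp_path / "records.csv"
    path.write_text(
        "month,occupation,cause,source,gender\n0,nurse,assault,official,female\n"
    )
    with pytest.warns(UserWarning, match="assault"):
        frame = read_records(path)
    assert frame.loc[0, "cause"] == "other"


def test_missing_column_and_empty_file_are_format_errors(tmp_path):
    bad = tmp_path / "bad.csv"
    bad.write_text("month,occupation,cause,source\n0,nurse,fall,official\n")
    with pytest.raises(FormatError, match="gender"):
        read_records(bad)
    empty = tmp_path / "empty.csv"
    empty.write_text("")
    with pytest.raises(FormatError):
        read_records(empty)


def test_perception_summary_exact_and_extreme():
    q = gen_questionnaires(GeneratorConfig(n_staff=25, hazard_probs={
        "ergonomic": 1.0, "aggression": 1.0, "biological": 1.0,
        "chemical": 1.0, "noise": 1.0}, seed=3))
    assert all(v == 100.0 for v in perception_summary(q).values())
    none = gen_questionnaires(GeneratorConfig(n_staff=25, hazard_probs={
        "ergonomic": 0.0, "aggression": 0.0, "biological": 0.0,
        "chemical": 0.0, "noise": 0.0}, seed=3))
    assert all(v == 0.0 for v in perception_summary(none).values())
    with pytest.raises(AnalysisError):
        perception_summary(q.iloc[:0])


def test_invalid_record_fields_rejected():
    with pytest.raises(DomainError):
        InjuryRecord(month=-1, occupation="nurse", cause="fall", source="official")
    with pytest.raises(DomainError):
        InjuryRecord(month=0, occupation="nurse", cause="meteor", source="official")


@settings(max_examples=30, deadline=None)
@given(
    counts=st.dictionaries(
        st.sampled_from(CAUSES), st.integers(min_value=1, max_value=40),
        min_size=1, max_size=6,
    ),
    decimals=st.integers(min_value=0, max_value=3),
)
def test_breakdown_is_pure_and_consistent(counts, decimals):
    frame = _frame(counts)
    first = cause_breakdown(frame, decimals)
    second = cause_breakdown(frame, decimals)
    assert first == second
    assert sum(first.counts.values()) == len(frame)
    for cause, n in counts.items():
        assert first.counts[cause] == n


def test_records_frame_roundtrip_dataclasses():
    records = [
        InjuryRecord(0, "nurse", "aggression", "official", "female"),
        InjuryRecord(5, "nursing_technician", "fall", "self_report", "male"),
    ]
    assert frame_to_records(records_to_frame(records)) == records
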