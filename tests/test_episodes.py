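"""Severity bands, reliable-change categories, bins and wrangling."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from careflow.episodes import (
    ChangeCategory,
    SeverityBand,
    band_of_score,
    below_clinical_cutoff,
    bin_missed,
    bin_total_sessions,
    change_category,
    classify,
    wrangle_episodes,
)

scores = st.floats(min_value=0.0, max_value=40.0, allow_nan=False)


@pytest.mark.parametrize(
    ("score", "band"),
    [
        (0.0, SeverityBand.HEALTHY),
        (5.999, SeverityBand.HEALTHY),
        (6.0, SeverityBand.LOW),
        (9.999, SeverityBand.LOW),
        (10.0, SeverityBand.MILD),
        (14.999, SeverityBand.MILD),
        (15.0, SeverityBand.MODERATE),
        (20.0, SeverityBand.MODERATELY_SEVERE),
        (24.9, SeverityBand.MODERATELY_SEVERE),
        (25.0, SeverityBand.SEVERE),
        (40.0, SeverityBand.SEVERE),
    ],
)
def test_band_boundaries(score, band):
    assert band_of_score(score) is band


@pytest.mark.parametrize("score", [-0.1, 40.1, float("nan"), float("inf")])
def test_band_rejects_out_of_range(score):
    with pytest.raises(ValueError):
        band_of_score(score)


@given(scores)
def test_bands_tile_the_scale(s):
    """Every score in [0, 40] belongs to exactly one band, and band rank is
    non-decreasing in the score (no gaps, no overlaps)."""
    band = band_of_score(s)
    assert isinstance(band, SeverityBand)
    eps = 1e-6
    if s + eps <= 40:
        assert band_of_score(s + eps).rank >= band.rank


@pytest.mark.parametrize(
    ("pre", "post", "cat"),
    [
        (30, 20, ChangeCategory.SIGNIFICANT_IMPROVEMENT),
        (30, 24, ChangeCategory.SIGNIFICANT_IMPROVEMENT),  # d = -6 boundary
        (15, 21, ChangeCategory.SIGNIFICANT_DETERIORATION),  # d = +6 boundary
        (10, 10, ChangeCategory.NONSIGNIFICANT_IMPROVEMENT),  # zero change
        (10, 5.5, ChangeCategory.NONSIGNIFICANT_IMPROVEMENT),
        (10, 15.5, ChangeCategory.NONSIGNIFICANT_DETERIORATION),
    ],
)
def test_change_category_table(pre, post, cat):
    assert change_category(pre, post) is cat


@given(scores, scores)
def test_change_category_mirror_for_significant_change(pre, post):
    """Swapping pre and post flips significant improvement and deterioration."""
    if abs(post - pre) >= 6:
        forward = change_category(pre, post)
        backward = change_category(post, pre)
        pair = {forward, backward}
        assert pair == {
            ChangeCategory.SIGNIFICANT_IMPROVEMENT,
            ChangeCategory.SIGNIFICANT_DETERIORATION,
        }


@given(scores)
def test_cutoff_matches_low_bands(s):
    assert below_clinical_cutoff(s) == (
        band_of_score(s) in (SeverityBand.HEALTHY, SeverityBand.LOW)
    )


@pytest.mark.parametrize(
    ("n", "label"),
    [(0, "<2"), (1, "<2"), (2, "2-7"), (7, "2-7"), (8, "8-15"), (15, "8-15"),
     (16, "16-20"), (20, "16-20"), (21, ">20"), (100, ">20")],
)
def test_session_bins(n, label):
    assert bin_total_sessions(n) == label


@pytest.mark.parametrize(
    ("n", "label"), [(0, "0"), (1, "1"), (2, "2"), (3, "3"), (4, "4+"), (12, "4+")]
)
def test_missed_bins(n, label):
    assert bin_missed(n) == label


def test_bins_reject_negative_counts():
    with pytest.raises(ValueError):
        bin_total_sessions(-1)
    with pytest.raises(ValueError):
        bin_missed(-3)


def test_bins_surjective_and_monotone():
    session_labels = [bin_total_sessions(n) for n in range(0, 40)]
    missed_labels = [bin_missed(n) for n in range(0, 10)]
    assert set(session_labels) == {"<2", "2-7", "8-15", "16-20", ">20"}
    assert set(missed_labels) == {"0", "1", "2", "3", "4+"}
    # monotone: label order index never decreases with n
    s_order = ["<2", "2-7", "8-15", "16-20", ">20"]
    m_order = ["0", "1", "2", "3", "4+"]
    assert [s_order.index(x) for x in session_labels] == sorted(
        s_order.index(x) for x in session_labels
    )
    assert [m_order.index(x) for x in missed_labels] == sorted(
        m_order.index(x) for x in missed_labels
    )


# ---------------------------------------------------------------------------
# Wrangling


def _raw(rows: list[dict]) -> pd.DataFrame:
    base = {
        "client_id": "A",
        "gender": "female",
        "age": 40,
        "first_date": "2012-03-01",
        "last_date": "2012-06-01",
        "pre_score": 22.0,
        "post_score": 12.0,
        "individual_sessions": 8,
        "group_sessions": 0,
        "cna_count": 1,
        "dna_count": 0,
        "discharge": "goals_achieved",
    }
    return pd.DataFrame([{**base, **r} for r in rows])


def test_wrangle_drops_missing_and_reports_per_column():
    raw = _raw([{"client_id": f"C{i}"} for i in range(5)])
    raw.loc[2, "post_score"] = np.nan
    table, report = wrangle_episodes(raw)
    assert len(table) == 4
    assert report.missing == {"post_score": 1}
    assert report.n_input == 5 and report.n_dropped == 1


def test_wrangle_clean_table_is_identity_with_empty_report():
    raw = _raw([{"client_id": f"C{i}"} for i in range(4)])
    table, report = wrangle_episodes(raw)
    assert len(table) == 4
    assert report.missing == {} and report.n_dropped == 0
    assert (table["total_sessions"] == 8).all()
    assert list(table["episode_index"]) == [1, 1, 1, 1]


def test_wrangle_orders_episodes_by_first_date():
    raw = _raw(
        [
            {"client_id": "A", "first_date": "2010-05-01", "last_date": "2010-06-01"},
            {"client_id": "A", "first_date": "2008-05-01", "last_date": "2008-06-01"},
        ]
    )
    table, _ = wrangle_episodes(raw)
    by_date = table.sort_values("first_date")
    assert list(by_date["episode_index"]) == [1, 2]
    assert by_date.iloc[0]["first_date"].year == 2008


def test_wrangle_missing_column_is_schema_error():
    raw = _raw([{}]).drop(columns=["dna_count"])
    with pytest.raises(ValueError, match="dna_count"):
        wrangle_episodes(raw)


@pytest.mark.parametrize(
    ("column", "value"),
    [
        ("first_date", "not-a-date"),
        ("pre_score", 41.0),
        ("pre_score", "high"),
        ("individual_sessions", -2),
        ("gender", "unknown"),
        ("discharge", "left"),
    ],
)
def test_wrangle_invalid_values_dropped_and_counted(column, value):
    raw = _raw([{"client_id": "C0"}, {"client_id": "C1", column: value}])
    table, report = wrangle_episodes(raw)
    assert len(table) == 1
    assert report.missing == {column: 1}


def test_wrangle_never_invents_rows():
    raw = _raw([{"client_id": f"C{i}"} for i in range(8)])
    raw.loc[1, "pre_score"] = np.nan
    raw.loc[1, "gender"] = "?"
    raw.loc[5, "last_date"] = "2001-01-01"  # before first_date
    table, report = wrangle_episodes(raw)
    assert len(table) + report.n_dropped == len(raw)
    assert report.n_dropped == 2  # row 1 counted once despite two bad columns


def test_wrangle_flags_underage_without_dropping():
    raw = _raw([{"age": 17}, {"age": 30}])
    table, report = wrangle_episodes(raw)
    assert len(table) == 2
    assert report.flags == {"age_below_18": 1}


def test_classify_adds_consistent_columns():
    raw = _raw([{"pre_score": 27.0, "post_score": 20.0, "dna_count": 6}])
    table, _ = wrangle_episodes(raw)
    out = classify(table)
    row = out.iloc[0]
    assert row["pre_band"] == "severe"
    assert row["post_band"] == "moderately_severe"
    assert row["change_category"] == "significant_improvement"
    assert row["dna_bin"] == "4+"
    assert row["session_mix"] == "individual_only"
    assert not row["below_cutoff_pre"]
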