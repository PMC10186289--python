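"""Synthetic generator calibration and exact-composition fixtures."""

import numpy as np
import pandas as pd
import pytest

from careflow.episodes import SeverityBand, classify, wrangle_episodes
from careflow.synth import (
    TABLE_BAND_COUNTS,
    CompositionSpec,
    GeneratorConfig,
    build_fixture,
    default_config,
    generate_episodes,
)

BANDS = [b.value for b in SeverityBand]


def test_default_config_matches_service_composition():
    cfg = default_config()
    assert sum(cfg.band_weights) == 2933
    assert cfg.female_prob == 0.60
    assert cfg.repeat_probs == (0.942, 0.056, 0.002)
    assert cfg.seed == 1
    cfg.validate()


def test_invalid_config_lists_all_violations():
    cfg = GeneratorConfig(n_clients=0, repeat_probs=(0.5, 0.2, 0.2), female_prob=1.5)
    with pytest.raises(ValueError) as err:
        cfg.validate()
    msg = str(err.value)
    assert "n_clients" in msg and "repeat_probs" in msg and "female_prob" in msg


def test_degenerate_band_weights_pin_the_pre_band():
    cfg = GeneratorConfig(n_clients=200, band_weights=(0, 0, 0, 0, 0, 1), seed=5)
    table = classify(generate_episodes(cfg))
    assert (table["pre_band"] == "severe").all()


def test_single_episode_clients():
    cfg = GeneratorConfig(n_clients=100, repeat_probs=(1.0, 0.0, 0.0), seed=2)
    table = generate_episodes(cfg)
    assert len(table) == 100
    assert table["client_id"].nunique() == 100
    assert (table["episode_index"] == 1).all()


def test_seed_determinism():
    a = generate_episodes(GeneratorConfig(n_clients=300, seed=9))
    b = generate_episodes(GeneratorConfig(n_clients=300, seed=9))
    pd.testing.assert_frame_equal(a, b)
    c = generate_episodes(GeneratorConfig(n_clients=300, seed=10))
    assert not a.equals(c)


def test_generated_table_passes_wrangling_with_zero_drops(default_table):
    raw = default_table.drop(columns=["total_sessions", "episode_index"]).assign(
        first_date=default_table["first_date"].dt.strftime("%Y-%m-%d"),
        last_date=default_table["last_date"].dt.strftime("%Y-%m-%d"),
    )
    wrangled, report = wrangle_episodes(raw)
    assert report.n_dropped == 0
    assert len(wrangled) == len(default_table)
    assert (
        wrangled["total_sessions"]
        == wrangled["individual_sessions"] + wrangled["group_sessions"]
    ).all()
    assert (wrangled["first_date"] <= wrangled["last_date"]).all()


def test_missed_appointment_means_recover_configuration(large_table):
    """Per-band CNA/DNA sample means sit within 3 SE of the configured means."""
    cfg = default_config()
    table = classify(large_table)
    for model, column in ((cfg.cna_model, "cna_count"), (cfg.dna_model, "dna_count")):
        for band, (mean, sd) in zip(BANDS, model):
            x = table.loc[table["pre_band"] == band, column]
            se = sd / np.sqrt(len(x))
            assert abs(x.mean() - mean) < 3 * se, (column, band)


def test_individual_session_means_recover_configuration(large_table):
    """Among episodes without group sessions the per-band individual-session
    draws are untouched by the attendance-mode overlay, so their sample
    means recover the configured negative-binomial means."""
    cfg = default_config()
    table = classify(large_table)
    solo = table.loc[table["group_sessions"] == 0]
    for band, (mean, sd) in zip(BANDS, cfg.session_model):
        x = solo.loc[solo["pre_band"] == band, "individual_sessions"]
        se = sd / np.sqrt(len(x))
        assert abs(x.mean() - mean) < 3 * se, band


def test_severe_band_session_mean_matches_published_value():
    """At the default size, pre-severe episodes average ~16.2 individual
    sessions (within 3 standard errors of the published mean)."""
    table = classify(generate_episodes(default_config(seed=4)))
    sev = table.loc[table["pre_band"] == "severe", "individual_sessions"]
    se = 13.8 / np.sqrt(len(sev))
    assert abs(sev.mean() - 16.2) < 3 * se


def test_band_transitions_are_local(large_table):
    """>= 90% of episodes end within one band of where they started."""
    table = classify(large_table)
    rank = {b: i for i, b in enumerate(BANDS)}
    move = (table["pre_band"].map(rank) - table["post_band"].map(rank)).abs()
    assert (move <= 1).mean() >= 0.9


def test_band_composition_recovers_weights(large_table):
    table = classify(large_table)
    observed = table["pre_band"].value_counts(normalize=True)
    expected = np.array(TABLE_BAND_COUNTS) / sum(TABLE_BAND_COUNTS)
    for band, exp in zip(BANDS, expected):
        se = np.sqrt(exp * (1 - exp) / len(table))
        assert abs(observed[band] - exp) < 4 * se, band


def test_group_attendance_shares(large_table):
    table = classify(large_table)
    share = table["session_mix"].value_counts(normalize=True)
    assert share.get("group_only", 0) == pytest.approx(0.031, abs=0.005)
    assert share.get("mixed", 0) == pytest.approx(0.056, abs=0.007)


# ---------------------------------------------------------------------------
# Composition fixtures


def test_fixture_exact_composition():
    spec = CompositionSpec(
        strata=[({"pre_band": "severe", "post_band": "severe"}, 3)],
        filler={"pre_band": "moderate", "post_band": "healthy"},
        total=5,
    )
    table = classify(build_fixture(spec))
    assert len(table) == 5
    assert ((table["pre_band"] == "severe") & (table["post_band"] == "severe")).sum() == 3


def test_fixture_empty():
    table = build_fixture(CompositionSpec(strata=[], filler={}, total=0))
    assert len(table) == 0


def test_fixture_rejects_overfull_strata():
    spec = CompositionSpec(strata=[({"pre_band": "mild"}, 6)], filler={}, total=5)
    with pytest.raises(ValueError, match="exceed"):
        build_fixture(spec)


def test_fixture_rejects_contradictory_pattern():
    # a severe post band cannot coexist with significant improvement from healthy
    spec = CompositionSpec(
        strata=[
            (
                {
                    "pre_band": "healthy",
                    "post_band": "severe",
                    "change_category": "significant_improvement",
                },
                1,
            )
        ],
        filler={},
        total=1,
    )
    with pytest.raises(ValueError, match="satisfiable"):
        build_fixture(spec)


def test_fixture_patterns_classify_as_requested():
    spec = CompositionSpec(
        strata=[
            (
                {
                    "pre_band": "severe",
                    "sessions_bin": "8-15",
                    "cna_bin": "4+",
                    "change_category": "significant_improvement",
                    "discharge": "dropped_out",
                    "session_mix": "mixed",
                },
                4,
            )
        ],
        filler={"pre_band": "mild"},
        total=6,
    )
    table = classify(build_fixture(spec))
    sub = table.iloc[:4]
    assert (sub["pre_band"] == "severe").all()
    assert (sub["sessions_bin"] == "8-15").all()
    assert (sub["cna_bin"] == "4+").all()
    assert (sub["change_category"] == "significant_improvement").all()
    assert (sub["discharge"] == "dropped_out").all()
    assert (sub["session_mix"] == "mixed").all()


def test_fixture_repeat_use_composition():
    spec = CompositionSpec(
        strata=[
            ({"episodes_per_client": 2}, 3),
            ({"episodes_per_client": 3}, 1),
        ],
        filler={},
        total=13,
    )
    table = build_fixture(spec)
    per_client = table.groupby("client_id")["episode_index"].max()
    assert sorted(per_client) == [1, 1, 1, 1, 2, 2, 2, 3]
    assert len(table) == 13


def test_fixture_passes_wrangling():
    spec = CompositionSpec(
        strata=[({"pre_band": "severe", "dna_bin": "2"}, 10)],
        filler={"pre_band": "low"},
        total=25,
    )
    fixture = build_fixture(spec)
    raw = fixture.drop(columns=["total_sessions", "episode_index"])
    _, report = wrangle_episodes(raw)
    assert report.n_dropped == 0
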