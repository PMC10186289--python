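"""Synthetic therapy-episode generator and exact-composition fixtures.

The clinical episode data the analysis pipeline is designed for are not
publicly available, so this module provides two substitutes:

``generate_episodes``
    A stochastic generator whose default configuration is calibrated to the
    published service characteristics: six pre-therapy severity bands with
    fixed marginal weights, band-conditional negative-binomial models for
    individual sessions and missed appointments (CNA / DNA), a band-local
    pre-to-post transition kernel (most episodes move at most one band), a
    discharge kernel whose dropout share rises with severity, a weak
    positive pre-score/sessions correlation induced by a Gaussian copula,
    and zero-inflated group-session attendance.

``build_fixture``
    A deterministic constructor that lays out an episode table with an
    exact composition (so many episodes matching this attribute pattern,
    so many matching that), used to reproduce printed pathway counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from datetime import date, timedelta

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import ndtr

from .episodes import (
    EPISODE_COLUMNS,
    MISSED_BIN_LABELS,
    SESSION_BIN_LABELS,
    NatureOfDischarge,
    SessionMix,
    SeverityBand,
)

__all__ = [
    "GeneratorConfig",
    "CompositionSpec",
    "default_config",
    "generate_episodes",
    "build_fixture",
]

_BANDS = [b.value for b in SeverityBand]
_BAND_LO = np.array([0.0, 6.0, 10.0, 15.0, 20.0, 25.0])
_BAND_HI = np.array([6.0, 10.0, 15.0, 20.0, 25.0, 40.0])

#: Published service composition: episode counts per pre-therapy band
#: (healthy .. severe), N = 2,933.
TABLE_BAND_COUNTS = (129, 212, 431, 604, 718, 839)

#: Per-band (mean, SD) of individual sessions attended.
TABLE_INDIVIDUAL_SESSIONS = (
    (9.9, 6.7), (10.8, 7.7), (11.5, 7.4), (12.4, 8.2), (14.3, 11.2), (16.2, 13.8),
)
#: Per-band (mean, SD) of cancelled appointments (CNA).
TABLE_CNA = ((1.2, 1.5), (1.5, 1.7), (1.3, 1.8), (1.4, 1.8), (1.7, 2.1), (2.0, 2.3))
#: Per-band (mean, SD) of missed-without-notice appointments (DNA).
TABLE_DNA = ((0.7, 1.1), (1.0, 1.4), (1.1, 1.9), (1.2, 1.6), (1.7, 2.4), (2.2, 2.6))
#: Per-band (mean, SD) of client age, truncated to [18, 89] years.
TABLE_AGE = (
    (40.9, 15.4), (41.5, 15.2), (39.8, 14.4), (41.0, 14.4), (40.5, 13.4), (42.5, 12.2),
)

# Pre-to-post band transition kernels: distribution over band offsets
# (post rank minus pre rank).  Mass is concentrated on {-1, 0, +1} so that
# >= 90% of episodes move at most one band; improvement dominates, and the
# offsets reachable from each band keep the post rank in range.
DEFAULT_TRANSITION_KERNEL = {
    "healthy": {0: 0.95, 1: 0.04, 2: 0.01},
    "low": {-1: 0.82, 0: 0.12, 1: 0.04, 2: 0.02},
    "mild": {-2: 0.04, -1: 0.55, 0: 0.32, 1: 0.08, 2: 0.01},
    "moderate": {-3: 0.02, -2: 0.08, -1: 0.55, 0: 0.30, 1: 0.05},
    "moderately_severe": {-3: 0.02, -2: 0.07, -1: 0.52, 0: 0.35, 1: 0.04},
    "severe": {-3: 0.02, -2: 0.06, -1: 0.50, 0: 0.42},
}

# Discharge kernels (goals achieved / partially / no change / dropped out):
# dropout share rises with severity, ~10-13% in the lower three bands and
# ~17-27% in the upper three.
DEFAULT_DISCHARGE_KERNEL = {
    "healthy": {"goals_achieved": 0.45, "goals_partially_achieved": 0.30,
                "no_change": 0.15, "dropped_out": 0.10},
    "low": {"goals_achieved": 0.50, "goals_partially_achieved": 0.28,
            "no_change": 0.11, "dropped_out": 0.11},
    "mild": {"goals_achieved": 0.50, "goals_partially_achieved": 0.27,
             "no_change": 0.10, "dropped_out": 0.13},
    "moderate": {"goals_achieved": 0.55, "goals_partially_achieved": 0.20,
                 "no_change": 0.08, "dropped_out": 0.17},
    "moderately_severe": {"goals_achieved": 0.42, "goals_partially_achieved": 0.23,
                          "no_change": 0.13, "dropped_out": 0.22},
    "severe": {"goals_achieved": 0.35, "goals_partially_achieved": 0.22,
               "no_change": 0.16, "dropped_out": 0.27},
}


@dataclass
class GeneratorConfig:
    """Full parameterization of the synthetic episode distribution.

    Defaults reproduce the published service characteristics (band
    composition, per-band session/CNA/DNA/age moments, repeat-use shares,
    gender mix) and the reported pre-score/sessions correlation of 0.2.
    """

    n_clients: int = 2766
    #: P(client has 1 / 2 / 3 episodes).
    repeat_probs: tuple = (0.942, 0.056, 0.002)
    #: Pre-band sampling weights, healthy .. severe (need not be normalised).
    band_weights: tuple = TABLE_BAND_COUNTS
    #: Per-band (mean, SD) of individual sessions.
    session_model: tuple = TABLE_INDIVIDUAL_SESSIONS
    #: Zero-inflated group attendance: shares of group-only and mixed
    #: episodes, and the count model given any group attendance.
    group_session_model: dict = field(default_factory=lambda: {
        "p_group_only": 0.031,
        "p_mixed": 0.056,
        "count_mean_given_any": 10.0,
        "count_sd_given_any": 5.0,
    })
    cna_model: tuple = TABLE_CNA
    dna_model: tuple = TABLE_DNA
    #: Per-pre-band distribution over post-band rank offsets.
    transition_kernel: dict = field(
        default_factory=lambda: {b: dict(v) for b, v in DEFAULT_TRANSITION_KERNEL.items()}
    )
    #: Per-pre-band distribution over the four discharge outcomes.
    discharge_kernel: dict = field(
        default_factory=lambda: {b: dict(v) for b, v in DEFAULT_DISCHARGE_KERNEL.items()}
    )
    #: Target Pearson correlation between pre_score and total_sessions.
    score_session_dependence: float = 0.2
    age_model: tuple = TABLE_AGE
    female_prob: float = 0.60
    date_window: tuple = ("2007-09-01", "2019-09-01")
    session_interval_days: int = 7
    seed: int = 1

    def validate(self) -> None:
        """Raise ``ValueError`` listing every constraint violation."""
        problems: list[str] = []
        if self.n_clients < 1:
            problems.append("n_clients must be >= 1")
        if abs(sum(self.repeat_probs) - 1.0) > 1e-9 or min(self.repeat_probs) < 0:
            problems.append("repeat_probs must be non-negative and sum to 1")
        if len(self.band_weights) != 6 or min(self.band_weights) < 0:
            problems.append("band_weights needs 6 non-negative entries")
        elif sum(self.band_weights) <= 0:
            problems.append("band_weights must have positive total")
        for name, model in (("session_model", self.session_model),
                            ("cna_model", self.cna_model),
                            ("dna_model", self.dna_model),
                            ("age_model", self.age_model)):
            if len(model) != 6 or any(
                not np.isfinite([m, s]).all() or m < 0 or s < 0 for m, s in model
            ):
                problems.append(f"{name} needs 6 finite non-negative (mean, SD) pairs")
        for band in _BANDS:
            kern = self.transition_kernel.get(band)
            if kern is None or abs(sum(kern.values()) - 1.0) > 1e-9 or min(kern.values()) < 0:
                problems.append(f"transition_kernel[{band!r}] must be a distribution")
            dk = self.discharge_kernel.get(band)
            if dk is None or abs(sum(dk.values()) - 1.0) > 1e-9 or min(dk.values()) < 0:
                problems.append(f"discharge_kernel[{band!r}] must be a distribution")
        g = self.group_session_model
        if not (0 <= g["p_group_only"] and 0 <= g["p_mixed"]
                and g["p_group_only"] + g["p_mixed"] <= 1):
            problems.append("group-session mode probabilities must be in [0,1]")
        if not 0 <= self.female_prob <= 1:
            problems.append("female_prob must be in [0,1]")
        if not -1 < self.score_session_dependence < 1:
            problems.append("score_session_dependence must be in (-1, 1)")
        if self.session_interval_days < 0:
            problems.append("session_interval_days must be >= 0")
        start, end = (date.fromisoformat(d) for d in self.date_window)
        if end < start:
            problems.append("date_window end precedes start")
        if problems:
            raise ValueError("invalid generator config: " + "; ".join(problems))


def default_config(seed: int = 1) -> GeneratorConfig:
    """The calibrated default configuration (2,766 clients, seed 1)."""
    return GeneratorConfig(seed=seed)


# Affine map from the target Pearson correlation to the latent copula
# correlation.  The band-conditional session means already induce a
# between-band correlation of ~0.17 at the default calibration; the copula
# supplies the remainder within bands.  Constants fitted once by simulation
# against the default configuration.
_RHO_BASE = 0.1700
_RHO_SLOPE = 0.2213


def _latent_rho(target: float) -> float:
    return float(np.clip((target - _RHO_BASE) / _RHO_SLOPE, -0.99, 0.99))


def _nbinom_params(mean: float, sd: float):
    """Method-of-moments negative-binomial (r, p); None → Poisson fallback."""
    var = sd * sd
    if var <= mean or mean <= 0:
        return None
    r = mean * mean / (var - mean)
    return r, r / (r + mean)


def _count_ppf(u: np.ndarray, mean: float, sd: float) -> np.ndarray:
    nb = _nbinom_params(mean, sd)
    if nb is None:
        return stats.poisson.ppf(u, mu=max(mean, 0.0))
    return stats.nbinom.ppf(u, nb[0], nb[1])


def generate_episodes(config: GeneratorConfig | None = None) -> pd.DataFrame:
    """Draw a synthetic episode table from the configured distribution.

    Reproducible for a fixed config (including its seed).  Returns a
    wrangled-schema table (:data:`careflow.episodes.EPISODE_COLUMNS`).
    """
    cfg = config if config is not None else default_config()
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)

    eps_per_client = rng.choice([1, 2, 3], size=cfg.n_clients, p=np.asarray(cfg.repeat_probs))
    client_ids = np.repeat(
        np.array([f"C{i + 1:05d}" for i in range(cfg.n_clients)]), eps_per_client
    )
    n = int(eps_per_client.sum())

    weights = np.asarray(cfg.band_weights, dtype=float)
    band = rng.choice(6, size=n, p=weights / weights.sum())

    # Gaussian copula linking within-band pre-score position to the session
    # count quantile.
    rho = _latent_rho(cfg.score_session_dependence)
    z1 = rng.standard_normal(n)
    z2 = rho * z1 + np.sqrt(1.0 - rho * rho) * rng.standard_normal(n)
    u1, u2 = ndtr(z1), ndtr(z2)

    pre = _BAND_LO[band] + u1 * (_BAND_HI[band] - _BAND_LO[band])

    sess_mean = np.array([m for m, _ in cfg.session_model])
    sess_sd = np.array([s for _, s in cfg.session_model])
    individual = np.zeros(n)
    for b in range(6):
        mask = band == b
        if mask.any():
            individual[mask] = _count_ppf(u2[mask], sess_mean[b], sess_sd[b])

    # Group-session attendance: a small share of episodes are group-only or
    # mixed; the rest attend no group sessions.
    g = cfg.group_session_model
    mode_u = rng.random(n)
    group_only = mode_u < g["p_group_only"]
    mixed = (~group_only) & (mode_u < g["p_group_only"] + g["p_mixed"])
    group = np.zeros(n)
    n_any = int(group_only.sum() + mixed.sum())
    if n_any:
        cm, cs = g["count_mean_given_any"] - 1.0, g["count_sd_given_any"]
        nb = _nbinom_params(cm, cs)
        if nb is None:
            counts = rng.poisson(max(cm, 0.0), size=n_any)
        else:
            counts = rng.poisson(rng.gamma(nb[0], (1 - nb[1]) / nb[1], size=n_any))
        group[group_only | mixed] = 1 + counts
    individual[group_only] = 0
    individual[mixed] = np.maximum(individual[mixed], 1)

    def _band_counts(model):
        out = np.zeros(n)
        for b in range(6):
            mask = band == b
            if not mask.any():
                continue
            mean, sd = model[b]
            nb = _nbinom_params(mean, sd)
            if nb is None:
                out[mask] = rng.poisson(max(mean, 0.0), size=int(mask.sum()))
            else:
                lam = rng.gamma(nb[0], (1 - nb[1]) / nb[1], size=int(mask.sum()))
                out[mask] = rng.poisson(lam)
        return out

    cna = _band_counts(cfg.cna_model)
    dna = _band_counts(cfg.dna_model)

    # Band-level pre -> post transition, then uniform jitter within the
    # destination band.
    offset = np.zeros(n, dtype=int)
    for b, name in enumerate(_BANDS):
        mask = band == b
        if not mask.any():
            continue
        kern = cfg.transition_kernel[name]
        offs = np.array(sorted(kern), dtype=int)
        probs = np.array([kern[o] for o in offs])
        offset[mask] = rng.choice(offs, size=int(mask.sum()), p=probs / probs.sum())
    post_band = np.clip(band + offset, 0, 5)
    post = _BAND_LO[post_band] + rng.random(n) * (_BAND_HI[post_band] - _BAND_LO[post_band])

    discharge = np.empty(n, dtype=object)
    outcomes = [d.value for d in NatureOfDischarge]
    for b, name in enumerate(_BANDS):
        mask = band == b
        if not mask.any():
            continue
        kern = cfg.discharge_kernel[name]
        probs = np.array([kern[o] for o in outcomes])
        discharge[mask] = rng.choice(outcomes, size=int(mask.sum()), p=probs / probs.sum())

    age_mean = np.array([m for m, _ in cfg.age_model])
    age_sd = np.array([s for _, s in cfg.age_model])
    a = (18.0 - age_mean[band]) / age_sd[band]
    b_ = (89.0 - age_mean[band]) / age_sd[band]
    age = np.round(
        stats.truncnorm.ppf(rng.random(n), a, b_, loc=age_mean[band], scale=age_sd[band])
    )

    gender = np.where(rng.random(n) < cfg.female_prob, "female", "male")

    start, end = (date.fromisoformat(d) for d in cfg.date_window)
    span = (end - start).days
    first = np.array(
        [start + timedelta(days=int(o)) for o in rng.integers(0, span + 1, size=n)]
    )
    total = (individual + group).astype(int)
    last = np.array(
        [
            f + timedelta(days=int(max(t - 1, 0)) * cfg.session_interval_days)
            for f, t in zip(first, total)
        ]
    )

    df = pd.DataFrame(
        {
            "client_id": client_ids,
            "gender": gender,
            "age": age.astype(float),
            "first_date": pd.to_datetime(first),
            "last_date": pd.to_datetime(last),
            "pre_score": np.round(pre, 1),
            "post_score": np.round(post, 1),
            "individual_sessions": individual.astype(int),
            "group_sessions": group.astype(int),
            "total_sessions": total,
            "cna_count": cna.astype(int),
            "dna_count": dna.astype(int),
            "discharge": discharge,
        }
    )
    df["_order"] = np.arange(len(df))
    df = df.sort_values(["client_id", "first_date", "last_date", "_order"], kind="stable")
    df["episode_index"] = df.groupby("client_id").cumcount() + 1
    df = df.sort_values("_order", kind="stable").drop(columns="_order")
    return df.reset_index(drop=True)[EPISODE_COLUMNS]


# ---------------------------------------------------------------------------
# Exact-composition fixtures


@dataclass
class CompositionSpec:
    """Exact layout of an episode table by attribute pattern.

    ``strata`` is a list of ``(pattern, count)`` pairs; ``filler`` is the
    pattern applied to the remaining episodes up to ``total``.  A pattern is
    a dict over the keys in :data:`PATTERN_KEYS`; every unspecified field
    takes a documented deterministic default.  With ``episodes_per_client``
    in a pattern, ``count`` is the number of *clients* in that stratum, each
    contributing that many episodes.
    """

    strata: list
    filler: dict
    total: int

    def validate(self) -> None:
        problems = []
        if self.total < 0:
            problems.append("total must be >= 0")
        used = 0
        for pattern, count in self.strata:
            if count < 0:
                problems.append("stratum counts must be >= 0")
            used += count * int(pattern.get("episodes_per_client", 1))
            unknown = set(pattern) - PATTERN_KEYS
            if unknown:
                problems.append(f"unknown pattern key(s): {sorted(unknown)}")
        if set(self.filler) - PATTERN_KEYS:
            problems.append(
                f"unknown filler key(s): {sorted(set(self.filler) - PATTERN_KEYS)}"
            )
        if used > self.total:
            problems.append(
                f"stratum episode counts ({used}) exceed total ({self.total})"
            )
        if problems:
            raise ValueError("invalid composition spec: " + "; ".join(problems))


PATTERN_KEYS = {
    "pre_band", "post_band", "change_category", "discharge",
    "sessions_bin", "total_sessions", "session_mix",
    "cna_bin", "cna_count", "dna_bin", "dna_count",
    "gender", "age", "episodes_per_client",
}

# Representative values used when a pattern pins a bin but not a count.
_SESSION_BIN_REP = {"<2": 1, "2-7": 4, "8-15": 10, "16-20": 18, ">20": 24}
_MISSED_BIN_REP = {"0": 0, "1": 1, "2": 2, "3": 3, "4+": 5}
# Closed score interval per band (half-open bands narrowed at the top).
_BAND_CLOSED = {
    name: (lo, hi if name == "severe" else hi - 0.5)
    for name, lo, hi in zip(_BANDS, _BAND_LO, _BAND_HI)
}
# Closed post-minus-pre interval per change category.
_CHANGE_CLOSED = {
    "significant_improvement": (-40.0, -6.0),
    "nonsignificant_improvement": (-5.5, 0.0),
    "nonsignificant_deterioration": (0.5, 5.5),
    "significant_deterioration": (6.0, 40.0),
}
_FIXTURE_EPOCH = date(2010, 1, 4)


def _solve_scores(pattern: dict) -> tuple[float, float]:
    """Pick (pre, post) satisfying the pattern's band/change constraints.

    Intervals are intersected and midpoints taken, so the choice is
    deterministic and sits away from classification boundaries wherever the
    constraints allow.
    """
    a, b = _BAND_CLOSED[pattern.get("pre_band", "moderate")]
    if "post_band" in pattern:
        c, d = _BAND_CLOSED[pattern["post_band"]]
    else:
        c, d = 0.0, 40.0
    if "change_category" in pattern:
        lo_d, hi_d = _CHANGE_CLOSED[pattern["change_category"]]
    elif "post_band" in pattern:
        lo_d, hi_d = -40.0, 40.0
    else:
        lo_d, hi_d = -2.0, -2.0  # default: small non-significant improvement
    t_lo, t_hi = max(lo_d, c - b), min(hi_d, d - a)
    if t_lo > t_hi:
        raise ValueError(f"pattern has no satisfiable pre/post scores: {pattern}")
    t = round((t_lo + t_hi) / 2.0, 1)
    p_lo, p_hi = max(a, c - t), min(b, d - t)
    pre = round((p_lo + p_hi) / 2.0, 1)
    return pre, round(pre + t, 1)


def _resolve_sessions(pattern: dict) -> tuple[int, int]:
    """Individual and group session counts consistent with the pattern."""
    if "total_sessions" in pattern:
        total = int(pattern["total_sessions"])
    elif "sessions_bin" in pattern:
        label = pattern["sessions_bin"]
        if label not in _SESSION_BIN_REP:
            raise ValueError(f"unknown sessions_bin {label!r}; use {SESSION_BIN_LABELS}")
        total = _SESSION_BIN_REP[label]
    else:
        total = 10
    mix = pattern.get("session_mix", SessionMix.INDIVIDUAL_ONLY.value)
    mix = mix.value if isinstance(mix, SessionMix) else mix
    if mix == "individual_only":
        if total < 1:
            raise ValueError("individual_only requires total_sessions >= 1")
        return total, 0
    if mix == "group_only":
        if total < 1:
            raise ValueError("group_only requires total_sessions >= 1")
        return 0, total
    if mix == "mixed":
        if total < 2:
            raise ValueError("mixed sessions require total_sessions >= 2")
        group = max(1, total // 3)
        return total - group, group
    if mix == "no_sessions":
        if total != 0:
            raise ValueError("no_sessions requires total_sessions = 0")
        return 0, 0
    raise ValueError(f"unknown session_mix {mix!r}")


def _resolve_missed(pattern: dict, kind: str) -> int:
    if f"{kind}_count" in pattern:
        return int(pattern[f"{kind}_count"])
    if f"{kind}_bin" in pattern:
        label = pattern[f"{kind}_bin"]
        if label not in _MISSED_BIN_REP:
            raise ValueError(f"unknown {kind}_bin {label!r}; use {MISSED_BIN_LABELS}")
        return _MISSED_BIN_REP[label]
    return 0


def build_fixture(spec: CompositionSpec) -> pd.DataFrame:
    """Deterministically construct an episode table matching ``spec``.

    The output uses the wrangled schema and passes
    :func:`careflow.episodes.wrangle_episodes` with zero drops.
    """
    spec.validate()
    rows: list[dict] = []
    client_no = 0

    def _emit(pattern: dict, n_clients: int) -> None:
        nonlocal client_no
        per_client = int(pattern.get("episodes_per_client", 1))
        pre, post = _solve_scores(pattern)
        individual, group = _resolve_sessions(pattern)
        total = individual + group
        cna = _resolve_missed(pattern, "cna")
        dna = _resolve_missed(pattern, "dna")
        discharge = pattern.get("discharge", NatureOfDischarge.GOALS_ACHIEVED.value)
        discharge = discharge.value if isinstance(discharge, NatureOfDischarge) else discharge
        gender = pattern.get("gender", "female")
        age = float(pattern.get("age", 41))
        for _ in range(n_clients):
            client_no += 1
            cid = f"F{client_no:05d}"
            for k in range(per_client):
                first = _FIXTURE_EPOCH + timedelta(days=365 * k)
                last = first + timedelta(days=max(total - 1, 0) * 7)
                rows.append(
                    {
                        "client_id": cid,
                        "episode_index": k + 1,
                        "gender": gender,
                        "age": age,
                        "first_date": pd.Timestamp(first),
                        "last_date": pd.Timestamp(last),
                        "pre_score": pre,
                        "post_score": post,
                        "individual_sessions": individual,
                        "group_sessions": group,
                        "total_sessions": total,
                        "cna_count": cna,
                        "dna_count": dna,
                        "discharge": discharge,
                    }
                )

    used = 0
    for pattern, count in spec.strata:
        _emit(pattern, count)
        used += count * int(pattern.get("episodes_per_client", 1))
    remaining = spec.total - used
    if remaining:
        if int(spec.filler.get("episodes_per_client", 1)) != 1:
            raise ValueError("filler pattern must use one episode per client")
        _emit(spec.filler, remaining)
    df = pd.DataFrame(rows, columns=EPISODE_COLUMNS)
    if len(df) == 0:
        df = pd.DataFrame(columns=EPISODE_COLUMNS)
    return df


def with_seed(config: GeneratorConfig, seed: int) -> GeneratorConfig:
    """Copy of ``config`` with a different seed."""
    return replace(config, seed=seed)
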