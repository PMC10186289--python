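"""Therapy-episode domain model: severity bands, reliable-change categories,
attendance bins and the row-filtering ("wrangling") step.

An *episode* is one client's journey through a psychological-therapies
service, from first to last session.  Psychological distress is measured on
the CORE-10 scale (0-40 points); scores are classified into six ordered
severity bands, and pre/post score differences into four reliable-change
categories using the +/-6-point Reliable Change Index threshold.

Episode tables are plain :class:`pandas.DataFrame` objects with the column
schema in :data:`EPISODE_COLUMNS`; every function in this package accepts
and returns that schema.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SeverityBand",
    "ChangeCategory",
    "NatureOfDischarge",
    "SessionMix",
    "SCORE_MIN",
    "SCORE_MAX",
    "CLINICAL_CUTOFF",
    "RCI_THRESHOLD",
    "BAND_LOWER_EDGES",
    "SESSION_BIN_LABELS",
    "MISSED_BIN_LABELS",
    "RAW_COLUMNS",
    "EPISODE_COLUMNS",
    "band_of_score",
    "change_category",
    "bin_total_sessions",
    "bin_missed",
    "below_clinical_cutoff",
    "classify",
    "wrangle_episodes",
    "DropReport",
]

SCORE_MIN = 0.0
SCORE_MAX = 40.0

#: Clinical cut-off on the CORE-10 scale: scores strictly below 10 indicate
#: sub-clinical psychological distress (the healthy and low bands).
CLINICAL_CUTOFF = 10.0

#: Reliable Change Index threshold on the CORE-10 scale: a pre-to-post
#: change of 6 or more points is classified as significant.
RCI_THRESHOLD = 6.0


class SeverityBand(str, enum.Enum):
    """Six ordered CORE severity bands, healthy (lowest) through severe."""

    HEALTHY = "healthy"
    LOW = "low"
    MILD = "mild"
    MODERATE = "moderate"
    MODERATELY_SEVERE = "moderately_severe"
    SEVERE = "severe"

    @property
    def rank(self) -> int:
        return _BAND_ORDER.index(self)

    def __lt__(self, other: "SeverityBand") -> bool:  # type: ignore[override]
        if not isinstance(other, SeverityBand):
            return NotImplemented
        return self.rank < other.rank


_BAND_ORDER = [
    SeverityBand.HEALTHY,
    SeverityBand.LOW,
    SeverityBand.MILD,
    SeverityBand.MODERATE,
    SeverityBand.MODERATELY_SEVERE,
    SeverityBand.SEVERE,
]

#: Lower edges of the six bands.  Band *i* covers ``[edge[i], edge[i+1])``
#: with the top band closed at 40: healthy [0,6), low [6,10), mild [10,15),
#: moderate [15,20), moderately severe [20,25), severe [25,40].
BAND_LOWER_EDGES = np.array([0.0, 6.0, 10.0, 15.0, 20.0, 25.0])


class ChangeCategory(str, enum.Enum):
    """Reliable-change classification of the pre-to-post score difference."""

    SIGNIFICANT_IMPROVEMENT = "significant_improvement"
    NONSIGNIFICANT_IMPROVEMENT = "nonsignificant_improvement"
    SIGNIFICANT_DETERIORATION = "significant_deterioration"
    NONSIGNIFICANT_DETERIORATION = "nonsignificant_deterioration"


class NatureOfDischarge(str, enum.Enum):
    """Clinician-assessed outcome at the end of the episode."""

    GOALS_ACHIEVED = "goals_achieved"
    GOALS_PARTIALLY_ACHIEVED = "goals_partially_achieved"
    NO_CHANGE = "no_change"
    DROPPED_OUT = "dropped_out"


class SessionMix(str, enum.Enum):
    """Whether an episode consisted of individual, group or mixed sessions."""

    INDIVIDUAL_ONLY = "individual_only"
    GROUP_ONLY = "group_only"
    MIXED = "mixed"
    NO_SESSIONS = "no_sessions"


#: Session-count bins tied to stepped-care intervention durations; "<2"
#: collects the out-of-range episodes with fewer than two sessions.
SESSION_BIN_LABELS = ["<2", "2-7", "8-15", "16-20", ">20"]

#: Missed-appointment (CNA / DNA) bins: singleton 0-3 plus an open "4+".
MISSED_BIN_LABELS = ["0", "1", "2", "3", "4+"]

#: Columns expected in a raw episode CSV.  ``total_sessions`` is optional
#: on input and recomputed during wrangling.
RAW_COLUMNS = [
    "client_id",
    "gender",
    "age",
    "first_date",
    "last_date",
    "pre_score",
    "post_score",
    "individual_sessions",
    "group_sessions",
    "cna_count",
    "dna_count",
    "discharge",
]

#: Canonical column order of a wrangled episode table.
EPISODE_COLUMNS = [
    "client_id",
    "episode_index",
    "gender",
    "age",
    "first_date",
    "last_date",
    "pre_score",
    "post_score",
    "individual_sessions",
    "group_sessions",
    "total_sessions",
    "cna_count",
    "dna_count",
    "discharge",
]

GENDERS = ["male", "female"]


def _maybe_item(x, scalar: bool):
    """Collapse to a Python scalar when the input was scalar."""
    if not scalar:
        return x
    return x.item() if isinstance(x, np.ndarray) else x


def _check_scores(score: np.ndarray, name: str = "score") -> np.ndarray:
    arr = np.asarray(score, dtype=float)
    bad = ~np.isfinite(arr) | (arr < SCORE_MIN) | (arr > SCORE_MAX)
    if np.any(bad):
        offender = arr[bad].flat[0]
        raise ValueError(
            f"{name} must be a finite CORE-10 value in [0, 40]; got {offender!r}"
        )
    return arr


def band_of_score(score):
    """Map a CORE-10 score to its severity band.

    Bands are half-open ``[lo, hi)`` with the top band closed at 40.
    Accepts a scalar or an array; returns a :class:`SeverityBand` or an
    object array of bands respectively.
    """
    scalar = np.isscalar(score) or np.ndim(score) == 0
    arr = _check_scores(score)
    idx = np.searchsorted(BAND_LOWER_EDGES[1:], arr, side="right")
    bands = np.array(_BAND_ORDER, dtype=object)[idx]
    return _maybe_item(bands, scalar)


def change_category(pre, post):
    """Classify the pre-to-post score difference by the +/-6-point RCI.

    Let ``d = post - pre``: ``d <= -6`` is significant improvement,
    ``-6 < d <= 0`` non-significant improvement (zero change counts as an
    improvement of zero points), ``0 < d < 6`` non-significant
    deterioration and ``d >= 6`` significant deterioration.
    """
    scalar = np.isscalar(pre) or np.ndim(pre) == 0
    pre_a = _check_scores(pre, "pre")
    post_a = _check_scores(post, "post")
    d = post_a - pre_a
    out = np.empty(d.shape, dtype=object)
    out[d <= -RCI_THRESHOLD] = ChangeCategory.SIGNIFICANT_IMPROVEMENT
    out[(d > -RCI_THRESHOLD) & (d <= 0)] = ChangeCategory.NONSIGNIFICANT_IMPROVEMENT
    out[(d > 0) & (d < RCI_THRESHOLD)] = ChangeCategory.NONSIGNIFICANT_DETERIORATION
    out[d >= RCI_THRESHOLD] = ChangeCategory.SIGNIFICANT_DETERIORATION
    return _maybe_item(out, scalar)


def _check_counts(n, name: str) -> np.ndarray:
    arr = np.asarray(n)
    if np.any(arr < 0):
        raise ValueError(f"{name} must be non-negative; got {arr[arr < 0].flat[0]!r}")
    return arr


def bin_total_sessions(n):
    """Bin a total session count: <2, 2-7, 8-15, 16-20, >20."""
    scalar = np.isscalar(n) or np.ndim(n) == 0
    arr = _check_counts(n, "session count")
    idx = np.searchsorted([2, 8, 16, 21], arr, side="right")
    labels = np.array(SESSION_BIN_LABELS, dtype=object)[idx]
    return _maybe_item(labels, scalar)


def bin_missed(n):
    """Bin a missed-appointment (CNA or DNA) count: 0, 1, 2, 3, 4+."""
    scalar = np.isscalar(n) or np.ndim(n) == 0
    arr = _check_counts(n, "missed-appointment count")
    idx = np.minimum(arr, 4).astype(int)
    labels = np.array(MISSED_BIN_LABELS, dtype=object)[idx]
    return _maybe_item(labels, scalar)


def below_clinical_cutoff(score):
    """True when the score falls below the clinical cut-off of 10 points.

    Equivalent to the band being healthy or low.
    """
    scalar = np.isscalar(score) or np.ndim(score) == 0
    arr = _check_scores(score)
    out = arr < CLINICAL_CUTOFF
    return bool(out) if scalar else out


def session_mix(individual: np.ndarray, group: np.ndarray) -> np.ndarray:
    """Label episodes individual-only / group-only / mixed / no-sessions.

    Returns an object array of :class:`SessionMix` *values* (strings).
    """
    ind = np.asarray(individual)
    grp = np.asarray(group)
    out = np.full(ind.shape, SessionMix.NO_SESSIONS.value, dtype=object)
    out[(ind > 0) & (grp == 0)] = SessionMix.INDIVIDUAL_ONLY.value
    out[(ind == 0) & (grp > 0)] = SessionMix.GROUP_ONLY.value
    out[(ind > 0) & (grp > 0)] = SessionMix.MIXED.value
    return out


def classify(episodes: pd.DataFrame) -> pd.DataFrame:
    """Add derived categorical columns to a wrangled episode table.

    Adds ``pre_band``, ``post_band``, ``change_category``, ``sessions_bin``,
    ``cna_bin``, ``dna_bin``, ``session_mix`` and ``below_cutoff_pre``
    (enum *values* as strings, so the frame stays CSV-friendly).
    """
    out = episodes.copy()
    if len(out) == 0:
        for col in ("pre_band", "post_band", "change_category", "sessions_bin",
                    "cna_bin", "dna_bin", "session_mix"):
            out[col] = pd.Series([], dtype=object)
        out["below_cutoff_pre"] = pd.Series([], dtype=bool)
        return out
    pre = out["pre_score"].to_numpy(dtype=float)
    post = out["post_score"].to_numpy(dtype=float)
    out["pre_band"] = [b.value for b in band_of_score(pre)]
    out["post_band"] = [b.value for b in band_of_score(post)]
    out["change_category"] = [c.value for c in change_category(pre, post)]
    out["sessions_bin"] = bin_total_sessions(out["total_sessions"].to_numpy())
    out["cna_bin"] = bin_missed(out["cna_count"].to_numpy())
    out["dna_bin"] = bin_missed(out["dna_count"].to_numpy())
    out["session_mix"] = session_mix(
        out["individual_sessions"].to_numpy(), out["group_sessions"].to_numpy()
    )
    out["below_cutoff_pre"] = below_clinical_cutoff(pre)
    return out


@dataclass
class DropReport:
    """Accounting of rows removed (and anomalies flagged) during wrangling.

    ``missing`` counts, per column, the rows whose value was absent,
    unparseable or outside the column's domain; a row failing on several
    columns is counted under each, but only once in ``n_dropped``.
    """

    n_input: int = 0
    n_kept: int = 0
    n_dropped: int = 0
    missing: dict = field(default_factory=dict)
    flags: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_kept": self.n_kept,
            "n_dropped": self.n_dropped,
            "missing": dict(self.missing),
            "flags": dict(self.flags),
        }


_ENUM_DOMAINS = {
    "gender": set(GENDERS),
    "discharge": {d.value for d in NatureOfDischarge},
}
_COUNT_COLUMNS = ["individual_sessions", "group_sessions", "cna_count", "dna_count"]
_SCORE_COLUMNS = ["pre_score", "post_score"]
_DATE_COLUMNS = ["first_date", "last_date"]


def wrangle_episodes(raw: pd.DataFrame) -> tuple[pd.DataFrame, DropReport]:
    """Filter a raw episode table down to complete, valid rows.

    Rows with a missing, unparseable or out-of-domain value in any required
    column are dropped and tallied per column.  ``total_sessions`` is
    recomputed as individual + group sessions, and ``episode_index`` is
    assigned per client in ascending ``first_date`` order (ties broken by
    ``last_date``, then input order).

    Parameters
    ----------
    raw : pandas.DataFrame
        Table with the :data:`RAW_COLUMNS` schema; dates as ISO-8601 text
        or datetimes.

    Returns
    -------
    (episodes, report)
        The wrangled table with :data:`EPISODE_COLUMNS` and a
        :class:`DropReport`.

    Raises
    ------
    ValueError
        If a required column is absent from ``raw``.
    """
    absent = [c for c in RAW_COLUMNS if c not in raw.columns]
    if absent:
        raise ValueError(f"raw episode table is missing required column(s): {absent}")

    report = DropReport(n_input=len(raw))
    df = raw.copy().reset_index(drop=True)
    bad = pd.Series(False, index=df.index)

    def _flag(col: str, mask: pd.Series) -> None:
        nonlocal bad
        n = int(mask.sum())
        if n:
            report.missing[col] = report.missing.get(col, 0) + n
            bad |= mask

    for col in _DATE_COLUMNS:
        parsed = pd.to_datetime(df[col], errors="coerce", format="ISO8601")
        _flag(col, parsed.isna())
        df[col] = parsed
    for col in _SCORE_COLUMNS:
        vals = pd.to_numeric(df[col], errors="coerce")
        _flag(col, vals.isna() | (vals < SCORE_MIN) | (vals > SCORE_MAX))
        df[col] = vals
    for col in _COUNT_COLUMNS:
        vals = pd.to_numeric(df[col], errors="coerce")
        _flag(col, vals.isna() | (vals < 0) | (vals % 1 != 0))
        df[col] = vals
    age = pd.to_numeric(df["age"], errors="coerce")
    _flag("age", age.isna())
    df["age"] = age
    _flag("client_id", df["client_id"].isna())
    for col, domain in _ENUM_DOMAINS.items():
        vals = df[col].astype("string").str.strip().str.lower()
        _flag(col, ~vals.isin(domain))
        df[col] = vals
    # Date order: a last session before the first is unparseable history.
    order_bad = (~bad) & (df["last_date"] < df["first_date"])
    _flag("last_date", order_bad)

    kept = df.loc[~bad].copy()
    report.n_dropped = int(bad.sum())
    report.n_kept = len(kept)

    underage = int((kept["age"] < 18).sum())
    if underage:
        report.flags["age_below_18"] = underage

    kept["total_sessions"] = (
        kept["individual_sessions"].astype(int) + kept["group_sessions"].astype(int)
    )
    for col in _COUNT_COLUMNS:
        kept[col] = kept[col].astype(int)
    kept["age"] = kept["age"].astype(float)

    # Stable per-client episode numbering by date.
    kept["_order"] = np.arange(len(kept))
    kept = kept.sort_values(
        ["client_id", "first_date", "last_date", "_order"], kind="stable"
    )
    kept["episode_index"] = kept.groupby("client_id").cumcount() + 1
    kept = kept.sort_values("_order", kind="stable").drop(columns="_order")
    kept = kept.reset_index(drop=True)[EPISODE_COLUMNS]
    return kept, report
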