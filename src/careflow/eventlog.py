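"""Episode tables → process-mining event logs, and CSV/XES round-tripping.

Each therapy episode becomes one *case*.  An ordered list of *aspects*
(pre-therapy band, session-count bin, DNA/CNA bin, post band, change
category, discharge ...) selects which categorical features become
activities, each stamped with a lifecycle stage:

* ``first``  — events at the first therapy session (the pre-therapy band),
  timestamped with the episode's first date;
* ``during`` — events during therapy (attendance aspects), timestamped
  5 days after the first session;
* ``last``   — events at the final session (outcome aspects), timestamped
  with the episode's last date.
"""

from __future__ import annotations

import warnings
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field, replace
from pathlib import Path

import pandas as pd

from .episodes import classify

__all__ = [
    "Aspect",
    "ASPECTS",
    "EventLog",
    "LIFECYCLES",
    "DURING_OFFSET_DAYS",
    "build_event_log",
    "write_log",
    "read_log",
]

LIFECYCLES = ["first", "during", "last"]
_LIFECYCLE_RANK = {s: i for i, s in enumerate(LIFECYCLES)}

#: Days added to the first-session date to timestamp during-therapy events.
DURING_OFFSET_DAYS = 5

EVENT_COLUMNS = ["case_id", "activity", "activity_instance", "lifecycle", "timestamp"]

_BAND_DISPLAY = {
    "healthy": "Healthy",
    "low": "Low",
    "mild": "Mild",
    "moderate": "Moderate",
    "moderately_severe": "Moderately severe",
    "severe": "Severe",
}
_CHANGE_DISPLAY = {
    "significant_improvement": "Improvement significant",
    "nonsignificant_improvement": "Improvement non-significant",
    "significant_deterioration": "Deterioration significant",
    "nonsignificant_deterioration": "Deterioration non-significant",
}
_DISCHARGE_DISPLAY = {
    "goals_achieved": "Goals achieved",
    "goals_partially_achieved": "Goals partially achieved",
    "no_change": "No change",
    "dropped_out": "Dropped out",
}
_MIX_DISPLAY = {
    "individual_only": "Individual sessions only",
    "group_only": "Group sessions only",
    "mixed": "Mixed individual and group sessions",
    "no_sessions": "No sessions attended",
}


@dataclass(frozen=True)
class Aspect:
    """A categorical feature of an episode exposed as an activity.

    ``column`` is the classified-table column holding the category value and
    ``labels`` maps category values to activity label text (override to
    re-skin maps).
    """

    name: str
    stage: str
    column: str
    labels: dict = field(default_factory=dict)
    template: str = "{}"

    def label(self, value) -> str:
        return self.labels.get(value, self.template.format(value))

    def with_labels(self, labels: dict) -> "Aspect":
        return replace(self, labels={**self.labels, **labels})


ASPECTS = {
    a.name: a
    for a in [
        Aspect("pre_band", "first", "pre_band",
               {k: f"Pre - {v}" for k, v in _BAND_DISPLAY.items()}),
        Aspect("total_sessions_bin", "during", "sessions_bin",
               template="{} total sessions"),
        Aspect("session_mix", "during", "session_mix", dict(_MIX_DISPLAY)),
        Aspect("dna_bin", "during", "dna_bin", template="{} DNA"),
        Aspect("cna_bin", "during", "cna_bin", template="{} CNA"),
        Aspect("post_band", "last", "post_band",
               {k: f"Post - {v}" for k, v in _BAND_DISPLAY.items()}),
        Aspect("change_category", "last", "change_category", dict(_CHANGE_DISPLAY)),
        Aspect("discharge", "last", "discharge", dict(_DISCHARGE_DISPLAY)),
    ]
}


@dataclass
class EventLog:
    """An ordered event table plus the aspect sequence that produced it.

    ``events`` columns: case_id, activity, activity_instance, lifecycle,
    timestamp.  ``(case_id, activity_instance)`` is unique, and within a
    case timestamps are non-decreasing in lifecycle order.
    """

    events: pd.DataFrame
    aspect_sequence: tuple = ()

    @property
    def n_cases(self) -> int:
        return self.events["case_id"].nunique()

    def traces(self) -> "pd.Series":
        """Activity sequence per case: Series case_id → tuple of labels.

        Events are ordered by lifecycle stage, then by activity instance
        (which encodes the aspect position within the stage).
        """
        ev = self.events.copy()
        ev["_rank"] = ev["lifecycle"].map(_LIFECYCLE_RANK)
        ev = ev.sort_values(["case_id", "_rank", "activity_instance"], kind="stable")
        return ev.groupby("case_id", sort=True)["activity"].agg(tuple)

    def __eq__(self, other) -> bool:
        """Order-insensitive equality on the events; the aspect sequence is
        carrier metadata (the CSV dialect cannot store it) and not compared."""
        if not isinstance(other, EventLog):
            return NotImplemented
        a = self.events.sort_values(["case_id", "activity_instance"]).reset_index(drop=True)
        b = other.events.sort_values(["case_id", "activity_instance"]).reset_index(drop=True)
        return a[EVENT_COLUMNS].equals(b[EVENT_COLUMNS])


def _resolve_aspects(aspects) -> list[Aspect]:
    resolved = []
    for a in aspects:
        if isinstance(a, Aspect):
            resolved.append(a)
        elif a in ASPECTS:
            resolved.append(ASPECTS[a])
        else:
            raise ValueError(f"unknown aspect {a!r}; known: {sorted(ASPECTS)}")
    if not resolved:
        raise ValueError("aspect list must be non-empty")
    ranks = [_LIFECYCLE_RANK[a.stage] for a in resolved]
    if ranks != sorted(ranks):
        raise ValueError(
            "aspects must be ordered first -> during -> last; got stages "
            f"{[a.stage for a in resolved]}"
        )
    return resolved


def build_event_log(episodes: pd.DataFrame, aspects) -> EventLog:
    """Convert an episode table into an event log for the given aspects.

    ``episodes`` may be a wrangled or an already-classified table; one event
    is emitted per episode per aspect.  Episodes shorter than the
    during-therapy offset clamp their during events to the last date so the
    within-case time ordering holds (a warning is issued).
    """
    resolved = _resolve_aspects(aspects)
    if len(episodes) and "pre_band" not in episodes.columns:
        episodes = classify(episodes)
    if len(episodes) == 0:
        return EventLog(
            pd.DataFrame(columns=EVENT_COLUMNS),
            tuple(a.name for a in resolved),
        )

    case_ids = (
        episodes["client_id"].astype(str)
        + "-"
        + episodes["episode_index"].astype(int).astype(str)
    )
    first = pd.to_datetime(episodes["first_date"])
    last = pd.to_datetime(episodes["last_date"])
    during = first + pd.Timedelta(days=DURING_OFFSET_DAYS)
    clamped = during > last
    if clamped.any() and any(a.stage == "during" for a in resolved):
        warnings.warn(
            f"{int(clamped.sum())} episode(s) shorter than {DURING_OFFSET_DAYS} days: "
            "during-therapy events clamped to the last session date",
            stacklevel=2,
        )
    during = during.where(~clamped, last)
    stamps = {"first": first, "during": during, "last": last}

    frames = []
    for k, aspect in enumerate(resolved):
        values = episodes[aspect.column]
        frames.append(
            pd.DataFrame(
                {
                    "case_id": case_ids,
                    "activity": [aspect.label(v) for v in values],
                    "activity_instance": case_ids + f":{k:02d}",
                    "lifecycle": aspect.stage,
                    "timestamp": stamps[aspect.stage],
                    "_case_order": range(len(episodes)),
                    "_pos": k,
                }
            )
        )
    events = (
        pd.concat(frames, ignore_index=True)
        .sort_values(["_case_order", "_pos"], kind="stable")
        .drop(columns=["_case_order", "_pos"])
        .reset_index(drop=True)
    )
    return EventLog(events, tuple(a.name for a in resolved))


# ---------------------------------------------------------------------------
# Serialization

_XES_EXTENSIONS = [
    ("Concept", "concept", "http://www.xes-standard.org/concept.xesext"),
    ("Lifecycle", "lifecycle", "http://www.xes-standard.org/lifecycle.xesext"),
    ("Time", "time", "http://www.xes-standard.org/time.xesext"),
]


def write_log(log: EventLog, path, format: str = "csv") -> None:
    """Write an event log as CSV (five columns, ISO dates) or XES 2.0."""
    path = Path(path)
    if format == "csv":
        out = log.events.copy()
        out["timestamp"] = pd.to_datetime(out["timestamp"]).dt.strftime("%Y-%m-%d")
        out.to_csv(path, index=False)
    elif format == "xes":
        root = ET.Element("log", {"xes.version": "2.0", "xes.features": "nested-attributes"})
        for name, prefix, uri in _XES_EXTENSIONS:
            ET.SubElement(root, "extension", {"name": name, "prefix": prefix, "uri": uri})
        glob = ET.SubElement(root, "global", {"scope": "trace"})
        ET.SubElement(glob, "string", {"key": "concept:name", "value": ""})
        ET.SubElement(root, "string", {
            "key": "aspect_sequence", "value": ",".join(log.aspect_sequence)
        })
        for case_id, case_events in log.events.groupby("case_id", sort=True):
            trace = ET.SubElement(root, "trace")
            ET.SubElement(trace, "string", {"key": "concept:name", "value": str(case_id)})
            for _, ev in case_events.iterrows():
                e = ET.SubElement(trace, "event")
                ET.SubElement(e, "string", {"key": "concept:name", "value": ev["activity"]})
                ET.SubElement(e, "string", {
                    "key": "concept:instance", "value": ev["activity_instance"]
                })
                ET.SubElement(e, "string", {
                    "key": "lifecycle:transition", "value": ev["lifecycle"]
                })
                stamp = pd.Timestamp(ev["timestamp"]).strftime("%Y-%m-%dT%H:%M:%S")
                ET.SubElement(e, "date", {"key": "time:timestamp", "value": stamp})
        ET.indent(root)
        ET.ElementTree(root).write(path, xml_declaration=True, encoding="unicode")
    else:
        raise ValueError(f"unknown log format {format!r}; use 'csv' or 'xes'")


def _xes_attr(elem, key: str, context: str) -> str:
    for child in elem:
        if child.get("key") == key:
            return child.get("value")
    raise ValueError(f"XES parse error: missing {key!r} on {context}")


def read_log(path, format: str = "csv") -> EventLog:
    """Read an event log written by :func:`write_log`."""
    path = Path(path)
    if format == "csv":
        df = pd.read_csv(path, dtype={"case_id": str})
        missing = [c for c in EVENT_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"event CSV {path} is missing column(s) {missing}")
        df["timestamp"] = pd.to_datetime(df["timestamp"], format="ISO8601")
        return EventLog(df[EVENT_COLUMNS], ())
    if format == "xes":
        root = ET.parse(path).getroot()
        aspect_seq: tuple = ()
        for child in root:
            if child.tag == "string" and child.get("key") == "aspect_sequence":
                value = child.get("value", "")
                aspect_seq = tuple(v for v in value.split(",") if v)
        rows = []
        for t_idx, trace in enumerate(root.iter("trace")):
            case_id = _xes_attr(trace, "concept:name", f"trace #{t_idx}")
            for e_idx, ev in enumerate(trace.iter("event")):
                ctx = f"event #{e_idx} of trace {case_id!r}"
                rows.append(
                    {
                        "case_id": case_id,
                        "activity": _xes_attr(ev, "concept:name", ctx),
                        "activity_instance": _xes_attr(ev, "concept:instance", ctx),
                        "lifecycle": _xes_attr(ev, "lifecycle:transition", ctx),
                        "timestamp": pd.Timestamp(_xes_attr(ev, "time:timestamp", ctx)),
                    }
                )
        return EventLog(pd.DataFrame(rows, columns=EVENT_COLUMNS), aspect_seq)
    raise ValueError(f"unknown log format {format!r}; use 'csv' or 'xes'")
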