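"""Trace-variant analysis and directly-follows process maps.

A *trace variant* is a distinct activity sequence with the number of cases
that followed it.  Process maps are directly-follows graphs (DFGs) counted
over whole variants: coverage filtering keeps the minimal prefix of the
most frequent variants whose cumulative case share reaches a threshold, so
a map annotated "90%" shows the pathways of (at least) 90% of cases.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field

import pandas as pd

from .eventlog import EventLog

__all__ = [
    "START",
    "END",
    "ProcessMap",
    "trace_variants",
    "filter_coverage",
    "rare_variants",
    "directly_follows_graph",
    "to_dot",
]

#: Pseudo-activities marking case entry and exit in a process map.
START = "__start__"
END = "__end__"


def trace_variants(log: EventLog) -> pd.DataFrame:
    """Tabulate distinct activity sequences.

    Returns a frame with columns ``activities`` (tuple), ``case_count`` and
    ``share``, sorted by descending count with lexicographic tie-break on
    the activity sequence.
    """
    traces = log.traces()
    counts = Counter(traces)
    rows = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    total = sum(counts.values())
    df = pd.DataFrame(
        {
            "activities": [r[0] for r in rows],
            "case_count": [r[1] for r in rows],
        }
    )
    df["share"] = df["case_count"] / total if total else 0.0
    return df


def filter_coverage(variants: pd.DataFrame, threshold: float) -> tuple[pd.DataFrame, float]:
    """Keep the minimal prefix of variants covering >= ``threshold`` of cases.

    ``variants`` must be sorted as produced by :func:`trace_variants`.
    Whole variants are kept (never partial cases), so the achieved coverage
    — returned alongside the filtered table — may exceed the threshold.
    """
    if not 0 < threshold <= 1:
        raise ValueError(f"coverage threshold must be in (0, 1]; got {threshold}")
    cum = variants["share"].cumsum()
    # minimal prefix whose cumulative share reaches the threshold
    reached = cum >= threshold - 1e-12
    if reached.any():
        k = int(reached.idxmax()) + 1
    else:
        k = len(variants)
    kept = variants.iloc[:k].reset_index(drop=True)
    achieved = float(kept["share"].sum())
    return kept, achieved


def rare_variants(variants: pd.DataFrame, max_share: float) -> pd.DataFrame:
    """Variants with share <= ``max_share``, least common first."""
    out = variants.loc[variants["share"] <= max_share + 1e-12]
    return out.sort_values(
        ["case_count", "activities"], kind="stable"
    ).reset_index(drop=True)


@dataclass
class ProcessMap:
    """Frequency-annotated directly-follows graph with start/end nodes.

    ``nodes`` maps activity → case count; ``edges`` maps (from, to) → count
    of cases where *to* directly follows *from* (including the start/end
    pseudo-nodes).  ``coverage`` is the fraction of all cases represented.
    """

    nodes: dict = field(default_factory=dict)
    edges: dict = field(default_factory=dict)
    n_cases_included: int = 0
    n_cases_total: int = 0
    coverage: float = 0.0

    def validate(self) -> None:
        """Check flow conservation at every interior node."""
        inbound: Counter = Counter()
        outbound: Counter = Counter()
        for (a, b), c in self.edges.items():
            outbound[a] += c
            inbound[b] += c
        for node, count in self.nodes.items():
            if inbound[node] != count or outbound[node] != count:
                raise AssertionError(
                    f"flow conservation violated at {node!r}: "
                    f"in={inbound[node]}, out={outbound[node]}, node={count}"
                )
        if outbound[START] != self.n_cases_included or inbound[END] != self.n_cases_included:
            raise AssertionError("start/end flow does not match included case count")

    def as_dict(self) -> dict:
        return {
            "nodes": {k: v for k, v in sorted(self.nodes.items())},
            "edges": [
                {"from": a, "to": b, "case_count": c}
                for (a, b), c in sorted(self.edges.items())
            ],
            "n_cases_included": self.n_cases_included,
            "n_cases_total": self.n_cases_total,
            "coverage": self.coverage,
        }

    def to_json(self) -> str:
        return json.dumps(self.as_dict(), indent=1)


def directly_follows_graph(log: EventLog, variants: pd.DataFrame | None = None) -> ProcessMap:
    """Count a DFG over the cases belonging to the included variants.

    ``variants`` defaults to all variants of the log; it must be non-empty
    and drawn from the log (an unknown activity sequence is an error).
    Counts are case counts: edge (a, b) is the number of included cases in
    which *b* directly follows *a*.
    """
    traces = log.traces()
    total = len(traces)
    all_counts = Counter(traces)
    if variants is None:
        variants = trace_variants(log)
    if len(variants) == 0:
        raise ValueError("cannot build a process map from an empty variant set")
    nodes: Counter = Counter()
    edges: Counter = Counter()
    included = 0
    for _, row in variants.iterrows():
        seq = tuple(row["activities"])
        count = all_counts.get(seq)
        if count is None:
            raise ValueError(f"variant {seq!r} does not occur in the log")
        included += count
        for act in seq:
            nodes[act] += count
        path = (START, *seq, END)
        for a, b in zip(path, path[1:]):
            edges[(a, b)] += count
    pmap = ProcessMap(
        nodes=dict(nodes),
        edges=dict(edges),
        n_cases_included=included,
        n_cases_total=total,
        coverage=included / total if total else 0.0,
    )
    pmap.validate()
    return pmap


def to_dot(pmap: ProcessMap, annotation: str = "both") -> str:
    """Render a process map as a deterministic Graphviz DOT digraph.

    ``annotation`` selects node/edge frequency text: ``absolute`` (case
    counts), ``relative`` (percentages of included cases, one decimal
    place) or ``both``.
    """
    if annotation not in {"absolute", "relative", "both"}:
        raise ValueError(f"unknown annotation {annotation!r}")
    denom = pmap.n_cases_included or 1

    def fmt(count: int) -> str:
        pct = 100.0 * count / denom
        if annotation == "absolute":
            return f"{count}"
        if annotation == "relative":
            return f"{pct:.1f}%"
        return f"{count} ({pct:.1f}%)"

    ids = {name: f"n{i}" for i, name in enumerate(sorted(pmap.nodes))}
    lines = [
        "digraph process_map {",
        "  rankdir=TB;",
        '  node [shape=box, style=rounded, fontname="Helvetica"];',
        f'  __start [shape=circle, label="start", style=filled, fillcolor="#c8e6c9"];',
        f'  __end [shape=doublecircle, label="end", style=filled, fillcolor="#ffcdd2"];',
    ]
    for name in sorted(pmap.nodes):
        lines.append(
            f'  {ids[name]} [label="{name}\\n{fmt(pmap.nodes[name])}"];'
        )
    for (a, b), c in sorted(pmap.edges.items()):
        src = "__start" if a == START else ids[a]
        dst = "__end" if b == END else ids[b]
        lines.append(f'  {src} -> {dst} [label="{fmt(c)}"];')
    lines.append("}")
    return "\n".join(lines) + "\n"


def variants_to_json(variants: pd.DataFrame) -> str:
    """JSON export of a variant table (activities, case_count, share)."""
    return json.dumps(
        [
            {
                "activities": list(row["activities"]),
                "case_count": int(row["case_count"]),
                "share": float(row["share"]),
            }
            for _, row in variants.iterrows()
        ],
        indent=1,
    )
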