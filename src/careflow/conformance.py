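"""Declarative conformance checking of event logs.

Five rule primitives over per-case activity sequences — starts_with,
ends_with, contains, absent and precedence — plus checking an event log
against an expected transition set (an idealised process map), reporting
every off-map directly-follows pair.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

from .discovery import END, START
from .eventlog import EventLog

__all__ = [
    "ConformanceRule",
    "RuleReport",
    "check_rule",
    "check_rules",
    "check_expectation_map",
    "rule_from_dict",
]

_RULE_KINDS = {"starts_with", "ends_with", "contains", "absent", "precedence"}


@dataclass(frozen=True)
class ConformanceRule:
    """A declarative behavioural rule.

    For ``precedence``, ``antecedent`` must occur somewhere earlier in the
    case than every occurrence of ``consequent``; the other kinds test the
    single ``subject`` activity.
    """

    kind: str
    subject: str = ""
    antecedent: str = ""
    consequent: str = ""

    def __post_init__(self) -> None:
        if self.kind not in _RULE_KINDS:
            raise ValueError(f"unknown rule kind {self.kind!r}; use one of {sorted(_RULE_KINDS)}")
        if self.kind == "precedence":
            if not self.antecedent or not self.consequent:
                raise ValueError("precedence rules need antecedent and consequent labels")
            if self.antecedent == self.consequent:
                raise ValueError("precedence antecedent and consequent must differ")
        elif not self.subject:
            raise ValueError(f"{self.kind} rule needs a non-empty subject label")

    def describe(self) -> str:
        if self.kind == "precedence":
            return f"precedence({self.antecedent!r} before {self.consequent!r})"
        return f"{self.kind}({self.subject!r})"

    def holds(self, trace: tuple) -> bool:
        if self.kind == "starts_with":
            return len(trace) > 0 and trace[0] == self.subject
        if self.kind == "ends_with":
            return len(trace) > 0 and trace[-1] == self.subject
        if self.kind == "contains":
            return self.subject in trace
        if self.kind == "absent":
            return self.subject not in trace
        seen_antecedent = False
        for act in trace:
            if act == self.consequent and not seen_antecedent:
                return False
            if act == self.antecedent:
                seen_antecedent = True
        return True


@dataclass
class RuleReport:
    """Aggregated outcome of one rule over a log."""

    rule: ConformanceRule
    conforming_cases: int = 0
    violating_cases: int = 0
    violating_case_ids: list = field(default_factory=list)

    @property
    def fraction_conforming(self) -> float:
        total = self.conforming_cases + self.violating_cases
        return self.conforming_cases / total if total else 1.0

    def as_dict(self) -> dict:
        return {
            "rule": self.rule.describe(),
            "conforming_cases": self.conforming_cases,
            "violating_cases": self.violating_cases,
            "violating_case_ids": list(self.violating_case_ids),
            "fraction_conforming": self.fraction_conforming,
        }


def check_rule(log: EventLog, rule: ConformanceRule) -> RuleReport:
    """Evaluate one rule per case and aggregate.

    A subject label never occurring anywhere in the log triggers a warning
    (likely a typo) but the rule is still evaluated.
    """
    traces = log.traces()
    vocabulary = {act for trace in traces for act in trace}
    referenced = (
        {rule.antecedent, rule.consequent} if rule.kind == "precedence" else {rule.subject}
    )
    unknown = referenced - vocabulary
    if unknown:
        warnings.warn(
            f"rule {rule.describe()} references label(s) never observed in the log: "
            f"{sorted(unknown)}",
            stacklevel=2,
        )
    report = RuleReport(rule=rule)
    for case_id, trace in traces.items():
        if rule.holds(trace):
            report.conforming_cases += 1
        else:
            report.violating_cases += 1
            report.violating_case_ids.append(case_id)
    return report


def check_rules(log: EventLog, rules) -> list[RuleReport]:
    return [check_rule(log, r) for r in rules]


def check_expectation_map(log: EventLog, expected: set) -> dict:
    """Compare observed directly-follows pairs with an expected transition set.

    ``expected`` contains (from, to) activity pairs and must include the
    start/end pseudo-transitions (:data:`START` / :data:`END`).  Returns a
    report listing every observed off-map transition with its case count
    and the fraction of fully on-map cases.
    """
    if not expected:
        raise ValueError("expected transition set must be non-empty")
    expected = {tuple(t) for t in expected}
    traces = log.traces()
    off_map: dict = {}
    clean_cases = 0
    for _case_id, trace in traces.items():
        path = (START, *trace, END)
        clean = True
        for pair in zip(path, path[1:]):
            if pair not in expected:
                off_map[pair] = off_map.get(pair, 0) + 1
                clean = False
        clean_cases += clean
    total = len(traces)
    return {
        "off_map_transitions": [
            {"from": a, "to": b, "case_count": c} for (a, b), c in sorted(off_map.items())
        ],
        "n_cases": total,
        "conforming_cases": clean_cases,
        "fraction_conforming": clean_cases / total if total else 1.0,
    }


def rule_from_dict(d: dict) -> ConformanceRule:
    """Build a rule from its YAML/JSON form: {kind, subject | antecedent+consequent}."""
    return ConformanceRule(
        kind=d.get("kind", ""),
        subject=d.get("subject", ""),
        antecedent=d.get("antecedent", ""),
        consequent=d.get("consequent", ""),
    )
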