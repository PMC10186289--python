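"""End-to-end Define-Measure-Analyse pipeline.

Wrangles (or generates) an episode table, classifies it, builds the
requested event logs, discovers coverage-filtered process maps with rare-
pathway listings and off-map transition reports, computes band summaries
and the nonparametric test battery, and writes everything plus a manifest
to an output directory.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import conformance as conf
from . import discovery, stats
from .episodes import classify, wrangle_episodes
from .eventlog import ASPECTS, EventLog, build_event_log
from .synth import GeneratorConfig, generate_episodes, with_seed

__all__ = [
    "DEFAULT_MAP_REQUESTS",
    "PipelineConfig",
    "PipelineError",
    "run_pipeline",
]

log = logging.getLogger("careflow")

#: The default map set: aspect sequence and coverage threshold per map,
#: mirroring the service analysis (band outcome, change and discharge maps
#: at 90%, the sessions map at 95%, DNA at 90% and CNA at 80%).
DEFAULT_MAP_REQUESTS = [
    (("pre_band", "post_band"), 0.90),
    (("pre_band", "change_category"), 0.90),
    (("pre_band", "discharge"), 0.90),
    (("pre_band", "total_sessions_bin", "change_category"), 0.95),
    (("pre_band", "dna_bin", "change_category"), 0.90),
    (("pre_band", "cna_bin", "change_category"), 0.80),
]

_KW_VARIABLES = ["age", "total_sessions", "individual_sessions",
                 "group_sessions", "cna_count", "dna_count", "post_score"]


class PipelineError(RuntimeError):
    """A stage failure, tagged with the stage name; earlier outputs remain."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.__cause__ = cause


@dataclass
class PipelineConfig:
    """Everything :func:`run_pipeline` needs.

    ``source`` is an episode CSV path, a :class:`GeneratorConfig`, or an
    already-wrangled DataFrame.  ``map_requests`` pairs an aspect-name
    sequence with a coverage threshold in (0, 1].
    """

    source: object
    out_dir: Path = Path("careflow_out")
    map_requests: list = field(default_factory=lambda: list(DEFAULT_MAP_REQUESTS))
    rules: list = field(default_factory=list)
    rare_max_share: float = 0.01
    annotation: str = "both"
    seed: int | None = None

    def validate(self) -> None:
        if not self.map_requests:
            raise ValueError("at least one map request is required")
        for aspects, threshold in self.map_requests:
            if not 0 < threshold <= 1:
                raise ValueError(f"coverage threshold {threshold} outside (0, 1]")
            unknown = [a for a in aspects if a not in ASPECTS]
            if unknown:
                raise ValueError(f"unknown aspect(s) {unknown}; known: {sorted(ASPECTS)}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        doc = yaml.safe_load(Path(path).read_text())
        source: object
        if "csv" in doc.get("input", {}):
            source = Path(doc["input"]["csv"])
        else:
            source = GeneratorConfig(**doc.get("input", {}).get("generate", {}))
        maps = [
            (tuple(m["aspects"]), float(m.get("coverage", 0.9)))
            for m in doc.get("maps", [])
        ] or list(DEFAULT_MAP_REQUESTS)
        rules = [conf.rule_from_dict(r) for r in doc.get("rules", [])]
        return cls(
            source=source,
            out_dir=Path(doc.get("out_dir", "careflow_out")),
            map_requests=maps,
            rules=rules,
            rare_max_share=float(doc.get("rare_max_share", 0.01)),
            annotation=doc.get("annotation", "both"),
            seed=doc.get("seed"),
        )


def _write_json(path: Path, obj) -> None:
    path.write_text(json.dumps(obj, indent=1, sort_keys=True) + "\n")


def _episodes_from_source(config: PipelineConfig, manifest: dict, out: Path) -> pd.DataFrame:
    if isinstance(config.source, GeneratorConfig):
        gen = config.source
        if config.seed is not None:
            gen = with_seed(gen, config.seed)
        log.info("generating %d clients (seed %s)", gen.n_clients, gen.seed)
        episodes = generate_episodes(gen)
        manifest["source"] = {"kind": "generated", "n_clients": gen.n_clients,
                              "seed": gen.seed}
    elif isinstance(config.source, pd.DataFrame):
        episodes = config.source
        manifest["source"] = {"kind": "dataframe"}
    else:
        raw = pd.read_csv(config.source)
        episodes, report = wrangle_episodes(raw)
        _write_json(out / "wrangle_report.json", report.as_dict())
        manifest["outputs"].append("wrangle_report.json")
        manifest["source"] = {"kind": "csv", "path": str(config.source),
                              "wrangle": report.as_dict()}
        log.info("wrangled %d rows -> %d episodes", report.n_input, report.n_kept)
    return episodes


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full pipeline; returns the manifest (also written to disk)."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"outputs": [], "maps": {}, "n_episodes": None}

    stage = "load"
    try:
        episodes = _episodes_from_source(config, manifest, out)
        stage = "classify"
        table = classify(episodes)
        manifest["n_episodes"] = len(table)
        csv_out = table.copy()
        for col in ("first_date", "last_date"):
            csv_out[col] = pd.to_datetime(csv_out[col]).dt.strftime("%Y-%m-%d")
        csv_out.to_csv(out / "episodes.csv", index=False)
        manifest["outputs"].append("episodes.csv")

        stage = "mine"
        for aspects, threshold in config.map_requests:
            name = "-".join(aspects)
            elog = build_event_log(table, aspects)
            variants = discovery.trace_variants(elog)
            kept, achieved = discovery.filter_coverage(variants, threshold)
            pmap = discovery.directly_follows_graph(elog, kept)
            rare = discovery.rare_variants(variants, config.rare_max_share)
            off_map = conf.check_expectation_map(elog, set(pmap.edges))

            vpath = out / f"variants_{name}.csv"
            v = variants.copy()
            v["activities"] = [" > ".join(a) for a in v["activities"]]
            v.to_csv(vpath, index=False)
            (out / f"map_{name}.dot").write_text(
                discovery.to_dot(pmap, config.annotation)
            )
            _write_json(out / f"map_{name}.json", pmap.as_dict())
            _write_json(
                out / f"rare_{name}.json",
                json.loads(discovery.variants_to_json(rare)),
            )
            _write_json(out / f"offmap_{name}.json", off_map)
            manifest["outputs"] += [
                f"variants_{name}.csv", f"map_{name}.dot",
                f"map_{name}.json", f"rare_{name}.json", f"offmap_{name}.json",
            ]
            manifest["maps"][name] = {
                "aspects": list(aspects),
                "threshold": threshold,
                "coverage": achieved,
                "n_variants_total": len(variants),
                "n_variants_kept": len(kept),
                "n_cases": pmap.n_cases_total,
                "fraction_on_map": off_map["fraction_conforming"],
            }
            log.info("map %s: %d/%d variants, coverage %.3f",
                     name, len(kept), len(variants), achieved)

        stage = "stats"
        summary = stats.summarize_by_band(table)
        summary.to_csv(out / "summary_bands.csv", index=False)
        manifest["outputs"].append("summary_bands.csv")

        tests: dict = {"alpha": stats.ALPHA, "shapiro_wilk": [], "kruskal_wallis": [],
                       "pairwise_wilcoxon": [], "chi_squared": None,
                       "pairwise_chi_squared": [], "correlation": []}
        bands = table["pre_band"]
        for var in _KW_VARIABLES:
            tests["shapiro_wilk"].append(
                {"variable": var, **stats.shapiro_wilk(table[var]).as_dict()}
            )
            tests["kruskal_wallis"].append(
                {"variable": var, **stats.kruskal_wallis(table[var], bands).as_dict()}
            )
            tests["pairwise_wilcoxon"].append(
                {
                    "variable": var,
                    "results": [
                        r.as_dict()
                        for r in stats.pairwise_wilcoxon_bonferroni(table[var], bands)
                    ],
                }
            )
        gender_band = pd.crosstab(table["gender"], table["pre_band"])
        tests["chi_squared"] = stats.chi_squared_independence(gender_band).as_dict()
        tests["pairwise_chi_squared"] = [
            r.as_dict() for r in stats.pairwise_chi_squared_bonferroni(gender_band)
        ]
        tests["correlation"] = [
            stats.pearson_r(table["pre_score"], table["total_sessions"]).as_dict(),
            stats.spearman_r(table["pre_score"], table["total_sessions"]).as_dict(),
        ]
        _write_json(out / "tests.json", tests)
        manifest["outputs"].append("tests.json")

        _write_json(out / "repeat_use.json", stats.repeat_use_summary(table))
        manifest["outputs"].append("repeat_use.json")

        stage = "conform"
        if config.rules:
            full_log = build_event_log(table, config.map_requests[0][0])
            reports = [r.as_dict() for r in conf.check_rules(full_log, config.rules)]
            _write_json(out / "conformance.json", reports)
            manifest["outputs"].append("conformance.json")
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001 - tag and re-raise with stage
        raise PipelineError(stage, exc) from exc

    manifest["outputs"].sort()
    _write_json(out / "manifest.json", manifest)
    return manifest
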