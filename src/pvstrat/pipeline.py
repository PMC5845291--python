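"""End-to-end pipeline: ingest -> detect -> compare -> decide.

Every stage is a pure function of (inputs, configuration), so a rerun with
the same files and settings produces byte-identical artifacts.  Counts in and
out of each filtering step are logged so the cleaning funnel is auditable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path

import yaml

from . import report_ingest, reference_eval, signal_detection
from .decision import DecisionReport, ThresholdSet, decide_all, write_decision_report
from .reference_eval import build_fourfold, indicators, write_fourfold, write_indicators
from .signal_detection import DetectionConfig, Method, detect, write_signals
from .types import DrugType

__all__ = ["RunConfig", "PipelineResult", "run_pipeline", "load_run_config", "EmptySampleError"]

logger = logging.getLogger(__name__)

DEFAULT_METHODS = (Method.PRR, Method.MHRA, Method.IC)


class EmptySampleError(RuntimeError):
    """No pairs survive the cleaning funnel (dedicated CLI exit code)."""


@dataclass
class RunConfig:
    reports_path: str
    reference_path: str
    out_dir: str
    stratum: DrugType = DrugType.TCM
    methods: tuple[Method, ...] = DEFAULT_METHODS
    min_count: int = 3
    detection: DetectionConfig = field(default_factory=DetectionConfig)
    thresholds: ThresholdSet | None = None  # None -> derive from the indicators
    strict_dedup: bool = False


@dataclass
class PipelineResult:
    total_sample: "report_ingest.Sample"
    stratum_sample: "report_ingest.Sample"
    indicator_sets: list[reference_eval.IndicatorSet]
    report: DecisionReport
    artifacts: dict[str, Path]


def load_run_config(path: str | Path) -> RunConfig:
    """Read a YAML run configuration.

    Recognised keys: reports, reference, out_dir, stratum, methods, min_count,
    detection: {...DetectionConfig fields...}, thresholds: {rt, pt, dt} (as
    proportions) or 'auto', strict_dedup.
    """
    raw = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
    det = DetectionConfig(**raw.get("detection", {}))
    th = raw.get("thresholds", "auto")
    if th in (None, "auto"):
        thresholds = None
    else:
        thresholds = ThresholdSet(
            rt=Fraction(str(th["rt"])),
            pt=Fraction(str(th["pt"])),
            dt=Fraction(str(th["dt"])),
        )
    return RunConfig(
        reports_path=raw["reports"],
        reference_path=raw["reference"],
        out_dir=raw.get("out_dir", "."),
        stratum=DrugType.coerce(raw.get("stratum", "TCM")),
        methods=tuple(Method(m) for m in raw.get("methods", [m.value for m in DEFAULT_METHODS])),
        min_count=int(raw.get("min_count", 3)),
        detection=det,
        thresholds=thresholds,
        strict_dedup=bool(raw.get("strict_dedup", False)),
    )


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Run the full chain and write all artifacts under ``config.out_dir``."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Path] = {}

    records = report_ingest.read_reports(config.reports_path)
    refdb = report_ingest.read_reference(config.reference_path)
    logger.info("pipeline: %d split records, %d reference pairs", len(records), len(refdb))

    total = report_ingest.build_total_sample(
        records, refdb, min_count=config.min_count, strict_dedup=config.strict_dedup
    )
    if not total.pairs:
        raise EmptySampleError("no pairs survive filtering in the total sample")
    stratum = report_ingest.extract_stratum(total, config.stratum)
    if not stratum.pairs:
        raise EmptySampleError(f"stratum {config.stratum.value!r} is empty after filtering")
    logger.info(
        "pipeline: total sample %d pairs, stratum %d pairs",
        len(total.pairs),
        len(stratum.pairs),
    )

    artifacts["pairs_total"] = out / "pairs_total.csv"
    artifacts["pairs_stratum"] = out / "pairs_stratum.csv"
    report_ingest.write_pairs(total, artifacts["pairs_total"])
    report_ingest.write_pairs(stratum, artifacts["pairs_stratum"])

    indicator_sets = []
    total_runs, stratum_runs = [], []
    for method in config.methods:
        run_total = detect(total, method, config.detection)
        run_sub = detect(stratum, method, config.detection)
        total_runs.append(run_total)
        stratum_runs.append(run_sub)
        logger.info(
            "pipeline: %s positives total=%d stratum=%d",
            method.value,
            len(run_total.positives),
            len(run_sub.positives),
        )
        fourfold = build_fourfold(run_total, run_sub, stratum)
        artifacts[f"fourfold_{method.value}"] = out / f"fourfold_{method.value}.json"
        write_fourfold(fourfold, method, artifacts[f"fourfold_{method.value}"])
        indicator_sets.append(indicators(fourfold, method))

    artifacts["signals_total"] = out / "signals_total.csv"
    artifacts["signals_stratum"] = out / "signals_stratum.csv"
    write_signals(total_runs, artifacts["signals_total"])
    write_signals(stratum_runs, artifacts["signals_stratum"])

    artifacts["indicators"] = out / "indicators.csv"
    write_indicators(indicator_sets, artifacts["indicators"])

    report = decide_all(indicator_sets, config.thresholds)
    artifacts["decision"] = out / "decision.json"
    write_decision_report(report, artifacts["decision"])
    logger.info("pipeline: consensus %s", report.consensus)

    return PipelineResult(total, stratum, indicator_sets, report, artifacts)
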