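"""One-call reproduction of the full analysis chain.

Stages, in order: study-population summary -> per-marker two-group
comparisons -> per-group correlation matrices with Ward clustering ->
repeated-DCV PLS-DA with variable selection and a reduced-model refit ->
Gaussian-kernel KPLS regressions of the clinical outcomes. All randomness
flows from one master seed; outputs are deterministic JSON/CSV.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .cohort import CohortTable, read_cohort
from .correlate import cluster_markers, correlation_matrix
from .dcv import (
    DCVConfig,
    DCVResult,
    assess_variable_significance,
    refit_reduced_model,
    run_dcv_classification,
    run_dcv_regression,
)
from .simulate import SyntheticConfig, generate_cohort
from .univariate import compare_markers, summarize_cohort

log = logging.getLogger("frailmark")

DEFAULT_OUTCOMES = ("age", "bmi", "alm", "sppb")


@dataclass
class AnalysisConfig:
    input_path: str | None = None
    synthetic: SyntheticConfig | None = None
    dcv: DCVConfig = field(default_factory=DCVConfig)
    outcomes: tuple[str, ...] = DEFAULT_OUTCOMES
    output_dir: str | None = None
    seed: int = 0

    def __post_init__(self):
        if (self.input_path is None) == (self.synthetic is None):
            raise ValueError("set exactly one of input_path / synthetic")


@dataclass
class ReportBundle:
    table1: object  # DataFrame
    marker_tests: list
    correlations: dict  # group -> (CorrelationResult, Dendrogram, order, labels)
    dcv_full: DCVResult
    significant_markers: list
    dcv_reduced: DCVResult
    regressions: dict  # outcome -> DCVResult
    provenance: dict


def _config_hash(config: AnalysisConfig) -> str:
    def default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if hasattr(o, "__dict__"):
            return o.__dict__
        return str(o)

    doc = {k: v for k, v in config.__dict__.items() if k != "output_dir"}
    blob = json.dumps(doc, default=default, sort_keys=True)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _dcv_to_dict(res: DCVResult) -> dict:
    d = {
        "mode": res.mode,
        "marker_names": list(res.marker_names),
        "mean": res.mean,
        "sd": res.sd,
        "ci95": list(res.ci()),
        "per_repetition": res.per_rep_overall.tolist(),
        "mean_complexity": res.mean_complexity(),
        "redraws": len(res.redraw_log),
    }
    if res.per_rep_class_acc:
        d["per_class"] = {
            c: {"mean": float(np.mean(v)), "sd": float(np.std(v, ddof=1)) if len(v) > 1 else 0.0}
            for c, v in res.per_rep_class_acc.items()
        }
    if res.coef_samples is not None:
        d["coefficient_medians"] = np.median(res.coef_samples, axis=0).tolist()
    if res.sample_scores is not None:
        mean, lo, hi = res.sample_score_summary()
        d["sample_scores"] = {"mean": mean.tolist(), "lo": lo.tolist(), "hi": hi.tolist()}
    return d


def _corr_to_dict(corr, dend, order, labels) -> dict:
    return {
        "group": corr.group,
        "n": corr.n,
        "marker_names": list(corr.marker_names),
        "r": corr.r.tolist(),
        "p": corr.p.tolist(),
        "sig_mask": corr.sig_mask.tolist(),
        "merges": [[int(a), int(b), float(h)] for a, b, h in dend.merges],
        "leaf_order": [int(i) for i in order],
        "k2_labels": [int(l) for l in labels],
    }


def run_full_analysis(config: AnalysisConfig) -> ReportBundle:
    """Execute every stage on one cohort; optionally write all artifacts."""
    if config.input_path is not None:
        log.info("stage cohort: reading %s", config.input_path)
        table, report = read_cohort(config.input_path)
        if report.dropped:
            log.warning("dropped %d rows during validation", len(report.dropped))
    else:
        log.info("stage cohort: generating synthetic cohort (seed %d)", config.seed)
        table = generate_cohort(config.synthetic, seed=config.seed)

    log.info("stage table1: study-population summary")
    table1 = summarize_cohort(table)

    log.info("stage markers: per-marker comparisons")
    marker_tests = compare_markers(table)

    log.info("stage correlation: per-group matrices + Ward clustering")
    correlations = {}
    for group in ("PFS", "CONTROL"):
        corr = correlation_matrix(table, group)
        dend, order, _, labels = cluster_markers(corr)
        correlations[group] = (corr, dend, order, labels)

    cfg = config.dcv
    log.info("stage dcv: full PLS-DA model (%d repetitions)", cfg.repetitions)
    dcv_full = run_dcv_classification(table, config=cfg)
    verdicts = assess_variable_significance(dcv_full)
    significant = [v for v in verdicts if v.significant]
    selected = [v.name for v in significant] or [
        v.name for v in sorted(verdicts, key=lambda v: -abs(v.median_coef))[:3]
    ]
    log.info("stage dcv: reduced model on %s", selected)
    dcv_reduced = refit_reduced_model(table, selected, config=cfg)

    regressions = {}
    for outcome in config.outcomes:
        log.info("stage kpls: regression of %s", outcome)
        regressions[outcome] = run_dcv_regression(table, outcome, config=cfg)

    provenance = {
        "seed": config.seed,
        "config_hash": _config_hash(config),
        "version": __version__,
        "n_subjects": table.n_subjects,
        "class_sizes": table.class_sizes(),
    }

    bundle = ReportBundle(
        table1=table1,
        marker_tests=marker_tests,
        correlations=correlations,
        dcv_full=dcv_full,
        significant_markers=significant,
        dcv_reduced=dcv_reduced,
        regressions=regressions,
        provenance=provenance,
    )
    if config.output_dir is not None:
        write_bundle(bundle, config.output_dir)
    return bundle


def write_bundle(bundle: ReportBundle, output_dir) -> None:
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)

    bundle.table1.to_csv(out / "table1.csv", index=False)

    marker_rows = []
    for t in bundle.marker_tests:
        marker_rows.append(
            {
                "marker": t.variable,
                "test": t.test,
                "statistic": t.statistic,
                "p": t.p,
                "direction": t.direction,
                **{f"{g}_{k}": v for g, box in t.group_summaries.items() for k, v in box.items()},
            }
        )
    import pandas as pd

    pd.DataFrame(marker_rows).to_csv(out / "markers.csv", index=False)

    for group, (corr, dend, order, labels) in bundle.correlations.items():
        (out / f"corr_{group}.json").write_text(
            json.dumps(_corr_to_dict(corr, dend, order, labels), indent=1)
        )
        (out / f"dendrogram_{group}.nwk").write_text(
            dend.to_newick(list(corr.marker_names)) + "\n"
        )

    (out / "dcv_full.json").write_text(json.dumps(_dcv_to_dict(bundle.dcv_full), indent=1))
    (out / "dcv_reduced.json").write_text(json.dumps(_dcv_to_dict(bundle.dcv_reduced), indent=1))
    for outcome, res in bundle.regressions.items():
        (out / f"kpls_{outcome}.json").write_text(json.dumps(_dcv_to_dict(res), indent=1))

    report = {
        "provenance": bundle.provenance,
        "significant_markers": [
            {"name": v.name, "direction": v.direction, "median_coef": v.median_coef, "ci": list(v.ci)}
            for v in bundle.significant_markers
        ],
        "dcv_full": {"mean": bundle.dcv_full.mean, "sd": bundle.dcv_full.sd},
        "dcv_reduced": {"mean": bundle.dcv_reduced.mean, "sd": bundle.dcv_reduced.sd},
        "regressions": {k: {"mean_q2": r.mean, "sd": r.sd} for k, r in bundle.regressions.items()},
    }
    (out / "report.json").write_text(json.dumps(report, indent=1))
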