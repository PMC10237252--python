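"""End-to-end analysis runs: score -> summarise -> compare -> ROC -> report.

A run is fully determined by a :class:`RunConfig` (one input source, a seed,
and the analysis conventions); the emitted report echoes the config so every
number in it is recomputable.  Reports are written both as JSON and as a
human-readable text table mirroring the usual layout of a score-validation
results section: descriptives, per-parameter associations, group comparison,
then ROC/cutoff/accuracy.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from . import __version__
from .cohort import build_fixture_cohort, read_cohort, write_scored_cohort
from .diagnostics import (
    band_outcome_table,
    chi_square,
    descriptive_summary,
    diagnostic_metrics,
    mann_whitney,
    optimal_cutoff,
    roc_curve,
)
from .errors import MsnsError
from .rubric import PARAMETERS, compute_msns
from .simulate import GeneratorConfig, generate_observation_cohort, generate_scores

log = logging.getLogger("msns")


@dataclass(frozen=True)
class RunConfig:
    """One analysis run: exactly one input source, conventions, seed, outputs."""

    input_path: Optional[str] = None
    use_fixture: bool = False
    generator: Optional[GeneratorConfig] = None
    percentage_convention: str = "truncate"
    output_dir: Optional[str] = None
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self):
        sources = sum([self.input_path is not None, self.use_fixture,
                       self.generator is not None])
        if sources != 1:
            raise MsnsError("exactly one input source must be set "
                            "(input_path, fixture, or generator)")


@dataclass
class AnalysisReport:
    """Everything one run computed, plus the config that determines it."""

    provenance: str
    n_records: int
    seed: int
    version: str
    config: dict
    descriptives: Optional[list] = None
    associations: Optional[dict] = None
    group_comparison: dict = field(default_factory=dict)
    roc_points: list = field(default_factory=list)
    auc: float = float("nan")
    cutoff: int = 0
    metrics: dict = field(default_factory=dict)
    validation: Optional[dict] = None

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), sort_keys=True, **kwargs)

    def to_text(self) -> str:
        lines = [
            f"MSNS analysis report (msns {self.version})",
            f"input: {self.provenance}   n={self.n_records}   seed={self.seed}",
            "",
        ]
        if self.descriptives:
            lines.append("Baseline characteristics:")
            for row in self.descriptives:
                lines.append(f"  {row['field']:>22}  {row['category']:<10}"
                             f" {row['count']:>4} ({row['percent']}%)")
            lines.append("")
        if self.associations:
            lines.append("Per-parameter association with outcome (chi-square)"
                         " and group comparison (Mann-Whitney):")
            for p, a in self.associations.items():
                chi = a["chi_square"]
                mw = a["mann_whitney"]
                warn = " [expected<5]" if chi["small_expected_cells"] else ""
                lines.append(
                    f"  {p:>22}  chi2={chi['statistic']:.2f} df={chi['degrees_of_freedom']}"
                    f" p={chi['p_value']:.3g}{warn}  |  median "
                    f"{mw['median_discharged']:.0f}/{mw['median_expired']:.0f}"
                    f"  z={mw['z_value']:.2f} p={mw['p_value']:.3g}")
            lines.append("")
        gc = self.group_comparison
        if gc:
            lines.append(
                "Total score, discharged vs expired: "
                f"median {gc['median_discharged']:.1f} "
                f"(IQR {gc['iqr_discharged'][0]:.1f}-{gc['iqr_discharged'][1]:.1f}) vs "
                f"{gc['median_expired']:.1f} "
                f"(IQR {gc['iqr_expired'][0]:.1f}-{gc['iqr_expired'][1]:.1f}), "
                f"U={gc['u_statistic']:.1f}, z={gc['z_value']:.2f}, "
                f"p={gc['p_value']:.3g} ({gc['method']})")
        m = self.metrics
        if m:
            lines += [
                f"ROC AUC = {self.auc:.3f}; optimal cutoff: score <= {self.cutoff}",
                f"  sensitivity {m['sensitivity']:.3f} "
                f"(95% CI {m['sensitivity_ci'][0]:.3f}-{m['sensitivity_ci'][1]:.3f})",
                f"  specificity {m['specificity']:.3f} "
                f"(95% CI {m['specificity_ci'][0]:.3f}-{m['specificity_ci'][1]:.3f})",
                f"  PPV {m['ppv']:.3f}  NPV {m['npv']:.3f}  "
                f"Youden J {m['youden_j']:.3f}",
            ]
        return "\n".join(lines) + "\n"


def _comparison_dict(gc) -> dict:
    # group a = discharged, group b = expired throughout the pipeline
    return {
        "u_statistic": gc.u_statistic, "z_value": gc.z_value,
        "p_value": gc.p_value, "method": gc.method,
        "median_discharged": gc.median_a, "iqr_discharged": list(gc.iqr_a),
        "median_expired": gc.median_b, "iqr_expired": list(gc.iqr_b),
    }


def run_analysis(config: RunConfig) -> AnalysisReport:
    """Execute the full pipeline for one config and return (and optionally
    write) the report.

    Stages run in order — acquire, validate, score, describe, associate,
    compare, ROC — and any stage failure raises :class:`MsnsError` (or a
    validation error) naming the stage, before later statistics are touched.
    With a score-level generator the physiology stages are skipped and the
    report covers the total score only.
    """
    logging.basicConfig(level=config.log_level)
    report_kwargs: dict = {"seed": config.seed, "version": __version__,
                           "config": _config_dict(config)}

    cohort = None
    if config.input_path is not None:
        cohort, vreport = read_cohort(config.input_path)
        report_kwargs["validation"] = vreport.to_dict()
        log.info("read %d rows, accepted %d", vreport.n_read, vreport.n_accepted)
        if len(cohort) == 0:
            raise MsnsError("stage read: no valid records in input")
    elif config.use_fixture:
        cohort = build_fixture_cohort(config.seed)
    elif config.generator.mode == "observation_level":
        cohort = generate_observation_cohort(config.generator)

    if cohort is not None:
        results = [compute_msns(r) for r in cohort]
        log.info("scored %d records", len(results))
        totals = np.array([r.total for r in results])
        outcomes = np.array(cohort.outcomes())
        report_kwargs["provenance"] = cohort.provenance
        report_kwargs["descriptives"] = descriptive_summary(
            cohort, config.percentage_convention).to_dict("records")
        associations = {}
        for p in PARAMETERS:
            table = band_outcome_table(cohort, results, p)
            chi = chi_square(table.to_numpy())
            subs = np.array([r.subscores[p] for r in results])
            mw = mann_whitney(subs[outcomes == "discharged"],
                              subs[outcomes == "expired"])
            associations[p] = {
                "table": table.to_numpy().tolist(),
                "chi_square": {
                    "statistic": chi.statistic,
                    "degrees_of_freedom": chi.degrees_of_freedom,
                    "p_value": chi.p_value,
                    "small_expected_cells": chi.small_expected_cells,
                },
                "mann_whitney": _comparison_dict(mw),
            }
        report_kwargs["associations"] = associations
    else:  # score-level synthetic input
        frame = generate_scores(config.generator)
        totals = frame["total_score"].to_numpy()
        outcomes = frame["outcome"].to_numpy()
        report_kwargs["provenance"] = f"synthetic-scores:{config.generator.seed}"
    report_kwargs["n_records"] = len(totals)

    gc = mann_whitney(totals[outcomes == "discharged"], totals[outcomes == "expired"])
    roc = roc_curve(totals, outcomes)
    cutoff = optimal_cutoff(roc)
    metrics = diagnostic_metrics(totals, outcomes, cutoff)
    log.info("analysed %d records: AUC=%.3f cutoff<=%d", len(totals), roc.auc, cutoff)

    report = AnalysisReport(
        group_comparison=_comparison_dict(gc),
        roc_points=roc.to_frame().to_dict("records"),
        auc=roc.auc,
        cutoff=cutoff,
        metrics={
            "sensitivity": metrics.sensitivity,
            "specificity": metrics.specificity,
            "ppv": metrics.ppv, "npv": metrics.npv,
            "youden_j": metrics.youden_j,
            "sensitivity_ci": list(metrics.sensitivity_ci),
            "specificity_ci": list(metrics.specificity_ci),
            "ppv_ci": list(metrics.ppv_ci), "npv_ci": list(metrics.npv_ci),
            "tp": metrics.tp, "fn": metrics.fn,
            "fp": metrics.fp, "tn": metrics.tn,
        },
        **report_kwargs,
    )

    if config.output_dir is not None:
        out = Path(config.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(report.to_json(indent=2) + "\n")
        (out / "report.txt").write_text(report.to_text())
        if cohort is not None:
            write_scored_cohort(cohort, results, out / "scored_cohort.csv")
        log.info("wrote report to %s", out)
    return report


def _config_dict(config: RunConfig) -> dict:
    d = dataclasses.asdict(config)
    return d


def score_file(in_path, out_path, report_path=None) -> "tuple[int, int]":
    """Score a cohort file, appending the nine score columns.

    Returns ``(n_scored, n_rejected)``; the optional JSON validation report
    lists every rejected row.
    """
    cohort, vreport = read_cohort(in_path)
    results = [compute_msns(r) for r in cohort]
    write_scored_cohort(cohort, results, out_path)
    if report_path is not None:
        Path(report_path).write_text(vreport.to_json(indent=2) + "\n")
    return len(results), vreport.n_rejected
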