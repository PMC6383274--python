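"""Assemble machine- and human-readable analysis reports.

``run_analysis`` executes the full pipeline on a subject-level dataset:
group summaries with t-tests, categorical distributions with chi-square
tests, the 2x4 joint-exposure table with crude odds ratios and Woolf CIs,
unconditional (sex-adjusted) and conditional logistic fits of the
joint-exposure model, and the four additive-interaction measures with
delta-method and bootstrap confidence intervals.

Every number in the markdown report is also present in the JSON document;
regeneration from the same inputs is byte-identical apart from the
timestamp field. Sections that fail (e.g. regression non-convergence)
degrade gracefully: the section is marked failed and a warning recorded.
"""

from __future__ import annotations

import datetime
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .contingency import (
    build_exposure_table,
    chisq_rxc,
    crude_or,
    summarize_by_group,
    two_sample_t,
)
from .errors import AddinterError
from .interaction import measures_from_dataset
from .records import StudyDataset
from .regression import Design, fit_joint_exposure

__all__ = ["AnalysisReport", "run_analysis", "write_report"]

NUMERIC_VARIABLES = ("age", "height", "weight", "waist", "hip", "bmi", "whr")
CATEGORICAL_VARIABLES = ("sex", "family_history", "bmi_category", "whr_abnormal")


@dataclass
class AnalysisReport:
    summary: dict
    group_summaries: list = field(default_factory=list)
    categorical: list = field(default_factory=list)
    exposure: dict = field(default_factory=dict)
    regression: dict = field(default_factory=dict)
    interaction: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)
    provenance: dict = field(default_factory=dict)

    def to_json_dict(self) -> dict:
        return {
            "summary": self.summary,
            "group_summaries": self.group_summaries,
            "categorical": self.categorical,
            "exposure": self.exposure,
            "regression": self.regression,
            "interaction": self.interaction,
            "warnings": self.warnings,
            "provenance": self.provenance,
        }


def _categorical_section(dataset: StudyDataset) -> list:
    out = []
    for var in CATEGORICAL_VARIABLES:
        levels: dict[str, list[int]] = {}
        for rec in dataset.records:
            value = getattr(rec, var)
            key = value.value if hasattr(value, "value") else str(int(value)) if isinstance(value, bool) else str(value)
            levels.setdefault(key, [0, 0])[0 if rec.is_case else 1] += 1
        table = [counts for counts in levels.values()]
        entry = {"variable": var, "levels": {k: v for k, v in sorted(levels.items())}}
        try:
            result = chisq_rxc(table)
            entry["chi_square"] = {
                "statistic": result.statistic,
                "df": result.df,
                "p": result.p,
            }
        except AddinterError as exc:
            entry["chi_square"] = {"error": str(exc)}
        out.append(entry)
    return out


def run_analysis(
    dataset: StudyDataset,
    alpha: float = 0.05,
    bootstrap: int = 2000,
    seed: int = 0,
    continuity: bool = False,
) -> AnalysisReport:
    """Run every analysis stage on a validated dataset."""
    warnings_list = list(dataset.pair_warnings)
    summary = {
        "n_records": len(dataset.records),
        "n_pairs": dataset.n_pairs,
        "n_dropped_rows": len(dataset.dropped),
        "dropped_reasons": [reason for _, reason in dataset.dropped],
        "n_excluded_from_pairs": dataset.n_excluded_from_pairs,
    }
    report = AnalysisReport(summary=summary)

    # Table-1-style numeric summaries with Welch t-tests
    try:
        summaries = summarize_by_group(dataset, NUMERIC_VARIABLES)
        by_var: dict[str, dict] = {}
        for s in summaries:
            by_var.setdefault(s.variable, {})[s.group] = s
        rows = []
        for var, groups in by_var.items():
            row = {"variable": var}
            for group, s in groups.items():
                row[group] = {"n": s.n, "mean": s.mean, "sd": s.sd}
            if "case" in groups and "control" in groups:
                t = two_sample_t(groups["control"], groups["case"])
                row["t"] = t.t
                row["df"] = t.df
                row["p"] = t.p
            rows.append(row)
        report.group_summaries = rows
    except AddinterError as exc:
        warnings_list.append(f"group summaries failed: {exc}")

    # Table-2-style categorical distributions with chi-square
    try:
        report.categorical = _categorical_section(dataset)
    except AddinterError as exc:
        warnings_list.append(f"categorical section failed: {exc}")

    # 2x4 exposure table with crude ORs (unconditional: all valid records)
    try:
        table = build_exposure_table(dataset)
        cells = {}
        for (fh, ab), (case, control) in table.counts.items():
            key = f"fh{fh}_bmi{ab}"
            cells[key] = {"cases": case, "controls": control}
            if (fh, ab) != (0, 0):
                try:
                    est = crude_or(table, (fh, ab), alpha=alpha,
                                   continuity=continuity)
                except AddinterError as exc:
                    cells[key]["error"] = str(exc)
                else:
                    cells[key]["or"] = est.or_point
                    cells[key]["ci_low"] = est.ci_low
                    cells[key]["ci_high"] = est.ci_high
        report.exposure = {"cells": cells, "alpha": alpha}
    except AddinterError as exc:
        table = None
        warnings_list.append(f"exposure table failed: {exc}")

    # regression fits
    report.regression = {}
    for label, design, adjust in (
        ("unconditional_sex_adjusted", Design.UNCONDITIONAL, True),
        ("conditional_pairs", Design.CONDITIONAL_PAIRS, False),
    ):
        try:
            fit = fit_joint_exposure(
                dataset, design=design, adjust_for_sex=adjust, alpha=alpha
            )
            report.regression[label] = {
                "converged": fit.converged,
                "n_used": fit.n_used,
                "loglik": fit.loglik,
                "terms": {
                    term: {
                        "coef": float(row["coef"]),
                        "se": float(row["se"]),
                        "or": float(row["OR"]),
                        "ci_low": float(row["ci_low"]),
                        "ci_high": float(row["ci_high"]),
                        "p": float(row["p"]),
                    }
                    for term, row in fit.or_table.iterrows()
                },
            }
        except AddinterError as exc:
            report.regression[label] = {"converged": False, "error": str(exc)}
            warnings_list.append(f"regression {label} failed: {exc}")

    # interaction measures, delta + bootstrap
    try:
        measured = measures_from_dataset(
            dataset,
            alpha=alpha,
            continuity=continuity,
            bootstrap=bootstrap,
            seed=seed,
        )
        report.interaction = {
            method: m.as_dict() for method, m in measured.items()
        }
    except AddinterError as exc:
        report.interaction = {"error": str(exc)}
        warnings_list.append(f"interaction section failed: {exc}")

    report.warnings = warnings_list
    return report


# ------------------------------------------------------------- rendering

def _fmt(x, nd=3):
    if x is None:
        return "-"
    if isinstance(x, float):
        return f"{x:.{nd}f}"
    return str(x)


def _md_table(header: list[str], rows: list[list[str]]) -> list[str]:
    lines = ["| " + " | ".join(header) + " |",
             "|" + "|".join("---" for _ in header) + "|"]
    lines += ["| " + " | ".join(row) + " |" for row in rows]
    return lines


def render_markdown(report: AnalysisReport) -> str:
    """Human-readable report; every figure mirrors the JSON document."""
    lines = ["# Matched case-control interaction analysis", ""]
    s = report.summary
    lines.append(
        f"Records: {s['n_records']}; complete pairs: {s['n_pairs']}; "
        f"dropped rows: {s['n_dropped_rows']}; "
        f"excluded from pair analyses: {s['n_excluded_from_pairs']}."
    )
    lines.append("")
    if report.group_summaries:
        lines.append("## Group summaries (mean, SD) with Welch t-tests")
        rows = []
        for row in report.group_summaries:
            control = row.get("control", {})
            case = row.get("case", {})
            rows.append([
                row["variable"],
                f"{_fmt(control.get('mean'), 2)} ({_fmt(control.get('sd'), 2)})",
                f"{_fmt(case.get('mean'), 2)} ({_fmt(case.get('sd'), 2)})",
                _fmt(row.get("t")),
                _fmt(row.get("p"), 4),
            ])
        lines += _md_table(
            ["variable", "control mean (SD)", "case mean (SD)", "t", "p"], rows
        )
        lines.append("")
    if report.categorical:
        lines.append("## Categorical distributions with chi-square tests")
        rows = []
        for entry in report.categorical:
            chi = entry.get("chi_square", {})
            rows.append([
                entry["variable"],
                "; ".join(
                    f"{level}: {case}/{control}"
                    for level, (case, control) in entry["levels"].items()
                ),
                _fmt(chi.get("statistic")),
                _fmt(chi.get("p"), 4),
            ])
        lines += _md_table(["variable", "case/control by level", "chi2", "p"], rows)
        lines.append("")
    if report.exposure:
        lines.append("## Joint-exposure (FH x abnormal BMI) table")
        rows = []
        for key, cell in report.exposure["cells"].items():
            rows.append([
                key,
                str(cell["cases"]),
                str(cell["controls"]),
                _fmt(cell.get("or")) if "or" in cell else "1.000",
                (f"{_fmt(cell['ci_low'])}~{_fmt(cell['ci_high'])}"
                 if "ci_low" in cell else "-"),
            ])
        lines += _md_table(["cell", "cases", "controls", "OR", "95% CI"], rows)
        lines.append("")
    if report.regression:
        lines.append("## Logistic regression (joint-exposure model)")
        for label, fit in report.regression.items():
            if not fit.get("converged"):
                lines.append(f"- {label}: failed ({fit.get('error', 'unknown')})")
                continue
            lines.append(f"### {label}")
            rows = [
                [term, _fmt(v["coef"]), _fmt(v["se"]), _fmt(v["or"]),
                 f"{_fmt(v['ci_low'])}~{_fmt(v['ci_high'])}", _fmt(v["p"], 4)]
                for term, v in fit["terms"].items()
            ]
            lines += _md_table(["term", "B", "SE", "OR", "95% CI", "p"], rows)
            lines.append("")
    if report.interaction and "error" not in report.interaction:
        lines.append("## Additive interaction measures")
        rows = []
        for method, m in report.interaction.items():
            for name in ("si", "reri", "ap", "pap"):
                entry = m.get(name)
                if entry is None:
                    rows.append([name.upper(), method, "-", "-"])
                    continue
                rows.append([
                    name.upper(),
                    method,
                    _fmt(entry["estimate"]),
                    (f"{_fmt(entry['ci_low'])}~{_fmt(entry['ci_high'])}"
                     if entry.get("ci_low") is not None else "-"),
                ])
        lines += _md_table(["measure", "CI method", "estimate", "95% CI"], rows)
        first = next(iter(report.interaction.values()))
        lines.append("")
        lines.append(f"Interaction classification: **{first['classification']}**.")
        lines.append("")
    if report.warnings:
        lines.append("## Warnings")
        lines += [f"- {w}" for w in report.warnings]
        lines.append("")
    return "\n".join(lines) + "\n"


class _JSONEncoder(json.JSONEncoder):
    def default(self, o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        return super().default(o)


def write_report(
    report: AnalysisReport,
    out_dir: str | Path,
    dataset: StudyDataset | None = None,
    seed: int | None = None,
    config_hash: str | None = None,
    alpha: float = 0.05,
) -> None:
    """Write report.json, report.md and the tables/ TSV analogues."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report.provenance = {
        "package": "addinter",
        "version": __version__,
        "seed": seed,
        "config_hash": config_hash,
        "timestamp": datetime.datetime.now(datetime.timezone.utc).isoformat(),
    }
    doc = report.to_json_dict()
    (out / "report.json").write_text(
        json.dumps(doc, indent=1, cls=_JSONEncoder) + "\n"
    )
    (out / "report.md").write_text(render_markdown(report))
    tables = out / "tables"
    tables.mkdir(exist_ok=True)
    if report.group_summaries:
        lines = ["variable\tcontrol_mean\tcontrol_sd\tcase_mean\tcase_sd\tt\tp"]
        for row in report.group_summaries:
            control, case = row.get("control", {}), row.get("case", {})
            lines.append(
                "\t".join([
                    row["variable"],
                    _fmt(control.get("mean")), _fmt(control.get("sd")),
                    _fmt(case.get("mean")), _fmt(case.get("sd")),
                    _fmt(row.get("t")), _fmt(row.get("p"), 5),
                ])
            )
        (tables / "group_summaries.tsv").write_text("\n".join(lines) + "\n")
    if report.categorical:
        lines = ["variable\tlevel\tcases\tcontrols"]
        for entry in report.categorical:
            for level, (case, control) in entry["levels"].items():
                lines.append(f"{entry['variable']}\t{level}\t{case}\t{control}")
        (tables / "categorical.tsv").write_text("\n".join(lines) + "\n")
    if dataset is not None and report.exposure:
        table = build_exposure_table(dataset)
        table.to_tsv(tables / "exposure_2x4.tsv", alpha=alpha)
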