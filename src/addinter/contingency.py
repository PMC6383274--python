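"""Joint-exposure contingency tables, crude odds ratios and classic tests.

The central object is the 2x4 ("Botto-Khoury") table: case and control
counts over the four combinations of two binary exposures — here family
history (FH) and abnormal BMI — with the doubly-unexposed cell as the common
reference. Crude odds ratios against that reference feed the
additive-interaction measures directly.

Confidence intervals for odds ratios use the Woolf (log) method:

    SE(log OR) = sqrt(1/a + 1/b + 1/c + 1/d)
    CI = exp(log OR +/- z_{1-alpha/2} * SE)

Group comparisons use the Welch two-sample t-test computed from summary
statistics (with equal group sizes it coincides with the pooled-variance
form) and the Pearson chi-square without continuity correction.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError, ZeroCellError
from .records import Status, StudyDataset

__all__ = [
    "ExposureTable2x4",
    "OddsRatioEstimate",
    "GroupSummary",
    "TTestResult",
    "ChiSquareResult",
    "build_exposure_table",
    "crude_or",
    "woolf_ci",
    "two_sample_t",
    "chisq_rxc",
    "summarize_by_group",
]

#: cell order used throughout: (FH, BMI-abnormal)
CELLS = ((0, 0), (0, 1), (1, 0), (1, 1))
REFERENCE_CELL = (0, 0)


@dataclass(frozen=True)
class OddsRatioEstimate:
    """Crude odds ratio of one exposure cell against the reference cell."""

    or_point: float
    log_or: float
    se_log_or: float
    ci_low: float
    ci_high: float
    alpha: float
    cell: tuple[int, int]
    reference: tuple[int, int] = REFERENCE_CELL
    continuity: bool = False


@dataclass(frozen=True)
class GroupSummary:
    """Per-group descriptive summary of one numeric variable."""

    variable: str
    group: str
    n: int
    mean: float
    sd: float | None  # None when n < 2 (flagged, no SD)


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: float
    p: float


@dataclass(frozen=True)
class ChiSquareResult:
    statistic: float
    df: int
    p: float


@dataclass
class ExposureTable2x4:
    """Case/control counts over the four (FH, BMI-abnormal) exposure cells."""

    counts: dict[tuple[int, int], tuple[int, int]] = field(
        default_factory=lambda: {c: (0, 0) for c in CELLS}
    )

    def __post_init__(self) -> None:
        for cell in CELLS:
            case, control = self.counts.get(cell, (0, 0))
            if case < 0 or control < 0 or case != int(case) or control != int(control):
                raise ValidationError(
                    f"cell {cell} counts must be non-negative integers, "
                    f"got {(case, control)}"
                )
            self.counts[cell] = (int(case), int(control))

    def cell(self, fh: int, bmi_abnormal: int) -> tuple[int, int]:
        return self.counts[(int(fh), int(bmi_abnormal))]

    @property
    def case_total(self) -> int:
        return sum(c for c, _ in self.counts.values())

    @property
    def control_total(self) -> int:
        return sum(c for _, c in self.counts.values())

    def or_triple(self, continuity: bool = False) -> tuple[float, float, float]:
        """(OR11, OR10, OR01): both-exposed, FH-only, BMI-only crude ORs."""
        return (
            crude_or(self, (1, 1), continuity=continuity).or_point,
            crude_or(self, (1, 0), continuity=continuity).or_point,
            crude_or(self, (0, 1), continuity=continuity).or_point,
        )

    def log_or_covariance(self, continuity: bool = False) -> np.ndarray:
        """3x3 covariance of (log OR11, log OR10, log OR01).

        The three log odds ratios share the reference cell, so the
        off-diagonal covariance is the reference cell's variance
        contribution 1/a00 + 1/b00; the diagonal adds each cell's own
        1/a + 1/b. This is the covariance of the saturated joint-exposure
        logistic model's non-intercept coefficients.
        """
        add = 0.5 if continuity else 0.0
        a0, b0 = self.counts[REFERENCE_CELL]
        if not continuity and (a0 == 0 or b0 == 0):
            raise ZeroCellError("reference cell has a zero count")
        shared = 1.0 / (a0 + add) + 1.0 / (b0 + add)
        cov = np.full((3, 3), shared)
        for i, cell in enumerate(((1, 1), (1, 0), (0, 1))):
            a, b = self.counts[cell]
            if not continuity and (a == 0 or b == 0):
                raise ZeroCellError(f"cell {cell} has a zero count")
            cov[i, i] = shared + 1.0 / (a + add) + 1.0 / (b + add)
        return cov

    # ------------------------------------------------------------------ io
    def to_json(self) -> str:
        cells = {f"{fh}{ab}": list(self.counts[(fh, ab)]) for fh, ab in CELLS}
        return json.dumps({"cells": cells}, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "ExposureTable2x4":
        doc = json.loads(text)
        counts = {}
        for key, (case, control) in doc["cells"].items():
            counts[(int(key[0]), int(key[1]))] = (case, control)
        return cls(counts=counts)

    def to_tsv(self, path: str | Path | None = None, alpha: float = 0.05) -> str:
        """Render the table with ORs and CIs, one row per exposure cell."""
        lines = ["FH\tBMI\tcases\tcontrols\tOR\t95%CI"]
        for fh, ab in CELLS:
            case, control = self.counts[(fh, ab)]
            mark = lambda x: "+" if x else "-"
            if (fh, ab) == REFERENCE_CELL:
                or_txt, ci_txt = "1.000", "-"
            else:
                try:
                    est = crude_or(self, (fh, ab), alpha=alpha)
                except ZeroCellError:
                    or_txt, ci_txt = "-", "-"
                else:
                    or_txt = f"{est.or_point:.3f}"
                    ci_txt = f"{est.ci_low:.3f}~{est.ci_high:.3f}"
            lines.append(
                f"{mark(fh)}\t{mark(ab)}\t{case}\t{control}\t{or_txt}\t{ci_txt}"
            )
        text = "\n".join(lines) + "\n"
        if path is not None:
            Path(path).write_text(text)
        return text


def build_exposure_table(
    dataset: StudyDataset, paired_only: bool = False
) -> ExposureTable2x4:
    """Tally the dataset into the 2x4 joint-exposure table.

    With ``paired_only`` only records from complete case-control pairs are
    counted (the design-respecting choice for matched analyses).
    """
    records = dataset.paired_records() if paired_only else dataset.records
    counts = {c: [0, 0] for c in CELLS}
    for rec in records:
        counts[rec.exposure_cell()][0 if rec.is_case else 1] += 1
    return ExposureTable2x4(counts={c: tuple(v) for c, v in counts.items()})


def woolf_ci(
    case_cell: float,
    control_cell: float,
    case_ref: float,
    control_ref: float,
    alpha: float = 0.05,
    continuity: bool = False,
) -> tuple[float, float]:
    """Woolf log-scale confidence interval for a 2x2 odds ratio."""
    a, b, c, d = case_cell, control_cell, case_ref, control_ref
    if min(a, b, c, d) < 0:
        raise ValidationError("counts must be non-negative")
    if min(a, b, c, d) == 0:
        if not continuity:
            raise ZeroCellError(
                "zero cell count; pass continuity=True for the "
                "Haldane-Anscombe +0.5 correction"
            )
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    log_or = math.log((a * d) / (b * c))
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    z = stats.norm.ppf(1 - alpha / 2)
    return (math.exp(log_or - z * se), math.exp(log_or + z * se))


def crude_or(
    table: ExposureTable2x4,
    cell: tuple[int, int],
    alpha: float = 0.05,
    continuity: bool = False,
) -> OddsRatioEstimate:
    """Crude odds ratio of ``cell`` against the (0, 0) reference cell.

    Zero counts raise :class:`ZeroCellError` unless ``continuity`` applies
    the Haldane-Anscombe +0.5 correction to all four counts (flagged in the
    returned estimate).
    """
    cell = (int(cell[0]), int(cell[1]))
    a, b = table.counts[cell]
    c, d = table.counts[REFERENCE_CELL]
    applied = False
    if min(a, b, c, d) == 0:
        if not continuity:
            raise ZeroCellError(
                f"zero count in cell {cell} or reference; "
                "pass continuity=True for the +0.5 correction"
            )
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
        applied = True
    log_or = math.log((a * d) / (b * c))
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    low, high = woolf_ci(a, b, c, d, alpha=alpha)
    return OddsRatioEstimate(
        or_point=math.exp(log_or),
        log_or=log_or,
        se_log_or=se,
        ci_low=low,
        ci_high=high,
        alpha=alpha,
        cell=cell,
        continuity=applied,
    )


def two_sample_t(summary_1: GroupSummary, summary_2: GroupSummary) -> TTestResult:
    """Welch two-sample t-test from group summaries.

    Returns the absolute t statistic with Welch-Satterthwaite degrees of
    freedom and the two-sided p-value. With equal n and equal variances the
    statistic coincides with the pooled-variance form.
    """
    for s in (summary_1, summary_2):
        if s.n < 2:
            raise ValidationError(f"group {s.group!r} needs n >= 2, got {s.n}")
        if s.sd is None or s.sd < 0:
            raise ValidationError(f"group {s.group!r} has invalid SD {s.sd!r}")
    v1 = summary_1.sd**2 / summary_1.n
    v2 = summary_2.sd**2 / summary_2.n
    diff = abs(summary_2.mean - summary_1.mean)
    if v1 + v2 == 0:
        if diff == 0:
            return TTestResult(t=0.0, df=summary_1.n + summary_2.n - 2, p=1.0)
        return TTestResult(t=math.inf, df=summary_1.n + summary_2.n - 2, p=0.0)
    t = diff / math.sqrt(v1 + v2)
    df = (v1 + v2) ** 2 / (
        v1**2 / (summary_1.n - 1) + v2**2 / (summary_2.n - 1)
    )
    p = 2 * stats.t.sf(t, df)
    return TTestResult(t=t, df=df, p=p)


def chisq_rxc(table: Sequence[Sequence[float]] | np.ndarray) -> ChiSquareResult:
    """Pearson chi-square test of independence, no continuity correction."""
    observed = np.asarray(table, dtype=float)
    if observed.ndim != 2 or observed.min() < 0:
        raise ValidationError("table must be a 2-D array of non-negative counts")
    if (observed.sum(axis=0) == 0).any() or (observed.sum(axis=1) == 0).any():
        raise ValidationError("table has a zero marginal row or column")
    statistic, p, df, _ = stats.chi2_contingency(observed, correction=False)
    return ChiSquareResult(statistic=float(statistic), df=int(df), p=float(p))


def summarize_by_group(
    dataset: StudyDataset, variables: Iterable[str]
) -> list[GroupSummary]:
    """Per-status mean/SD/n for numeric subject attributes.

    ``variables`` are attribute names of ``SubjectRecord`` (age, height,
    weight, waist, hip, bmi, whr). SD uses the n-1 denominator. Groups with
    fewer than two observations are flagged with ``sd=None``.
    """
    frame = pd.DataFrame(
        {
            "status": [r.status.value for r in dataset.records],
            **{
                var: [float(getattr(r, var)) for r in dataset.records]
                for var in variables
            },
        }
    )
    out: list[GroupSummary] = []
    for var in variables:
        for group in (Status.CONTROL.value, Status.CASE.value):
            values = frame.loc[frame["status"] == group, var]
            n = int(values.size)
            if n == 0:
                continue
            out.append(
                GroupSummary(
                    variable=var,
                    group=group,
                    n=n,
                    mean=float(values.mean()),
                    sd=float(values.std(ddof=1)) if n >= 2 else None,
                )
            )
    return out
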