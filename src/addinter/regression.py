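"""Logistic regression for the case-control design.

Two estimators are offered, both maximum likelihood:

* unconditional logistic regression with covariate adjustment (typically
  sex), Newton-Raphson to gradient tolerance 1e-8, covariance from the
  inverse observed information;
* conditional logistic regression for 1:1 matched pairs, which maximizes
  the conditional likelihood given each pair's case total and therefore
  uses only discordant pairs for a single binary exposure (McNemar
  identity: OR = ratio of discordant-pair counts).

The joint-exposure design codes the four (FH, BMI-abnormal) states as three
mutually exclusive indicators against the doubly-unexposed reference, so a
saturated unconditional fit reproduces the crude 2x4 odds ratios and their
Woolf variances exactly.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.discrete.conditional_models import ConditionalLogit
from statsmodels.tools.sm_exceptions import PerfectSeparationError

from .errors import ConvergenceError, ValidationError
from .records import StudyDataset

__all__ = [
    "Design",
    "Term",
    "ModelSpec",
    "FitResult",
    "fit_logistic",
    "fit_conditional_pairs",
    "joint_exposure_design",
    "JOINT_EXPOSURE_TERMS",
]

GRADIENT_TOL = 1e-8
MAX_ITER = 100


class Design(str, enum.Enum):
    UNCONDITIONAL = "unconditional"
    CONDITIONAL_PAIRS = "conditional_pairs"


@dataclass(frozen=True)
class Term:
    """One model term.

    ``kind`` is ``"binary"`` (0/1 indicator), ``"numeric"``, or
    ``"categorical"`` — the latter expands to indicator columns for every
    level except the stated ``reference``.
    """

    name: str
    kind: str = "binary"
    reference: str | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("binary", "numeric", "categorical"):
            raise ValidationError(f"unknown term kind {self.kind!r}")
        if self.kind == "categorical" and self.reference is None:
            raise ValidationError(
                f"categorical term {self.name!r} needs an explicit reference level"
            )


@dataclass(frozen=True)
class ModelSpec:
    terms: tuple[Term, ...]
    design: Design = Design.UNCONDITIONAL

    def __post_init__(self) -> None:
        if self.design is Design.CONDITIONAL_PAIRS:
            pass  # pair_id is taken from the dataset records


@dataclass
class FitResult:
    """Fitted coefficients with covariance and the derived OR table."""

    coefficients: pd.Series
    covariance: pd.DataFrame
    or_table: pd.DataFrame  # columns: OR, ci_low, ci_high, se, p
    loglik: float
    converged: bool
    n_used: int
    design: Design = Design.UNCONDITIONAL
    warnings: list[str] = field(default_factory=list)


def _record_value(rec, name: str):
    if hasattr(rec, name):
        value = getattr(rec, name)
        if isinstance(value, enum.Enum):
            return value.value
        return value
    if name in rec.extras:
        return rec.extras[name]
    raise ValidationError(f"no subject attribute or extra column {name!r}")


def build_design_matrix(
    dataset: StudyDataset, spec: ModelSpec, paired_only: bool = False
) -> tuple[np.ndarray, pd.DataFrame, np.ndarray]:
    """(y, X, pair ids) for the requested terms.

    X has no intercept column; the fitters add one where appropriate.
    """
    records = (
        dataset.paired_records()
        if (paired_only or spec.design is Design.CONDITIONAL_PAIRS)
        else dataset.records
    )
    if not records:
        raise ValidationError("no usable records for the requested design")
    y = np.array([1.0 if r.is_case else 0.0 for r in records])
    groups = np.array([r.pair_id for r in records])
    columns: dict[str, np.ndarray] = {}
    for term in spec.terms:
        raw = [_record_value(r, term.name) for r in records]
        if term.kind == "numeric":
            columns[term.name] = np.asarray(raw, dtype=float)
        elif term.kind == "binary":
            columns[term.name] = np.asarray(
                [float(bool(v)) if not isinstance(v, str) else float(v in ("1", "true", "yes", "male"))
                 for v in raw]
            )
        else:
            levels = sorted({str(v) for v in raw})
            if term.reference not in levels:
                raise ValidationError(
                    f"reference level {term.reference!r} absent from {term.name!r}"
                )
            for level in levels:
                if level == term.reference:
                    continue
                columns[f"{term.name}[{level}]"] = np.asarray(
                    [1.0 if str(v) == level else 0.0 for v in raw]
                )
    X = pd.DataFrame(columns)
    return y, X, groups


def _check_rank(X: pd.DataFrame, with_intercept: bool) -> None:
    mat = X.to_numpy(dtype=float)
    if with_intercept:
        mat = np.column_stack([np.ones(len(mat)), mat])
    if np.linalg.matrix_rank(mat) < mat.shape[1]:
        raise ConvergenceError(
            f"design matrix is rank deficient over columns {list(X.columns)}"
        )


def _or_table(params: pd.Series, cov: pd.DataFrame, alpha: float) -> pd.DataFrame:
    from scipy import stats

    z = stats.norm.ppf(1 - alpha / 2)
    se = np.sqrt(np.diag(cov.to_numpy()))
    rows = []
    for i, name in enumerate(params.index):
        b = params.iloc[i]
        rows.append(
            {
                "term": name,
                "coef": b,
                "se": se[i],
                "OR": np.exp(b),
                "ci_low": np.exp(b - z * se[i]),
                "ci_high": np.exp(b + z * se[i]),
                "p": 2 * stats.norm.sf(abs(b) / se[i]) if se[i] > 0 else np.nan,
            }
        )
    return pd.DataFrame(rows).set_index("term")


def fit_logistic(
    dataset: StudyDataset,
    spec: ModelSpec,
    alpha: float = 0.05,
) -> FitResult:
    """Unconditional logistic MLE (Newton, tol 1e-8, max 100 iterations)."""
    y, X, _ = build_design_matrix(dataset, spec)
    if y.min() == y.max():
        raise ValidationError("outcome is constant; cannot fit")
    _check_rank(X, with_intercept=True)
    Xc = sm.add_constant(X, prepend=True, has_constant="add")
    model = sm.Logit(y, Xc)
    try:
        fit = model.fit(method="newton", maxiter=MAX_ITER, tol=GRADIENT_TOL, disp=False)
    except (PerfectSeparationError, np.linalg.LinAlgError) as exc:
        raise ConvergenceError(f"logistic fit failed: {exc}") from exc
    if not fit.mle_retvals.get("converged", False):
        raise ConvergenceError(
            "logistic fit did not converge "
            f"in {MAX_ITER} Newton iterations (possible separation)"
        )
    params = pd.Series(fit.params, index=Xc.columns)
    cov = pd.DataFrame(fit.cov_params(), index=Xc.columns, columns=Xc.columns)
    table = _or_table(params.drop("const"), cov.drop("const").drop(columns="const"), alpha)
    return FitResult(
        coefficients=params,
        covariance=cov,
        or_table=table,
        loglik=float(fit.llf),
        converged=True,
        n_used=len(y),
        design=Design.UNCONDITIONAL,
    )


def fit_conditional_pairs(
    dataset: StudyDataset,
    spec: ModelSpec,
    alpha: float = 0.05,
) -> FitResult:
    """Conditional logistic MLE for the 1:1 matched design.

    Only complete pairs enter; pairs concordant on every term carry no
    information and an error is raised when no discordant pair exists for
    any term.
    """
    spec = ModelSpec(terms=spec.terms, design=Design.CONDITIONAL_PAIRS)
    y, X, groups = build_design_matrix(dataset, spec)
    if X.empty:
        raise ValidationError("model has no terms")
    frame = X.copy()
    frame["_group"] = groups
    discordant = frame.groupby("_group").nunique().drop(columns=[], errors="ignore")
    has_info = [
        col for col in X.columns if (discordant[col] > 1).any()
    ]
    missing = [col for col in X.columns if col not in has_info]
    if missing:
        raise ValidationError(
            f"no discordant pairs for term(s) {missing}; "
            "conditional likelihood is flat"
        )
    _check_rank(X, with_intercept=False)
    model = ConditionalLogit(y, X.to_numpy(), groups=groups)
    try:
        fit = model.fit(method="newton", maxiter=MAX_ITER, tol=GRADIENT_TOL,
                        disp=False)
    except (PerfectSeparationError, np.linalg.LinAlgError) as exc:
        raise ConvergenceError(f"conditional logistic fit failed: {exc}") from exc
    params = pd.Series(np.atleast_1d(fit.params), index=X.columns)
    if not np.all(np.isfinite(params)) or np.abs(params).max() > 30:
        raise ConvergenceError("conditional fit diverged (separation)")
    cov = pd.DataFrame(fit.cov_params(), index=X.columns, columns=X.columns)
    table = _or_table(params, cov, alpha)
    return FitResult(
        coefficients=params,
        covariance=cov,
        or_table=table,
        loglik=float(fit.llf),
        converged=True,
        n_used=len(y),
        design=Design.CONDITIONAL_PAIRS,
    )


#: names of the three joint-exposure indicator columns
JOINT_EXPOSURE_TERMS = ("fh_only", "bmi_only", "fh_and_bmi")


def joint_exposure_design(dataset: StudyDataset, paired_only: bool = False) -> pd.DataFrame:
    """Subject table with three mutually exclusive joint-exposure indicators.

    ``fh_only``, ``bmi_only`` and ``fh_and_bmi`` code the (FH, BMI-abnormal)
    states (1,0), (0,1) and (1,1) against the doubly-unexposed reference;
    exactly one indicator (or none, for the reference) is set per record.
    """
    records = dataset.paired_records() if paired_only else dataset.records
    rows = []
    for rec in records:
        fh, ab = rec.exposure_cell()
        rows.append(
            {
                "subject_id": rec.subject_id,
                "pair_id": rec.pair_id,
                "case": int(rec.is_case),
                "fh_only": int(fh == 1 and ab == 0),
                "bmi_only": int(fh == 0 and ab == 1),
                "fh_and_bmi": int(fh == 1 and ab == 1),
            }
        )
    return pd.DataFrame(rows)


def joint_exposure_spec(design: Design = Design.UNCONDITIONAL,
                        adjust_for_sex: bool = False) -> ModelSpec:
    """ModelSpec with the three joint-exposure indicators (optionally sex)."""
    terms = [Term("fh_only"), Term("bmi_only"), Term("fh_and_bmi")]
    if adjust_for_sex:
        terms.append(Term("male"))
    return ModelSpec(terms=tuple(terms), design=design)


def fit_joint_exposure(
    dataset: StudyDataset,
    design: Design = Design.UNCONDITIONAL,
    adjust_for_sex: bool = False,
    alpha: float = 0.05,
) -> FitResult:
    """Fit the joint-exposure model on indicators derived from the records.

    Helper used by the CLI: attaches the three indicators (and a ``male``
    dummy when adjusting for sex) as extras before fitting.
    """
    from .records import Sex

    for rec in dataset.records:
        fh, ab = rec.exposure_cell()
        rec.extras = dict(rec.extras)
        rec.extras["fh_only"] = int(fh == 1 and ab == 0)
        rec.extras["bmi_only"] = int(fh == 0 and ab == 1)
        rec.extras["fh_and_bmi"] = int(fh == 1 and ab == 1)
        rec.extras["male"] = int(rec.sex is Sex.MALE)
    spec = joint_exposure_spec(design=design, adjust_for_sex=adjust_for_sex)
    if design is Design.CONDITIONAL_PAIRS:
        if adjust_for_sex:
            # sex is matched, hence concordant within pairs: drop it
            spec = joint_exposure_spec(design=design, adjust_for_sex=False)
        return fit_conditional_pairs(dataset, spec, alpha=alpha)
    return fit_logistic(dataset, spec, alpha=alpha)
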