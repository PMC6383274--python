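"""Additive-interaction measures on the odds-ratio scale.

Given the three crude odds ratios from a 2x4 joint-exposure table —
OR11 (both factors), OR10 (factor A only), OR01 (factor B only), each
against the doubly-unexposed reference whose risk is normalized to 1 —
the four classic measures of departure from additivity are

    RERI = OR11 - OR10 - OR01 + 1          (relative excess risk due
                                            to interaction)
    AP   = RERI / OR11                      (attributable proportion)
    PAP  = RERI / (OR11 - 1)                ("pure" attributable proportion)
    SI   = (OR11 - 1) / ((OR10 - 1) + (OR01 - 1))   (synergy index)

Odds ratios stand in for the risk ratios of the defining formulas under the
rare-disease approximation, as is standard for case-control data. Exact
additivity of excess risks (OR11 = OR10 + OR01 - 1) gives RERI = AP =
PAP = 0 and SI = 1 simultaneously; RERI > 0 signals super-additive
(positive) interaction.

Confidence intervals come from two routes: the Hosmer-Lemeshow delta method
on the log-odds-ratio scale (SI handled on the log-SI scale), and a
design-respecting percentile bootstrap that resamples matched pairs.
"""

from __future__ import annotations

import enum
import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .contingency import ExposureTable2x4, build_exposure_table
from .errors import UndefinedMeasureError, ValidationError
from .records import StudyDataset

__all__ = [
    "InteractionClass",
    "MeasureEstimate",
    "InteractionMeasures",
    "reri",
    "synergy_index",
    "attributable_proportion",
    "pure_attributable_proportion",
    "compute_measures",
    "delta_ci",
    "bootstrap_ci",
    "bootstrap_all",
    "measures_from_table",
    "classify_interaction",
]

_MEASURES = ("reri", "ap", "pap", "si")


def _check_positive(**ors: float) -> None:
    for name, value in ors.items():
        if not value > 0:
            raise ValidationError(f"{name} must be positive, got {value!r}")


def reri(or11: float, or10: float, or01: float) -> float:
    """Relative excess risk due to interaction: OR11 - OR10 - OR01 + 1."""
    _check_positive(or11=or11, or10=or10, or01=or01)
    return or11 - or10 - or01 + 1.0


def synergy_index(or11: float, or10: float, or01: float) -> float:
    """Synergy index (OR11 - 1) / ((OR10 - 1) + (OR01 - 1)).

    Undefined when the summed excess risks in the denominator are not
    positive (both single-exposure ORs at or below 1): raises
    :class:`UndefinedMeasureError` rather than returning a sentinel.
    """
    _check_positive(or11=or11, or10=or10, or01=or01)
    denominator = (or10 - 1.0) + (or01 - 1.0)
    if denominator <= 0:
        raise UndefinedMeasureError(
            "synergy index undefined: (OR10 - 1) + (OR01 - 1) = "
            f"{denominator:.6g} is not positive"
        )
    return (or11 - 1.0) / denominator


def attributable_proportion(or11: float, or10: float, or01: float) -> float:
    """Proportion of the doubly-exposed risk attributable to interaction."""
    return reri(or11, or10, or01) / or11


def pure_attributable_proportion(or11: float, or10: float, or01: float) -> float:
    """Interaction's share of the doubly-exposed *excess* risk,
    RERI / (OR11 - 1); equals 1 - 1/SI. Requires OR11 > 1."""
    value = reri(or11, or10, or01)
    if or11 <= 1.0:
        raise UndefinedMeasureError(
            f"pure attributable proportion undefined for OR11 = {or11:.6g} <= 1"
        )
    return value / (or11 - 1.0)


class InteractionClass(str, enum.Enum):
    POSITIVE = "positive"
    NONE = "none"
    NEGATIVE = "negative"


@dataclass(frozen=True)
class MeasureEstimate:
    estimate: float
    ci_low: float | None = None
    ci_high: float | None = None
    method: str | None = None  # "delta" or "bootstrap"


@dataclass(frozen=True)
class InteractionMeasures:
    """The four additive-interaction measures with optional CIs."""

    reri: MeasureEstimate
    ap: MeasureEstimate
    si: MeasureEstimate | None
    pap: MeasureEstimate | None
    or11: float
    or10: float
    or01: float

    def classification(self) -> InteractionClass:
        return classify_interaction(self)

    def as_dict(self) -> dict:
        def one(m: MeasureEstimate | None):
            if m is None:
                return None
            return {
                "estimate": m.estimate,
                "ci_low": m.ci_low,
                "ci_high": m.ci_high,
                "method": m.method,
            }

        return {
            "or11": self.or11,
            "or10": self.or10,
            "or01": self.or01,
            "reri": one(self.reri),
            "ap": one(self.ap),
            "si": one(self.si),
            "pap": one(self.pap),
            "classification": self.classification().value,
        }


def compute_measures(or11: float, or10: float, or01: float) -> InteractionMeasures:
    """Point estimates of all four measures from an OR triple.

    SI and PAP are set to ``None`` where undefined (their defining
    denominators non-positive) instead of raising, so a partially defined
    result can still be reported.
    """
    r = reri(or11, or10, or01)
    ap = r / or11
    try:
        si = MeasureEstimate(synergy_index(or11, or10, or01))
    except UndefinedMeasureError:
        si = None
    try:
        pap = MeasureEstimate(pure_attributable_proportion(or11, or10, or01))
    except UndefinedMeasureError:
        pap = None
    return InteractionMeasures(
        reri=MeasureEstimate(r),
        ap=MeasureEstimate(ap),
        si=si,
        pap=pap,
        or11=or11,
        or10=or10,
        or01=or01,
    )


def classify_interaction(
    measures: InteractionMeasures | float,
) -> InteractionClass:
    """Positive iff RERI > 0 (equivalently SI > 1 when defined)."""
    value = measures.reri.estimate if isinstance(measures, InteractionMeasures) else measures
    if value > 0:
        return InteractionClass.POSITIVE
    if value < 0:
        return InteractionClass.NEGATIVE
    return InteractionClass.NONE


# --------------------------------------------------------------- delta CIs

def _gradients(measure: str, b: np.ndarray) -> tuple[float, np.ndarray, bool]:
    """(point value, gradient w.r.t. (b11, b10, b01), log-scale flag).

    ``b`` holds the log odds ratios. SI is propagated on the log-SI scale
    (the Hosmer-Lemeshow recommendation), so the returned point value and
    gradient are those of log SI and the flag asks for exponentiated bounds.
    PAP rides on SI through PAP = 1 - 1/SI.
    """
    t11, t10, t01 = np.exp(b)
    if measure == "reri":
        value = t11 - t10 - t01 + 1.0
        grad = np.array([t11, -t10, -t01])
        return value, grad, False
    if measure == "ap":
        value = (t11 - t10 - t01 + 1.0) / t11
        grad = np.array([(t10 + t01 - 1.0) / t11, -t10 / t11, -t01 / t11])
        return value, grad, False
    if measure == "si":
        numer = t11 - 1.0
        denom = (t10 - 1.0) + (t01 - 1.0)
        if numer <= 0 or denom <= 0:
            raise UndefinedMeasureError(
                "log synergy index undefined at the point estimate: "
                f"OR11 - 1 = {numer:.6g}, (OR10 - 1) + (OR01 - 1) = {denom:.6g}"
            )
        value = math.log(numer / denom)
        grad = np.array([t11 / numer, -t10 / denom, -t01 / denom])
        return value, grad, True
    raise ValueError(f"unknown measure {measure!r}")


def delta_ci(
    measure: str,
    log_or_estimates: np.ndarray,
    covariance: np.ndarray,
    alpha: float = 0.05,
) -> tuple[float, float]:
    """Delta-method confidence interval for one interaction measure.

    Parameters
    ----------
    measure
        One of ``"reri"``, ``"ap"``, ``"si"``, ``"pap"``.
    log_or_estimates
        Length-3 vector (log OR11, log OR10, log OR01).
    covariance
        3x3 covariance of those log odds ratios (e.g.
        :meth:`ExposureTable2x4.log_or_covariance` or a model covariance).

    RERI and AP get normal intervals on their own scale; SI is handled on
    the log scale with exponentiated bounds; the PAP interval is the
    monotone transform 1 - 1/SI of the SI interval.
    """
    b = np.asarray(log_or_estimates, dtype=float)
    cov = np.asarray(covariance, dtype=float)
    if b.shape != (3,) or cov.shape != (3, 3):
        raise ValidationError("expect a 3-vector of log ORs and a 3x3 covariance")
    if not np.allclose(cov, cov.T, atol=1e-10):
        raise ValidationError("covariance must be symmetric")
    if measure == "pap":
        si_low, si_high = delta_ci("si", b, cov, alpha=alpha)
        return (1.0 - 1.0 / si_low, 1.0 - 1.0 / si_high)
    value, grad, log_scale = _gradients(measure, b)
    variance = float(grad @ cov @ grad)
    if variance < 0:
        raise ValidationError("covariance is not positive semi-definite")
    z = stats.norm.ppf(1 - alpha / 2)
    half = z * math.sqrt(variance)
    low, high = value - half, value + half
    if log_scale:
        return (math.exp(low), math.exp(high))
    return (low, high)


# --------------------------------------------------------------- bootstrap

def _measure_from_triple(measure: str, triple: tuple[float, float, float]) -> float:
    or11, or10, or01 = triple
    if measure == "reri":
        return reri(or11, or10, or01)
    if measure == "ap":
        return attributable_proportion(or11, or10, or01)
    if measure == "si":
        return synergy_index(or11, or10, or01)
    if measure == "pap":
        return pure_attributable_proportion(or11, or10, or01)
    raise ValueError(f"unknown measure {measure!r}")


def _pair_cells(dataset: StudyDataset) -> tuple[np.ndarray, np.ndarray]:
    pairs = dataset.complete_pairs()
    if not pairs:
        raise ValidationError("dataset has no complete case-control pairs")
    case_cells = np.empty(len(pairs), dtype=np.intp)
    control_cells = np.empty(len(pairs), dtype=np.intp)
    for i, (case, control) in enumerate(pairs.values()):
        fh, ab = case.exposure_cell()
        case_cells[i] = 2 * fh + ab
        fh, ab = control.exposure_cell()
        control_cells[i] = 2 * fh + ab
    return case_cells, control_cells


def _replicate_triples(
    case_cells: np.ndarray,
    control_cells: np.ndarray,
    n_replicates: int,
    rng: np.random.Generator,
    continuity: bool,
) -> np.ndarray:
    """OR triples for pair-resampled replicates, shape (B, 3).

    Zero cells are handled by the Haldane-Anscombe +0.5 correction when
    ``continuity`` is set; otherwise the replicate's affected ORs become
    NaN and count as undefined.
    """
    n = case_cells.size
    idx = rng.integers(0, n, size=(n_replicates, n))
    case_counts = np.zeros((n_replicates, 4))
    control_counts = np.zeros((n_replicates, 4))
    offsets = np.arange(n_replicates)[:, None] * 4
    case_counts.reshape(-1)[:] = np.bincount(
        (case_cells[idx] + offsets).ravel(), minlength=n_replicates * 4
    )
    control_counts.reshape(-1)[:] = np.bincount(
        (control_cells[idx] + offsets).ravel(), minlength=n_replicates * 4
    )
    if continuity:
        zero = (case_counts == 0) | (control_counts == 0)
        bump = zero.any(axis=1, keepdims=True)
        case_counts = case_counts + 0.5 * bump
        control_counts = control_counts + 0.5 * bump
    with np.errstate(divide="ignore", invalid="ignore"):
        odds = case_counts / control_counts
        triples = np.stack(
            [odds[:, 3] / odds[:, 0], odds[:, 2] / odds[:, 0], odds[:, 1] / odds[:, 0]],
            axis=1,
        )
    triples[~np.isfinite(triples)] = np.nan
    return triples


def bootstrap_ci(
    dataset: StudyDataset,
    measure: str,
    n_replicates: int = 2000,
    seed: int | None = None,
    alpha: float = 0.05,
    continuity: bool = True,
) -> tuple[float, float]:
    """Percentile bootstrap CI resampling matched pairs with replacement.

    The resampling unit is the complete case-control pair, preserving the
    matched design. Replicates where the measure is undefined are dropped
    and counted; more than 20% undefined attaches a warning.
    """
    if n_replicates < 100:
        raise ValidationError("need at least 100 bootstrap replicates")
    if seed is None:
        raise ValidationError("bootstrap seed is required for reproducibility")
    result = bootstrap_all(
        dataset,
        n_replicates=n_replicates,
        seed=seed,
        alpha=alpha,
        continuity=continuity,
        measures=(measure,),
    )
    return result[measure]


def bootstrap_all(
    dataset: StudyDataset,
    n_replicates: int = 2000,
    seed: int | None = None,
    alpha: float = 0.05,
    continuity: bool = True,
    measures: tuple[str, ...] = _MEASURES,
) -> dict[str, tuple[float, float]]:
    """Percentile bootstrap CIs for several measures from one resampling."""
    if seed is None:
        raise ValidationError("bootstrap seed is required for reproducibility")
    rng = np.random.default_rng(seed)
    case_cells, control_cells = _pair_cells(dataset)
    triples = _replicate_triples(
        case_cells, control_cells, n_replicates, rng, continuity
    )
    or11, or10, or01 = triples[:, 0], triples[:, 1], triples[:, 2]
    out: dict[str, tuple[float, float]] = {}
    with np.errstate(divide="ignore", invalid="ignore"):
        values = {
            "reri": or11 - or10 - or01 + 1.0,
            "ap": (or11 - or10 - or01 + 1.0) / or11,
            "si": np.where(
                (or10 - 1) + (or01 - 1) > 0,
                (or11 - 1.0) / ((or10 - 1.0) + (or01 - 1.0)),
                np.nan,
            ),
            "pap": np.where(
                or11 > 1, (or11 - or10 - or01 + 1.0) / (or11 - 1.0), np.nan
            ),
        }
    for measure in measures:
        if measure not in values:
            raise ValueError(f"unknown measure {measure!r}")
        draws = values[measure]
        defined = draws[np.isfinite(draws)]
        n_undef = n_replicates - defined.size
        if defined.size == 0:
            raise UndefinedMeasureError(
                f"{measure} undefined in every bootstrap replicate"
            )
        if n_undef > 0.2 * n_replicates:
            warnings.warn(
                f"{measure}: {n_undef}/{n_replicates} bootstrap replicates "
                "had an undefined value; percentile interval uses the rest",
                stacklevel=2,
            )
        out[measure] = (
            float(np.quantile(defined, alpha / 2)),
            float(np.quantile(defined, 1 - alpha / 2)),
        )
    return out


# ----------------------------------------------------------- full pipeline

def measures_from_table(
    table: ExposureTable2x4,
    alpha: float = 0.05,
    continuity: bool = False,
) -> InteractionMeasures:
    """Point estimates + delta-method CIs straight from a 2x4 table."""
    or11, or10, or01 = table.or_triple(continuity=continuity)
    b = np.log([or11, or10, or01])
    cov = table.log_or_covariance(continuity=continuity)
    point = compute_measures(or11, or10, or01)

    def with_ci(m: MeasureEstimate | None, name: str) -> MeasureEstimate | None:
        if m is None:
            return None
        try:
            low, high = delta_ci(name, b, cov, alpha=alpha)
        except UndefinedMeasureError:
            return m
        return MeasureEstimate(m.estimate, low, high, "delta")

    return InteractionMeasures(
        reri=with_ci(point.reri, "reri"),
        ap=with_ci(point.ap, "ap"),
        si=with_ci(point.si, "si"),
        pap=with_ci(point.pap, "pap"),
        or11=or11,
        or10=or10,
        or01=or01,
    )


def measures_from_dataset(
    dataset: StudyDataset,
    alpha: float = 0.05,
    continuity: bool = False,
    bootstrap: int | None = None,
    seed: int | None = None,
    paired_only: bool = False,
) -> dict[str, InteractionMeasures]:
    """Delta-method measures, plus bootstrap-CI measures when requested.

    The crude 2x4 table is unconditional, so by default every valid record
    contributes; the bootstrap always resamples complete pairs. Returns a
    dict with key ``"delta"`` and, if ``bootstrap`` replicates were
    requested, ``"bootstrap"``.
    """
    table = build_exposure_table(dataset, paired_only=paired_only)
    out = {"delta": measures_from_table(table, alpha=alpha, continuity=continuity)}
    if bootstrap:
        cis = bootstrap_all(
            dataset, n_replicates=bootstrap, seed=seed, alpha=alpha
        )
        delta = out["delta"]

        def wrap(m: MeasureEstimate | None, name: str) -> MeasureEstimate | None:
            if m is None:
                return None
            low, high = cis[name]
            return MeasureEstimate(m.estimate, low, high, "bootstrap")

        out["bootstrap"] = InteractionMeasures(
            reri=wrap(delta.reri, "reri"),
            ap=wrap(delta.ap, "ap"),
            si=wrap(delta.si, "si"),
            pap=wrap(delta.pap, "pap"),
            or11=delta.or11,
            or10=delta.or10,
            or01=delta.or01,
        )
    return out
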