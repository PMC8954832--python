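"""Confusion matrices, chance-corrected performance metrics and library
characterization.

The binary task fixes PGI Sunite lamb as the positive class.  Besides
sensitivity, specificity and accuracy, the report carries Cohen's kappa,

    kappa = (P0 - Pe) / (1 - Pe),

where P0 is the accuracy and Pe the agreement expected by chance from the
marginal totals; kappa is graded excellent (> 0.75), good (0.40 < k <= 0.75)
or poor (k <= 0.40).  Kappa is preferred over raw accuracy here because the
test set is imbalanced (few non-PGI samples), so a classifier ignoring the
minority class can still post a high accuracy.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
from scipy import stats

from .data import ISOTOPES, NON_PGI, PGI, IsotopeLibrary

__all__ = [
    "ConfusionMatrix",
    "PerformanceReport",
    "LibraryCharacterization",
    "confusion",
    "metrics",
    "characterize",
    "round_half_up",
]

GRADE_EXCELLENT = "excellent"
GRADE_GOOD = "good"
GRADE_POOR = "poor"


@dataclass(frozen=True)
class ConfusionMatrix:
    TP: int
    FN: int
    TN: int
    FP: int

    def __post_init__(self) -> None:
        if min(self.TP, self.FN, self.TN, self.FP) < 0:
            raise ValueError("confusion-matrix counts must be non-negative")
        if self.total == 0:
            raise ValueError("confusion matrix must contain at least one sample")

    @property
    def total(self) -> int:
        return self.TP + self.FN + self.TN + self.FP


@dataclass(frozen=True)
class PerformanceReport:
    sensitivity: float
    specificity: float
    accuracy: float
    Pe: float
    kappa: float
    grade: str


@dataclass
class LibraryCharacterization:
    """Per-isotope descriptives plus the between-group Welch t-test."""

    mean: dict[str, float]
    sd: dict[str, float]
    minimum: dict[str, float]
    maximum: dict[str, float]
    t_statistic: dict[str, float] | None
    p_value: dict[str, float] | None


def confusion(actual, predicted, positive: str = PGI) -> ConfusionMatrix:
    """Tabulate binary predictions against truth with the given positive class."""
    actual, predicted = list(actual), list(predicted)
    if not actual or len(actual) != len(predicted):
        raise ValueError("actual and predicted must be equal-length, non-empty")
    known = {PGI, NON_PGI}
    for lab in set(actual) | set(predicted):
        if lab not in known:
            raise ValueError(f"unknown label {lab!r}")
    tp = sum(a == positive and p == positive for a, p in zip(actual, predicted))
    fn = sum(a == positive and p != positive for a, p in zip(actual, predicted))
    tn = sum(a != positive and p != positive for a, p in zip(actual, predicted))
    fp = sum(a != positive and p == positive for a, p in zip(actual, predicted))
    return ConfusionMatrix(TP=tp, FN=fn, TN=tn, FP=fp)


def metrics(cm: ConfusionMatrix) -> PerformanceReport:
    """Sensitivity, specificity, accuracy, chance agreement and graded kappa."""
    if cm.TP + cm.FN == 0:
        raise ValueError("no positive samples: sensitivity undefined")
    if cm.TN + cm.FP == 0:
        raise ValueError("no negative samples: specificity undefined")
    total = cm.total
    sensitivity = cm.TP / (cm.TP + cm.FN)
    specificity = cm.TN / (cm.TN + cm.FP)
    p0 = (cm.TP + cm.TN) / total
    pe = ((cm.TP + cm.FN) * (cm.TP + cm.FP) + (cm.TN + cm.FN) * (cm.TN + cm.FP)) / total**2
    if pe == 1.0:
        kappa = 1.0 if p0 == 1.0 else 0.0  # degenerate marginals
    else:
        kappa = (p0 - pe) / (1 - pe)
    if kappa > 0.75:
        grade = GRADE_EXCELLENT
    elif kappa > 0.40:
        grade = GRADE_GOOD
    else:
        grade = GRADE_POOR
    return PerformanceReport(
        sensitivity=sensitivity,
        specificity=specificity,
        accuracy=p0,
        Pe=pe,
        kappa=kappa,
        grade=grade,
    )


def round_half_up(value: float, decimals: int = 4) -> float:
    """Report-style rounding (half away from zero), e.g. 0.74444 -> 0.7444."""
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def characterize(lib: IsotopeLibrary) -> LibraryCharacterization:
    """Descriptive statistics per isotope, plus a Welch two-sample t-test
    between the PGI and non-PGI groups when both are present.

    The unequal-variance (Welch) form is used: the two groups' spreads
    differ visibly (non-PGI d2H is twice as dispersed as PGI).
    """
    X = lib.values
    mean = {iso: float(m) for iso, m in zip(ISOTOPES, X.mean(axis=0))}
    sd = {iso: float(s) for iso, s in zip(ISOTOPES, X.std(axis=0, ddof=1) if len(lib) > 1 else np.zeros(4))}
    minimum = {iso: float(v) for iso, v in zip(ISOTOPES, X.min(axis=0))}
    maximum = {iso: float(v) for iso, v in zip(ISOTOPES, X.max(axis=0))}

    groups = np.array(lib.groups)
    a, b = X[groups == PGI], X[groups == NON_PGI]
    t_stat = p_val = None
    if len(a) >= 2 and len(b) >= 2:
        t_stat, p_val = {}, {}
        for j, iso in enumerate(ISOTOPES):
            with np.errstate(invalid="ignore"), warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                res = stats.ttest_ind(a[:, j], b[:, j], equal_var=False)
            t_stat[iso] = float(res.statistic)
            p_val[iso] = float(res.pvalue)
        if any(not np.isfinite(v) for v in t_stat.values()):
            t_stat = p_val = None  # degenerate (zero-variance) groups
    return LibraryCharacterization(
        mean=mean, sd=sd, minimum=minimum, maximum=maximum,
        t_statistic=t_stat, p_value=p_val,
    )
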