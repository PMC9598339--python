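"""Classifier metrics, score testing, reference ranges, unit conversion.

The "positive" class throughout is DM&HBP (disease): sensitivity is the
fraction of DM&HBP units called DM&HBP, specificity the fraction of
controls called control.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP

import numpy as np
from scipy import stats

from .core import ANALYTES, BiomarkerPanel, Group, ReferenceRange, Sex
from .chemometrics import PCAResult

__all__ = [
    "ConfusionMatrix",
    "ClassMetrics",
    "GroupComparison",
    "MOLAR_MASS_G_PER_MOL",
    "TABLE_REFERENCE_RANGES",
    "confusion_matrix",
    "classification_metrics",
    "compare_component_scores",
    "convert_concentration",
    "flag_above_reference",
    "cohort_above_reference",
    "round_percent",
]

#: Molar masses (g/mol) for mmol/L <-> mg/dL conversion.
MOLAR_MASS_G_PER_MOL = {
    "urea": 60.06,
    "creatinine": 113.12,
    "glucose": 180.16,
}

#: Clinical reference ranges for the five urine analytes (Wu's handbook
#: values in SI units): urea/creatinine/phosphate sex-specific in mmol/L,
#: glucose an upper bound only, total protein in mg/dL.
TABLE_REFERENCE_RANGES = [
    ReferenceRange("urea", Sex.M, 51.6, 549.0),
    ReferenceRange("urea", Sex.W, 46.9, 580.0),
    ReferenceRange("creatinine", Sex.M, 2.12, 34.6),
    ReferenceRange("creatinine", Sex.W, 1.4, 28.9),
    ReferenceRange("glucose", Sex.UNKNOWN, None, 0.83),
    ReferenceRange("phosphate", Sex.M, 1.6, 61.0),
    ReferenceRange("phosphate", Sex.W, 2.3, 48.0),
    ReferenceRange("total_protein", Sex.UNKNOWN, 1.0, 15.0),
]


@dataclass(frozen=True)
class ConfusionMatrix:
    """2x2 counts with CT as negative and DMHBP as positive class."""

    tn: int  # CT predicted CT
    fp: int  # CT predicted DMHBP
    fn: int  # DMHBP predicted CT
    tp: int  # DMHBP predicted DMHBP

    def __post_init__(self) -> None:
        counts = (self.tn, self.fp, self.fn, self.tp)
        if any(c < 0 for c in counts):
            raise ValueError("confusion counts must be non-negative")
        if sum(counts) < 1:
            raise ValueError("confusion matrix must contain at least one unit")

    @property
    def total(self) -> int:
        return self.tn + self.fp + self.fn + self.tp


@dataclass(frozen=True)
class ClassMetrics:
    """Sensitivity (DMHBP recall), specificity (CT recall), accuracy."""

    sensitivity: float
    specificity: float
    accuracy: float

    def as_percent(self, decimals: int = 1) -> dict[str, float]:
        """Half-up rounded percentages for report display."""
        return {
            "sensitivity": round_percent(self.sensitivity, decimals),
            "specificity": round_percent(self.specificity, decimals),
            "accuracy": round_percent(self.accuracy, decimals),
        }


def round_percent(fraction: float, decimals: int = 1) -> float:
    """Round a fraction to a percentage with half-up ties (report style)."""
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(fraction * 100.0)).quantize(q, rounding=ROUND_HALF_UP))


def confusion_matrix(truth, predicted) -> ConfusionMatrix:
    """Tally a 2x2 confusion matrix from parallel label sequences."""
    if len(truth) != len(predicted) or len(truth) == 0:
        raise ValueError("truth and predicted must have equal, nonzero length")

    def _g(lab) -> Group:
        return lab if isinstance(lab, Group) else Group(lab)

    tn = fp = fn = tp = 0
    for t, p in zip(truth, predicted):
        t, p = _g(t), _g(p)
        if t == Group.CT:
            if p == Group.CT:
                tn += 1
            else:
                fp += 1
        else:
            if p == Group.CT:
                fn += 1
            else:
                tp += 1
    return ConfusionMatrix(tn=tn, fp=fp, fn=fn, tp=tp)


def classification_metrics(cm: ConfusionMatrix) -> ClassMetrics:
    """Sensitivity, specificity and overall accuracy of a 2x2 table."""
    if cm.tp + cm.fn == 0:
        raise ZeroDivisionError("no DMHBP units: sensitivity undefined")
    if cm.tn + cm.fp == 0:
        raise ZeroDivisionError("no CT units: specificity undefined")
    return ClassMetrics(
        sensitivity=cm.tp / (cm.tp + cm.fn),
        specificity=cm.tn / (cm.tn + cm.fp),
        accuracy=(cm.tp + cm.tn) / cm.total,
    )


@dataclass(frozen=True)
class GroupComparison:
    """Two-group comparison of PCA score values on one component.

    Normality is screened per group by a Kolmogorov-Smirnov test against a
    normal with the sample mean and SD (alpha = 0.1); the pooled-variance
    two-tailed Student's t-test is always computed, and ``normal_ct`` /
    ``normal_dm`` flag where the normality screen failed.
    """

    component_index: int
    ks_p_ct: float
    ks_p_dm: float
    t_statistic: float
    t_p: float
    significant: bool  # t_p < 0.05
    normal_ct: bool  # ks_p >= 0.1
    normal_dm: bool


def _ks_normality_p(x: np.ndarray) -> float:
    sd = np.std(x, ddof=1)
    if sd == 0:
        return 0.0
    return float(stats.kstest(x, "norm", args=(np.mean(x), sd)).pvalue)


def compare_component_scores(
    pca: PCAResult, groups, component_index: int
) -> GroupComparison:
    """t-test a PCA component's scores between the CT and DM&HBP groups."""
    groups = np.asarray(
        [g.value if isinstance(g, Group) else str(g) for g in groups]
    )
    scores = pca.scores[:, component_index]
    a = scores[groups == Group.CT.value]
    b = scores[groups == Group.DMHBP.value]
    if a.size < 3 or b.size < 3:
        raise ValueError("each group needs at least 3 score values")
    if np.std(a) == 0 and np.std(b) == 0:
        raise ValueError("zero-variance scores in both groups: test undefined")
    t_stat, t_p = stats.ttest_ind(b, a, equal_var=True)
    ks_a, ks_b = _ks_normality_p(a), _ks_normality_p(b)
    return GroupComparison(
        component_index=component_index,
        ks_p_ct=ks_a,
        ks_p_dm=ks_b,
        t_statistic=float(t_stat),
        t_p=float(t_p),
        significant=bool(t_p < 0.05),
        normal_ct=bool(ks_a >= 0.1),
        normal_dm=bool(ks_b >= 0.1),
    )


def convert_concentration(value: float, analyte: str, direction: str) -> float:
    """Convert mmol/L <-> mg/dL via molar mass (mg/dL = mmol/L * M / 10).

    ``direction`` is ``"mmolL_to_mgdL"`` or ``"mgdL_to_mmolL"``.  Analytes
    without a registered molar mass (phosphate as measured, total protein)
    are not convertible.
    """
    if value < 0:
        raise ValueError("concentration must be >= 0")
    if analyte not in MOLAR_MASS_G_PER_MOL:
        raise ValueError(
            f"no molar mass registered for {analyte!r}; conversion unsupported"
        )
    m = MOLAR_MASS_G_PER_MOL[analyte]
    if direction == "mmolL_to_mgdL":
        return value * m / 10.0
    if direction == "mgdL_to_mmolL":
        return value * 10.0 / m
    raise ValueError(f"unknown direction {direction!r}")


def _applicable_upper(ranges, analyte: str, sex: Sex):
    matches = [r for r in ranges if r.analyte == analyte]
    if not matches:
        raise ValueError(f"no reference range registered for analyte {analyte!r}")
    exact = [r for r in matches if r.sex == sex]
    if exact:
        return exact[0].upper
    anysex = [r for r in matches if r.sex == Sex.UNKNOWN]
    if anysex:
        return anysex[0].upper
    # unknown sex with only sex-specific ranges: fall back to the wider
    # (larger) upper bound so nobody is flagged on the stricter sex's range
    uppers = [r.upper for r in matches if r.upper is not None]
    return max(uppers) if uppers else None


def flag_above_reference(
    panel: BiomarkerPanel,
    ranges=None,
    sex: Sex = Sex.UNKNOWN,
) -> dict[str, bool]:
    """Flag analytes strictly above their applicable upper reference bound.

    A value exactly at the bound is not flagged.  With unknown sex the
    wider of the men's/women's bounds applies.
    """
    ranges = TABLE_REFERENCE_RANGES if ranges is None else ranges
    out = {}
    for a in ANALYTES:
        upper = _applicable_upper(ranges, a, sex)
        out[a] = bool(upper is not None and panel[a] > upper)
    return out


def cohort_above_reference(panels, ranges=None, sexes=None) -> dict[str, tuple[int, int]]:
    """Per-analyte (n flagged, n total) over a cohort of panels."""
    ranges = TABLE_REFERENCE_RANGES if ranges is None else ranges
    sexes = [Sex.UNKNOWN] * len(panels) if sexes is None else list(sexes)
    counts = {a: 0 for a in ANALYTES}
    for p, sx in zip(panels, sexes):
        flags = flag_above_reference(p, ranges, sx)
        for a in ANALYTES:
            counts[a] += int(flags[a])
    return {a: (counts[a], len(panels)) for a in ANALYTES}
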