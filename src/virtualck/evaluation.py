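"""Agreement between machine (dTSR) and pathologist (vTSR) TSR calls.

A 2x2 contingency table crosses the dichotomized labels; Cohen's kappa
corrects the observed agreement for chance, and the continuous dTSR scores
against binary vTSR truth give an ROC curve whose AUC is computed as the
normalized rank sum (ties credited one half), which equals the trapezoidal
area under the empirical curve.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
from scipy.stats import rankdata
from sklearn.metrics import roc_curve

__all__ = [
    "ContingencyTable2x2",
    "ROCCurve",
    "build_contingency",
    "cohen_kappa",
    "roc_auc",
    "agreement_report",
    "UndefinedKappaError",
]

LOW, HIGH = "low", "high"


class UndefinedKappaError(ValueError):
    """Raised when expected agreement is 1 (all mass in one cell)."""


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts: rows = vTSR {low, high}, columns = dTSR {low, high}.

    ``a`` = (vTSR-low, dTSR-low), ``b`` = (vTSR-low, dTSR-high),
    ``c`` = (vTSR-high, dTSR-low), ``d`` = (vTSR-high, dTSR-high).
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for v in (self.a, self.b, self.c, self.d):
            if v < 0 or int(v) != v:
                raise ValueError("counts must be non-negative integers")
        if self.n < 1:
            raise ValueError("table must contain at least one observation")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d


@dataclass
class ROCCurve:
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float


def _check_labels(labels) -> list[str]:
    out = []
    for v in labels:
        s = str(v).lower().replace("vtsr-", "").replace("dtsr-", "")
        if s not in (LOW, HIGH):
            raise ValueError(f"label must be 'low' or 'high', got {v!r}")
        out.append(s)
    return out


def build_contingency(vtsr_labels, dtsr_labels) -> ContingencyTable2x2:
    """Cross-tabulate paired low/high label lists (order-invariant)."""
    v = _check_labels(vtsr_labels)
    d = _check_labels(dtsr_labels)
    if len(v) != len(d):
        raise ValueError("label lists must have equal length")
    a = sum(1 for x, y in zip(v, d) if x == LOW and y == LOW)
    b = sum(1 for x, y in zip(v, d) if x == LOW and y == HIGH)
    c = sum(1 for x, y in zip(v, d) if x == HIGH and y == LOW)
    dd = sum(1 for x, y in zip(v, d) if x == HIGH and y == HIGH)
    return ContingencyTable2x2(a, b, c, dd)


def cohen_kappa(table: ContingencyTable2x2) -> float:
    """Chance-corrected agreement: (p_o - p_e) / (1 - p_e)."""
    n = table.n
    a, b, c, d = table.a, table.b, table.c, table.d
    p_o = (a + d) / n
    p_e = ((a + b) * (a + c) + (c + d) * (b + d)) / n**2
    if p_e == 1.0:
        raise UndefinedKappaError("expected agreement is 1; kappa undefined")
    return (p_o - p_e) / (1.0 - p_e)


def roc_auc(scores, truth) -> ROCCurve:
    """ROC of continuous dTSR percents against binary vTSR truth.

    Positive class is vTSR-high (label 1).  AUC is the Mann-Whitney
    rank-sum statistic normalized by n_pos * n_neg, with tied score pairs
    counting one half.
    """
    s = np.asarray(scores, dtype=float)
    t = np.asarray([1 if str(v).lower() in ("1", "high", "vtsr-high", "true") else 0 for v in truth])
    if s.shape != t.shape:
        raise ValueError("scores and truth must have equal length")
    n_pos, n_neg = int(t.sum()), int((1 - t).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    ranks = rankdata(s)  # average ranks handle ties -> half credit
    auc = (ranks[t == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)
    fpr, tpr, thr = roc_curve(t, s)
    return ROCCurve(fpr=fpr, tpr=tpr, thresholds=thr, auc=float(auc))


def _round2(x: float) -> float:
    return float(Decimal(repr(x)).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def agreement_report(table: ContingencyTable2x2) -> dict:
    """Marginal and column-conditional percentages, observed agreement, kappa.

    Percentages are rounded half-up to two decimals, mirroring how such
    tables are conventionally printed.
    """
    n = table.n
    a, b, c, d = table.a, table.b, table.c, table.d
    col_low, col_high = a + c, b + d
    report = {
        "n": n,
        "counts": {"a": a, "b": b, "c": c, "d": d},
        "dtsr_low_n": col_low,
        "dtsr_high_n": col_high,
        "dtsr_low_pct": _round2(100.0 * col_low / n),
        "dtsr_high_pct": _round2(100.0 * col_high / n),
        "vtsr_low_n": a + b,
        "vtsr_high_n": c + d,
        "vtsr_low_pct": _round2(100.0 * (a + b) / n),
        "vtsr_high_pct": _round2(100.0 * (c + d) / n),
        "within_dtsr_low": {
            "vtsr_low_pct": _round2(100.0 * a / col_low) if col_low else None,
            "vtsr_high_pct": _round2(100.0 * c / col_low) if col_low else None,
        },
        "within_dtsr_high": {
            "vtsr_low_pct": _round2(100.0 * b / col_high) if col_high else None,
            "vtsr_high_pct": _round2(100.0 * d / col_high) if col_high else None,
        },
        "observed_agreement": (a + d) / n,
    }
    try:
        report["kappa"] = cohen_kappa(table)
    except UndefinedKappaError:
        report["kappa"] = None
    return report
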