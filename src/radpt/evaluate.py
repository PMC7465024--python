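"""ROC/AUC analysis, risk stratification tables, and PI-RADS comparison."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

RISK_ROWS = ("H", "I", "L")


@dataclass
class ROCResult:
    thresholds: np.ndarray
    tpr: np.ndarray
    fpr: np.ndarray
    auc: float


def roc_auc(scores, labels) -> ROCResult:
    """ROC curve and trapezoidal AUC.

    Tied scores collapse onto one threshold, so the trapezoidal area
    equals the Mann-Whitney concordance probability U/(n1*n0) with
    half-credit for tied pairs.
    """
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(int)
    n1 = int((y == 1).sum())
    n0 = int((y == 0).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("AUC undefined: both classes must be present")
    order = np.argsort(-scores, kind="stable")
    s = scores[order]
    t = y[order]
    # threshold boundaries where the score value changes
    distinct = np.flatnonzero(np.diff(s)) + 1
    cut = np.concatenate([[0], distinct, [s.size]])
    tp = np.cumsum(t)
    fp = np.cumsum(1 - t)
    tpr = np.concatenate([[0.0], tp[cut[1:] - 1] / n1])
    fpr = np.concatenate([[0.0], fp[cut[1:] - 1] / n0])
    auc = float(np.trapezoid(tpr, fpr))
    thresholds = np.concatenate([[np.inf], s[cut[1:] - 1]])
    return ROCResult(thresholds=thresholds, tpr=tpr, fpr=fpr, auc=auc)


def binarize_pirads(scores) -> np.ndarray:
    """PI-RADS 1-2 -> "low", 3-5 -> "high" (vectorised)."""
    s = np.asarray(scores)
    if np.any((s < 1) | (s > 5)):
        raise ValueError("PI-RADS scores must lie in 1..5")
    return np.where(s >= 3, "high", "low")


@dataclass
class StratificationTable:
    """DRCS rows x predicted high/low columns for one or more methods."""

    counts: pd.DataFrame  # index: H/I/L; columns: (method, high/low)
    totals: pd.Series

    def per_class_accuracy(self, method: str) -> dict[str, float]:
        """correct-high/total-high and correct-low/total-low, in percent."""
        high_total = self.totals["H"]
        low_total = self.totals["L"]
        return {
            "high": 100.0 * self.counts.loc["H", (method, "high")] / high_total,
            "low": 100.0 * self.counts.loc["L", (method, "low")] / low_total,
        }

    def overall_accuracy(self, method: str) -> float:
        """(correct high + correct low) / all lesions (intermediates count
        in the denominator), in percent."""
        correct = (self.counts.loc["H", (method, "high")]
                   + self.counts.loc["L", (method, "low")])
        return 100.0 * correct / self.totals.sum()


def stratification_table(drcs_labels, **predictions) -> StratificationTable:
    """Cross-tabulate true DRCS categories against binary predictions.

    Each keyword argument is a method name mapped to a vector of
    ``"high"`` / ``"low"`` predictions aligned with ``drcs_labels``.
    """
    r = np.asarray(drcs_labels)
    if not set(np.unique(r)) <= {"H", "I", "L"}:
        raise ValueError("DRCS labels must be H/I/L")
    data = {}
    for method, pred in predictions.items():
        p = np.asarray(pred)
        if p.shape != r.shape:
            raise ValueError(f"prediction length mismatch for {method!r}")
        if not set(np.unique(p)) <= {"high", "low"}:
            raise ValueError(f"predictions for {method!r} must be high/low")
        for cat in ("high", "low"):
            data[(method, cat)] = [
                int(np.sum((r == row) & (p == cat))) for row in RISK_ROWS
            ]
    counts = pd.DataFrame(data, index=list(RISK_ROWS))
    counts.columns = pd.MultiIndex.from_tuples(counts.columns)
    totals = pd.Series({row: int(np.sum(r == row)) for row in RISK_ROWS})
    return StratificationTable(counts=counts, totals=totals)


def table_from_counts(counts: dict[str, dict[str, int]]) -> StratificationTable:
    """Build a StratificationTable directly from printed confusion counts.

    ``counts`` maps method name -> {"H": (high, low), "I": ..., "L": ...}
    giving the number of truly H/I/L lesions predicted high and low.
    """
    labels = []
    preds: dict[str, list] = {m: [] for m in counts}
    first = next(iter(counts))
    for row in RISK_ROWS:
        hi, lo = counts[first][row]
        labels += [row] * (hi + lo)
    for method, table in counts.items():
        for row in RISK_ROWS:
            hi, lo = table[row]
            if hi + lo != sum(1 for x in labels if x == row):
                raise ValueError("methods disagree on row totals")
            preds[method] += ["high"] * hi + ["low"] * lo
    return stratification_table(np.asarray(labels), **{
        m: np.asarray(v) for m, v in preds.items()
    })
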