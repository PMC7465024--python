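"""Wilcoxon rank-sum prefilter + MRMR ranking of the top-k features.

The prefilter keeps features whose two-sided rank-sum p-value is below
an unadjusted threshold (default 0.01); survivors are then greedily
ranked by the MRMR difference criterion (relevance minus mean redundancy,
plug-in mutual information on equal-frequency bins).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from radpt.features import feature_columns


@dataclass
class SelectionResult:
    """Rank-ordered surviving features with p-values and MRMR scores."""

    features: list[str]
    p_values: dict[str, float]
    mrmr_scores: dict[str, float]
    setting: str = ""
    pool: str = ""

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "rank": np.arange(1, len(self.features) + 1),
                "feature": self.features,
                "p_value": [self.p_values[f] for f in self.features],
                "mrmr_score": [self.mrmr_scores[f] for f in self.features],
            }
        )


def ranksum_test(group0, group1) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    Exact enumeration for n0 + n1 <= 12 without ties; otherwise the
    normal approximation with tie and continuity corrections.  Fully
    tied data yields p = 1.
    """
    x = np.asarray(group0, dtype=float)
    y = np.asarray(group1, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be nonempty")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return float(x.size * y.size) / 2.0, 1.0
    small = x.size + y.size <= 12
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (small and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method,
                             use_continuity=True)
    return float(res.statistic), float(min(res.pvalue, 1.0))


def _equal_freq_bins(x: np.ndarray, n_bins: int) -> np.ndarray:
    """Discretize a continuous vector into (at most) equal-frequency bins."""
    qs = np.quantile(x, np.linspace(0, 1, n_bins + 1)[1:-1])
    edges = np.unique(qs)
    return np.searchsorted(edges, x, side="left")


def _codes(arr, n_bins: int) -> np.ndarray:
    a = np.asarray(arr)
    if a.dtype.kind in "OUSb" or np.unique(a).size <= n_bins:
        _, codes = np.unique(a, return_inverse=True)
        return codes
    return _equal_freq_bins(a.astype(float), n_bins)


def mutual_information(x, y, n_bins: int = 10) -> float:
    """Plug-in mutual information (nats) on equal-frequency bins.

    Discrete-valued arguments (labels, or anything with <= n_bins
    distinct values) are used as-is.  Constant arguments give 0.
    """
    cx = _codes(x, n_bins)
    cy = _codes(y, n_bins)
    if cx.size != cy.size:
        raise ValueError("arguments must be the same length")
    nx, ny = cx.max() + 1, cy.max() + 1
    if nx < 2 or ny < 2:
        return 0.0
    joint = np.bincount(cx * ny + cy, minlength=nx * ny).reshape(nx, ny)
    p = joint / joint.sum()
    px = p.sum(axis=1, keepdims=True)
    py = p.sum(axis=0, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(p > 0, p * np.log(p / (px * py)), 0.0)
    return float(max(t.sum(), 0.0))


def mrmr_rank(table: pd.DataFrame, labels, k: int = 10,
              n_bins: int = 10) -> tuple[list[str], dict[str, float]]:
    """Greedy MRMR (difference scheme) ranking of feature columns.

    First pick maximises I(f; y); each later pick maximises
    ``I(f; y) - mean_s I(f; s)`` over already-selected s.  Ties break
    deterministically by feature name.  Returns the ordered names and
    their criterion scores at selection time.
    """
    cols = sorted(c for c in table.columns)
    y = np.asarray(labels)
    if k > len(cols):
        warnings.warn(f"only {len(cols)} candidates for k={k}; returning all")
        k = len(cols)
    data = {c: table[c].to_numpy(dtype=float) for c in cols}
    relevance = {c: mutual_information(data[c], y, n_bins) for c in cols}
    selected: list[str] = []
    scores: dict[str, float] = {}
    redundancy = {c: 0.0 for c in cols}
    remaining = set(cols)
    while len(selected) < k:
        best, best_score = None, -np.inf
        for c in sorted(remaining):
            red = redundancy[c] / len(selected) if selected else 0.0
            score = relevance[c] - red
            if score > best_score + 1e-15:
                best, best_score = c, score
        selected.append(best)
        scores[best] = best_score
        remaining.discard(best)
        for c in remaining:
            redundancy[c] += mutual_information(data[c], data[best], n_bins)
    return selected, scores


def binarize_labels(risk_labels, setting: str) -> tuple[np.ndarray, np.ndarray]:
    """Label coding for a classification setting.

    ``L_vs_H`` keeps only low/high lesions (high positive); ``L_vs_IH``
    keeps all lesions with intermediate + high merged as positives.
    Returns ``(keep_mask, y)`` with y aligned to the kept rows.
    """
    r = np.asarray(risk_labels)
    if setting == "L_vs_H":
        keep = (r == "L") | (r == "H")
        return keep, (r[keep] == "H").astype(int)
    if setting == "L_vs_IH":
        keep = np.ones(r.shape, dtype=bool)
        return keep, np.isin(r, ["I", "H"]).astype(int)
    raise ValueError(f"unknown setting {setting!r}")


def select_features(table: pd.DataFrame, labels, p_threshold: float = 0.01,
                    k: int = 10, n_bins: int = 10, setting: str = "",
                    pool: str = "") -> SelectionResult:
    """Rank-sum prefilter followed by MRMR ranking of the survivors.

    ``labels`` is a binary vector aligned with the table rows.  Columns
    with missing cells are compared pair-wise (NaNs dropped per column);
    zero survivors raises an empty-selection error.
    """
    y = np.asarray(labels).astype(int)
    cols = feature_columns(table)
    p_values: dict[str, float] = {}
    survivors = []
    for c in cols:
        v = table[c].to_numpy(dtype=float)
        ok = np.isfinite(v)
        g0, g1 = v[ok & (y == 0)], v[ok & (y == 1)]
        if g0.size == 0 or g1.size == 0:
            p_values[c] = 1.0
            continue
        _, p = ranksum_test(g0, g1)
        p_values[c] = p
        if p < p_threshold:
            survivors.append(c)
    if not survivors:
        raise ValueError("empty selection: no feature passed the prefilter")
    sub = table[survivors].copy()
    # MRMR binning needs complete columns; impute residual NaNs by median
    sub = sub.fillna(sub.median())
    ranked, scores = mrmr_rank(sub, y, k=k, n_bins=n_bins)
    return SelectionResult(
        features=ranked,
        p_values={f: p_values[f] for f in ranked},
        mrmr_scores=scores,
        setting=setting,
        pool=pool,
    )


def pool_columns(table: pd.DataFrame, rois=("IT", "PT"), sequences=("T2W", "ADC")):
    """Subset feature columns by ROI family and sequence.

    ``rois`` entries may be exact ROI names (``PT_3_6``) or the families
    ``IT`` / ``PT`` (all rings).
    """
    from radpt.features import FeatureSpec

    out = []
    for c in feature_columns(table):
        spec = FeatureSpec.from_name(c)
        roi_ok = any(
            spec.roi == r or (r == "PT" and spec.roi.startswith("PT_"))
            or (r == "IT" and spec.roi == "IT")
            for r in rois
        )
        if roi_ok and spec.sequence in sequences:
            out.append(c)
    return out
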