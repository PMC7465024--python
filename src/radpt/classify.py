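"""QDA risk classification with patient-grouped repeated cross-validation.

The classifier is Gaussian class-conditional with class-specific
covariances, maximum-likelihood fits, and trace-scaled shrinkage
``(1 - g) * Cov + g * (trace(Cov)/d) * I``.  Scores are log posterior
odds.  Cross-validation is 100-run 3-fold, stratified by class at the
patient level; all lesions of a patient share a fold.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from radpt.evaluate import roc_auc


@dataclass
class QDAModel:
    classes: np.ndarray
    priors: np.ndarray
    means: list[np.ndarray]
    covariances: list[np.ndarray]
    shrinkage: float
    feature_names: list[str] = field(default_factory=list)
    norm_mean: np.ndarray | None = None
    norm_sd: np.ndarray | None = None

    def to_json(self) -> str:
        return json.dumps(
            {
                "classes": self.classes.tolist(),
                "priors": self.priors.tolist(),
                "means": [m.tolist() for m in self.means],
                "covariances": [c.tolist() for c in self.covariances],
                "shrinkage": self.shrinkage,
                "feature_names": self.feature_names,
                "norm_mean": None if self.norm_mean is None else self.norm_mean.tolist(),
                "norm_sd": None if self.norm_sd is None else self.norm_sd.tolist(),
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "QDAModel":
        d = json.loads(text)
        return cls(
            classes=np.asarray(d["classes"]),
            priors=np.asarray(d["priors"], dtype=float),
            means=[np.asarray(m, dtype=float) for m in d["means"]],
            covariances=[np.asarray(c, dtype=float) for c in d["covariances"]],
            shrinkage=d["shrinkage"],
            feature_names=list(d["feature_names"]),
            norm_mean=None if d["norm_mean"] is None else np.asarray(d["norm_mean"]),
            norm_sd=None if d["norm_sd"] is None else np.asarray(d["norm_sd"]),
        )


def qda_fit(X, y, shrinkage: float = 1e-3, feature_names=None) -> QDAModel:
    """Maximum-likelihood QDA fit with trace-scaled covariance shrinkage."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2:
        raise ValueError("need at least two classes")
    if counts.min() < 2:
        raise ValueError("need >= 2 samples per class")
    d = X.shape[1]
    means, covs = [], []
    for c in classes:
        Xc = X[y == c]
        mu = Xc.mean(axis=0)
        cov = (Xc - mu).T @ (Xc - mu) / Xc.shape[0]
        cov = (1 - shrinkage) * cov + shrinkage * (np.trace(cov) / d) * np.eye(d)
        sign, _ = np.linalg.slogdet(cov)
        if sign <= 0:
            raise ValueError("singular class covariance after shrinkage")
        means.append(mu)
        covs.append(cov)
    return QDAModel(
        classes=classes,
        priors=counts / counts.sum(),
        means=means,
        covariances=covs,
        shrinkage=shrinkage,
        feature_names=list(feature_names or []),
    )


def _log_gaussian(X: np.ndarray, mu: np.ndarray, cov: np.ndarray) -> np.ndarray:
    d = mu.size
    diff = X - mu
    solved = np.linalg.solve(cov, diff.T).T
    _, logdet = np.linalg.slogdet(cov)
    return -0.5 * (d * np.log(2 * np.pi) + logdet + np.einsum("ij,ij->i", diff, solved))


def qda_score(model: QDAModel, X) -> np.ndarray:
    """Log posterior odds of the positive (last) class per sample."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != model.means[0].size:
        raise ValueError("feature dimension mismatch")
    if model.norm_mean is not None:
        X = (X - model.norm_mean) / model.norm_sd
    g0 = _log_gaussian(X, model.means[0], model.covariances[0]) + np.log(model.priors[0])
    g1 = _log_gaussian(X, model.means[1], model.covariances[1]) + np.log(model.priors[1])
    return g1 - g0


@dataclass
class CVResult:
    """Per-run-per-fold AUCs plus fold bookkeeping for one CV experiment."""

    fold_aucs: np.ndarray  # (runs, folds)
    seed: int
    runs: int
    folds: int

    @property
    def mean_auc(self) -> float:
        return float(np.nanmean(self.fold_aucs))

    @property
    def sd_auc(self) -> float:
        return float(np.nanstd(self.fold_aucs))

    def to_frame(self) -> pd.DataFrame:
        runs, folds = self.fold_aucs.shape
        return pd.DataFrame(
            {
                "run": np.repeat(np.arange(runs), folds),
                "fold": np.tile(np.arange(folds), runs),
                "auc": self.fold_aucs.ravel(),
            }
        )


def _patient_class(patient_ids: np.ndarray, y: np.ndarray):
    """Per-patient stratification label: the maximum-risk (max y) lesion."""
    out = {}
    for pid, label in zip(patient_ids, y):
        out[pid] = max(out.get(pid, 0), int(label))
    return out


def _grouped_folds(patient_ids, y, folds, rng):
    """Patient-level class-stratified fold assignment (patient -> fold)."""
    pc = _patient_class(np.asarray(patient_ids), np.asarray(y))
    assignment = {}
    cursor = 0  # carried across classes so overall fold sizes balance
    for cls in sorted(set(pc.values())):
        pats = sorted(p for p, c in pc.items() if c == cls)
        rng.shuffle(pats)
        for p in pats:
            assignment[p] = cursor % folds
            cursor += 1
    return assignment


def _normalise_fit(Xtr):
    mu = Xtr.mean(axis=0)
    sd = Xtr.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    return mu, sd


def cross_validate(X, y, patient_ids, runs: int = 100, folds: int = 3,
                   seed: int = 0, shrinkage: float = 1e-3,
                   max_resample: int = 20) -> CVResult:
    """Repeated patient-grouped stratified k-fold CV of the QDA model.

    Feature z-normalisation is fit on each training fold only.  Folds
    whose training part lacks a class are resampled (logged via the
    resample counter); the AUC of a single-class test fold is NaN.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(int)
    patient_ids = np.asarray(patient_ids)
    classes = np.unique(y)
    if classes.size != 2:
        raise ValueError("binary labels required")
    for c in classes:
        if np.unique(patient_ids[y == c]).size < folds:
            raise ValueError("need >= folds patients per class")
    rng = np.random.default_rng(seed)
    aucs = np.full((runs, folds), np.nan)
    for r in range(runs):
        for attempt in range(max_resample):
            assignment = _grouped_folds(patient_ids, y, folds, rng)
            fold_of = np.array([assignment[p] for p in patient_ids])
            ok = all(
                np.unique(y[fold_of != f]).size == 2 for f in range(folds)
            )
            if ok:
                break
        for f in range(folds):
            tr = fold_of != f
            te = ~tr
            if np.unique(y[tr]).size < 2 or not te.any():
                continue
            mu, sd = _normalise_fit(X[tr])
            model = qda_fit((X[tr] - mu) / sd, y[tr], shrinkage)
            scores = qda_score(model, (X[te] - mu) / sd)
            if np.unique(y[te]).size == 2:
                aucs[r, f] = roc_auc(scores, y[te]).auc
    return CVResult(fold_aucs=aucs, seed=seed, runs=runs, folds=folds)


def fit_and_holdout(X1, y1, X2, y2, patients1, patients2,
                    shrinkage: float = 1e-3, feature_names=None):
    """Fit on all of D1 (z-normalisation from D1 only), score D2.

    Returns ``(scores_on_D2, model)``.  Any patient appearing in both
    cohorts is a protocol violation.
    """
    overlap = set(np.asarray(patients1)) & set(np.asarray(patients2))
    if overlap:
        raise ValueError(f"patient leakage between cohorts: {sorted(overlap)[:5]}")
    X1 = np.asarray(X1, dtype=float)
    X2 = np.asarray(X2, dtype=float)
    mu, sd = _normalise_fit(X1)
    model = qda_fit((X1 - mu) / sd, np.asarray(y1).astype(int), shrinkage,
                    feature_names=feature_names)
    model.norm_mean = mu
    model.norm_sd = sd
    scores = qda_score(model, X2)
    return scores, model
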