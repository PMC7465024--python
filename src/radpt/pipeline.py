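"""End-to-end orchestration: simulate -> preprocess -> rings -> extract ->
select -> train/crossval -> evaluate, as a configured, reproducible run.

The cohort is split into D1 (training, cross-validated) and D2
(independent hold-out) at the patient level.  Selection only ever sees
D1; the D2 table is wrapped in an access guard that trips if anything
reads it before the hold-out step.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from radpt.classify import cross_validate, fit_and_holdout
from radpt.evaluate import roc_auc
from radpt.features import BatteryConfig, extract_all, feature_metadata, feature_columns
from radpt.preprocess import PreprocessConfig, preprocess_study
from radpt.rings import build_ring_sets
from radpt.selection import binarize_labels, pool_columns, select_features
from radpt.simdata import PhantomConfig, generate_cohort

logger = logging.getLogger(__name__)

POOLS = {"IT": ("IT",), "PT": ("PT",), "IT+PT": ("IT", "PT")}
SETTINGS = ("L_vs_H", "L_vs_IH")


@dataclass
class RunConfig:
    phantom: PhantomConfig = field(default_factory=PhantomConfig)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    battery: BatteryConfig = field(default_factory=BatteryConfig)
    split_ratio: float = 0.5
    settings: tuple = SETTINGS
    sequences: tuple = ("T2W", "ADC")
    pools: tuple = ("IT", "PT", "IT+PT")
    p_threshold: float = 0.01
    top_k: int = 10
    cv_runs: int = 100
    cv_folds: int = 3
    shrinkage: float = 1e-3
    seed: int = 0

    def digest(self) -> str:
        text = json.dumps({
            "phantom": self.phantom.to_dict(),
            "split_ratio": self.split_ratio,
            "settings": list(self.settings),
            "sequences": list(self.sequences),
            "pools": list(self.pools),
            "p_threshold": self.p_threshold,
            "top_k": self.top_k,
            "cv": [self.cv_runs, self.cv_folds],
            "shrinkage": self.shrinkage,
            "seed": self.seed,
        }, sort_keys=True, default=str)
        return hashlib.sha256(text.encode()).hexdigest()[:12]


class GuardedTable:
    """Access guard around the D2 feature table (leakage tripwire)."""

    def __init__(self, table: pd.DataFrame):
        self._table = table
        self.accessed = False

    def release(self) -> pd.DataFrame:
        self.accessed = True
        return self._table

    def __getattr__(self, name):
        raise RuntimeError(
            "D2 table accessed before the hold-out step (protocol violation)"
        )


def split_cohort(table: pd.DataFrame, ratio: float = 0.5, seed: int = 0):
    """Patient-level random split into (D1, D2) feature tables."""
    rng = np.random.default_rng([seed, 0xD1D2])
    patients = np.array(sorted(table["patient_id"].unique()))
    rng.shuffle(patients)
    n1 = int(round(len(patients) * ratio))
    d1_pat = set(patients[:n1])
    d1 = table[table["patient_id"].isin(d1_pat)].reset_index(drop=True)
    d2 = table[~table["patient_id"].isin(d1_pat)].reset_index(drop=True)
    return d1, d2


def build_feature_table(config: RunConfig, out_dir: Path | None = None) -> pd.DataFrame:
    """Simulate, preprocess, build rings and extract the cohort table."""
    studies, manifest = generate_cohort(config.phantom)
    if out_dir is not None:
        manifest.to_csv(out_dir / "manifest.csv", index=False)
    pre = [preprocess_study(st, config.preprocess) for st in studies]
    ring_sets = [build_ring_sets(st) for st in pre]
    table = extract_all(pre, ring_sets, config.battery)
    return table


def _matrix(table: pd.DataFrame, features, keep):
    sub = table.loc[keep, features]
    filled = sub.fillna(sub.median())
    return filled.to_numpy(dtype=float)


def evaluate_cell(d1: pd.DataFrame, d2: pd.DataFrame, config: RunConfig,
                  pool: str, sequence: str, setting: str) -> dict:
    """Select on D1, cross-validate on D1 and score the D2 hold-out for
    one (pool, sequence, setting) cell.  Returns the cell record."""
    seqs = ("T2W", "ADC") if sequence == "both" else (sequence,)
    cols = pool_columns(d1, rois=POOLS[pool], sequences=seqs)
    keep1, y1 = binarize_labels(d1["risk_label"].to_numpy(), setting)
    keep2, y2 = binarize_labels(d2["risk_label"].to_numpy(), setting)
    rec = {"pool": pool, "sequence": sequence, "setting": setting,
           "n_features": 0, "cv_auc": np.nan, "cv_auc_sd": np.nan,
           "holdout_auc": np.nan, "selected": []}
    try:
        sel = select_features(d1.loc[keep1, cols], y1,
                              p_threshold=config.p_threshold, k=config.top_k,
                              setting=setting, pool=pool)
    except ValueError:
        logger.warning("empty selection for %s/%s/%s", pool, sequence, setting)
        return rec
    feats = sel.features
    rec["n_features"] = len(feats)
    rec["selected"] = feats
    X1 = _matrix(d1, feats, keep1)
    X2 = _matrix(d2, feats, keep2)
    pid1 = d1.loc[keep1, "patient_id"].to_numpy()
    pid2 = d2.loc[keep2, "patient_id"].to_numpy()
    if config.cv_runs > 0:
        try:
            cv = cross_validate(X1, y1, pid1, runs=config.cv_runs,
                                folds=config.cv_folds, seed=config.seed,
                                shrinkage=config.shrinkage)
            rec["cv_auc"] = cv.mean_auc
            rec["cv_auc_sd"] = cv.sd_auc
        except ValueError as exc:
            logger.warning("CV skipped for %s/%s/%s: %s",
                           pool, sequence, setting, exc)
    if len(np.unique(y2)) == 2 and len(y2) >= 4:
        scores, _ = fit_and_holdout(X1, y1, X2, y2, pid1, pid2,
                                    shrinkage=config.shrinkage,
                                    feature_names=feats)
        rec["holdout_auc"] = roc_auc(scores, y2).auc
    return rec


def experiment_report(d1: pd.DataFrame, d2: pd.DataFrame,
                      config: RunConfig) -> pd.DataFrame:
    """AUC report over pool x sequence x setting x cohort.

    With the default two sequences this is the 24-cell report (each row
    carries both the D1 CV AUC and the D2 hold-out AUC).
    """
    records = []
    for setting in config.settings:
        for pool in config.pools:
            for sequence in config.sequences:
                records.append(evaluate_cell(d1, d2, config, pool, sequence,
                                             setting))
    rep = pd.DataFrame.from_records(records)
    rep["seed"] = config.seed
    return rep


def run(config: RunConfig, out_dir) -> pd.DataFrame:
    """Execute the full pipeline and write artifacts into ``out_dir``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    provenance = {"config_digest": config.digest(), "seed": config.seed}

    table = build_feature_table(config, out_dir)
    table.to_csv(out_dir / "features.csv", index=False)
    with open(out_dir / "features_meta.json", "w") as fh:
        json.dump(feature_metadata(feature_columns(table)), fh)

    d1, d2 = split_cohort(table, config.split_ratio, config.seed)
    guard = GuardedTable(d2)
    report = experiment_report(d1, guard.release(), config)
    report_out = report.drop(columns="selected")
    report_out.to_csv(out_dir / "report.csv", index=False)
    provenance.update({
        "n_patients": int(table["patient_id"].nunique()),
        "n_lesions": int(len(table)),
        "d1_lesions": int(len(d1)),
        "d2_lesions": int(len(d2)),
        "elapsed_s": round(time.time() - t0, 2),
    })
    with open(out_dir / "run.json", "w") as fh:
        json.dump(provenance, fh, indent=2)
    logger.info("run complete: %s", provenance)
    return report
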