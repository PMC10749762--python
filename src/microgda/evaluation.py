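"""Evaluation harnesses: AUC, repeated stratified k-fold CV, leave-one-study-out.

The headline metric is the area under the ROC curve (equivalently the
Mann-Whitney concordance of disease probabilities). Repeated CV summaries
report the mean AUC together with a t-based margin of error,

    ME = t[1 - alpha/2, n-1] * s / sqrt(n),

with s the sample standard deviation over repeats. Leave-one-study-out (LOSO)
holds out an entire cohort: the held-out cohort is the unlabeled target domain
for adaptation and the unlabeled node set for the GCN, and its labels are used
only to score the predictions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Callable

import numpy as np
from scipy import stats as sp_stats
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

from .data_io import AbundanceMatrix, concat_samples

#: predict_fn(train, test, seed) -> per-sample disease probabilities for `test`
PredictFn = Callable[[AbundanceMatrix, AbundanceMatrix, int], np.ndarray]


@dataclass
class EvalConfig:
    n_folds: int = 10
    n_repeats: int = 10
    alpha: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")


@dataclass
class CVResult:
    per_repeat_auc: list[float]
    mean_auc: float
    margin_of_error: float

    def to_json(self, path: str | Path, config: EvalConfig | None = None) -> None:
        payload = {
            "mean_auc": self.mean_auc,
            "margin_of_error": self.margin_of_error,
            "per_repeat_auc": self.per_repeat_auc,
        }
        if config is not None:
            payload["config"] = {
                "n_folds": config.n_folds,
                "n_repeats": config.n_repeats,
                "alpha": config.alpha,
                "seed": config.seed,
            }
        Path(path).write_text(json.dumps(payload, indent=2))


def auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """ROC AUC of disease scores against binary labels (1 = disease)."""
    labels = np.asarray(labels, dtype=float)
    scores = np.asarray(scores, dtype=float)
    if len(np.unique(labels)) < 2:
        raise ValueError("AUC undefined for single-class labels")
    return float(roc_auc_score(labels, scores))


def margin_of_error(values: np.ndarray | list[float], alpha: float = 0.05) -> float:
    """Half-width of the t confidence interval for the mean of `values`."""
    values = np.asarray(values, dtype=float)
    n = values.size
    if n < 2:
        raise ValueError("need at least 2 values")
    s = values.std(ddof=1)
    t_crit = sp_stats.t.ppf(1.0 - alpha / 2.0, n - 1)
    return float(t_crit * s / np.sqrt(n))


def stratified_fold_indices(
    labels: np.ndarray, n_folds: int, seed: int
) -> list[np.ndarray]:
    """Deterministic stratified fold assignment (test indices per fold)."""
    labels = np.asarray(labels, dtype=int)
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    return [test for _, test in skf.split(np.zeros(len(labels)), labels)]


def stratified_kfold(
    dataset: AbundanceMatrix,
    config: EvalConfig,
    predict_fn: PredictFn,
) -> CVResult:
    """Repeated stratified k-fold CV with pooled out-of-fold AUC per repeat.

    Each repeat reshuffles the folds (seeded from ``config.seed`` and the
    repeat index), predicts every sample exactly once while it is held out,
    and scores the pooled out-of-fold disease probabilities.
    """
    if dataset.label is None or not np.all(dataset.labeled_mask):
        raise ValueError("cross-validation needs fully labeled data")
    labels = dataset.label.astype(int)
    counts = np.bincount(labels, minlength=2)
    if counts.min() < config.n_folds:
        raise ValueError(
            f"smallest class has {counts.min()} samples, fewer than {config.n_folds} folds"
        )
    per_repeat = []
    for rep in range(config.n_repeats):
        rep_seed = int((config.seed * 1009 + rep) % (2**31 - 1))
        pooled = np.empty(dataset.n_samples)
        for fold_idx, test_idx in enumerate(
            stratified_fold_indices(labels, config.n_folds, rep_seed)
        ):
            train_idx = np.setdiff1d(np.arange(dataset.n_samples), test_idx)
            train = dataset.subset(train_idx)
            test = dataset.subset(test_idx)
            fold_seed = int((rep_seed + 7919 * fold_idx) % (2**31 - 1))
            pooled[test_idx] = np.asarray(predict_fn(train, test, fold_seed))
        per_repeat.append(auc(pooled, labels))
    return CVResult(
        per_repeat_auc=per_repeat,
        mean_auc=float(np.mean(per_repeat)),
        margin_of_error=margin_of_error(per_repeat, config.alpha),
    )


def loso(
    cohorts: list[AbundanceMatrix],
    held_out: str,
    predict_fn: PredictFn,
    seed: int = 0,
) -> float:
    """Leave-one-study-out AUC on the held-out cohort.

    Training data are all cohorts except ``held_out``; the held-out cohort is
    passed to ``predict_fn`` label-blinded and its labels score the result.
    """
    if len(cohorts) < 2:
        raise ValueError("LOSO needs at least 2 cohorts")
    names = []
    for m in cohorts:
        if m.cohort is None:
            raise ValueError("every matrix needs a cohort id")
        names.append(m.cohort[0])
    if held_out not in names:
        raise ValueError(f"unknown cohort {held_out!r}; have {names}")
    test = cohorts[names.index(held_out)]
    train = concat_samples([m for m, n in zip(cohorts, names) if n != held_out])
    if test.label is None or not np.all(test.labeled_mask):
        raise ValueError("held-out cohort must be labeled for scoring")
    blinded = AbundanceMatrix(
        test.sample_ids, test.taxa, test.values, cohort=test.cohort, label=None
    )
    scores = np.asarray(predict_fn(train, blinded, seed))
    return auc(scores, test.label)
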