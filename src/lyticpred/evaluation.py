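"""Jackknife / k-fold evaluation protocols and the four performance metrics.

Metrics from pooled confusion counts (all as percentages except MCC):

    Sn  = 100 * TP / (TP + FN)
    Sp  = 100 * TN / (TN + FP)          (standard form; a ``printed``
                                         variant with FN in the denominator
                                         is kept for auditability)
    Acc = 100 * (TP + TN) / total
    MCC = (TP*TN - FP*FN) / sqrt((TP+FP)(TN+FN)(TP+FN)(TN+FP))

MCC is defined as 0 when any denominator factor vanishes; Sn/Sp are 0 when
their denominators vanish.

SMOTE placement in cross-validation:

* ``none``    — no balancing.
* ``outside`` — balance the full matrix once, then leave one (original)
  sample out per round. Synthetic points derived from the held-out sample
  stay in the training split, so accuracy is optimistically biased; this
  mirrors the balance-then-jackknife protocol reported in the source
  method.
* ``inside``  — balance each training split only (leak-free).

Synthetic samples are never test points in any mode by default.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable

import numpy as np
from sklearn.model_selection import StratifiedKFold

from .balancing import ORIGINAL, FeatureMatrix, smote_balance
from .classify import TrainedModel, predict
from .errors import ConfigError, InputError

Trainer = Callable[[FeatureMatrix], TrainedModel]

SMOTE_MODES = ("none", "outside", "inside")


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self):
        for name in ("tp", "tn", "fp", "fn"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass(frozen=True)
class EvaluationReport:
    """Confusion counts plus Sn/Sp/Acc percentages and MCC."""

    counts: ConfusionCounts
    sn: float
    sp: float
    mcc: float
    acc: float
    protocol: dict = field(default_factory=dict)
    predictions: dict | None = None

    def to_json(self, path: str | Path) -> None:
        payload = {
            "counts": {
                "tp": self.counts.tp,
                "tn": self.counts.tn,
                "fp": self.counts.fp,
                "fn": self.counts.fn,
            },
            "sn": self.sn,
            "sp": self.sp,
            "mcc": self.mcc,
            "acc": self.acc,
            "protocol": self.protocol,
        }
        Path(path).write_text(json.dumps(payload, indent=2) + "\n")

    def to_tsv_line(self) -> str:
        """One-line TSV in Sn, Sp, MCC, Acc column order."""
        return f"{self.sn:.2f}\t{self.sp:.2f}\t{self.mcc:.4f}\t{self.acc:.2f}"


def compute_metrics(
    counts: ConfusionCounts,
    sp_variant: str = "standard",
    protocol: dict | None = None,
) -> EvaluationReport:
    """Compute Sn/Sp/MCC/Acc from confusion counts.

    ``sp_variant="printed"`` uses TN/(TN+FN) instead of the standard
    TN/(TN+FP).
    """
    if sp_variant not in ("standard", "printed"):
        raise ConfigError("sp_variant must be 'standard' or 'printed'")
    if counts.total == 0:
        raise InputError("cannot compute metrics on zero samples")
    tp, tn, fp, fn = counts.tp, counts.tn, counts.fp, counts.fn
    sn = 100.0 * tp / (tp + fn) if tp + fn else 0.0
    sp_den = tn + fn if sp_variant == "printed" else tn + fp
    sp = 100.0 * tn / sp_den if sp_den else 0.0
    acc = 100.0 * (tp + tn) / counts.total
    denom = (tp + fp) * (tn + fn) * (tp + fn) * (tn + fp)
    mcc = (tp * tn - fp * fn) / math.sqrt(denom) if denom else 0.0
    return EvaluationReport(
        counts=counts,
        sn=sn,
        sp=sp,
        mcc=mcc,
        acc=acc,
        protocol=dict(protocol or {}),
    )


def _accumulate(
    truths: list[int], preds: list[int]
) -> ConfusionCounts:
    tp = sum(1 for t, p in zip(truths, preds) if t == 1 and p == 1)
    tn = sum(1 for t, p in zip(truths, preds) if t == 0 and p == 0)
    fp = sum(1 for t, p in zip(truths, preds) if t == 0 and p == 1)
    fn = sum(1 for t, p in zip(truths, preds) if t == 1 and p == 0)
    return ConfusionCounts(tp=tp, tn=tn, fp=fp, fn=fn)


def _fold_seed(seed: int, index: int) -> int:
    """Deterministic per-fold child seed."""
    return int(np.random.SeedSequence([seed, index]).generate_state(1)[0])


def _check_mode(smote_mode: str) -> None:
    if smote_mode not in SMOTE_MODES:
        raise ConfigError(
            f"unknown smote_mode {smote_mode!r}; choose from {SMOTE_MODES}"
        )


def jackknife(
    matrix: FeatureMatrix,
    trainer: Trainer,
    smote_mode: str = "none",
    seed: int = 0,
    smote_k: int = 5,
    sp_variant: str = "standard",
) -> EvaluationReport:
    """Leave-one-out evaluation over the original samples.

    Each original sample is predicted by a model trained on everything
    else (plus, depending on ``smote_mode``, synthetic minority samples).
    """
    _check_mode(smote_mode)
    if min(matrix.class_counts().values(), default=0) < 2:
        raise InputError("jackknife needs >= 2 samples per class")

    working = (
        smote_balance(matrix, k=smote_k, seed=seed)
        if smote_mode == "outside"
        else matrix
    )
    test_idx = np.flatnonzero(working.provenance == ORIGINAL)

    truths: list[int] = []
    preds: list[int] = []
    predictions: dict[str, int] = {}
    for i in test_idx:
        rest = working.subset_rows(np.delete(np.arange(working.n_samples), i))
        if smote_mode == "inside":
            rest = smote_balance(rest, k=smote_k, seed=_fold_seed(seed, int(i)))
        model = trainer(rest)
        pred = int(predict(model, working.subset_rows([i]))[0])
        truths.append(int(working.labels[i]))
        preds.append(pred)
        predictions[working.sample_ids[i]] = pred

    report = compute_metrics(
        _accumulate(truths, preds),
        sp_variant=sp_variant,
        protocol={"protocol": "jackknife", "smote_mode": smote_mode, "seed": seed},
    )
    return EvaluationReport(
        counts=report.counts,
        sn=report.sn,
        sp=report.sp,
        mcc=report.mcc,
        acc=report.acc,
        protocol=report.protocol,
        predictions=predictions,
    )


def kfold(
    matrix: FeatureMatrix,
    trainer: Trainer,
    k: int = 5,
    smote_mode: str = "none",
    seed: int = 0,
    smote_k: int = 5,
    sp_variant: str = "standard",
) -> EvaluationReport:
    """Stratified k-fold evaluation; the fast alternative to jackknife.

    With ``k`` equal to the sample count this reduces to the jackknife
    (every fold holds out one sample). Synthetic samples are never test
    points.
    """
    _check_mode(smote_mode)
    if k < 2:
        raise ConfigError("k must be >= 2")
    counts = matrix.class_counts()
    if len(counts) < 2:
        raise InputError("k-fold needs both classes present")
    if k > min(counts.values()) and k != matrix.n_samples:
        raise InputError(
            f"k={k} exceeds smallest class size {min(counts.values())}"
        )

    working = (
        smote_balance(matrix, k=smote_k, seed=seed)
        if smote_mode == "outside"
        else matrix
    )
    orig_idx = np.flatnonzero(working.provenance == ORIGINAL)

    if k == len(orig_idx):
        # Degenerate stratification: leave-one-out folds.
        folds = [np.array([i]) for i in orig_idx]
    else:
        skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        folds = [
            orig_idx[test]
            for _, test in skf.split(
                working.values[orig_idx], working.labels[orig_idx]
            )
        ]

    truths: list[int] = []
    preds: list[int] = []
    predictions: dict[str, int] = {}
    for fold_no, test in enumerate(folds):
        train_rows = np.setdiff1d(np.arange(working.n_samples), test)
        train_matrix = working.subset_rows(train_rows)
        if smote_mode == "inside":
            train_matrix = smote_balance(
                train_matrix, k=smote_k, seed=_fold_seed(seed, fold_no)
            )
        model = trainer(train_matrix)
        fold_preds = predict(model, working.subset_rows(test))
        for row, pred in zip(test, fold_preds):
            truths.append(int(working.labels[row]))
            preds.append(int(pred))
            predictions[working.sample_ids[row]] = int(pred)

    report = compute_metrics(
        _accumulate(truths, preds),
        sp_variant=sp_variant,
        protocol={
            "protocol": "kfold",
            "k": k,
            "smote_mode": smote_mode,
            "seed": seed,
        },
    )
    return EvaluationReport(
        counts=report.counts,
        sn=report.sn,
        sp=report.sp,
        mcc=report.mcc,
        acc=report.acc,
        protocol=report.protocol,
        predictions=predictions,
    )


def accuracy_evaluator(
    trainer: Trainer,
    k: int = 3,
    smote_mode: str = "none",
    seed: int = 0,
) -> Callable[[FeatureMatrix], float]:
    """An IFS evaluator: k-fold CV accuracy (%) of ``trainer`` on a matrix."""

    def _evaluate(matrix: FeatureMatrix) -> float:
        return kfold(matrix, trainer, k=k, smote_mode=smote_mode, seed=seed).acc

    return _evaluate
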