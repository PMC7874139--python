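"""F-score feature ranking and incremental feature selection (IFS).

The per-feature F-score is the ratio of between-class mean separation to
within-class spread:

    F_i = [(m_i+ - m_i)^2 + (m_i- - m_i)^2] /
          [ s+_i / (n+ - 1) + s-_i / (n- - 1) ]

where m_i is the overall mean of feature i, m_i+/m_i- the class means, and
s+/s- the within-class sums of squared deviations. The default applies the
Bessel 1/(n-1) factor to both classes (the standard symmetric form); the
``printed`` variant omits it on the positive-class sum, matching a published
asymmetric rendering of the formula.

Zero-denominator features score ``+inf`` when the numerator is positive
(a perfect separator, ranked first) and ``0`` when the numerator is also
zero (a constant feature).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .balancing import FeatureMatrix
from .errors import ConfigError, InputError

Evaluator = Callable[[FeatureMatrix], float]


@dataclass(frozen=True)
class FeatureRanking:
    """Features with F-scores, sorted descending (ties broken by name)."""

    entries: tuple[tuple[str, float], ...]

    def __post_init__(self):
        scores = [s for _, s in self.entries]
        if any(
            scores[i] < scores[i + 1] for i in range(len(scores) - 1)
        ):
            raise ConfigError("ranking scores must be non-increasing")

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(nm for nm, _ in self.entries)

    def top(self, d: int) -> tuple[str, ...]:
        return self.names[:d]

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(self.entries, columns=["feature", "f_score"]).to_csv(
            path, index=False
        )


@dataclass(frozen=True)
class IFSCurve:
    """Accuracy of nested top-d feature subsets; ``selected_d`` is the
    smallest d attaining the maximum accuracy."""

    points: tuple[tuple[int, float], ...]

    @property
    def selected_d(self) -> int:
        best = max(acc for _, acc in self.points)
        return min(d for d, acc in self.points if acc == best)

    @property
    def best_accuracy(self) -> float:
        return max(acc for _, acc in self.points)

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(self.points, columns=["n_features", "accuracy"]).to_csv(
            path, index=False
        )

    def plot(self, path: str | Path) -> None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        d, acc = zip(*self.points)
        fig, ax = plt.subplots(figsize=(6, 4))
        ax.plot(d, acc, marker="o", ms=3)
        ax.axvline(self.selected_d, ls="--", color="grey", lw=0.8)
        ax.set_xlabel("number of top-ranked features")
        ax.set_ylabel("accuracy (%)")
        fig.tight_layout()
        fig.savefig(path, dpi=120)
        plt.close(fig)


def fscore_rank(matrix: FeatureMatrix, variant: str = "symmetric") -> FeatureRanking:
    """Rank every feature by F-score, descending.

    Parameters
    ----------
    matrix : FeatureMatrix
        Two-class matrix with >= 2 samples per class.
    variant : {"symmetric", "printed"}
        ``symmetric`` applies the 1/(n-1) Bessel factor to both class sums;
        ``printed`` omits it on the positive-class sum.
    """
    if variant not in ("symmetric", "printed"):
        raise ConfigError("variant must be 'symmetric' or 'printed'")
    counts = matrix.class_counts()
    if len(counts) < 2:
        raise InputError("F-score needs both classes present")
    if min(counts.values()) < 2:
        raise InputError("F-score needs >= 2 samples per class")

    pos = matrix.values[matrix.labels == 1]
    neg = matrix.values[matrix.labels == 0]
    n_pos, n_neg = pos.shape[0], neg.shape[0]

    overall_mean = matrix.values.mean(axis=0)
    pos_mean = pos.mean(axis=0)
    neg_mean = neg.mean(axis=0)
    numer = (pos_mean - overall_mean) ** 2 + (neg_mean - overall_mean) ** 2

    pos_ss = ((pos - pos_mean) ** 2).sum(axis=0)
    neg_ss = ((neg - neg_mean) ** 2).sum(axis=0)
    if variant == "symmetric":
        denom = pos_ss / (n_pos - 1) + neg_ss / (n_neg - 1)
    else:
        denom = pos_ss + neg_ss / (n_neg - 1)

    with np.errstate(divide="ignore", invalid="ignore"):
        scores = numer / denom
    scores = np.where(denom == 0, np.where(numer > 0, np.inf, 0.0), scores)

    order = sorted(
        range(matrix.n_features),
        key=lambda i: (-scores[i], matrix.feature_names[i]),
    )
    return FeatureRanking(
        entries=tuple(
            (matrix.feature_names[i], float(scores[i])) for i in order
        )
    )


def ifs_select(
    matrix: FeatureMatrix,
    ranking: FeatureRanking,
    evaluator: Evaluator,
    step: int = 1,
) -> IFSCurve:
    """Incremental feature selection over nested top-d subsets.

    Evaluates d = 1, 1+step, 1+2*step, ... (ceil(n/step) evaluator calls);
    ``evaluator`` maps a feature-subset matrix to an accuracy in [0, 100].
    """
    if len(ranking) == 0:
        raise InputError("empty ranking")
    if step < 1:
        raise ConfigError("step must be >= 1")
    n = len(ranking)
    points: list[tuple[int, float]] = []
    for d in range(1, n + 1, step):
        sub = matrix.subset_features(ranking.top(d))
        acc = float(evaluator(sub))
        if not 0.0 <= acc <= 100.0 and not math.isnan(acc):
            raise ConfigError(f"evaluator returned {acc}, expected [0, 100]")
        points.append((d, acc))
    return IFSCurve(points=tuple(points))
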