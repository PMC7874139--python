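"""Minority-class oversampling to parity (SMOTE) and the feature-matrix type.

SMOTE synthesizes minority samples on the open segment between a minority
point and one of its k nearest minority neighbors (Euclidean distance):

    x_new = x_i + alpha * (x_nn - x_i),   alpha ~ Uniform(0, 1)

Exactly (majority - minority) synthetic samples are generated so class
counts end equal; seed points and neighbors are drawn with replacement.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from sklearn.neighbors import NearestNeighbors

from .errors import InputError, ValidationError
from .features import FeatureVector

ORIGINAL = "original"
SYNTHETIC = "synthetic"


@dataclass
class FeatureMatrix:
    """Labeled samples x named features — the common currency of the pipeline.

    ``provenance`` marks each row ``original`` or ``synthetic`` (SMOTE
    output); all constructors default it to ``original``.
    """

    sample_ids: list[str]
    feature_names: tuple[str, ...]
    values: np.ndarray
    labels: np.ndarray
    provenance: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        n = len(self.sample_ids)
        if self.provenance is None:
            self.provenance = np.array([ORIGINAL] * n, dtype=object)
        else:
            self.provenance = np.asarray(self.provenance, dtype=object)
        if self.values.shape != (n, len(self.feature_names)):
            raise ValidationError(
                f"matrix shape {self.values.shape} inconsistent with "
                f"{n} samples x {len(self.feature_names)} features"
            )
        if self.labels.shape != (n,) or self.provenance.shape != (n,):
            raise ValidationError("labels/provenance length != sample count")
        if len(set(self.sample_ids)) != n:
            raise ValidationError("duplicate sample ids")
        if len(set(self.feature_names)) != len(self.feature_names):
            raise ValidationError("duplicate feature names")

    # -- shape helpers -----------------------------------------------------

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_features(self) -> int:
        return len(self.feature_names)

    def class_counts(self) -> dict[int, int]:
        labels, counts = np.unique(self.labels, return_counts=True)
        return dict(zip(labels.tolist(), counts.tolist()))

    # -- subsetting --------------------------------------------------------

    def subset_rows(self, index: Sequence[int]) -> "FeatureMatrix":
        index = np.asarray(index, dtype=int)
        return FeatureMatrix(
            sample_ids=[self.sample_ids[i] for i in index],
            feature_names=self.feature_names,
            values=self.values[index].copy(),
            labels=self.labels[index].copy(),
            provenance=self.provenance[index].copy(),
        )

    def subset_features(self, names: Sequence[str]) -> "FeatureMatrix":
        pos = {nm: i for i, nm in enumerate(self.feature_names)}
        try:
            cols = [pos[nm] for nm in names]
        except KeyError as exc:
            raise ValidationError(f"unknown feature name {exc.args[0]!r}") from None
        return FeatureMatrix(
            sample_ids=list(self.sample_ids),
            feature_names=tuple(names),
            values=self.values[:, cols].copy(),
            labels=self.labels.copy(),
            provenance=self.provenance.copy(),
        )

    # -- construction / serialization -------------------------------------

    @classmethod
    def from_vectors(
        cls,
        ids: Sequence[str],
        vectors: Sequence[FeatureVector],
        labels: Sequence[int],
    ) -> "FeatureMatrix":
        if not vectors:
            raise InputError("cannot build a matrix from zero vectors")
        names = vectors[0].names
        for v in vectors[1:]:
            if v.names != names:
                raise ValidationError("feature vectors disagree on names/order")
        return cls(
            sample_ids=list(ids),
            feature_names=names,
            values=np.vstack([v.values for v in vectors]),
            labels=np.asarray(labels, dtype=int),
        )

    def to_csv(self, path: str | Path) -> None:
        df = pd.DataFrame(self.values, columns=list(self.feature_names))
        df.insert(0, "sample_id", self.sample_ids)
        df["label"] = self.labels
        df["provenance"] = self.provenance
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "FeatureMatrix":
        df = pd.read_csv(path)
        meta = {"sample_id", "label", "provenance"}
        names = tuple(c for c in df.columns if c not in meta)
        return cls(
            sample_ids=df["sample_id"].astype(str).tolist(),
            feature_names=names,
            values=df[list(names)].to_numpy(dtype=float),
            labels=df["label"].to_numpy(dtype=int),
            provenance=df["provenance"].to_numpy(dtype=object)
            if "provenance" in df
            else None,
        )


def imbalance_ratio(matrix: FeatureMatrix) -> float:
    """Majority-class count divided by minority-class count."""
    counts = matrix.class_counts()
    if len(counts) < 2:
        raise InputError("imbalance ratio needs both classes present")
    values = sorted(counts.values())
    return values[-1] / values[0]


def smote_balance(
    matrix: FeatureMatrix,
    k: int = 5,
    seed: int | None = None,
    alpha_sampler: Callable[[np.random.Generator], float] | None = None,
) -> FeatureMatrix:
    """Oversample the minority class to parity with SMOTE.

    Original rows are preserved unchanged (and first); synthetic rows are
    appended with ids ``synthetic:<label>:<n>`` and provenance marked.
    ``alpha_sampler`` exists for testing degenerate interpolation weights;
    by default alpha is drawn uniformly in the open interval (0, 1).

    Raises
    ------
    InputError
        If a class is missing, the minority class has < 2 samples, or
        ``k`` exceeds minority size - 1.
    """
    if seed is None:
        raise InputError("smote_balance requires an explicit seed")
    counts = matrix.class_counts()
    if len(counts) < 2:
        raise InputError("SMOTE needs both classes present")
    minority_label = min(counts, key=lambda lbl: (counts[lbl], lbl))
    majority_label = max(counts, key=lambda lbl: (counts[lbl], lbl))
    n_min, n_maj = counts[minority_label], counts[majority_label]
    if n_min < 2:
        raise InputError(
            f"minority class ({minority_label}) has {n_min} sample(s); "
            f"SMOTE needs >= 2"
        )
    if k > n_min - 1:
        raise InputError(
            f"k={k} exceeds minority size - 1 = {n_min - 1}"
        )
    need = n_maj - n_min
    if need == 0:
        return matrix.subset_rows(range(matrix.n_samples))

    rng = np.random.default_rng(seed)
    min_idx = np.flatnonzero(matrix.labels == minority_label)
    X_min = matrix.values[min_idx]
    nn = NearestNeighbors(n_neighbors=k + 1).fit(X_min)
    # Drop the self-neighbor in column 0.
    neighbor_table = nn.kneighbors(X_min, return_distance=False)[:, 1:]

    new_rows = np.empty((need, matrix.n_features))
    for s in range(need):
        i = int(rng.integers(len(min_idx)))
        j = int(neighbor_table[i, int(rng.integers(k))])
        if alpha_sampler is not None:
            alpha = float(alpha_sampler(rng))
        else:
            alpha = float(rng.uniform())
            while alpha == 0.0:  # enforce the open interval
                alpha = float(rng.uniform())
        new_rows[s] = X_min[i] + alpha * (X_min[j] - X_min[i])

    synth_ids = [f"synthetic:{minority_label}:{s}" for s in range(need)]
    return FeatureMatrix(
        sample_ids=list(matrix.sample_ids) + synth_ids,
        feature_names=matrix.feature_names,
        values=np.vstack([matrix.values, new_rows]),
        labels=np.concatenate(
            [matrix.labels, np.full(need, minority_label, dtype=int)]
        ),
        provenance=np.concatenate(
            [matrix.provenance, np.array([SYNTHETIC] * need, dtype=object)]
        ),
    )
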