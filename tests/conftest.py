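from __future__ import annotations

import numpy as np
import pytest

from lyticpred.balancing import FeatureMatrix
from lyticpred.features import ACSTable, NUCLEI
from lyticpred.io import AMINO_ACIDS, SS_STATES, ProteinRecord


@pytest.fixture
def synthetic_acs_table():
    """A complete, deterministic ACS table with distinct values per triple."""
    entries = {}
    for i, aa in enumerate(AMINO_ACIDS):
        for j, st in enumerate(SS_STATES):
            for k, nuc in enumerate(NUCLEI):
                entries[(aa, st, nuc)] = 100.0 + i + 0.1 * j + 0.01 * k
    return ACSTable(entries)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_record(rng, length, rec_id="r0", label=1):
    seq = "".join(rng.choice(list(AMINO_ACIDS), size=length))
    return ProteinRecord(id=rec_id, sequence=seq, label=label)


def random_matrix(rng, n_pos, n_neg, n_features, shift=0.0):
    pos = rng.normal(size=(n_pos, n_features)) + shift
    neg = rng.normal(size=(n_neg, n_features))
    return FeatureMatrix(
        sample_ids=[f"p{i}" for i in range(n_pos)]
        + [f"n{i}" for i in range(n_neg)],
        feature_names=tuple(f"f{i}" for i in range(n_features)),
        values=np.vstack([pos, neg]),
        labels=np.array([1] * n_pos + [0] * n_neg),
    )
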