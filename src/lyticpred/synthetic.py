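"""Seeded synthetic fixtures: protein records, PSSM/ss2 files on disk, and
two-class Gaussian feature matrices.

Class separation is injected at the residue-frequency level: each class has
a softmax-tilted base composition (opposite tilts), and every sequence draws
its own composition from a Dirichlet centered on the class base. At
``separation=0`` the two classes are statistically identical, giving a null
dataset for calibration tests. PSSM scores are integers in [-10, 10] with a
class-dependent column bias; secondary-structure states follow a sticky
3-state Markov chain.

Everything written here parses back through :mod:`lyticpred.io` unchanged,
and identical specs produce byte-identical files.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .balancing import FeatureMatrix
from .errors import ConfigError
from .io import (
    AMINO_ACIDS,
    NEGATIVE,
    POSITIVE,
    PSIBLAST_COLUMN_ORDER,
    SS_STATES,
    LabeledDataset,
    load_dataset,
)

# Fixed alternating tilt over the alphabetical residue order; positives are
# tilted toward +, negatives toward -.
_RESIDUE_TILT = np.array([1.0 if i % 2 == 0 else -1.0 for i in range(20)])

_SS_STICKINESS = 0.8  # probability of repeating the previous state


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of a synthetic two-class dataset; ``seed`` is mandatory."""

    n_pos: int
    n_neg: int
    seed: int
    length_range: tuple[int, int] = (50, 80)
    separation: float = 1.0

    def __post_init__(self):
        if self.n_pos < 0 or self.n_neg < 0:
            raise ConfigError("sample counts must be >= 0")
        lo, hi = self.length_range
        if lo < 2 or hi < lo:
            raise ConfigError("length_range must satisfy 2 <= lo <= hi")
        if self.separation < 0:
            raise ConfigError("separation must be >= 0")


def _class_composition(label: int, separation: float) -> np.ndarray:
    sign = 1.0 if label == POSITIVE else -1.0
    logits = 0.5 * separation * sign * _RESIDUE_TILT
    weights = np.exp(logits)
    return weights / weights.sum()


def _draw_sequence(rng: np.random.Generator, length: int, base: np.ndarray) -> str:
    comp = rng.dirichlet(50.0 * base)
    letters = rng.choice(list(AMINO_ACIDS), size=length, p=comp)
    return "".join(letters)


def _draw_pssm_rows(
    rng: np.random.Generator, length: int, label: int, separation: float
) -> np.ndarray:
    """Integer scores in [-10, 10], columns in canonical alphabetical order."""
    sign = 1.0 if label == POSITIVE else -1.0
    bias = np.rint(separation * sign * _RESIDUE_TILT)
    raw = rng.integers(-5, 6, size=(length, 20)) + bias
    return np.clip(raw, -10, 10).astype(int)


def _draw_ss_states(rng: np.random.Generator, length: int) -> str:
    states = [SS_STATES[int(rng.integers(3))]]
    for _ in range(length - 1):
        if rng.random() < _SS_STICKINESS:
            states.append(states[-1])
        else:
            others = [s for s in SS_STATES if s != states[-1]]
            states.append(others[int(rng.integers(2))])
    return "".join(states)


def _write_pssm(path: Path, record_id: str, scores: np.ndarray, sequence: str) -> None:
    """Emit the PSI-BLAST ``-out_ascii_pssm`` layout (native column order)."""
    perm = [AMINO_ACIDS.index(aa) for aa in PSIBLAST_COLUMN_ORDER]
    lines = [
        "",
        "Last position-specific scoring matrix computed, weighted, synthetic fixture",
        "            " + "   ".join(PSIBLAST_COLUMN_ORDER + PSIBLAST_COLUMN_ORDER),
    ]
    for i, row in enumerate(scores, start=1):
        native = row[perm]
        cells = " ".join(f"{int(v):4d}" for v in native)
        pct = " ".join(f"{0:4d}" for _ in range(20))
        lines.append(f"{i:5d} {sequence[i - 1]} {cells} {pct}  0.00 0.00")
    lines.append("")
    path.write_text("\n".join(lines))


def _write_ss2(path: Path, states: str, sequence: str) -> None:
    lines = ["# PSF format remark: three-state prediction (synthetic fixture)", ""]
    for i, (aa, st) in enumerate(zip(sequence, states), start=1):
        probs = {s: 0.1 for s in SS_STATES}
        probs[st] = 0.8
        lines.append(
            f"{i:4d} {aa} {st}   {probs['C']:.3f}  {probs['H']:.3f}  {probs['E']:.3f}"
        )
    lines.append("")
    path.write_text("\n".join(lines))


def gen_records(spec: SyntheticSpec, outdir: str | Path) -> LabeledDataset:
    """Write pos/neg FASTA, per-record PSSM and ss2 files plus a manifest,
    then load them back through the package parsers.

    Returns the round-tripped :class:`LabeledDataset`, so anything this
    function hands out is guaranteed to satisfy the io-layer invariants.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed)

    fasta_lines = {POSITIVE: [], NEGATIVE: []}
    manifest_lines: list[str] = []
    for label, count, prefix in (
        (POSITIVE, spec.n_pos, "pos"),
        (NEGATIVE, spec.n_neg, "neg"),
    ):
        base = _class_composition(label, spec.separation)
        for n in range(count):
            rid = f"{prefix}_{n:04d}"
            length = int(rng.integers(spec.length_range[0], spec.length_range[1] + 1))
            seq = _draw_sequence(rng, length, base)
            fasta_lines[label].append(f">{rid}\n{seq}\n")
            _write_pssm(
                outdir / f"{rid}.pssm",
                rid,
                _draw_pssm_rows(rng, length, label, spec.separation),
                seq,
            )
            _write_ss2(outdir / f"{rid}.ss2", _draw_ss_states(rng, length), seq)
            manifest_lines.append(f"{rid}\t{rid}.pssm\t{rid}.ss2")

    (outdir / "pos.fasta").write_text("".join(fasta_lines[POSITIVE]))
    (outdir / "neg.fasta").write_text("".join(fasta_lines[NEGATIVE]))
    (outdir / "manifest.tsv").write_text("\n".join(manifest_lines) + "\n")

    return load_dataset(
        outdir / "pos.fasta", outdir / "neg.fasta", outdir / "manifest.tsv"
    )


def gen_feature_matrix(
    spec: SyntheticSpec,
    n_features: int = 20,
    shift: float | np.ndarray | None = None,
) -> FeatureMatrix:
    """Two unit-variance Gaussian classes with a mean shift on the positives.

    ``shift`` may be a scalar (applied to every feature), a per-feature
    vector, or None to use ``spec.separation`` on every feature.
    """
    rng = np.random.default_rng(spec.seed)
    if shift is None:
        shift = spec.separation
    shift_vec = np.broadcast_to(np.asarray(shift, dtype=float), (n_features,))

    pos = rng.normal(size=(spec.n_pos, n_features)) + shift_vec
    neg = rng.normal(size=(spec.n_neg, n_features))
    values = np.vstack([pos, neg])
    labels = np.array([POSITIVE] * spec.n_pos + [NEGATIVE] * spec.n_neg)
    ids = [f"pos_{i:04d}" for i in range(spec.n_pos)] + [
        f"neg_{i:04d}" for i in range(spec.n_neg)
    ]
    names = tuple(f"f{i:03d}" for i in range(n_features))
    return FeatureMatrix(
        sample_ids=ids, feature_names=names, values=values, labels=labels
    )
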