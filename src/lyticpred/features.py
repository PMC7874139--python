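"""The four sequence feature encoders and their concatenation.

* AAC — amino-acid composition: 20 per-residue occurrence frequencies.
* DC — dipeptide composition: 400 adjacent ordered-pair frequencies
  normalized by L - 1.
* PSSM-AC — auto-covariance of mean-centered PSSM columns at lags 1..lg.
* acACS — lag-indexed summary of the sequence after substituting each
  residue by its average chemical shift (per nucleus, conditioned on the
  residue's secondary-structure state).

Feature names are prefixed by their block (``AAC:``, ``DC:``, ``acACS:``,
``PSSM-AC:``) so the combined namespace stays unique.

The acACS lag statistic is, by default, the *mean of signed differences*

    phi(lag) = 1/(L - lag) * sum_k [A_k - A_{k+lag}]

which is identically zero at lag 0 (the lag-0 entry is retained so the
vector layout is |nuclei| x (lambda + 1)). A conventional auto-covariance
variant (products of deviations from the mean) is available through
``acacs_variant="covariance"``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .errors import ConfigError, DomainError, InputError, ValidationError
from .io import AMINO_ACIDS, SS_STATES, ProteinRecord, PSSMProfile, SecondaryStructureTrack

#: The four backbone nuclei, in canonical order.
NUCLEI: tuple[str, ...] = ("15N", "13Ca", "1Ha", "1HN")

#: Ordered dipeptide names (AA, AC, ..., YY), lexicographic over the
#: alphabetical residue order.
DIPEPTIDES: tuple[str, ...] = tuple(
    a + b for a in AMINO_ACIDS for b in AMINO_ACIDS
)

BLOCK_NAMES: tuple[str, ...] = ("AAC", "DC", "acACS", "PSSM-AC")


@dataclass(frozen=True)
class FeatureVector:
    """Named real-valued features; the output currency of every encoder."""

    names: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self):
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 1 or len(self.names) != values.shape[0]:
            raise ValidationError(
                f"feature vector: {len(self.names)} names vs "
                f"{values.shape} values"
            )
        if len(set(self.names)) != len(self.names):
            raise ValidationError("feature vector: duplicate feature names")
        object.__setattr__(self, "values", values)

    def __len__(self) -> int:
        return self.values.shape[0]

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.names, self.values.tolist()))

    @staticmethod
    def concat(vectors: Sequence["FeatureVector"]) -> "FeatureVector":
        names: tuple[str, ...] = ()
        for v in vectors:
            names = names + v.names
        values = (
            np.concatenate([v.values for v in vectors])
            if vectors
            else np.empty(0)
        )
        return FeatureVector(names=names, values=values)


class ACSTable:
    """Average chemical shift lookup: (residue, state, nucleus) -> ppm.

    A complete table covers 20 residues x 3 states x 4 nuclei. The package
    ships a documented default (random-coil references with nominal
    secondary-structure offsets); user tables are loaded from plain-text
    files with whitespace-separated columns ``residue state nucleus value``.
    """

    def __init__(self, entries: Mapping[tuple[str, str, str], float]):
        self._table = dict(entries)
        for (aa, st, nuc), val in self._table.items():
            if not np.isfinite(val):
                raise ConfigError(f"ACS table: non-finite value for ({aa},{st},{nuc})")

    def lookup(self, residue: str, state: str, nucleus: str) -> float:
        try:
            return self._table[(residue, state, nucleus)]
        except KeyError:
            raise ConfigError(
                f"ACS table: missing entry for residue={residue!r} "
                f"state={state!r} nucleus={nucleus!r}"
            ) from None

    def is_complete(self, nuclei: Iterable[str] = NUCLEI) -> bool:
        return all(
            (aa, st, nuc) in self._table
            for aa in AMINO_ACIDS
            for st in SS_STATES
            for nuc in nuclei
        )

    @classmethod
    def from_file(cls, path: str | Path) -> "ACSTable":
        entries: dict[tuple[str, str, str], float] = {}
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                stripped = line.strip()
                if not stripped or stripped.startswith("#"):
                    continue
                parts = stripped.split()
                if len(parts) != 4:
                    raise ConfigError(
                        f"{path}: line {lineno}: expected "
                        f"'residue state nucleus value'"
                    )
                aa, st, nuc, val = parts
                entries[(aa, st, nuc)] = float(val)
        return cls(entries)

    @classmethod
    def default(cls) -> "ACSTable":
        """The table shipped with the package (see ``data/acs_default.tsv``)."""
        ref = resources.files("lyticpred.data").joinpath("acs_default.tsv")
        with resources.as_file(ref) as path:
            return cls.from_file(path)


@dataclass(frozen=True)
class EncoderConfig:
    """Hyperparameters of the lag-based encoders.

    Defaults follow the published operating point: ``lg = 28`` PSSM-AC lags,
    ``lam = 17`` acACS lags, all four nuclei.
    """

    lg: int = 28
    lam: int = 17
    nuclei: tuple[str, ...] = NUCLEI
    acacs_variant: str = "difference"

    def __post_init__(self):
        if self.lg < 1:
            raise ConfigError("lg must be >= 1")
        if self.lam < 1:
            raise ConfigError("lambda must be >= 1")
        if not self.nuclei:
            raise ConfigError("nuclei must be non-empty")
        for nuc in self.nuclei:
            if nuc not in NUCLEI:
                raise ConfigError(f"unknown nucleus {nuc!r}; choose from {NUCLEI}")
        if self.acacs_variant not in ("difference", "covariance"):
            raise ConfigError("acacs_variant must be 'difference' or 'covariance'")


def encode_aac(record: ProteinRecord) -> FeatureVector:
    """Amino-acid composition: count(a) / L for each residue a (20 entries)."""
    counts = np.zeros(20)
    index = {aa: i for i, aa in enumerate(AMINO_ACIDS)}
    for ch in record.sequence:
        counts[index[ch]] += 1
    return FeatureVector(
        names=tuple(f"AAC:{aa}" for aa in AMINO_ACIDS),
        values=counts / record.length,
    )


def encode_dc(record: ProteinRecord) -> FeatureVector:
    """Dipeptide composition: count("ab") / (L - 1) per ordered pair (400 entries)."""
    if record.length < 2:
        raise DomainError(
            f"record {record.id!r}: dipeptide composition needs L >= 2 "
            f"(L={record.length})"
        )
    index = {dp: i for i, dp in enumerate(DIPEPTIDES)}
    counts = np.zeros(400)
    seq = record.sequence
    for k in range(len(seq) - 1):
        counts[index[seq[k : k + 2]]] += 1
    return FeatureVector(
        names=tuple(f"DC:{dp}" for dp in DIPEPTIDES),
        values=counts / (record.length - 1),
    )


def encode_pssm_ac(profile: PSSMProfile, lg: int = 28) -> FeatureVector:
    """Auto-covariance of mean-centered PSSM columns at lags 1..lg.

    For column j and lag l:

        AC(j, l) = 1/(L - l) * sum_{i=1}^{L-l} (R_ij - Rbar_j)(R_{i+l,j} - Rbar_j)

    with Rbar_j the column mean over all L rows. Output has 20 x lg entries
    ordered column-major: all lags of column A, then C, and so on.
    """
    L = profile.length
    if lg < 1:
        raise DomainError("lg must be >= 1")
    if lg >= L:
        raise DomainError(
            f"profile {profile.record_id!r}: lg={lg} must be < sequence "
            f"length L={L}"
        )
    centered = profile.scores - profile.scores.mean(axis=0, keepdims=True)
    values = np.empty((20, lg))
    for lag in range(1, lg + 1):
        values[:, lag - 1] = (centered[:-lag] * centered[lag:]).sum(axis=0) / (L - lag)
    names = tuple(
        f"PSSM-AC:{aa}:lag{lag}"
        for aa in AMINO_ACIDS
        for lag in range(1, lg + 1)
    )
    return FeatureVector(names=names, values=values.ravel())


def substitute_acs(
    record: ProteinRecord,
    track: SecondaryStructureTrack,
    table: ACSTable,
    nucleus: str,
) -> np.ndarray:
    """Replace each residue by its average chemical shift for one nucleus."""
    if track.length != record.length:
        raise ValidationError(
            f"record {record.id!r}: track length {track.length} != "
            f"sequence length {record.length}"
        )
    return np.array(
        [
            table.lookup(aa, st, nucleus)
            for aa, st in zip(record.sequence, track.states)
        ]
    )


def _acacs_lags(values: np.ndarray, lam: int, variant: str) -> np.ndarray:
    L = values.shape[0]
    out = np.empty(lam + 1)
    if variant == "difference":
        for lag in range(lam + 1):
            n = L - lag
            out[lag] = (values[:n] - values[lag:]).sum() / n
    else:  # covariance
        centered = values - values.mean()
        for lag in range(lam + 1):
            n = L - lag
            out[lag] = (centered[:n] * centered[lag:]).sum() / n
    return out


def encode_acacs(
    record: ProteinRecord,
    track: SecondaryStructureTrack,
    table: ACSTable,
    lam: int = 17,
    nuclei: Sequence[str] = NUCLEI,
    variant: str = "difference",
) -> FeatureVector:
    """Lag summary of the chemical-shift-substituted sequence.

    One block of lambda + 1 entries (lags 0..lambda) per nucleus; lag 0 is
    identically zero under the default ``difference`` variant and is kept
    for layout fidelity. Total length |nuclei| x (lambda + 1).
    """
    if lam < 1:
        raise DomainError("lambda must be >= 1")
    if lam >= record.length:
        raise DomainError(
            f"record {record.id!r}: lambda={lam} must be < sequence "
            f"length L={record.length}"
        )
    if variant not in ("difference", "covariance"):
        raise ConfigError("variant must be 'difference' or 'covariance'")
    parts: list[FeatureVector] = []
    for nuc in nuclei:
        substituted = substitute_acs(record, track, table, nuc)
        lags = _acacs_lags(substituted, lam, variant)
        parts.append(
            FeatureVector(
                names=tuple(f"acACS:{nuc}:lag{l}" for l in range(lam + 1)),
                values=lags,
            )
        )
    return FeatureVector.concat(parts)


def encode_combined(
    record: ProteinRecord,
    profile: PSSMProfile | None = None,
    track: SecondaryStructureTrack | None = None,
    table: ACSTable | None = None,
    config: EncoderConfig | None = None,
    blocks: Sequence[str] = BLOCK_NAMES,
) -> FeatureVector:
    """Concatenate the selected feature blocks in the given order.

    Default order AAC, DC, acACS, PSSM-AC; with default hyperparameters the
    combined vector has 20 + 400 + 72 + 560 = 1052 entries.
    """
    config = config or EncoderConfig()
    for b in blocks:
        if b not in BLOCK_NAMES:
            raise ConfigError(f"unknown block {b!r}; choose from {BLOCK_NAMES}")
    parts: list[FeatureVector] = []
    for b in blocks:
        if b == "AAC":
            parts.append(encode_aac(record))
        elif b == "DC":
            parts.append(encode_dc(record))
        elif b == "acACS":
            if track is None:
                raise InputError(
                    f"record {record.id!r}: acACS block requires a "
                    f"secondary-structure track"
                )
            parts.append(
                encode_acacs(
                    record,
                    track,
                    table or ACSTable.default(),
                    lam=config.lam,
                    nuclei=config.nuclei,
                    variant=config.acacs_variant,
                )
            )
        elif b == "PSSM-AC":
            if profile is None:
                raise InputError(
                    f"record {record.id!r}: PSSM-AC block requires a PSSM profile"
                )
            parts.append(encode_pssm_ac(profile, lg=config.lg))
    return FeatureVector.concat(parts)
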