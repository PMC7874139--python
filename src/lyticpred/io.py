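"""Readers and writers for external formats and the labeled-dataset abstraction.

Formats handled here:

* FASTA (read/write) — labels are carried by the dataset manifest (one file
  per class), never parsed out of headers.
* PSI-BLAST ASCII PSSM (``-out_ascii_pssm`` layout) — read only; the toolkit
  parses profiles, it does not run PSI-BLAST.
* PSIPRED ``.ss2`` (VFORMAT) — read only; a plain-string constructor is the
  convenience fallback.
* A tab-separated manifest linking record id -> pssm path -> ss2 path.

The canonical amino-acid column order everywhere in the package is
alphabetical (``A C D E ... Y``); PSSM files in PSI-BLAST's native order are
permuted on read.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO

from .errors import ParseError, ValidationError

logger = logging.getLogger(__name__)

#: Canonical (alphabetical) 20-letter amino-acid order used for every
#: feature namespace in the package.
AMINO_ACIDS: str = "ACDEFGHIKLMNPQRSTVWY"

#: Ambiguous one-letter codes rejected at load time.
AMBIGUOUS_LETTERS: frozenset = frozenset("BJOUXZ")

#: PSI-BLAST's native column order in ASCII PSSM files.
PSIBLAST_COLUMN_ORDER: str = "ARNDCQEGHILKMFPSTWYV"

#: Three-state secondary-structure alphabet (PSIPRED convention).
SS_STATES: str = "HEC"

POSITIVE = 1
NEGATIVE = 0

_VALID_SET = frozenset(AMINO_ACIDS)


@dataclass(frozen=True)
class ProteinRecord:
    """A labeled, validated amino-acid sequence.

    Parameters
    ----------
    id : str
        Unique sequence identifier.
    sequence : str
        Sequence over the 20-letter alphabet. Lowercase input is upcased
        before validation; ambiguous letters (B, J, O, U, X, Z) are rejected.
    label : int
        Binary class: ``POSITIVE`` (1) or ``NEGATIVE`` (0).
    """

    id: str
    sequence: str
    label: int

    def __post_init__(self):
        seq = self.sequence.upper()
        object.__setattr__(self, "sequence", seq)
        if not seq:
            raise ValidationError(f"record {self.id!r}: empty sequence")
        for ch in seq:
            if ch not in _VALID_SET:
                kind = "ambiguous" if ch in AMBIGUOUS_LETTERS else "invalid"
                raise ValidationError(
                    f"record {self.id!r}: {kind} letter {ch!r} in sequence"
                )
        if self.label not in (POSITIVE, NEGATIVE):
            raise ValidationError(f"record {self.id!r}: label must be 0 or 1")

    @property
    def length(self) -> int:
        """Number of residues L."""
        return len(self.sequence)


@dataclass(frozen=True)
class PSSMProfile:
    """An L x 20 position-specific score matrix aligned to a sequence.

    ``scores`` columns follow :data:`AMINO_ACIDS` order regardless of the
    order in the source file.
    """

    record_id: str
    scores: np.ndarray

    def __post_init__(self):
        scores = np.asarray(self.scores, dtype=float)
        if scores.ndim != 2 or scores.shape[1] != 20:
            raise ValidationError(
                f"profile {self.record_id!r}: expected L x 20 matrix, "
                f"got shape {scores.shape}"
            )
        object.__setattr__(self, "scores", scores)

    @property
    def length(self) -> int:
        return self.scores.shape[0]


@dataclass(frozen=True)
class SecondaryStructureTrack:
    """Per-residue three-state (H/E/C) secondary structure string."""

    record_id: str
    states: str

    def __post_init__(self):
        for ch in self.states:
            if ch not in SS_STATES:
                raise ValidationError(
                    f"track {self.record_id!r}: state {ch!r} not in "
                    f"{{H, E, C}}"
                )

    @classmethod
    def from_string(cls, record_id: str, states: str) -> "SecondaryStructureTrack":
        """Plain-string fallback constructor (e.g. ``"CCEEHH"``)."""
        return cls(record_id=record_id, states=states.upper())

    @property
    def length(self) -> int:
        return len(self.states)


@dataclass
class LabeledDataset:
    """Ordered protein records with optional aligned profiles and tracks."""

    records: list[ProteinRecord] = field(default_factory=list)
    profiles: dict[str, PSSMProfile] = field(default_factory=dict)
    tracks: dict[str, SecondaryStructureTrack] = field(default_factory=dict)

    def __post_init__(self):
        ids = [r.id for r in self.records]
        if len(ids) != len(set(ids)):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError(f"duplicate record ids: {dup}")
        for rid in self.profiles:
            self._check_profile(rid)
        for rid in self.tracks:
            self._check_track(rid)

    def _record_by_id(self, rid: str) -> ProteinRecord:
        for r in self.records:
            if r.id == rid:
                return r
        raise ValidationError(f"no record with id {rid!r}")

    def _check_profile(self, rid: str) -> None:
        rec = self._record_by_id(rid)
        prof = self.profiles[rid]
        if prof.length != rec.length:
            raise ValidationError(
                f"profile {rid!r}: {prof.length} rows but sequence has "
                f"{rec.length} residues"
            )

    def _check_track(self, rid: str) -> None:
        rec = self._record_by_id(rid)
        track = self.tracks[rid]
        if track.length != rec.length:
            raise ValidationError(
                f"track {rid!r}: {track.length} states but sequence has "
                f"{rec.length} residues"
            )

    def attach_profile(self, profile: PSSMProfile) -> None:
        self.profiles[profile.record_id] = profile
        self._check_profile(profile.record_id)

    def attach_track(self, track: SecondaryStructureTrack) -> None:
        self.tracks[track.record_id] = track
        self._check_track(track.record_id)

    @property
    def positives(self) -> list[ProteinRecord]:
        return [r for r in self.records if r.label == POSITIVE]

    @property
    def negatives(self) -> list[ProteinRecord]:
        return [r for r in self.records if r.label == NEGATIVE]

    def __len__(self) -> int:
        return len(self.records)


def read_fasta(path: str | Path, label: int) -> list[ProteinRecord]:
    """Read one FASTA file into validated records sharing one class label.

    Raises
    ------
    ParseError
        If the file is not FASTA (first non-blank line does not start
        with ``>``).
    ValidationError
        If any sequence contains a letter outside the 20-letter alphabet;
        the message names the record id and the offending character.
    """
    path = Path(path)
    with open(path) as fh:
        lineno = 0
        for line in fh:
            lineno += 1
            if line.strip():
                if not line.startswith(">"):
                    raise ParseError(
                        f"{path}: line {lineno}: expected '>' header, "
                        f"got {line.strip()[:30]!r}"
                    )
                break
    records = [
        ProteinRecord(id=entry.id, sequence=str(entry.seq), label=label)
        for entry in SeqIO.parse(str(path), "fasta")
    ]
    if not records:
        logger.warning("%s: no FASTA entries found", path)
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path) -> None:
    """Write records as minimal two-line FASTA entries (id + sequence)."""
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n{rec.sequence}\n")


def _looks_like_pssm_header(tokens: Sequence[str]) -> bool:
    return len(tokens) >= 20 and all(
        t in _VALID_SET and len(t) == 1 for t in tokens[:20]
    )


def read_pssm_ascii(path: str | Path, record_id: str | None = None) -> PSSMProfile:
    """Parse a PSI-BLAST ``-out_ascii_pssm`` file into an L x 20 profile.

    Only the first 20 numeric columns (substitution scores) are kept; the
    percentage and information-content columns are discarded. Columns are
    re-ordered into the canonical alphabetical order whatever the order in
    the file's header.
    """
    path = Path(path)
    if record_id is None:
        record_id = path.stem
    column_order: str | None = None
    rows: list[list[float]] = []
    expected_index = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            tokens = line.split()
            if not tokens:
                continue
            if column_order is None:
                if _looks_like_pssm_header(tokens):
                    column_order = "".join(tokens[:20])
                    if set(column_order) != _VALID_SET:
                        raise ParseError(
                            f"{path}: line {lineno}: header does not name "
                            f"all 20 amino acids"
                        )
                continue
            if not tokens[0].isdigit():
                # Footer (Lambda/K statistics) terminates the matrix.
                break
            expected_index += 1
            if int(tokens[0]) != expected_index:
                raise ParseError(
                    f"{path}: line {lineno}: residue index {tokens[0]} out "
                    f"of order (expected {expected_index})"
                )
            if len(tokens) < 22:
                raise ParseError(
                    f"{path}: line {lineno}: expected >= 20 score columns, "
                    f"found {len(tokens) - 2}"
                )
            try:
                rows.append([float(t) for t in tokens[2:22]])
            except ValueError as exc:
                raise ParseError(
                    f"{path}: line {lineno}: non-numeric score cell ({exc})"
                ) from None
    if column_order is None:
        raise ParseError(f"{path}: no PSSM header line found")
    if not rows:
        raise ParseError(f"{path}: no PSSM data rows found")
    raw = np.array(rows, dtype=float)
    # Permute file columns into canonical alphabetical order.
    perm = [column_order.index(aa) for aa in AMINO_ACIDS]
    return PSSMProfile(record_id=record_id, scores=raw[:, perm])


def read_ss2(path: str | Path, record_id: str | None = None) -> SecondaryStructureTrack:
    """Parse a PSIPRED VFORMAT ``.ss2`` file into a state track.

    Expected row layout after the comment/blank preamble:
    ``index residue state pC pH pE``.
    """
    path = Path(path)
    if record_id is None:
        record_id = path.stem
    states: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped or stripped.startswith("#"):
                continue
            tokens = stripped.split()
            if len(tokens) < 3:
                raise ParseError(
                    f"{path}: line {lineno}: expected 'idx res state p p p' "
                    f"row, got {stripped[:40]!r}"
                )
            state = tokens[2]
            if state not in SS_STATES:
                raise ParseError(
                    f"{path}: line {lineno}: state {state!r} not in {{H, E, C}}"
                )
            states.append(state)
    return SecondaryStructureTrack(record_id=record_id, states="".join(states))


def read_manifest(path: str | Path) -> dict[str, dict[str, Path]]:
    """Read a tab-separated manifest ``id<TAB>pssm_path<TAB>ss2_path``.

    Relative paths are resolved against the manifest's directory. Either
    path column may be ``-`` to indicate absence.
    """
    path = Path(path)
    base = path.parent
    out: dict[str, dict[str, Path]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.rstrip("\n")
            if not stripped.strip() or stripped.startswith("#"):
                continue
            parts = stripped.split("\t")
            if len(parts) != 3:
                raise ParseError(
                    f"{path}: line {lineno}: expected 3 tab-separated "
                    f"columns, got {len(parts)}"
                )
            rid, pssm, ss2 = parts
            if rid in out:
                raise ParseError(f"{path}: line {lineno}: duplicate id {rid!r}")
            entry: dict[str, Path] = {}
            if pssm != "-":
                entry["pssm"] = base / pssm
            if ss2 != "-":
                entry["ss2"] = base / ss2
            out[rid] = entry
    return out


def load_dataset(
    pos_fasta: str | Path,
    neg_fasta: str | Path,
    manifest: str | Path | None = None,
) -> LabeledDataset:
    """Load a two-FASTA dataset, optionally attaching profiles and tracks."""
    records = read_fasta(pos_fasta, POSITIVE) + read_fasta(neg_fasta, NEGATIVE)
    ds = LabeledDataset(records=records)
    if manifest is not None:
        for rid, entry in read_manifest(manifest).items():
            if "pssm" in entry:
                ds.attach_profile(read_pssm_ascii(entry["pssm"], record_id=rid))
            if "ss2" in entry:
                ds.attach_track(read_ss2(entry["ss2"], record_id=rid))
    return ds
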