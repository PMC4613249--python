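"""Readers and writers for all external inputs and outputs.

Handles FASTA sequence files, PSI-BLAST ASCII PSSM profiles, per-residue
disorder score tables, InterPro domain annotation tables, class-label
tables, and CSV feature matrices / prediction reports.  All readers
validate rather than silently coerce: malformed numeric fields, mismatched
sequence lengths and out-of-range scores raise :class:`FormatError`.
"""

from __future__ import annotations

import csv
import logging
import math
import random
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO

logger = logging.getLogger(__name__)

#: The 20 standard one-letter amino-acid codes in PSI-BLAST's native
#: column order.  Used for PSSM columns and every per-residue table.
AMINO_ACIDS: str = "ARNDCQEGHILKMFPSTWYV"

#: Ambiguous / nonstandard one-letter codes removed during dataset filtering.
NONSTANDARD_RESIDUES: frozenset[str] = frozenset("BJOUXZ")

#: Minimum sequence length retained by dataset filtering.
MIN_SEQUENCE_LENGTH: int = 50


class FormatError(ValueError):
    """Raised when an input file violates its declared format."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ProteinRecord:
    """A protein sequence with an identifier and an optional class label.

    ``label`` is 1 for an antifreeze protein (AFP), 0 for a non-AFP, or
    ``None`` when unlabeled.
    """

    id: str
    sequence: str
    label: int | None = None

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("protein id must be non-empty")
        if len(self.sequence) < 1:
            raise ValueError(f"{self.id}: sequence must be non-empty")
        if self.label not in (None, 0, 1):
            raise ValueError(f"{self.id}: label must be 0, 1 or None")

    @property
    def length(self) -> int:
        return len(self.sequence)

    def with_label(self, label: int) -> "ProteinRecord":
        return ProteinRecord(self.id, self.sequence, label)


@dataclass(frozen=True)
class PSSMProfile:
    """An L x 20 position-specific scoring matrix for one protein.

    Rows follow residue positions; columns follow :data:`AMINO_ACIDS`
    (recorded in ``alphabet`` so downstream encoders never guess).
    Entry (i, j) is the log-odds score of residue i mutating to amino
    acid j.
    """

    protein_id: str
    scores: np.ndarray
    alphabet: str = AMINO_ACIDS

    def __post_init__(self) -> None:
        scores = np.asarray(self.scores, dtype=float)
        if scores.ndim != 2 or scores.shape[1] != len(self.alphabet):
            raise ValueError(
                f"{self.protein_id}: PSSM must be L x {len(self.alphabet)}, "
                f"got shape {scores.shape}"
            )
        object.__setattr__(self, "scores", scores)

    @property
    def length(self) -> int:
        return int(self.scores.shape[0])


@dataclass(frozen=True)
class DisorderProfile:
    """Per-residue intrinsic-disorder scores in [0, 1] for one protein."""

    protein_id: str
    scores: np.ndarray

    def __post_init__(self) -> None:
        scores = np.asarray(self.scores, dtype=float)
        if scores.ndim != 1:
            raise ValueError(f"{self.protein_id}: scores must be a vector")
        if scores.size and (scores.min() < 0.0 or scores.max() > 1.0):
            raise FormatError(
                f"{self.protein_id}: disorder scores must lie in [0, 1]"
            )
        object.__setattr__(self, "scores", scores)

    @property
    def length(self) -> int:
        return int(self.scores.size)


@dataclass(frozen=True)
class DomainAnnotation:
    """The set of InterPro entries annotated on one protein (may be empty)."""

    protein_id: str
    entries: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        entries = frozenset(self.entries)
        for entry in entries:
            if not _valid_interpro_id(entry):
                raise FormatError(
                    f"{self.protein_id}: invalid InterPro id {entry!r}"
                )
        object.__setattr__(self, "entries", entries)


def _valid_interpro_id(entry: str) -> bool:
    return (
        len(entry) == 9
        and entry.startswith("IPR")
        and entry[3:].isdigit()
    )


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read a FASTA file into :class:`ProteinRecord` objects, in file order.

    The record id is the first whitespace-delimited token of the header.
    Sequences are uppercased and trailing ``*`` stop symbols stripped.
    Duplicate ids raise (annotation joins require unique keys); a file whose
    first non-blank line is not a header raises :class:`FormatError`.
    """
    path = Path(path)
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            if not line.strip():
                continue
            if not line.startswith(">"):
                raise FormatError(
                    f"{path}:{lineno}: expected a FASTA header line "
                    f"starting with '>', got {line.strip()[:40]!r}"
                )
            break
        else:
            warnings.warn(f"{path}: empty FASTA file", stacklevel=2)
            return []

    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for seq_record in SeqIO.parse(str(path), "fasta"):
        rid = seq_record.id
        if not rid:
            raise FormatError(f"{path}: FASTA entry with empty header")
        if rid in seen:
            raise FormatError(f"{path}: duplicate FASTA id {rid!r}")
        seen.add(rid)
        seq = str(seq_record.seq).upper().rstrip("*")
        if not seq:
            raise FormatError(f"{path}: entry {rid!r} has an empty sequence")
        records.append(ProteinRecord(id=rid, sequence=seq))
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path,
                width: int = 60) -> None:
    """Write records as wrapped FASTA (inverse of :func:`read_fasta`)."""
    with open(path, "w") as handle:
        for rec in records:
            handle.write(f">{rec.id}\n")
            for start in range(0, len(rec.sequence), width):
                handle.write(rec.sequence[start:start + width] + "\n")


# ---------------------------------------------------------------------------
# Dataset filtering and splitting
# ---------------------------------------------------------------------------

def filter_dataset(
    records: Sequence[ProteinRecord],
    min_length: int = MIN_SEQUENCE_LENGTH,
    forbidden: frozenset[str] = NONSTANDARD_RESIDUES,
) -> tuple[list[ProteinRecord], list[tuple[str, str]]]:
    """Screen out short sequences and sequences with nonstandard residues.

    Returns ``(kept, rejected)`` where each rejected entry is
    ``(protein_id, reason)`` with reason in ``{"too_short",
    "nonstandard_residue"}``.  Length is checked first; filtering is total
    and idempotent.
    """
    kept: list[ProteinRecord] = []
    rejected: list[tuple[str, str]] = []
    forbidden = frozenset(forbidden)
    for rec in records:
        if rec.length < min_length:
            rejected.append((rec.id, "too_short"))
        elif forbidden & set(rec.sequence):
            rejected.append((rec.id, "nonstandard_residue"))
        else:
            kept.append(rec)
    return kept, rejected


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def split_holdout(
    records: Sequence[ProteinRecord],
    test_fraction: float = 0.2,
    seed: int = 0,
) -> tuple[list[ProteinRecord], list[ProteinRecord]]:
    """Random per-class train/test split preserving class proportions.

    The test set receives round-half-up(``test_fraction`` x class size)
    records of each class, drawn without replacement; everything else is
    training data.  Reproducible under ``seed``.
    """
    if not 0.0 < test_fraction < 1.0:
        raise ValueError("test_fraction must lie strictly between 0 and 1")
    by_class: dict[int, list[ProteinRecord]] = {}
    for rec in records:
        if rec.label is None:
            raise ValueError(f"{rec.id}: unlabeled record in split_holdout")
        by_class.setdefault(rec.label, []).append(rec)
    rng = random.Random(seed)
    train: list[ProteinRecord] = []
    test: list[ProteinRecord] = []
    for label in sorted(by_class):
        members = by_class[label]
        if len(members) < 2:
            raise ValueError(
                f"class {label} has {len(members)} member(s); "
                "need at least 2 to split"
            )
        n_test = _round_half_up(test_fraction * len(members))
        test_idx = set(rng.sample(range(len(members)), n_test))
        for i, rec in enumerate(members):
            (test if i in test_idx else train).append(rec)
    return train, test


# ---------------------------------------------------------------------------
# PSSM files
# ---------------------------------------------------------------------------

def read_pssm(
    path: str | Path,
    record: ProteinRecord | None = None,
    protein_id: str | None = None,
) -> PSSMProfile:
    """Read a PSSM from a PSI-BLAST ASCII file or a plain L x 20 matrix.

    The PSI-BLAST ``-out_ascii_pssm`` dialect (header lines, then one row
    per residue: position, residue letter, 20 log-odds columns, trailing
    weighted-percentage columns) is auto-detected; only the first 20 score
    columns are read.  A headerless whitespace-delimited L x 20 numeric
    matrix is also accepted.  When ``record`` is given, the residue column
    is cross-checked against its sequence and row count must equal its
    length.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    stripped = [ln for ln in lines if ln.strip()]
    if not stripped:
        raise FormatError(f"{path}: empty PSSM file")

    first_tokens = stripped[0].split()
    if all(_is_number(tok) for tok in first_tokens):
        rows = _parse_plain_matrix(path, stripped)
        residues = None
    else:
        rows, residues = _parse_psiblast_ascii(path, lines)

    scores = np.asarray(rows, dtype=float)
    pid = protein_id or (record.id if record else path.stem)
    if record is not None:
        if scores.shape[0] != record.length:
            raise FormatError(
                f"{path}: PSSM has {scores.shape[0]} rows but sequence "
                f"{record.id!r} has length {record.length}"
            )
        if residues is not None and "".join(residues) != record.sequence:
            mism = next(
                i for i, (a, b) in enumerate(zip(residues, record.sequence))
                if a != b
            )
            raise FormatError(
                f"{path}: PSSM residue column disagrees with sequence "
                f"{record.id!r} at position {mism + 1} "
                f"({residues[mism]!r} vs {record.sequence[mism]!r})"
            )
    return PSSMProfile(protein_id=pid, scores=scores)


def _is_number(token: str) -> bool:
    try:
        float(token)
    except ValueError:
        return False
    return True


def _parse_plain_matrix(path: Path, stripped: list[str]) -> list[list[float]]:
    rows = []
    for ln in stripped:
        vals = ln.split()
        if len(vals) != 20:
            raise FormatError(
                f"{path}: plain PSSM rows need 20 columns, got {len(vals)}"
            )
        rows.append([float(v) for v in vals])
    return rows


def _parse_psiblast_ascii(
    path: Path, lines: list[str]
) -> tuple[list[list[float]], list[str]]:
    # Locate the column-header line: 40 (or 20) amino-acid letters.
    header_idx = None
    for i, ln in enumerate(lines):
        toks = ln.split()
        if len(toks) in (20, 40) and all(
            t in AMINO_ACIDS and len(t) == 1 for t in toks
        ):
            header_idx = i
            break
    if header_idx is None:
        raise FormatError(
            f"{path}: not a PSI-BLAST ASCII PSSM (no amino-acid header row)"
        )
    rows: list[list[float]] = []
    residues: list[str] = []
    expected_pos = 1
    for ln in lines[header_idx + 1:]:
        toks = ln.split()
        if not toks:
            break  # blank line terminates the matrix block
        if not toks[0].isdigit():
            break  # footer (Lambda/K statistics)
        if len(toks) < 22:
            raise FormatError(
                f"{path}: truncated PSSM row at position {toks[0]}"
            )
        if int(toks[0]) != expected_pos:
            raise FormatError(
                f"{path}: non-consecutive PSSM row numbering at {toks[0]}"
            )
        expected_pos += 1
        residues.append(toks[1])
        try:
            rows.append([float(v) for v in toks[2:22]])
        except ValueError as exc:
            raise FormatError(
                f"{path}: non-numeric PSSM score in row {toks[0]}: {exc}"
            ) from None
    if not rows:
        raise FormatError(f"{path}: PSSM file contains no score rows")
    return rows, residues


def write_pssm(profile: PSSMProfile, path: str | Path,
               sequence: str | None = None) -> None:
    """Write a PSSM in the PSI-BLAST ASCII dialect (round-trips read_pssm)."""
    seq = sequence or "X" * profile.length
    with open(path, "w") as handle:
        handle.write("\nLast position-specific scoring matrix computed\n")
        handle.write(" " * 11 + "  ".join(AMINO_ACIDS) + "\n")
        for i, row in enumerate(profile.scores):
            cells = " ".join(f"{v:6.0f}" if float(v).is_integer()
                             else f"{v:8.3f}" for v in row)
            # PSI-BLAST appends weighted observed percentages; pad with zeros
            pct = " ".join("0" for _ in range(20))
            handle.write(f"{i + 1:5d} {seq[i]} {cells}  {pct}\n")
        handle.write("\n")


# ---------------------------------------------------------------------------
# Disorder, domain and label tables
# ---------------------------------------------------------------------------

def read_disorder(path: str | Path) -> dict[str, DisorderProfile]:
    """Read per-residue disorder scores keyed by protein id.

    Accepts tab/whitespace-delimited rows ``protein_id  position  score``
    (multi-protein, positions 1-based consecutive per protein).  Scores
    outside [0, 1] raise.
    """
    path = Path(path)
    per_protein: dict[str, list[tuple[int, float]]] = {}
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            toks = line.split()
            if len(toks) != 3:
                raise FormatError(
                    f"{path}:{lineno}: expected 'id position score', "
                    f"got {len(toks)} fields"
                )
            pid, pos_s, score_s = toks
            try:
                pos, score = int(pos_s), float(score_s)
            except ValueError:
                raise FormatError(
                    f"{path}:{lineno}: malformed numeric field"
                ) from None
            if not 0.0 <= score <= 1.0:
                raise FormatError(
                    f"{path}:{lineno}: disorder score {score} outside [0, 1]"
                )
            per_protein.setdefault(pid, []).append((pos, score))
    profiles = {}
    for pid, rows in per_protein.items():
        rows.sort()
        positions = [p for p, _ in rows]
        if positions != list(range(1, len(rows) + 1)):
            raise FormatError(
                f"{path}: protein {pid!r} has non-consecutive positions"
            )
        profiles[pid] = DisorderProfile(pid, np.array([s for _, s in rows]))
    return profiles


def write_disorder(profiles: Iterable[DisorderProfile],
                   path: str | Path) -> None:
    with open(path, "w") as handle:
        for prof in profiles:
            for i, score in enumerate(prof.scores, start=1):
                handle.write(f"{prof.protein_id}\t{i}\t{score:.6f}\n")


def read_domains(path: str | Path) -> dict[str, DomainAnnotation]:
    """Read two-column ``protein_id  interpro_id`` tables (set semantics)."""
    path = Path(path)
    entries: dict[str, set[str]] = {}
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            toks = line.split()
            if len(toks) != 2:
                raise FormatError(
                    f"{path}:{lineno}: expected 'protein_id interpro_id'"
                )
            pid, ipr = toks
            if not _valid_interpro_id(ipr):
                raise FormatError(
                    f"{path}:{lineno}: invalid InterPro id {ipr!r}"
                )
            entries.setdefault(pid, set()).add(ipr)
    return {
        pid: DomainAnnotation(pid, frozenset(iprs))
        for pid, iprs in entries.items()
    }


def write_domains(annotations: Iterable[DomainAnnotation],
                  path: str | Path) -> None:
    with open(path, "w") as handle:
        for ann in annotations:
            for ipr in sorted(ann.entries):
                handle.write(f"{ann.protein_id}\t{ipr}\n")


def read_labels(path: str | Path) -> dict[str, int]:
    """Read two-column ``protein_id  label`` tables (label in {0, 1})."""
    path = Path(path)
    labels: dict[str, int] = {}
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            toks = line.split()
            if len(toks) != 2 or toks[1] not in ("0", "1"):
                raise FormatError(
                    f"{path}:{lineno}: expected 'protein_id 0|1'"
                )
            if toks[0] in labels:
                raise FormatError(
                    f"{path}:{lineno}: duplicate label for {toks[0]!r}"
                )
            labels[toks[0]] = int(toks[1])
    return labels


def write_labels(records: Iterable[ProteinRecord], path: str | Path) -> None:
    with open(path, "w") as handle:
        for rec in records:
            if rec.label is None:
                raise ValueError(f"{rec.id}: cannot write missing label")
            handle.write(f"{rec.id}\t{rec.label}\n")


def attach_labels(records: Sequence[ProteinRecord],
                  labels: dict[str, int]) -> list[ProteinRecord]:
    """Return records with labels joined on id; unknown ids raise."""
    missing = [rec.id for rec in records if rec.id not in labels]
    if missing:
        raise KeyError(f"no label for protein(s): {missing[:5]}")
    return [rec.with_label(labels[rec.id]) for rec in records]


# ---------------------------------------------------------------------------
# Feature matrices and prediction reports (CSV)
# ---------------------------------------------------------------------------

def write_feature_matrix(matrix, path: str | Path) -> None:
    """Write a FeatureMatrix as CSV: id column, feature columns, optional
    trailing label column.  Lossless against :func:`read_feature_matrix`."""
    frame = matrix.to_dataframe()
    frame.to_csv(path, index_label="protein_id", float_format="%.12g")


def read_feature_matrix(path: str | Path):
    """Inverse of :func:`write_feature_matrix`."""
    import pandas as pd

    from .feature_assembly import FeatureMatrix

    frame = pd.read_csv(path, index_col="protein_id")
    return FeatureMatrix.from_dataframe(frame)


def write_predictions(
    ids: Sequence[str],
    labels: Sequence[int],
    votes: Sequence[int],
    n_members: int,
    path: str | Path,
) -> None:
    """CSV prediction report: id, predicted label, positive votes of G."""
    with open(path, "w", newline="") as handle:
        writer = csv.writer(handle)
        writer.writerow(["protein_id", "predicted_label",
                         "positive_votes", "n_members"])
        for pid, lab, vote in zip(ids, labels, votes, strict=True):
            writer.writerow([pid, int(lab), int(vote), n_members])
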