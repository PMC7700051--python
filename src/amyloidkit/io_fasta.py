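"""Reading and sanitizing labelled protein sequences.

Input is the two-FASTA convention (one file of amyloid/positive sequences,
one of non-amyloid/negative sequences) or a single FASTA plus a two-column
tab-separated label table.  Sequences are sanitized to the 20-letter
standard amino-acid alphabet before any downstream encoding: lowercase is
uppercased, whitespace and gap characters are stripped, and ambiguous or
non-standard residues (B, Z, X, U, O, ...) are removed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

from Bio import SeqIO

logger = logging.getLogger(__name__)

#: The 20 standard amino-acid one-letter codes, alphabetical.
STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"
_AA_SET = frozenset(STANDARD_AA)


class EmptySequenceError(ValueError):
    """Raised when a record has no standard residues left after sanitization."""


class DuplicateIdError(ValueError):
    """Raised when the same record id appears more than once across inputs."""


@dataclass(frozen=True)
class ProteinRecord:
    """One labelled, sanitized amino-acid sequence.

    Attributes
    ----------
    id : str
        First whitespace-delimited token of the FASTA header.
    sequence : str
        Uppercase sequence over the 20 standard letters.
    label : int
        1 for amyloid (positive), 0 for non-amyloid (negative).
    """

    id: str
    sequence: str
    label: int

    def __post_init__(self) -> None:
        if self.label not in (0, 1):
            raise ValueError(f"label must be 0 or 1, got {self.label!r}")
        if not self.sequence:
            raise EmptySequenceError(f"record {self.id!r} has an empty sequence")
        bad = set(self.sequence) - _AA_SET
        if bad:
            raise ValueError(
                f"record {self.id!r} contains non-standard residues {sorted(bad)}; "
                "sanitize first"
            )

    @property
    def length(self) -> int:
        """Residue count L after sanitization."""
        return len(self.sequence)


def sanitize_sequence(raw: str) -> str:
    """Return ``raw`` uppercased and restricted to the 20 standard letters.

    Whitespace, gap characters ('-', '.', '*') and any non-standard residue
    code (B, Z, X, U, O, ...) are removed.  May return an empty string;
    callers decide whether that is an error.  Idempotent.
    """
    return "".join(c for c in raw.upper() if c in _AA_SET)


def _parse_fasta(path: str | Path, label: int) -> tuple[list[ProteinRecord], dict[str, int]]:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"FASTA file not found: {path}")
    records: list[ProteinRecord] = []
    removed: dict[str, int] = {}
    for entry in SeqIO.parse(str(path), "fasta"):
        rec_id = entry.id
        raw = str(entry.seq)
        clean = sanitize_sequence(raw)
        n_removed = len(raw) - len(clean)
        removed[rec_id] = n_removed
        if n_removed:
            logger.info("record %s: removed %d non-standard characters", rec_id, n_removed)
        if not clean:
            raise EmptySequenceError(
                f"record {rec_id!r} in {path} is empty after sanitization"
            )
        records.append(ProteinRecord(id=rec_id, sequence=clean, label=label))
    return records, removed


def read_labelled_fasta(
    positives_path: str | Path,
    negatives_path: str | Path,
    return_removed_counts: bool = False,
):
    """Read the two-FASTA convention into a list of :class:`ProteinRecord`.

    Records from ``positives_path`` get label 1 (amyloid), records from
    ``negatives_path`` label 0.  Each record is sanitized; the number of
    removed characters per record is logged and, when
    ``return_removed_counts`` is true, returned as a second value
    (a dict id -> count).

    Raises
    ------
    FileNotFoundError
        If either file is missing.
    EmptySequenceError
        If any record sanitizes to the empty string (message names the id).
    DuplicateIdError
        If an id occurs more than once across both files.
    """
    pos, removed_pos = _parse_fasta(positives_path, label=1)
    neg, removed_neg = _parse_fasta(negatives_path, label=0)
    records = pos + neg
    _check_unique_ids(records)
    if return_removed_counts:
        return records, {**removed_pos, **removed_neg}
    return records


def read_fasta_with_labels(
    fasta_path: str | Path, labels_path: str | Path
) -> list[ProteinRecord]:
    """Read a single FASTA plus a tab-separated label table (header ``id\\tlabel``)."""
    labels_path = Path(labels_path)
    if not labels_path.exists():
        raise FileNotFoundError(f"label table not found: {labels_path}")
    label_map: dict[str, int] = {}
    with open(labels_path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:2] != ["id", "label"]:
            raise ValueError(
                f"label table must start with header 'id\\tlabel', got {header!r}"
            )
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            rec_id, label = line.split("\t")[:2]
            if rec_id in label_map:
                raise DuplicateIdError(f"duplicate id in label table: {rec_id!r}")
            label_map[rec_id] = int(label)
    unlabelled, _ = _parse_fasta(fasta_path, label=0)
    records = []
    for rec in unlabelled:
        if rec.id not in label_map:
            raise ValueError(f"record {rec.id!r} missing from label table")
        records.append(ProteinRecord(id=rec.id, sequence=rec.sequence, label=label_map[rec.id]))
    _check_unique_ids(records)
    return records


def _check_unique_ids(records: list[ProteinRecord]) -> None:
    seen: set[str] = set()
    for rec in records:
        if rec.id in seen:
            raise DuplicateIdError(f"duplicate record id: {rec.id!r}")
        seen.add(rec.id)


def write_fasta(records: list[ProteinRecord], path: str | Path, width: int = 70) -> None:
    """Write records as plain FASTA, wrapping sequence lines at ``width``."""
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")
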