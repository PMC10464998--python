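"""Protein sequence, label and prediction I/O.

All downstream modules consume the canonical representation enforced here:
uppercase sequences over the 20-letter alphabet, 1-based residue indexing
(residue 1 is the N-terminus). The default validation policy is ``strict``
(any non-canonical letter is an error); ``map-ambiguous`` maps U->C, B->D,
Z->E, O->K and drops X and gap characters.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd
from Bio import SeqIO

from .aa_tables import CANONICAL_AA

logger = logging.getLogger(__name__)

_CANONICAL_SET = set(CANONICAL_AA)
_AMBIGUOUS_MAP = {"U": "C", "B": "D", "Z": "E", "O": "K"}
_DROP_CHARS = set("X*-.")


class SequenceError(ValueError):
    """Raised for sequences that violate the canonical-alphabet contract."""


@dataclass
class ProteinRecord:
    """One protein: identifier, canonical sequence, optional binary label.

    ``label`` is CRBN-specific: 1 means the protein is degradable through a
    CRBN-recruiting degrader, 0 means it is not. Proteins degradable only
    through other E3 ligases are the label provider's responsibility (they
    are not inferred here).
    """

    id: str
    sequence: str
    label: int | None = None
    meta: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class Dataset:
    """Ordered protein collection; row i of any derived matrix is record i."""

    records: list[ProteinRecord]
    provenance: str = ""

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for rec in self.records:
            if rec.id in seen:
                raise ValueError(f"duplicate record id {rec.id!r} in dataset")
            seen.add(rec.id)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[ProteinRecord]:
        return iter(self.records)

    def __getitem__(self, i: int) -> ProteinRecord:
        return self.records[i]

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    def labels(self) -> np.ndarray:
        """Observed labels as an int array; raises if any record is unlabeled."""
        if any(r.label is None for r in self.records):
            missing = [r.id for r in self.records if r.label is None]
            raise ValueError(f"unlabeled records present: {missing[:5]}")
        return np.array([int(r.label) for r in self.records])

    def labeled_subset(self) -> "Dataset":
        return Dataset(
            [r for r in self.records if r.label is not None],
            provenance=self.provenance,
        )


def validate_sequence(sequence: str, policy: str = "strict") -> str:
    """Normalise a raw sequence to the canonical 20-letter alphabet.

    Parameters
    ----------
    sequence:
        Raw amino-acid string (any case, may contain whitespace).
    policy:
        ``strict`` errors on any non-canonical letter; ``map-ambiguous``
        maps U->C, B->D, Z->E, O->K and removes X / gap characters.

    The function is idempotent: validating an already-canonical sequence
    returns it unchanged.
    """
    if policy not in ("strict", "map-ambiguous"):
        raise ValueError(f"unknown validation policy {policy!r}")
    seq = "".join(sequence.split()).upper()
    if policy == "strict":
        for i, ch in enumerate(seq):
            if ch not in _CANONICAL_SET:
                raise SequenceError(
                    f"non-canonical residue {ch!r} at position {i + 1} "
                    f"(strict policy; use policy='map-ambiguous' to map/drop)"
                )
        if not seq:
            raise SequenceError("empty sequence")
        return seq
    out = []
    for i, ch in enumerate(seq):
        if ch in _CANONICAL_SET:
            out.append(ch)
        elif ch in _AMBIGUOUS_MAP:
            out.append(_AMBIGUOUS_MAP[ch])
        elif ch in _DROP_CHARS:
            continue
        else:
            raise SequenceError(f"unmappable character {ch!r} at position {i + 1}")
    if not out:
        raise SequenceError("empty sequence after ambiguity mapping")
    return "".join(out)


def read_fasta(path, policy: str = "strict") -> list[ProteinRecord]:
    """Read a FASTA file into validated :class:`ProteinRecord` objects.

    The record id is the first whitespace-delimited token of the header.
    Duplicate ids and empty sequences are errors naming the offending header.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"FASTA file not found: {path}")
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for entry in SeqIO.parse(str(path), "fasta"):
        if entry.id in seen:
            raise ValueError(f"duplicate FASTA id {entry.id!r} in {path}")
        seen.add(entry.id)
        raw = str(entry.seq)
        if not raw:
            raise SequenceError(f"empty sequence for FASTA header {entry.id!r}")
        try:
            seq = validate_sequence(raw, policy=policy)
        except SequenceError as exc:
            raise SequenceError(f"record {entry.id!r}: {exc}") from exc
        records.append(ProteinRecord(id=entry.id, sequence=seq))
    return records


def write_fasta(records, path, width: int = 60) -> None:
    """Write records as FASTA (wrap at ``width`` columns)."""
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


def attach_labels(records, table, on_unknown_id: str = "warn") -> Dataset:
    """Join a two-column id/label table onto records, returning a Dataset.

    Labels must be in {0, 1}. Records missing from the table keep
    ``label=None``. Ids in the table that match no record trigger a warning
    (``on_unknown_id='error'`` upgrades this to an exception).
    """
    if on_unknown_id not in ("warn", "error"):
        raise ValueError("on_unknown_id must be 'warn' or 'error'")
    path = Path(table)
    try:
        df = pd.read_csv(path, sep=r"\s+", header=None, comment="#", dtype=str)
    except pd.errors.EmptyDataError:
        df = pd.DataFrame(columns=[0, 1])
    if len(df.columns) < 2 and len(df) > 0:
        raise ValueError(f"label table {path} must have two columns (id, label)")
    label_map: dict[str, int] = {}
    for _, row in df.iterrows():
        pid, raw = str(row[0]), str(row[1])
        if raw not in ("0", "1"):
            raise ValueError(
                f"label for {pid!r} must be 0 or 1, got {raw!r}"
            )
        label_map[pid] = int(raw)
    by_id = {r.id: r for r in records}
    unknown = [pid for pid in label_map if pid not in by_id]
    if unknown:
        msg = f"{len(unknown)} labeled ids not present in records: {unknown[:5]}"
        if on_unknown_id == "error":
            raise ValueError(msg)
        logger.warning(msg)
    out = [
        ProteinRecord(r.id, r.sequence, label_map.get(r.id, r.label), dict(r.meta))
        for r in records
    ]
    n_pos = sum(1 for r in out if r.label == 1)
    n_neg = sum(1 for r in out if r.label == 0)
    logger.info("attached labels: %d positive, %d negative, %d unlabeled",
                n_pos, n_neg, len(out) - n_pos - n_neg)
    return Dataset(out, provenance=f"labels from {path}")


def write_predictions(dataset: Dataset, scores, path, threshold: float) -> None:
    """Write per-protein scores and threshold calls as a 3-column TSV.

    Columns: ``id``, ``score`` (6 decimals), ``call`` (1 iff score >=
    threshold; ties count as positive throughout the package).
    """
    scores = np.asarray(scores, dtype=float)
    if len(scores) != len(dataset):
        raise ValueError(
            f"scores length {len(scores)} != number of records {len(dataset)}"
        )
    with open(path, "w") as fh:
        fh.write(f"# threshold={threshold:.6f}\n")
        fh.write("id\tscore\tcall\n")
        for rec, s in zip(dataset, scores):
            fh.write(f"{rec.id}\t{s:.6f}\t{int(s >= threshold)}\n")
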