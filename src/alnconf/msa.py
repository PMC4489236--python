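"""Core sequence/alignment types, FASTA I/O and the column-identity keys.

The column-identity representation maps every alignment column to a vector of
per-sequence residue ordinals (1-based position in the ungapped sequence, or
``GAP``).  Two columns of any two alignments over the same sequence set are
"the same column" iff their keys are equal; all ensemble scoring and all
truth-based evaluation reduce to comparisons of these keys.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Sequence as TSequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

#: Amino-acid alphabet in the order used by the LG exchangeability tables;
#: 'X' (unknown, substitution score 0) is appended as the 21st letter.
AA_ORDER = "ARNDCQEGHILKMFPSTWYV"
ALPHABET = AA_ORDER + "X"

#: Sentinel used in column keys for a gap entry.
GAP = 0

#: Integer codes for encoded alignments: 0..19 residues, 20 = X, 21 = gap.
X_CODE = 20
GAP_CODE = 21

_CODE_OF = {aa: i for i, aa in enumerate(ALPHABET)}
_CODE_OF["-"] = GAP_CODE

_VALID_RESIDUES = frozenset(ALPHABET)


class MsaError(ValueError):
    """Raised on malformed sequence or alignment input."""


@dataclass(frozen=True)
class Sequence:
    """An ungapped, named amino-acid sequence."""

    id: str
    residues: str

    def __post_init__(self) -> None:
        if not self.id:
            raise MsaError("sequence id must be non-empty")
        if not self.residues:
            raise MsaError(f"sequence {self.id!r} is empty")
        if "-" in self.residues or "." in self.residues:
            raise MsaError(
                f"sequence {self.id!r} contains gap characters; "
                "use read_msa for gapped alignments"
            )
        bad = set(self.residues) - _VALID_RESIDUES
        if bad:
            raise MsaError(
                f"sequence {self.id!r} contains invalid letters {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.residues)


class Msa:
    """A multiple sequence alignment: equal-length gapped rows over named
    sequences, in a fixed canonical order (the input order).

    The gap character is ``-``.  No column may be all-gap unless the
    alignment was read with ``permissive=True``.
    """

    __slots__ = ("ids", "rows", "_encoded")

    def __init__(
        self,
        ids: TSequence[str],
        rows: TSequence[str],
        *,
        permissive: bool = False,
    ) -> None:
        if len(ids) != len(rows):
            raise MsaError("ids and rows must have equal length")
        if not ids:
            raise MsaError("alignment must contain at least one sequence")
        if len(set(ids)) != len(ids):
            dup = next(i for i in ids if list(ids).count(i) > 1)
            raise MsaError(f"duplicate sequence id {dup!r}")
        length = len(rows[0])
        for sid, row in zip(ids, rows):
            if len(row) != length:
                raise MsaError(
                    f"ragged alignment: row {sid!r} has length {len(row)}, "
                    f"expected {length}"
                )
        if length == 0:
            raise MsaError("alignment has zero columns")
        self.ids: tuple[str, ...] = tuple(ids)
        self.rows: tuple[str, ...] = tuple(rows)
        self._encoded: np.ndarray | None = None
        if not permissive:
            enc = self.encoded()
            allgap = np.all(enc == GAP_CODE, axis=0)
            if allgap.any():
                j = int(np.argmax(allgap))
                raise MsaError(f"column {j + 1} is all-gap")

    @property
    def length(self) -> int:
        """Number of columns."""
        return len(self.rows[0])

    @property
    def n_sequences(self) -> int:
        return len(self.ids)

    def encoded(self) -> np.ndarray:
        """Integer-coded matrix of shape (n_sequences, length)."""
        if self._encoded is None:
            mat = np.empty((len(self.rows), self.length), dtype=np.uint8)
            for i, row in enumerate(self.rows):
                mat[i] = [_CODE_OF[c] for c in row]
            self._encoded = mat
        return self._encoded

    def sequences(self) -> list[Sequence]:
        """The ungapped sequences, in alignment order."""
        return [
            Sequence(sid, row.replace("-", "")) for sid, row in zip(self.ids, self.rows)
        ]

    def row(self, sid: str) -> str:
        return self.rows[self.ids.index(sid)]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Msa):
            return NotImplemented
        return self.ids == other.ids and self.rows == other.rows

    def __hash__(self) -> int:
        return hash((self.ids, self.rows))

    def __repr__(self) -> str:
        return f"Msa({self.n_sequences} sequences x {self.length} columns)"


def _normalize_row(raw: str, sid: str) -> str:
    row = raw.upper().replace(".", "-")
    bad = set(row) - _VALID_RESIDUES - {"-"}
    if bad:
        raise MsaError(f"record {sid!r} contains invalid letters {sorted(bad)}")
    return row


def _parse_records(handle: io.TextIOBase) -> list[tuple[str, str]]:
    records = []
    seen: set[str] = set()
    for rec in SeqIO.parse(handle, "fasta"):
        sid = rec.id
        if sid in seen:
            raise MsaError(f"duplicate sequence id {sid!r}")
        seen.add(sid)
        records.append((sid, str(rec.seq)))
    if not records:
        raise MsaError("no FASTA records found")
    return records


def read_fasta(path: str | Path) -> list[Sequence]:
    """Read ungapped sequences from a FASTA file.

    Ids are the header up to the first whitespace; letters are upper-cased;
    gap characters are rejected (use :func:`read_msa` for alignments).
    """
    with open(path) as fh:
        records = _parse_records(fh)
    out = []
    for sid, raw in records:
        if not raw:
            raise MsaError(f"record {sid!r} is empty")
        norm = _normalize_row(raw, sid)
        if "-" in norm:
            raise MsaError(
                f"record {sid!r} contains gap characters; use read_msa"
            )
        out.append(Sequence(sid, norm))
    return out


def write_fasta(seqs: Iterable[Sequence], path: str | Path) -> None:
    """Write sequences as 60-column-wrapped FASTA."""
    records = [
        SeqRecord(Seq(s.residues), id=s.id, description="") for s in seqs
    ]
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fasta")


def read_msa(path: str | Path, *, permissive: bool = False) -> Msa:
    """Read a gapped FASTA alignment.

    ``.`` and ``-`` are both accepted as gaps and normalized to ``-``.
    All-gap columns are rejected unless ``permissive`` is set.
    """
    with open(path) as fh:
        records = _parse_records(fh)
    ids = [sid for sid, _ in records]
    rows = [_normalize_row(raw, sid) for sid, raw in records]
    return Msa(ids, rows, permissive=permissive)


def write_msa(msa: Msa, path: str | Path) -> None:
    """Write an alignment as 60-column-wrapped gapped FASTA."""
    records = [
        SeqRecord(Seq(row), id=sid, description="")
        for sid, row in zip(msa.ids, msa.rows)
    ]
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fasta")


def keys_matrix(msa: Msa) -> np.ndarray:
    """Column-identity keys as an (n_sequences, length) int32 matrix.

    Entry [i, j] is the 1-based ordinal of sequence i's residue in column j,
    or ``GAP`` (0) if sequence i has a gap there.  Along each row the
    non-zero entries are exactly 1..len(sequence i), strictly increasing.
    """
    enc = msa.encoded()
    isres = (enc != GAP_CODE).astype(np.int32)
    keys = np.cumsum(isres, axis=1)
    keys[isres == 0] = GAP
    return keys


def column_keys(msa: Msa) -> list[tuple[int, ...]]:
    """One hashable column-identity key per column (see :func:`keys_matrix`)."""
    km = keys_matrix(msa)
    return [tuple(int(v) for v in km[:, j]) for j in range(km.shape[1])]


def column_pairs(msa: Msa, col: int) -> set[tuple[tuple[str, int], tuple[str, int]]]:
    """All unordered residue pairs sharing column ``col``.

    Each pair is a canonical tuple ``((id_a, ordinal_a), (id_b, ordinal_b))``
    sorted by sequence position in the alignment, so symmetric pairs compare
    equal.  A column with k residues yields k*(k-1)/2 pairs.
    """
    if not 0 <= col < msa.length:
        raise IndexError(f"column {col} out of range [0, {msa.length})")
    km = keys_matrix(msa)
    members = [
        (msa.ids[i], int(km[i, col]))
        for i in range(msa.n_sequences)
        if km[i, col] != GAP
    ]
    pairs = set()
    for a in range(len(members)):
        for b in range(a + 1, len(members)):
            pairs.add((members[a], members[b]))
    return pairs


def iter_all_pairs(msa: Msa) -> Iterator[tuple[tuple[str, int], tuple[str, int]]]:
    """Iterate over the residue pairs of every column of ``msa``."""
    for j in range(msa.length):
        yield from column_pairs(msa, j)


def msa_from_encoded(ids: TSequence[str], enc: np.ndarray) -> Msa:
    """Build an Msa from an integer-coded matrix (inverse of ``encoded``)."""
    rows = ["".join(ALPHABET[c] if c != GAP_CODE else "-" for c in r) for r in enc]
    return Msa(ids, rows)
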