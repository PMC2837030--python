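"""Multiple sequence alignments in aligned-FASTA form.

Conventions used throughout the package:

* all rows have equal length; the representative (query) sequence is the
  first row;
* the alphabet is the 20 standard amino acids plus ``B``, ``Z``, ``X`` and
  the gap character ``-`` (``.`` is normalized to ``-`` on input, characters
  are upper-cased);
* coordinates in the API are 0-based half-open; rendered output is 1-based
  inclusive;
* ``column_mask`` marks columns that contribute profile positions (set by
  the compositional-complexity filter; all-true initially).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np

from .alphabet import CHAR_TO_CODE, GAP_CODE, MSA_ALPHABET

__all__ = ["MSAFormatError", "MultipleAlignment", "read_msa", "write_msa"]


class MSAFormatError(ValueError):
    """Malformed alignment input."""


@dataclass
class MultipleAlignment:
    sequence_ids: list[str]
    rows: list[str]
    query_index: int = 0
    column_mask: np.ndarray = field(default=None)

    def __post_init__(self):
        if not self.rows:
            raise MSAFormatError("alignment has no sequences")
        length = len(self.rows[0])
        for sid, row in zip(self.sequence_ids, self.rows):
            if len(row) != length:
                raise MSAFormatError(
                    f"unequal alignment lengths: sequence '{sid}' has "
                    f"{len(row)} columns, expected {length}")
            for ch in row:
                if ch not in MSA_ALPHABET:
                    raise MSAFormatError(
                        f"illegal character '{ch}' in sequence '{sid}'")
        query = self.rows[self.query_index]
        if all(c == "-" for c in query):
            raise MSAFormatError("query sequence contains only gaps")
        if self.column_mask is None:
            self.column_mask = np.ones(length, dtype=bool)
        else:
            self.column_mask = np.asarray(self.column_mask, dtype=bool)
            if self.column_mask.size != length:
                raise MSAFormatError("column_mask length mismatch")

    @property
    def length(self) -> int:
        return len(self.rows[0])

    @property
    def n_sequences(self) -> int:
        return len(self.rows)

    def codes(self) -> np.ndarray:
        """Integer-coded alignment matrix (n_sequences x length)."""
        out = np.empty((self.n_sequences, self.length), dtype=np.int8)
        for i, row in enumerate(self.rows):
            out[i] = [CHAR_TO_CODE[c] for c in row]
        return out

    def spans(self) -> np.ndarray:
        """Per-sequence (first, last) column index of non-gap residues.

        Sequences with no residues get (length, -1) so that every interiority
        test against them is false.
        """
        codes = self.codes()
        has_res = codes != GAP_CODE
        out = np.empty((self.n_sequences, 2), dtype=np.int64)
        for i in range(self.n_sequences):
            idx = np.flatnonzero(has_res[i])
            if idx.size == 0:
                out[i] = (self.length, -1)
            else:
                out[i] = (idx[0], idx[-1])
        return out


def _normalize(seq: str) -> str:
    return seq.upper().replace(".", "-")


def read_msa(source) -> MultipleAlignment:
    """Read an aligned-FASTA multiple alignment from a path or text stream."""
    if isinstance(source, (str, bytes)) or hasattr(source, "__fspath__"):
        with open(source) as fh:
            return read_msa(fh)
    ids: list[str] = []
    seqs: list[str] = []
    current: list[str] | None = None
    for line in source:
        line = line.rstrip("\n")
        if not line.strip():
            continue
        if line.startswith(">"):
            ids.append(line[1:].split()[0] if line[1:].split() else "")
            current = []
            seqs.append(current)
        else:
            if current is None:
                raise MSAFormatError("sequence data before first FASTA header")
            current.append(line.strip())
    if not ids:
        raise MSAFormatError("empty alignment input")
    rows = [_normalize("".join(parts)) for parts in seqs]
    return MultipleAlignment(sequence_ids=ids, rows=rows, query_index=0)


def write_msa(msa: MultipleAlignment, stream, width: int = 60) -> None:
    """Write an alignment as aligned FASTA (wrap at ``width`` columns)."""
    close = False
    if isinstance(stream, (str, bytes)) or hasattr(stream, "__fspath__"):
        stream = open(stream, "w")
        close = True
    try:
        for sid, row in zip(msa.sequence_ids, msa.rows):
            stream.write(f">{sid}\n")
            for k in range(0, len(row), width):
                stream.write(row[k:k + width] + "\n")
    finally:
        if close:
            stream.close()


def msa_to_string(msa: MultipleAlignment) -> str:
    buf = io.StringIO()
    write_msa(msa, buf)
    return buf.getvalue()
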