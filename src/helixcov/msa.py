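"""Multiple sequence alignment input and redundancy filtering.

Alignments of the transmembrane region of a polytopic membrane protein are
the raw material for coupling analysis.  FASTA and Stockholm are parsed with
Biopython; A3M files are normalised first (lowercase insert states are
removed so every row aligns to the match columns).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from Bio import AlignIO

GAP_CHARS = "-."

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
#: integer encoding: 0..19 amino acids, 20 = gap/unknown (treated as an
#: explicit 21st state by the coupling estimators)
AA_INDEX = {aa: i for i, aa in enumerate(AA_ALPHABET)}
GAP_STATE = 20
N_STATES = 21


class MsaFormatError(ValueError):
    """Raised when an alignment file does not parse as a valid alignment."""


@dataclass
class Msa:
    """An alignment of equal-length sequences over the amino-acid + gap alphabet.

    Parameters
    ----------
    sequences
        Upper-case aligned rows, gaps normalised to ``'-'``.
    labels
        One identifier per row.
    ref_map
        1-based reference residue number for each column.  Defaults to
        ``1..L``; for the membrane-protein use case this carries the
        reference-organism numbering of the aligned region.
    """

    sequences: list[str]
    labels: list[str]
    ref_map: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if len(self.sequences) == 0:
            raise MsaFormatError("empty alignment")
        lengths = {len(s) for s in self.sequences}
        if len(lengths) != 1:
            raise MsaFormatError(f"unequal sequence lengths: {sorted(lengths)}")
        if self.n_columns < 2:
            raise MsaFormatError("alignment needs at least 2 columns")
        if len(self.labels) != len(self.sequences):
            raise ValueError("labels/sequences length mismatch")
        if self.ref_map is None:
            self.ref_map = np.arange(1, self.n_columns + 1)
        else:
            self.ref_map = np.asarray(self.ref_map, dtype=int)
            if self.ref_map.shape != (self.n_columns,):
                raise ValueError("ref_map length must equal column count")
            if np.any(np.diff(self.ref_map) <= 0):
                raise ValueError("ref_map must be strictly increasing")

    @property
    def n_sequences(self) -> int:
        return len(self.sequences)

    @property
    def n_columns(self) -> int:
        return len(self.sequences[0])

    def encoded(self) -> np.ndarray:
        """Integer-encoded alignment, shape (n_sequences, L), gap state 20."""
        out = np.full((self.n_sequences, self.n_columns), GAP_STATE, dtype=np.int8)
        for r, seq in enumerate(self.sequences):
            for c, ch in enumerate(seq):
                out[r, c] = AA_INDEX.get(ch, GAP_STATE)
        return out


def _normalize_row(seq: str, drop_lowercase: bool) -> str:
    if drop_lowercase:
        seq = "".join(ch for ch in seq if not ch.islower())
    seq = seq.upper()
    return "".join("-" if ch in GAP_CHARS else ch for ch in seq)


def read_msa(path: str | Path, format: str = "fasta", ref_start: int = 1) -> Msa:
    """Read an alignment file.

    ``format`` is one of ``fasta``, ``a3m``, ``stockholm``.  A3M lowercase
    insert states are removed; remaining rows must then have equal length.
    ``ref_start`` sets the reference number of the first column.
    """
    path = Path(path)
    if format not in {"fasta", "a3m", "stockholm"}:
        raise ValueError(f"unknown alignment format: {format!r}")
    text = path.read_text()
    if not text.strip():
        raise MsaFormatError(f"empty alignment file: {path}")

    if format == "a3m":
        labels, seqs = [], []
        current: list[str] = []
        for line in text.splitlines():
            if line.startswith(">"):
                if current:
                    seqs.append("".join(current))
                    current = []
                labels.append(line[1:].split()[0] if line[1:].split() else "")
            elif line.strip() and not line.startswith("#"):
                current.append(line.strip())
        if current:
            seqs.append("".join(current))
        rows = [_normalize_row(s, drop_lowercase=True) for s in seqs]
    else:
        bio_format = "fasta" if format == "fasta" else "stockholm"
        try:
            aln = AlignIO.read(io.StringIO(text), bio_format)
        except ValueError as exc:
            raise MsaFormatError(f"cannot parse {path} as {format}: {exc}") from exc
        labels = [rec.id for rec in aln]
        rows = [_normalize_row(str(rec.seq), drop_lowercase=False) for rec in aln]

    if len(rows) < 2:
        raise MsaFormatError("an alignment needs at least 2 sequences")
    lengths = {len(r) for r in rows}
    if len(lengths) != 1:
        raise MsaFormatError(
            f"rows have unequal lengths after normalization: {sorted(lengths)}"
        )
    L = lengths.pop()
    return Msa(rows, labels, ref_map=np.arange(ref_start, ref_start + L))


def pairwise_identity(a: str, b: str) -> float:
    """Fraction of identical residues over columns where both rows are non-gap.

    Returns 0.0 when no column has both rows aligned (no shared signal).
    """
    arr_a = np.frombuffer(a.encode(), dtype="S1")
    arr_b = np.frombuffer(b.encode(), dtype="S1")
    both = (arr_a != b"-") & (arr_b != b"-")
    n = int(both.sum())
    if n == 0:
        return 0.0
    return float((arr_a[both] == arr_b[both]).sum() / n)


def filter_redundancy(msa: Msa, max_identity: float = 0.90) -> Msa:
    """Greedy redundancy filter at a pairwise-identity threshold.

    Sequences are visited in input order; a sequence is dropped when its
    identity with any already-retained sequence exceeds ``max_identity``.
    The identity denominator counts columns where both sequences are
    non-gap.  The retained set keeps the original order.
    """
    if not (0.0 < max_identity <= 1.0):
        raise ValueError("max_identity must be in (0, 1]")
    retained: list[int] = []
    for i, seq in enumerate(msa.sequences):
        if all(
            pairwise_identity(seq, msa.sequences[j]) <= max_identity
            for j in retained
        ):
            retained.append(i)
    return Msa(
        [msa.sequences[i] for i in retained],
        [msa.labels[i] for i in retained],
        ref_map=msa.ref_map.copy(),
    )
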