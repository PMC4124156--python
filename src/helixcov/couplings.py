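"""Residue-residue coupling strength matrices.

Two estimators are provided:

``mi_apc``
    Mutual information between column pairs with the average-product
    correction (APC), negatives clamped to zero.  Cheap, and adequate for
    the stripe-detection stage on synthetic data.

``mf_dca``
    Mean-field direct coupling analysis: the one-hot column covariance
    matrix is shrunk towards a multiple of the identity and inverted; the
    negative inverse gives the pairwise coupling blocks, whose Frobenius
    norms (zero-sum gauge, APC-corrected) are the coupling strengths.  Gaps
    are an explicit 21st state.

A matrix may also be ingested from / written to TSV, with the reference
residue numbering as header row and column.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .msa import GAP_STATE, Msa, N_STATES


@dataclass
class CouplingMatrix:
    """Symmetric non-negative L x L matrix of coupling strengths."""

    strengths: np.ndarray
    ref_map: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.strengths = np.asarray(self.strengths, dtype=float)
        if self.strengths.ndim != 2 or self.strengths.shape[0] != self.strengths.shape[1]:
            raise ValueError("strengths must be a square matrix")
        if not np.all(np.isfinite(self.strengths)):
            raise ValueError("strengths must be finite")
        if not np.allclose(self.strengths, self.strengths.T):
            raise ValueError("strengths must be symmetric")
        if np.any(self.strengths < 0):
            raise ValueError("strengths must be non-negative")
        if np.any(np.diag(self.strengths) != 0):
            raise ValueError("diagonal must be zero")
        if self.ref_map is None:
            self.ref_map = np.arange(1, self.L + 1)
        else:
            self.ref_map = np.asarray(self.ref_map, dtype=int)
            if self.ref_map.shape != (self.L,):
                raise ValueError("ref_map length must equal matrix size")

    @property
    def L(self) -> int:
        return self.strengths.shape[0]

    def index_of(self, residue: int) -> int:
        """Matrix index of a reference residue number."""
        hits = np.nonzero(self.ref_map == residue)[0]
        if hits.size == 0:
            raise KeyError(f"residue {residue} not in coupling matrix")
        return int(hits[0])

    def submatrix(self, rows: np.ndarray, cols: np.ndarray) -> np.ndarray:
        return self.strengths[np.ix_(rows, cols)]

    def to_tsv(self, path: str | Path) -> None:
        """Write as TSV with residue numbers as header row and first column.

        Floats are written with ``repr`` so that re-reading the decimal text
        reproduces the values bit-exactly.
        """
        path = Path(path)
        with path.open("w") as fh:
            fh.write("\t" + "\t".join(str(r) for r in self.ref_map) + "\n")
            for i in range(self.L):
                row = "\t".join(repr(float(v)) for v in self.strengths[i])
                fh.write(f"{self.ref_map[i]}\t{row}\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "CouplingMatrix":
        path = Path(path)
        lines = [ln.rstrip("\n") for ln in path.read_text().splitlines() if ln.strip()]
        if not lines:
            raise ValueError(f"empty coupling matrix file: {path}")
        header = lines[0].split("\t")
        ref_map = np.array([int(x) for x in header[1:]], dtype=int)
        rows = []
        row_refs = []
        for ln in lines[1:]:
            parts = ln.split("\t")
            row_refs.append(int(parts[0]))
            rows.append([float(x) for x in parts[1:]])
        if row_refs != list(ref_map):
            raise ValueError("row and column residue numbering disagree")
        return cls(np.array(rows, dtype=float), ref_map=ref_map)


def _column_counts(encoded: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Weighted per-column state frequencies, shape (L, N_STATES)."""
    n, L = encoded.shape
    freqs = np.zeros((L, N_STATES))
    for s in range(N_STATES):
        freqs[:, s] = weights @ (encoded == s)
    return freqs / weights.sum()


def sequence_weights(msa: Msa, cluster_identity: float = 0.80) -> np.ndarray:
    """Inverse cluster-size weights at an identity threshold (optional).

    Each sequence is weighted by 1 / (number of sequences within
    ``cluster_identity`` of it, itself included).
    """
    enc = msa.encoded()
    n, L = enc.shape
    counts = np.ones(n)
    for i in range(n):
        for j in range(i + 1, n):
            both = (enc[i] != GAP_STATE) & (enc[j] != GAP_STATE)
            m = both.sum()
            if m and (enc[i][both] == enc[j][both]).sum() / m > cluster_identity:
                counts[i] += 1
                counts[j] += 1
    return 1.0 / counts


def apc(matrix: np.ndarray) -> np.ndarray:
    """Average-product correction: ``M_ij - M_i. * M_.j / M_..``.

    Row/column means exclude the diagonal; the corrected diagonal is zeroed.
    """
    M = matrix.copy()
    np.fill_diagonal(M, 0.0)
    L = M.shape[0]
    if L < 2:
        return M
    col_mean = M.sum(axis=0) / (L - 1)
    total_mean = M.sum() / (L * (L - 1))
    if total_mean == 0:
        return M
    corrected = M - np.outer(col_mean, col_mean) / total_mean
    np.fill_diagonal(corrected, 0.0)
    return corrected


def mutual_information(enc: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Weighted mutual information between all column pairs (no APC)."""
    n, L = enc.shape
    W = weights.sum()
    mi = np.zeros((L, L))
    # per-column marginals
    f1 = _column_counts(enc, weights)
    for i in range(L):
        for j in range(i + 1, L):
            joint = np.zeros((N_STATES, N_STATES))
            np.add.at(joint, (enc[:, i], enc[:, j]), weights)
            joint /= W
            nz = joint > 0
            outer = np.outer(f1[i], f1[j])
            mi_ij = float(np.sum(joint[nz] * np.log(joint[nz] / outer[nz])))
            mi[i, j] = mi[j, i] = mi_ij
    return mi


def _mean_field_dca(enc: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Mean-field DCA coupling norms with shrinkage regularization.

    One state (the gap state) is dropped as the reference so the one-hot
    covariance is full rank; the covariance diagonal is shrunk by adding
    ``0.5 * mean(diag)`` before inversion.
    """
    n, L = enc.shape
    q = N_STATES - 1  # states kept in the covariance (gap is the reference)
    W = weights.sum()
    X = np.zeros((n, L * q))
    for s in range(q):
        X[:, s::q][enc == s] = 1.0
    wmean = (weights @ X) / W
    Xc = X - wmean
    C = (Xc.T * weights) @ Xc / W
    lam = 0.5 * np.mean(np.diag(C))
    if lam <= 0:
        lam = 1e-6
    C_reg = C + lam * np.eye(L * q)
    J = -np.linalg.inv(C_reg)

    norms = np.zeros((L, L))
    for i in range(L):
        for j in range(i + 1, L):
            block = J[i * q:(i + 1) * q, j * q:(j + 1) * q]
            # zero-sum gauge before taking the Frobenius norm
            block = (
                block
                - block.mean(axis=0, keepdims=True)
                - block.mean(axis=1, keepdims=True)
                + block.mean()
            )
            norms[i, j] = norms[j, i] = np.linalg.norm(block)
    return norms


def compute_couplings(
    msa: Msa,
    estimator: str = "mf_dca",
    use_sequence_weights: bool = False,
) -> CouplingMatrix:
    """Estimate the coupling-strength matrix of an alignment.

    The result is symmetric with zero diagonal and non-negative entries
    (APC residuals are clamped at zero).  Columns with a single observed
    state carry zero coupling.
    """
    if msa.n_sequences < 2:
        raise ValueError("need at least 2 sequences")
    enc = msa.encoded()
    weights = (
        sequence_weights(msa) if use_sequence_weights else np.ones(msa.n_sequences)
    )
    if estimator == "mi_apc":
        raw = mutual_information(enc, weights)
    elif estimator == "mf_dca":
        raw = _mean_field_dca(enc, weights)
    else:
        raise ValueError(f"unknown estimator: {estimator!r}")
    strengths = np.clip(apc(raw), 0.0, None)
    strengths = (strengths + strengths.T) / 2.0
    np.fill_diagonal(strengths, 0.0)
    # columns with a single observed state carry no covariation signal
    constant = np.array([len(np.unique(enc[:, c])) == 1 for c in range(msa.n_columns)])
    strengths[constant, :] = 0.0
    strengths[:, constant] = 0.0
    return CouplingMatrix(strengths, ref_map=msa.ref_map.copy())
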