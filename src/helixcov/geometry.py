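"""Structure comparison: Cβ distances, Kabsch superposition, Cα profiles.

Coordinates are handled as biotite ``AtomArray`` objects behind a thin
``Structure`` wrapper that adds residue-keyed lookup with the altloc rule
(highest occupancy, then 'A') and 1-based author residue numbers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile
from biotite.sequence import ProteinSequence
from biotite.sequence.align import SubstitutionMatrix, align_optimal


class Structure:
    """A single-model protein structure with residue-keyed atom access.

    Coordinates are kept in a parallel float64 array (``coords``) so the
    geometry operations run at full double precision; the underlying
    biotite ``AtomArray`` (float32) is used for I/O and metadata.
    """

    def __init__(self, atoms: struc.AtomArray, coords: np.ndarray | None = None):
        if atoms.array_length() == 0:
            raise ValueError("empty structure")
        self.coords = (
            np.array(coords, dtype=np.float64)
            if coords is not None
            else atoms.coord.astype(np.float64)
        )
        if self.coords.shape != (atoms.array_length(), 3):
            raise ValueError("coords shape must match atom count")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite coordinates")
        self.atoms = atoms
        self._index: dict[tuple[str, int, str], int] = {}
        for idx in range(atoms.array_length()):
            key = (str(atoms.chain_id[idx]), int(atoms.res_id[idx]),
                   str(atoms.atom_name[idx]))
            if key in self._index:
                raise ValueError(f"duplicate atom {key}")
            self._index[key] = idx

    # -- I/O ---------------------------------------------------------------

    @classmethod
    def from_pdb(cls, path: str | Path, model: int = 1,
                 chain: str | None = None) -> "Structure":
        pdb = PDBFile.read(str(path))
        atoms = pdb.get_structure(model=model, altloc="occupancy")
        atoms = atoms[struc.filter_amino_acids(atoms)]
        if chain is not None:
            atoms = atoms[atoms.chain_id == chain]
        if atoms.array_length() == 0:
            raise ValueError(f"no protein atoms in {path} (chain={chain})")
        return cls(atoms)

    def to_pdb(self, path: str | Path) -> None:
        atoms = self.atoms.copy()
        atoms.coord = self.coords  # biotite coerces to float32 for output
        pdb = PDBFile()
        pdb.set_structure(atoms)
        pdb.write(str(path))

    # -- residue access ----------------------------------------------------

    @property
    def chain(self) -> str:
        return str(self.atoms.chain_id[0])

    @property
    def residue_numbers(self) -> np.ndarray:
        mask = self.atoms.atom_name == "CA"
        return self.atoms.res_id[mask].astype(int)

    def sequence(self) -> str:
        mask = self.atoms.atom_name == "CA"
        out = []
        for res3 in self.atoms.res_name[mask]:
            try:
                out.append(ProteinSequence.convert_letter_3to1(res3.capitalize()))
            except KeyError:
                out.append("X")
        return "".join(out)

    def res_name(self, resnum: int, chain: str | None = None) -> str:
        idx = self._atom_index(resnum, "CA", chain)
        return str(self.atoms.res_name[idx])

    def _atom_index(self, resnum: int, atom_name: str,
                    chain: str | None = None) -> int:
        chain = chain if chain is not None else self.chain
        key = (chain, int(resnum), atom_name)
        if key not in self._index:
            raise KeyError(
                f"atom {atom_name} of residue {resnum} (chain {chain}) not found"
            )
        return self._index[key]

    def coord(self, resnum: int, atom_name: str,
              chain: str | None = None) -> np.ndarray:
        return self.coords[self._atom_index(resnum, atom_name, chain)]

    def has_atom(self, resnum: int, atom_name: str,
                 chain: str | None = None) -> bool:
        chain = chain if chain is not None else self.chain
        return (chain, int(resnum), atom_name) in self._index

    def transformed(self, rotation: np.ndarray,
                    translation: np.ndarray) -> "Structure":
        return Structure(self.atoms.copy(),
                         coords=self.coords @ rotation.T + translation)


# ---------------------------------------------------------------------------
# residue mapping
# ---------------------------------------------------------------------------

@dataclass
class ResidueMapping:
    """Ordered one-to-one pairs of residue numbers between two structures."""

    pairs: list[tuple[int, int]]

    def __post_init__(self) -> None:
        a_side = [p[0] for p in self.pairs]
        b_side = [p[1] for p in self.pairs]
        if len(set(a_side)) != len(a_side) or len(set(b_side)) != len(b_side):
            raise ValueError("mapping must be one-to-one")

    def __len__(self) -> int:
        return len(self.pairs)

    def restrict(self, residues_a: set[int]) -> "ResidueMapping":
        return ResidueMapping([p for p in self.pairs if p[0] in residues_a])

    def to_tsv(self, path: str | Path) -> None:
        Path(path).write_text(
            "res_a\tres_b\n"
            + "\n".join(f"{a}\t{b}" for a, b in self.pairs) + "\n"
        )

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ResidueMapping":
        rows = Path(path).read_text().splitlines()[1:]
        return cls([tuple(int(x) for x in r.split("\t")) for r in rows if r.strip()])


def map_by_alignment(a: Structure, b: Structure,
                     gap_open: int = 11, gap_extend: int = 1) -> ResidueMapping:
    """Cross-structure residue mapping from a global sequence alignment.

    Needleman-Wunsch with BLOSUM62 and affine gaps (open 11, extend 1);
    aligned non-gap column pairs become mapped residue pairs.
    """
    seq_a = ProteinSequence(a.sequence())
    seq_b = ProteinSequence(b.sequence())
    matrix = SubstitutionMatrix.std_protein_matrix()
    aln = align_optimal(
        seq_a, seq_b, matrix,
        gap_penalty=(-gap_open, -gap_extend), terminal_penalty=False,
    )[0]
    nums_a = a.residue_numbers
    nums_b = b.residue_numbers
    pairs = [
        (int(nums_a[ia]), int(nums_b[ib]))
        for ia, ib in aln.trace
        if ia != -1 and ib != -1
    ]
    return ResidueMapping(pairs)


# ---------------------------------------------------------------------------
# distances and superposition
# ---------------------------------------------------------------------------

def cb_distance(s: Structure, res_i: int, res_j: int) -> float:
    """Cβ-Cβ distance in Å (glycine falls back to Cα)."""

    def cb(res: int) -> np.ndarray:
        if s.res_name(res) == "GLY":
            return s.coord(res, "CA")
        if not s.has_atom(res, "CB"):
            raise KeyError(f"residue {res} ({s.res_name(res)}) lacks a CB atom")
        return s.coord(res, "CB")

    return float(np.linalg.norm(cb(res_i) - cb(res_j)))


@dataclass
class Superposition:
    rmsd: float
    rotation: np.ndarray        # applied to structure a
    translation: np.ndarray
    reflection_corrected: bool  # determinant correction was triggered


def kabsch(p: np.ndarray, q: np.ndarray) -> tuple[np.ndarray, np.ndarray, bool]:
    """Least-squares proper rotation + translation mapping points p onto q."""
    pc, qc = p.mean(axis=0), q.mean(axis=0)
    H = (p - pc).T @ (q - qc)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    corrected = d < 0
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = qc - R @ pc
    return R, t, corrected


def superpose_rmsd(
    a: Structure,
    b: Structure,
    mapping: ResidueMapping,
    atoms: Sequence[str] = ("CA",),
) -> Superposition:
    """RMSD of mapped atoms after optimal rigid superposition of a onto b."""
    if len(mapping) < 3:
        raise ValueError("need at least 3 mapped residues")
    pa, pb = [], []
    for ra, rb in mapping.pairs:
        for atom in atoms:
            pa.append(a.coord(ra, atom))
            pb.append(b.coord(rb, atom))
    pa, pb = np.array(pa), np.array(pb)
    R, t, corrected = kabsch(pa, pb)
    if corrected:
        warnings.warn("optimal superposition required a reflection correction")
    moved = pa @ R.T + t
    rmsd = float(np.sqrt(np.mean(np.sum((moved - pb) ** 2, axis=1))))
    return Superposition(rmsd=rmsd, rotation=R, translation=t,
                         reflection_corrected=corrected)


def smoothed_ca_profile(
    a: Structure,
    b: Structure,
    mapping: ResidueMapping,
    window: int = 1,
) -> pd.Series:
    """Smoothed per-residue Cα-Cα deviations between pre-superposed structures.

    Raw distances per mapped residue are smoothed with a centred moving
    average of odd width ``window``; the window shrinks at the edges.
    Indexed by the residue numbers of ``a``.
    """
    if window % 2 == 0:
        raise ValueError("window must be odd")
    dists = [
        float(np.linalg.norm(a.coord(ra, "CA") - b.coord(rb, "CA")))
        for ra, rb in mapping.pairs
    ]
    ser = pd.Series(dists, index=[ra for ra, _ in mapping.pairs])
    return ser.rolling(window, center=True, min_periods=1).mean()


def pair_distance_table(s: Structure, pairs: Sequence[tuple[int, int]]) -> pd.DataFrame:
    """Cβ-Cβ distance per residue pair, with the mean appended.

    Per-row errors are reported in the ``error`` column and excluded from
    the mean; at least one pair must succeed.
    """
    if not pairs:
        raise ValueError("empty pair list")
    rows = []
    for res_i, res_j in pairs:
        try:
            d = cb_distance(s, res_i, res_j)
            rows.append({"res_i": res_i, "res_j": res_j,
                         "distance": d, "error": ""})
        except KeyError as exc:
            rows.append({"res_i": res_i, "res_j": res_j,
                         "distance": np.nan, "error": str(exc)})
    df = pd.DataFrame(rows)
    if df["distance"].notna().sum() == 0:
        raise ValueError("no pair distance could be computed")
    mean_row = {"res_i": "mean", "res_j": "",
                "distance": float(df["distance"].mean()), "error": ""}
    return pd.concat([df, pd.DataFrame([mean_row])], ignore_index=True)
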