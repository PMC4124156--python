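"""Ranking of residue-residue couplings and restraint emission.

The strongest couplings of a matrix are ranked, exclusion rules are applied
(alignment indels, intrahelical pairs, membrane-topology violations), and
the surviving pairs are emitted as Cβ-Cβ distance restraints (CASP-RR or
TSV) for downstream model building.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np

from .annotations import HELIX_KINDS, HelixAnnotation, topology_depth_model
from .couplings import CouplingMatrix

STATUSES = {"retained", "intrahelical", "indel", "topology_violation"}


@dataclass(frozen=True)
class RankedPair:
    """A residue pair ranked by coupling strength.

    ``res_j`` is ``None`` for pairs whose partner column is an alignment
    indel (no residue in the reference sequence).
    """

    res_i: int
    res_j: int | None
    strength: float = float("nan")
    region_i: str | None = None
    region_j: str | None = None
    status: str = "retained"

    def __post_init__(self) -> None:
        if self.res_j is not None and self.res_i >= self.res_j:
            raise ValueError("pairs must be normalised with res_i < res_j")
        if self.status not in STATUSES:
            raise ValueError(f"unknown status: {self.status!r}")

    @property
    def key(self) -> tuple[int, int | None]:
        return (self.res_i, self.res_j)


def select_top_pairs(
    cm: CouplingMatrix, k: int = 50, min_separation: int = 0
) -> list[RankedPair]:
    """Top-k off-diagonal couplings, strength descending.

    Pairs are normalised to ``res_i < res_j``; ties at equal strength are
    broken by ascending ``(res_i, res_j)``.  ``min_separation`` drops pairs
    closer than that many residues in sequence (default 0: local pairs such
    as loop contacts at |i-j| = 9 are kept).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if min_separation < 0:
        raise ValueError("min_separation must be >= 0")
    L = cm.L
    entries = []
    for a in range(L):
        for b in range(a + 1, L):
            ri, rj = int(cm.ref_map[a]), int(cm.ref_map[b])
            if abs(rj - ri) < min_separation:
                continue
            entries.append((-cm.strengths[a, b], ri, rj))
    entries.sort()
    if k > len(entries):
        warnings.warn(
            f"requested k={k} but only {len(entries)} pairs available; returning all"
        )
        k = len(entries)
    return [
        RankedPair(res_i=ri, res_j=rj, strength=-neg)
        for neg, ri, rj in entries[:k]
    ]


def apply_exclusions(
    pairs: Sequence[RankedPair],
    ha: HelixAnnotation,
    indel_set: frozenset[int] | set[int] = frozenset(),
    depth_model: Callable[[int], float] | None = None,
    z_threshold: float = 12.0,
    printed_status: Mapping[tuple[int, int | None], str] | None = None,
) -> list[RankedPair]:
    """Assign an exclusion status to every ranked pair.

    Rules fire in priority order:

    1. ``indel`` — the partner column is an indel (``res_j`` is ``None``)
       or either residue is in ``indel_set``;
    2. ``intrahelical`` — both residues lie in the same helix segment;
    3. ``topology_violation`` — the membrane-normal coordinates implied by
       the topology differ by more than ``z_threshold`` Å, or the residues
       sit outside the membrane on opposite sides;
    4. ``retained`` otherwise.

    ``printed_status`` switches to strict mode: curated statuses are
    honoured verbatim (used when reproducing published exclusion lists
    whose quantitative topology criterion is not recorded).
    """
    if depth_model is None:
        depth_model = topology_depth_model(ha)

    def region_of(res: int) -> str:
        seg = ha.segment_of(res)
        if seg is None:
            raise KeyError(f"residue {res} not covered by the annotation")
        return seg.name

    out: list[RankedPair] = []
    for p in pairs:
        region_i = region_of(p.res_i)
        region_j = region_of(p.res_j) if p.res_j is not None else None

        if printed_status is not None:
            status = printed_status.get(p.key, "retained")
            if status not in STATUSES:
                raise ValueError(f"unknown printed status: {status!r}")
        elif p.res_j is None or p.res_i in indel_set or (
            p.res_j is not None and p.res_j in indel_set
        ):
            status = "indel"
        else:
            seg_i = ha.segment_of(p.res_i)
            seg_j = ha.segment_of(p.res_j)
            if seg_i is seg_j and seg_i.kind in HELIX_KINDS:
                status = "intrahelical"
            else:
                z_i, z_j = depth_model(p.res_i), depth_model(p.res_j)
                opposite_outside = (
                    seg_i.side != "membrane"
                    and seg_j.side != "membrane"
                    and seg_i.side != seg_j.side
                )
                if abs(z_i - z_j) > z_threshold or opposite_outside:
                    status = "topology_violation"
                else:
                    status = "retained"
        out.append(replace(p, region_i=region_i, region_j=region_j, status=status))
    return out


@dataclass
class RestraintSet:
    """Retained pairs plus the distance-restraint form to emit."""

    pairs: list[RankedPair]
    atom: str = "CB"
    d_lo: float = 0.0
    d_hi: float = 8.0

    def __post_init__(self) -> None:
        for p in self.pairs:
            if p.status != "retained":
                raise ValueError(
                    f"restraint set may contain only retained pairs, got {p.status}"
                )
            if p.res_j is None:
                raise ValueError("restraints need two residues")

    @classmethod
    def from_ranked(
        cls, pairs: Iterable[RankedPair], d_lo: float = 0.0, d_hi: float = 8.0
    ) -> "RestraintSet":
        return cls(
            [p for p in pairs if p.status == "retained"], d_lo=d_lo, d_hi=d_hi
        )

    def __len__(self) -> int:
        return len(self.pairs)


def write_restraints(
    rs: RestraintSet, path: str | Path, format: str = "casp_rr"
) -> None:
    """Write restraints as CASP-RR records ``i j d_lo d_hi prob`` or TSV."""
    if len(rs) == 0:
        raise ValueError("cannot write an empty restraint set")
    path = Path(path)
    lines = []
    if format == "casp_rr":
        for p in rs.pairs:
            if p.res_i == p.res_j:
                raise ValueError("restraint with identical residues")
            prob = p.strength if np.isfinite(p.strength) else 1.0
            lines.append(f"{p.res_i} {p.res_j} {rs.d_lo:g} {rs.d_hi:g} {prob:g}")
    elif format == "tsv":
        lines.append("res_i\tres_j\td_lo\td_hi\tstrength")
        for p in rs.pairs:
            lines.append(
                f"{p.res_i}\t{p.res_j}\t{rs.d_lo:g}\t{rs.d_hi:g}\t{p.strength:g}"
            )
    else:
        raise ValueError(f"unknown restraint format: {format!r}")
    path.write_text("\n".join(lines) + "\n")


def read_restraints(path: str | Path, format: str = "casp_rr") -> RestraintSet:
    """Read a restraint file written by :func:`write_restraints`."""
    path = Path(path)
    lines = [ln for ln in path.read_text().splitlines() if ln.strip()]
    pairs = []
    d_lo = d_hi = None
    if format == "casp_rr":
        rows = lines
    elif format == "tsv":
        rows = lines[1:]
    else:
        raise ValueError(f"unknown restraint format: {format!r}")
    for ln in rows:
        parts = ln.split()
        i, j = int(parts[0]), int(parts[1])
        d_lo, d_hi = float(parts[2]), float(parts[3])
        pairs.append(RankedPair(res_i=i, res_j=j, strength=float(parts[4])))
    if not pairs:
        raise ValueError(f"no restraints in {path}")
    return RestraintSet(pairs, d_lo=d_lo, d_hi=d_hi)
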