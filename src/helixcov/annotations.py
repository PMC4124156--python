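"""Helix/loop segment annotations with membrane topology.

A segment covers a 1-based reference residue range and carries a structural
kind (transmembrane helix, surface helix, loop) plus the membrane side it
lies on (``membrane`` for TM spans, ``cytoplasmic`` / ``periplasmic`` for
everything else).  Segment files are TOML::

    [[segment]]
    name = "TM2"
    start = 350
    end = 371
    kind = "TM"
    side = "membrane"
    n_side = "periplasmic"   # side of the segment's N-terminus (TM only)
"""

from __future__ import annotations

import tomllib
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

KINDS = {"TM", "surface_helix", "loop"}
SIDES = {"cytoplasmic", "periplasmic", "membrane"}
HELIX_KINDS = {"TM", "surface_helix"}


@dataclass(frozen=True)
class Segment:
    name: str
    start: int
    end: int
    kind: str
    side: str
    n_side: str | None = None  # membrane side of the N-terminal end (TM helices)

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"segment {self.name}: start > end")
        if self.kind not in KINDS:
            raise ValueError(f"segment {self.name}: unknown kind {self.kind!r}")
        if self.side not in SIDES:
            raise ValueError(f"segment {self.name}: unknown side {self.side!r}")

    @property
    def residues(self) -> range:
        return range(self.start, self.end + 1)

    def __len__(self) -> int:
        return self.end - self.start + 1


class HelixAnnotation:
    """Non-overlapping segments sorted by start residue."""

    def __init__(self, segments: Iterable[Segment]):
        segs = sorted(segments, key=lambda s: s.start)
        for a, b in zip(segs, segs[1:]):
            if a.end >= b.start:
                raise ValueError(f"segments {a.name} and {b.name} overlap")
        if not segs:
            raise ValueError("annotation needs at least one segment")
        names = [s.name for s in segs]
        if len(set(names)) != len(names):
            raise ValueError("duplicate segment names")
        self.segments = segs
        self._by_name = {s.name: s for s in segs}

    def __getitem__(self, name: str) -> Segment:
        return self._by_name[name]

    def __contains__(self, name: str) -> bool:
        return name in self._by_name

    def __iter__(self):
        return iter(self.segments)

    @property
    def helices(self) -> list[Segment]:
        """Segments that are helices (TM or surface)."""
        return [s for s in self.segments if s.kind in HELIX_KINDS]

    def segment_of(self, residue: int) -> Segment | None:
        for s in self.segments:
            if s.start <= residue <= s.end:
                return s
        return None

    @classmethod
    def from_toml(cls, path: str | Path) -> "HelixAnnotation":
        with Path(path).open("rb") as fh:
            data = tomllib.load(fh)
        segs = [
            Segment(
                name=d["name"],
                start=int(d["start"]),
                end=int(d["end"]),
                kind=d["kind"],
                side=d["side"],
                n_side=d.get("n_side"),
            )
            for d in data.get("segment", [])
        ]
        return cls(segs)

    def to_toml(self, path: str | Path) -> None:
        lines = []
        for s in self.segments:
            lines.append("[[segment]]")
            lines.append(f'name = "{s.name}"')
            lines.append(f"start = {s.start}")
            lines.append(f"end = {s.end}")
            lines.append(f'kind = "{s.kind}"')
            lines.append(f'side = "{s.side}"')
            if s.n_side is not None:
                lines.append(f'n_side = "{s.n_side}"')
            lines.append("")
        Path(path).write_text("\n".join(lines))


def topology_depth_model(
    ha: HelixAnnotation,
    half_thickness: float = 15.0,
    loop_offset: float = 3.0,
):
    """Map residues to an approximate membrane-normal coordinate z (Å).

    The cytoplasmic side is negative z.  Residues in a TM helix
    interpolate linearly from one membrane boundary to the other according
    to the helix's ``n_side``; residues in non-membrane segments sit just
    outside the boundary of their side (``half_thickness + loop_offset``).
    Returns a callable residue -> z, raising ``KeyError`` for residues not
    covered by the annotation.
    """
    side_z = {
        "cytoplasmic": -(half_thickness + loop_offset),
        "periplasmic": half_thickness + loop_offset,
    }

    def z_of(residue: int) -> float:
        seg = ha.segment_of(residue)
        if seg is None:
            raise KeyError(f"residue {residue} not covered by annotation")
        if seg.kind == "TM" and seg.side == "membrane":
            n_side = seg.n_side or "cytoplasmic"
            z0 = half_thickness if n_side == "periplasmic" else -half_thickness
            frac = (residue - seg.start) / max(len(seg) - 1, 1)
            return z0 + frac * (-2 * z0)
        return side_z[seg.side]

    return z_of
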