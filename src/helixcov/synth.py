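"""Seeded synthetic-data generators.

Every stage of the pipeline can be exercised without external data: the
generators produce coupling matrices with planted periodic helix-pair
stripes over gamma background noise, labelled helix-pair datasets for
training and calibration, two-leaflet phosphate bilayers with an optional
planted thinning depression, and toy helical bundles.  All generators are
pure functions of their parameters including the seed.

Default gamma parameters (background shape 1, scale 0.05; interacting
shape 4, scale 0.1) are chosen so that, under the default detector,
planted pairs score posteriors comfortably above the conventional
high-confidence threshold (0.57) and background pairs fall below the
low-confidence threshold (0.15); this is a self-consistency fixture
mirroring the decision thresholds used in practice, not a statement about
any particular protein.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .annotations import HelixAnnotation, Segment
from .bundle import build_ideal_bundle
from .couplings import CouplingMatrix
from .geometry import Structure
from .membrane import BilayerTrajectory

DEFAULT_BG = (1.0, 0.05)   # gamma (shape, scale) of background strengths
DEFAULT_FG = (4.0, 0.1)    # gamma (shape, scale) at interacting positions
STRIPE_PERIOD = 3.5        # residues per helical turn
STRIPE_FLOOR = 0.25        # amplitude between the periodic contact peaks


@dataclass(frozen=True)
class PlantedInteraction:
    helix_a: str
    helix_b: str
    orientation: str = "parallel"     # or "antiparallel"
    register: int = 0                 # offset of the stripe within the block


@dataclass
class PlantedTopology:
    """Ground truth for a synthetic coupling matrix."""

    segments: list[Segment]
    interactions: list[PlantedInteraction]
    signal: float = 2.0               # scales fg draws; 0 = background only
    bg: tuple[float, float] = DEFAULT_BG
    fg: tuple[float, float] = DEFAULT_FG
    seed: int = 1234

    def __post_init__(self) -> None:
        self.annotation = HelixAnnotation(self.segments)
        helix_names = {s.name for s in self.annotation.helices}
        for it in self.interactions:
            if it.helix_a not in helix_names or it.helix_b not in helix_names:
                raise ValueError(f"planted pair {it.helix_a}-{it.helix_b} "
                                 "not in the helix universe")
            if it.helix_a == it.helix_b:
                raise ValueError("planted pair must join distinct helices")


def _stripe_cells(n_a: int, n_b: int, orientation: str, register: int):
    """Cells of a periodic interface stripe in an (n_a, n_b) block.

    The stripe runs along the register diagonal (anti-diagonal for
    antiparallel packing); each cell carries a periodic amplitude factor,
    peaking once per helical turn where the interfaces face each other
    and decaying to a floor in between.
    """
    cells = []
    n = min(n_a, n_b)
    for t in range(n):
        i = t
        j = register + t if orientation == "parallel" else n_b - 1 - register - t
        if 0 <= i < n_a and 0 <= j < n_b:
            facing = max(np.cos(2 * np.pi * t / STRIPE_PERIOD), 0.0)
            cells.append((int(i), int(j), STRIPE_FLOOR + (1 - STRIPE_FLOOR) * facing))
    return cells


def gen_coupling_matrix(pt: PlantedTopology) -> CouplingMatrix:
    """Background gamma noise plus planted periodic interface stripes."""
    span_start = min(s.start for s in pt.segments)
    span_end = max(s.end for s in pt.segments)
    ref_map = np.arange(span_start, span_end + 1)
    L = len(ref_map)
    rng = np.random.default_rng(pt.seed)
    bg_shape, bg_scale = pt.bg
    m = rng.gamma(bg_shape, bg_scale, size=(L, L))
    m = np.triu(m, 1)
    m = m + m.T

    fg_shape, fg_scale = pt.fg
    ann = pt.annotation
    for it in pt.interactions:
        seg_a, seg_b = ann[it.helix_a], ann[it.helix_b]
        a0, b0 = seg_a.start - span_start, seg_b.start - span_start
        for i, j, amp in _stripe_cells(len(seg_a), len(seg_b), it.orientation,
                                       it.register):
            val = pt.signal * amp * rng.gamma(fg_shape, fg_scale)
            m[a0 + i, b0 + j] = val
            m[b0 + j, a0 + i] = val
    np.fill_diagonal(m, 0.0)
    return CouplingMatrix(m, ref_map=ref_map)


def default_seven_helix_topology(
    seed: int = 1234,
    signal: float = 2.0,
    helix_len: int = 18,
    loop_len: int = 4,
) -> PlantedTopology:
    """Seven helices in a ring-plus-chords contact topology (7 planted pairs)."""
    segments = []
    start = 1
    for k in range(7):
        n_side = "cytoplasmic" if k % 2 == 0 else "periplasmic"
        segments.append(Segment(
            name=f"H{k+1}", start=start, end=start + helix_len - 1,
            kind="TM", side="membrane", n_side=n_side,
        ))
        start += helix_len
        if k < 6 and loop_len > 0:
            # the loop sits on the C-terminal side of the helix
            c_side = "periplasmic" if n_side == "cytoplasmic" else "cytoplasmic"
            segments.append(Segment(
                name=f"L{k+1}", start=start, end=start + loop_len - 1,
                kind="loop", side=c_side,
            ))
            start += loop_len
    pairs = [("H1", "H2"), ("H2", "H3"), ("H3", "H4"), ("H4", "H5"),
             ("H5", "H6"), ("H6", "H7"), ("H1", "H7")]
    rng = np.random.default_rng(seed)
    interactions = [
        PlantedInteraction(
            a, b,
            orientation="parallel" if rng.random() < 0.5 else "antiparallel",
            register=int(rng.integers(0, 4)),
        )
        for a, b in pairs
    ]
    return PlantedTopology(segments=segments, interactions=interactions,
                           signal=signal, seed=seed)


def gen_labelled_helix_pairs(
    n_proteins: int,
    seed: int = 1234,
    pair_size: int = 20,
    interacting_fraction: float = 0.5,
    signal: float = 2.0,
) -> list[tuple[np.ndarray, bool]]:
    """Labelled (coupling submatrix, is_interacting) dataset.

    Each entry emulates one helix pair: a ``pair_size`` x ``pair_size``
    block of background draws, with a planted periodic stripe at random
    register and orientation when the pair interacts.  Signal strength is
    jittered per pair so raw scores spread over the probability range
    (needed for calibration fitting).
    """
    if n_proteins < 0:
        raise ValueError("n_proteins must be >= 0")
    rng = np.random.default_rng(seed)
    bg_shape, bg_scale = DEFAULT_BG
    fg_shape, fg_scale = DEFAULT_FG
    out = []
    for _ in range(n_proteins):
        label = bool(rng.random() < interacting_fraction)
        block = rng.gamma(bg_shape, bg_scale, size=(pair_size, pair_size))
        if label:
            orientation = "parallel" if rng.random() < 0.5 else "antiparallel"
            register = int(rng.integers(0, 4))
            strength = signal * rng.uniform(0.3, 1.3)
            for i, j, amp in _stripe_cells(pair_size, pair_size, orientation,
                                           register):
                block[i, j] = strength * amp * rng.gamma(fg_shape, fg_scale)
        out.append((block, label))
    return out


def gen_bilayer_trajectory(
    n_frames: int = 5,
    slab_sep: float = 38.0,
    depression: tuple[float, float, tuple[float, float]] | None = None,
    jitter: float = 0.0,
    seed: int = 1234,
    extent: float = 110.0,
    spacing: float = 8.0,
) -> BilayerTrajectory:
    """Two-leaflet phosphate bilayer with an optional thinning depression.

    Phosphate heads sit on square grids at z = ±``slab_sep``/2 over an
    ``extent`` x ``extent`` Å patch.  ``depression = (depth, sigma,
    (cx, cy))`` carves a Gaussian dimple of total depth ``depth`` split
    equally between the leaflets (thinning alike on both sides).
    ``jitter`` adds per-frame isotropic Gaussian noise.
    """
    if n_frames < 1:
        raise ValueError("need at least one frame")
    rng = np.random.default_rng(seed)
    xs = np.arange(-extent / 2, extent / 2 + spacing / 2, spacing)
    gx, gy = np.meshgrid(xs, xs, indexing="ij")
    xy = np.column_stack([gx.ravel(), gy.ravel()])
    n_per_leaflet = xy.shape[0]

    def leaflet_z(sign: float) -> np.ndarray:
        z = np.full(n_per_leaflet, sign * slab_sep / 2)
        if depression is not None:
            depth, sigma, (cx, cy) = depression
            r2 = (xy[:, 0] - cx) ** 2 + (xy[:, 1] - cy) ** 2
            z -= sign * (depth / 2) * np.exp(-r2 / (2 * sigma**2))
        return z

    base = np.concatenate([
        np.column_stack([xy, leaflet_z(+1.0)]),
        np.column_stack([xy, leaflet_z(-1.0)]),
    ])
    frames = np.array([
        base + (rng.normal(scale=jitter, size=base.shape) if jitter > 0 else 0.0)
        for _ in range(n_frames)
    ])
    metadata = pd.DataFrame({
        "resid": np.arange(1, 2 * n_per_leaflet + 1),
        "atom_name": ["P"] * (2 * n_per_leaflet),
        "role": ["phosphate_head"] * (2 * n_per_leaflet),
        "leaflet": ["upper"] * n_per_leaflet + ["lower"] * n_per_leaflet,
    })
    return BilayerTrajectory(frames=frames, metadata=metadata, box=None)


def gen_toy_bundle(
    n_helices: int,
    arrangement: str = "polygon",
    seed: int = 1234,
    helix_len: int = 18,
    spacing: float = 10.0,
) -> Structure:
    """Ideal helices at polygon vertices (adjacent axes ``spacing`` Å apart)."""
    if n_helices < 1:
        raise ValueError("need at least one helix")
    if arrangement != "polygon":
        raise ValueError(f"unknown arrangement: {arrangement!r}")
    segments = []
    start = 1
    for k in range(n_helices):
        segments.append(Segment(
            name=f"H{k+1}", start=start, end=start + helix_len - 1,
            kind="TM", side="membrane",
            n_side="cytoplasmic" if k % 2 == 0 else "periplasmic",
        ))
        start += helix_len + 2
    if n_helices == 1:
        placements = {"H1": np.zeros(2)}
    else:
        radius = spacing / (2 * np.sin(np.pi / n_helices)) if n_helices > 2 \
            else spacing / 2
        placements = {
            f"H{k+1}": radius * np.array([
                np.cos(2 * np.pi * k / n_helices),
                np.sin(2 * np.pi * k / n_helices),
            ])
            for k in range(n_helices)
        }
    rng = np.random.default_rng(seed)
    phases = {f"H{k+1}": float(rng.uniform(0, 2 * np.pi))
              for k in range(n_helices)}
    return build_ideal_bundle(placements, phases, segments).structure
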