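"""Membrane-trajectory observables.

Operates on a light-weight trajectory container (frames of coordinates
plus per-atom role/leaflet metadata) that can be filled from multi-model
PDB or DCD files via MDAnalysis.  Implements leaflet-resolved bilayer
thickness maps, positional-variance flexibility profiles (global motion
included, unlike a superposition-based RMSF), geometric hydrogen-bond
detection, height-resolved hydropathy counts, and spatial smoothing of
per-residue energy series.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

ROLES = {"phosphate_head", "protein_backbone", "protein_other", "other"}
LEAFLETS = {"upper", "lower", "n/a"}

#: Kyte-Doolittle hydropathy index (positive = hydrophobic)
KYTE_DOOLITTLE = {
    "ILE": 4.5, "VAL": 4.2, "LEU": 3.8, "PHE": 2.8, "CYS": 2.5, "MET": 1.9,
    "ALA": 1.8, "GLY": -0.4, "THR": -0.7, "SER": -0.8, "TRP": -0.9,
    "TYR": -1.3, "PRO": -1.6, "HIS": -3.2, "GLU": -3.5, "GLN": -3.5,
    "ASP": -3.5, "ASN": -3.5, "LYS": -3.9, "ARG": -4.5,
}

BACKBONE_ATOMS = {"N", "CA", "C", "O"}


@dataclass
class BilayerTrajectory:
    """Coordinate frames plus per-atom metadata.

    ``metadata`` columns: ``resid``, ``atom_name``, ``role`` (one of
    phosphate_head / protein_backbone / protein_other / other) and
    ``leaflet`` (upper / lower / n/a).  ``box`` holds per-frame orthogonal
    box dimensions (Å) or ``None`` for non-periodic analysis.
    """

    frames: np.ndarray              # (n_frames, n_atoms, 3)
    metadata: pd.DataFrame
    box: np.ndarray | None = None   # (n_frames, 3) or None

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[2] != 3:
            raise ValueError("frames must have shape (n_frames, n_atoms, 3)")
        if len(self.metadata) != self.frames.shape[1]:
            raise ValueError("metadata rows must match atom count")
        bad_roles = set(self.metadata["role"]) - ROLES
        if bad_roles:
            raise ValueError(f"unknown roles: {bad_roles}")
        phos = self.metadata["role"] == "phosphate_head"
        if (self.metadata.loc[phos, "leaflet"] == "n/a").any():
            raise ValueError("every phosphate_head atom needs a leaflet")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.frames.shape[1]

    def atom_indices(self, role: str, leaflet: str | None = None) -> np.ndarray:
        mask = self.metadata["role"] == role
        if leaflet is not None:
            mask &= self.metadata["leaflet"] == leaflet
        return np.nonzero(mask.to_numpy())[0]

    @classmethod
    def from_files(
        cls,
        topology: str | Path,
        metadata_tsv: str | Path,
        trajectory: str | Path | None = None,
    ) -> "BilayerTrajectory":
        """Load frames with MDAnalysis (multi-model PDB, or topology + DCD)
        and atom roles/leaflets from a companion TSV."""
        import MDAnalysis as mda

        if trajectory is None:
            u = mda.Universe(str(topology))
        else:
            u = mda.Universe(str(topology), str(trajectory))
        frames = np.array([u.atoms.positions.copy() for _ in u.trajectory])
        boxes = []
        for ts in u.trajectory:
            boxes.append(ts.dimensions[:3] if ts.dimensions is not None else None)
        box = (
            np.array(boxes, dtype=float)
            if all(b is not None for b in boxes) and boxes
            else None
        )
        meta = pd.read_csv(metadata_tsv, sep="\t")
        return cls(frames=frames, metadata=meta, box=box)


def _minimum_image(delta: np.ndarray, box: np.ndarray | None) -> np.ndarray:
    if box is None:
        return delta
    return delta - box * np.round(delta / box)


# ---------------------------------------------------------------------------
# thickness map
# ---------------------------------------------------------------------------

@dataclass
class ThicknessMap:
    """Time-averaged bilayer thickness on a 2D membrane-plane grid."""

    x_edges: np.ndarray
    y_edges: np.ndarray
    thickness: np.ndarray   # (nx, ny), NaN where unoccupied
    occupancy: np.ndarray   # (nx, ny) accumulation counts

    def minimum(self) -> tuple[float, float, float]:
        """(thickness, x, y) of the thinnest occupied bin (bin centres)."""
        if np.all(np.isnan(self.thickness)):
            raise ValueError("no occupied bin")
        idx = np.unravel_index(np.nanargmin(self.thickness), self.thickness.shape)
        xc = (self.x_edges[idx[0]] + self.x_edges[idx[0] + 1]) / 2
        yc = (self.y_edges[idx[1]] + self.y_edges[idx[1] + 1]) / 2
        return float(self.thickness[idx]), float(xc), float(yc)

    def to_tsv(self, path: str | Path) -> None:
        xc = (self.x_edges[:-1] + self.x_edges[1:]) / 2
        yc = (self.y_edges[:-1] + self.y_edges[1:]) / 2
        df = pd.DataFrame(self.thickness, index=xc, columns=yc)
        df.to_csv(path, sep="\t", na_rep="NA")


def thickness_map(
    traj: BilayerTrajectory,
    bin: float = 2.0,
    leaflet: str = "upper",
    z_projection: bool = False,
) -> ThicknessMap:
    """Leaflet-resolved membrane thickness on a square grid.

    Per frame and per occupied grid point: the nearest phosphate of the
    probed leaflet is found (within ``bin`` of the grid point in-plane),
    then the minimum 3D distance from that phosphate to any phosphate of
    the opposite leaflet is recorded; records are averaged over frames.
    ``z_projection=True`` replaces the 3D minimum distance by the |Δz| of
    the closest opposite phosphate.  Minimum-image convention applies when
    box dimensions are present.
    """
    other = {"upper": "lower", "lower": "upper"}[leaflet]
    same_idx = traj.atom_indices("phosphate_head", leaflet)
    opp_idx = traj.atom_indices("phosphate_head", other)
    if same_idx.size == 0 or opp_idx.size == 0:
        raise ValueError(f"leaflet {leaflet if same_idx.size == 0 else other} "
                         "contains no phosphate heads")

    all_phos_xy = traj.frames[:, np.concatenate([same_idx, opp_idx]), :2]
    lo = all_phos_xy.reshape(-1, 2).min(axis=0)
    hi = all_phos_xy.reshape(-1, 2).max(axis=0)
    x_edges = np.arange(lo[0] - bin, hi[0] + 2 * bin, bin)
    y_edges = np.arange(lo[1] - bin, hi[1] + 2 * bin, bin)
    xc = (x_edges[:-1] + x_edges[1:]) / 2
    yc = (y_edges[:-1] + y_edges[1:]) / 2
    gx, gy = np.meshgrid(xc, yc, indexing="ij")
    grid = np.column_stack([gx.ravel(), gy.ravel()])

    total = np.zeros(grid.shape[0])
    counts = np.zeros(grid.shape[0])
    for f in range(traj.n_frames):
        box = traj.box[f] if traj.box is not None else None
        same = traj.frames[f, same_idx]
        opp = traj.frames[f, opp_idx]
        tree = cKDTree(same[:, :2])
        dist_xy, nearest = tree.query(grid)
        occupied = dist_xy <= bin
        if not np.any(occupied):
            continue
        probes = same[nearest[occupied]]
        delta = _minimum_image(
            probes[:, None, :] - opp[None, :, :], box
        )
        if z_projection:
            d3 = np.linalg.norm(delta, axis=2)
            closest = np.argmin(d3, axis=1)
            vals = np.abs(delta[np.arange(len(closest)), closest, 2])
        else:
            vals = np.min(np.linalg.norm(delta, axis=2), axis=1)
        total[occupied] += vals
        counts[occupied] += 1

    nx, ny = len(xc), len(yc)
    with np.errstate(invalid="ignore"):
        mean = np.where(counts > 0, total / np.maximum(counts, 1), np.nan)
    return ThicknessMap(
        x_edges=x_edges, y_edges=y_edges,
        thickness=mean.reshape(nx, ny), occupancy=counts.reshape(nx, ny),
    )


# ---------------------------------------------------------------------------
# flexibility
# ---------------------------------------------------------------------------

def positional_variance(
    traj: BilayerTrajectory, selection: Sequence[int] | None = None
) -> pd.Series:
    """Per-residue positional variance (Å²) of backbone atoms.

    For each backbone atom the time-variance of its position about its
    trajectory mean (summed over x, y, z) is computed WITHOUT prior
    superposition, so rigid-body displacements of the helices contribute;
    atoms are then averaged within each residue.
    """
    if traj.n_frames < 2:
        raise ValueError("positional variance needs at least 2 frames")
    meta = traj.metadata
    mask = (meta["role"] == "protein_backbone").to_numpy()
    if selection is not None:
        mask &= meta["resid"].isin(selection).to_numpy()
    idx = np.nonzero(mask)[0]
    if idx.size == 0:
        raise ValueError("selection contains no backbone atoms")
    coords = traj.frames[:, idx, :]
    var = coords.var(axis=0, ddof=0).sum(axis=1)  # per atom, summed over xyz
    resids = meta["resid"].to_numpy()[idx]
    return pd.Series(var, index=resids).groupby(level=0).mean().rename("variance")


# ---------------------------------------------------------------------------
# hydrogen bonds
# ---------------------------------------------------------------------------

def hydrogen_bonds(
    frame: np.ndarray,
    donors: Sequence[tuple[int, int]],
    acceptors: Sequence[int],
    max_dist: float = 3.8,
    max_angle: float = 20.0,
) -> list[tuple[int, int]]:
    """Geometric hydrogen bonds in one frame.

    ``donors`` are (heavy-atom index, hydrogen index) pairs; ``acceptors``
    are atom indices.  A donor/acceptor pair is reported iff the
    donor-heavy -> acceptor distance is <= ``max_dist`` Å and the deviation
    of H-D···A from linearity, measured as the angle at the donor between
    the D->H and D->A directions, is <= ``max_angle`` degrees.  Both
    boundaries are inclusive.  A donor missing its hydrogen raises.
    """
    frame = np.asarray(frame, dtype=float)
    out = []
    for d_heavy, d_h in donors:
        if d_h is None or d_h < 0 or d_h >= len(frame):
            raise ValueError(f"donor {d_heavy} lacks a hydrogen atom")
        dpos, hpos = frame[d_heavy], frame[d_h]
        dh = hpos - dpos
        ndh = np.linalg.norm(dh)
        if ndh == 0:
            raise ValueError(f"donor {d_heavy}: hydrogen coincides with heavy atom")
        for a in acceptors:
            if a == d_heavy or a == d_h:
                continue
            da = frame[a] - dpos
            dist = np.linalg.norm(da)
            if dist > max_dist or dist == 0:
                continue
            cosang = float(dh @ da / (ndh * dist))
            angle = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
            if angle <= max_angle:
                out.append((d_heavy, a))
    return out


# ---------------------------------------------------------------------------
# hydropathy height profile
# ---------------------------------------------------------------------------

def hydropathy_height_profile(
    res_names: Sequence[str],
    ca_z: Sequence[float],
    membrane_z: tuple[float, float],
    n_bins: int,
) -> pd.DataFrame:
    """Counts of hydrophobic/hydrophilic residues per membrane height bin.

    Residues are binned by Cα z coordinate over ``membrane_z = (z_lo,
    z_hi)``; residues below/above the range land in explicit overflow
    bins.  Hydrophobic means a positive Kyte-Doolittle index.
    """
    z_lo, z_hi = membrane_z
    if not z_lo < z_hi:
        raise ValueError("need z_lo < z_hi")
    if n_bins < 1:
        raise ValueError("need n_bins >= 1")
    if len(res_names) != len(ca_z):
        raise ValueError("res_names and ca_z must have equal length")
    edges = np.linspace(z_lo, z_hi, n_bins + 1)
    labels = (
        ["below"]
        + [f"[{edges[i]:.2f},{edges[i+1]:.2f})" for i in range(n_bins)]
        + ["above"]
    )
    hydrophobic = np.zeros(n_bins + 2, dtype=int)
    hydrophilic = np.zeros(n_bins + 2, dtype=int)
    for name, z in zip(res_names, ca_z):
        kd = KYTE_DOOLITTLE.get(name.upper())
        if kd is None:
            raise KeyError(f"unknown residue name: {name}")
        if z < z_lo:
            b = 0
        elif z >= z_hi:
            b = n_bins + 1
        else:
            b = 1 + min(int((z - z_lo) / (z_hi - z_lo) * n_bins), n_bins - 1)
        if kd > 0:
            hydrophobic[b] += 1
        else:
            hydrophilic[b] += 1
    return pd.DataFrame(
        {"bin": labels, "hydrophobic": hydrophobic, "hydrophilic": hydrophilic}
    )


# ---------------------------------------------------------------------------
# local energy smoothing
# ---------------------------------------------------------------------------

def local_energy_average(
    energy_series: pd.DataFrame,
    ca_coords: dict[int, np.ndarray],
    cutoff: float = 10.0,
) -> pd.Series:
    """Time-average per residue, then average over spatial neighbours.

    ``energy_series`` has one column per residue (column labels are
    residue numbers) and one row per frame.  After time-averaging, each
    residue's value is replaced by the mean over all residues whose Cα
    lies within ``cutoff`` Å (inclusive, the residue itself included).
    """
    resids = [int(c) for c in energy_series.columns]
    missing = [r for r in ca_coords if r not in resids]
    if missing:
        raise KeyError(f"residues missing from the energy series: {missing}")
    time_avg = energy_series.mean(axis=0)
    time_avg.index = resids
    structure_res = sorted(ca_coords)
    coords = np.array([ca_coords[r] for r in structure_res])
    out = {}
    for i, r in enumerate(structure_res):
        d = np.linalg.norm(coords - coords[i], axis=1)
        neighbours = [structure_res[j] for j in np.nonzero(d <= cutoff)[0]]
        out[r] = float(np.mean([time_avg[n] for n in neighbours]))
    return pd.Series(out, name="local_energy")
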