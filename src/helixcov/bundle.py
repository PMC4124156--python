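"""Initial helical-bundle construction.

Builds a crude backbone + Cβ model of a transmembrane helix bundle:
helix axis positions in the membrane plane are obtained by stress
minimisation against the predicted helix-helix contacts, the rotation of
each helix about its axis is set from lipid/protein exposure labels, and
ideal α-helix geometry (1.5 Å rise, 100°/residue twist) supplies the
coordinates.  Loops are not built.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
from scipy.optimize import minimize
import biotite.structure as struc

from .annotations import HelixAnnotation, Segment
from .detector import HelixPairPrediction
from .geometry import Structure

RISE_PER_RESIDUE = 1.5       # Å along the helix axis
TWIST_PER_RESIDUE = 100.0    # degrees about the axis

# ideal backbone internal coordinates (poly-Ala α-helix)
_BOND = {"N-CA": 1.458, "CA-C": 1.525, "C-N": 1.329, "C-O": 1.231}
_ANGLE = {"N-CA-C": 111.2, "CA-C-N": 116.2, "C-N-CA": 121.7, "CA-C-O": 120.8}
_PHI, _PSI, _OMEGA = -57.8, -47.0, 180.0


def _place_atom(a, b, c, bond: float, angle: float, dihedral: float) -> np.ndarray:
    """NeRF placement of atom D from three predecessors and internal coords."""
    angle, dihedral = np.deg2rad(angle), np.deg2rad(dihedral)
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d2 = bond * np.array(
        [-np.cos(angle), np.sin(angle) * np.cos(dihedral),
         np.sin(angle) * np.sin(dihedral)]
    )
    return c + d2[0] * bc + d2[1] * m + d2[2] * n


def _ideal_cb(n: np.ndarray, ca: np.ndarray, c: np.ndarray) -> np.ndarray:
    # idealized tetrahedral Cβ from the backbone frame (L-chirality)
    b = ca - n
    cvec = c - ca
    a = np.cross(b, cvec)
    return -0.58273431 * a + 0.56802827 * b - 0.54067466 * cvec + ca


@dataclass
class CanonicalHelix:
    """Ideal helix in the canonical frame: axis = +z through the origin,
    N-terminus at the bottom, residue 0's Cβ radial direction at angle
    ``cb_angles[0]``."""

    n_res: int
    coords: dict[str, np.ndarray]   # atom name -> (n_res, 3)
    cb_angles: np.ndarray           # radial angle of each residue's Cβ (rad)


def _nerf_helix(n_res: int) -> dict[str, np.ndarray]:
    """NeRF-built α-helix from the ideal internal coordinates."""
    N = [np.array([0.0, 0.0, 0.0])]
    CA = [np.array([_BOND["N-CA"], 0.0, 0.0])]
    C = [_place_atom(np.array([0.0, 1.0, 0.0]), N[0], CA[0],
                     _BOND["CA-C"], _ANGLE["N-CA-C"], _PHI + 120.0)]
    for _ in range(1, n_res):
        # psi: N(i-1)-CA(i-1)-C(i-1) -> N(i); omega: CA(i-1)-C(i-1) -> CA(i);
        # phi: C(i-1)-N(i)-CA(i) -> C(i)
        N.append(_place_atom(N[-1], CA[-1], C[-1],
                             _BOND["C-N"], _ANGLE["CA-C-N"], _PSI))
        CA.append(_place_atom(CA[-1], C[-1], N[-1],
                              _BOND["N-CA"], _ANGLE["C-N-CA"], _OMEGA))
        C.append(_place_atom(C[-1], N[-1], CA[-1],
                             _BOND["CA-C"], _ANGLE["N-CA-C"], _PHI))
    O = [
        _place_atom(N[i], CA[i], C[i], _BOND["C-O"], _ANGLE["CA-C-O"], _PSI + 180.0)
        for i in range(n_res)
    ]
    CB = [_ideal_cb(N[i], CA[i], C[i]) for i in range(n_res)]
    return {k: np.array(v) for k, v in
            zip(["N", "CA", "C", "O", "CB"], [N, CA, C, O, CB])}


def _residue_template() -> dict[str, np.ndarray]:
    """Per-atom offsets from Cα in a local (radial, tangential, axial) frame.

    Extracted once from the natural screw axis of a NeRF-built helix; the
    rigid template is then propagated by the exact target screw motion, so
    intra-residue geometry stays ideal while the helix acquires exactly
    the canonical rise and twist.
    """
    coords = _nerf_helix(9)
    k = 4  # middle residue
    # exact screw axis from the residue -> residue rigid transform
    P = np.array([coords["N"][k - 1], coords["CA"][k - 1], coords["C"][k - 1]])
    Q = np.array([coords["N"][k], coords["CA"][k], coords["C"][k]])
    pc, qc = P.mean(axis=0), Q.mean(axis=0)
    U, _, Vt = np.linalg.svd((P - pc).T @ (Q - qc))
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    ang = np.arccos(np.clip((np.trace(R) - 1) / 2, -1.0, 1.0))
    axis = np.array([R[2, 1] - R[1, 2], R[0, 2] - R[2, 0],
                     R[1, 0] - R[0, 1]]) / (2 * np.sin(ang))
    t = qc - R @ pc
    if t @ axis < 0:
        axis = -axis
    # a point on the axis: fixed point of the in-plane part of the screw
    rot = _rotation_to_z(axis)
    ca_k = rot @ coords["CA"][k]
    ca_k1 = rot @ coords["CA"][k - 1]
    # solve for axis point (x0, y0): rotation by ang about it maps the
    # in-plane part of CA(k-1) to CA(k)
    c, s = np.cos(ang), np.sin(ang)
    M = np.eye(2) - np.array([[c, -s], [s, c]])
    rhs = ca_k[:2] - np.array([[c, -s], [s, c]]) @ ca_k1[:2]
    center = np.linalg.solve(M, rhs)

    ca_local = ca_k[:2] - center
    alpha = np.arctan2(ca_local[1], ca_local[0])
    e_r = np.array([np.cos(alpha), np.sin(alpha), 0.0])
    e_t = np.array([-np.sin(alpha), np.cos(alpha), 0.0])
    e_z = np.array([0.0, 0.0, 1.0])
    offsets = {}
    for name in ("N", "C", "O", "CB"):
        rel = rot @ coords[name][k] - rot @ coords["CA"][k]
        offsets[name] = np.array([rel @ e_r, rel @ e_t, rel @ e_z])
    return offsets


_TEMPLATE: dict[str, np.ndarray] | None = None


def ideal_helix(n_res: int) -> CanonicalHelix:
    """Build an ideal α-helix backbone (N, CA, C, O, CB) of ``n_res`` residues.

    Exact screw geometry: 1.5 Å rise and 100° twist per residue, with the
    Cα radius chosen so consecutive Cα-Cα distances are exactly 3.8 Å.
    """
    global _TEMPLATE
    if n_res < 2:
        raise ValueError("helix needs at least 2 residues")
    if _TEMPLATE is None:
        _TEMPLATE = _residue_template()
    twist = np.deg2rad(TWIST_PER_RESIDUE)
    radius = np.sqrt(3.8**2 - RISE_PER_RESIDUE**2) / (2 * np.sin(twist / 2))
    r_idx = np.arange(n_res)
    angles = r_idx * twist
    z_ca = r_idx * RISE_PER_RESIDUE
    z_ca = z_ca - (z_ca[0] + z_ca[-1]) / 2  # centre the span
    e_r = np.column_stack([np.cos(angles), np.sin(angles), np.zeros(n_res)])
    e_t = np.column_stack([-np.sin(angles), np.cos(angles), np.zeros(n_res)])
    e_z = np.broadcast_to(np.array([0.0, 0.0, 1.0]), (n_res, 3))
    ca = radius * e_r + z_ca[:, None] * np.array([0.0, 0.0, 1.0])
    coords = {"CA": ca}
    for name, off in _TEMPLATE.items():
        coords[name] = ca + off[0] * e_r + off[1] * e_t + off[2] * e_z
    cb_angles = np.arctan2(coords["CB"][:, 1], coords["CB"][:, 0])
    return CanonicalHelix(n_res=n_res, coords=coords, cb_angles=cb_angles)


def _rotation_to_z(axis: np.ndarray) -> np.ndarray:
    """Proper rotation mapping ``axis`` to +z."""
    axis = axis / np.linalg.norm(axis)
    z = np.array([0.0, 0.0, 1.0])
    v = np.cross(axis, z)
    s, c = np.linalg.norm(v), float(axis @ z)
    if s < 1e-12:
        return np.eye(3) if c > 0 else np.diag([1.0, -1.0, -1.0])
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + vx + vx @ vx * ((1 - c) / s**2)


# ---------------------------------------------------------------------------
# 2D placement from the contact graph
# ---------------------------------------------------------------------------

def place_helices(
    predictions: Sequence[HelixPairPrediction],
    contact_distance: float = 10.0,
    seed: int = 1234,
    n_starts: int = 8,
) -> dict[str, np.ndarray]:
    """Axis positions in the membrane plane from predicted contacts.

    Minimises ``sum_pairs (|p_a - p_b| - D)^2`` plus a repulsion penalty
    for unpaired helices closer than ``D`` (= ``contact_distance``), with
    deterministic seeded multi-start gradient descent.  The output is
    gauge-fixed: centroid at the origin, first helix on the +x axis, and
    the first off-axis helix at positive y.
    """
    # canonical ordering makes the seeded multi-start (and hence the chosen
    # minimum of the degenerate stress landscape) independent of input order
    names = sorted({n for p in predictions for n in (p.helix_a, p.helix_b)})
    if len(names) < 2:
        raise ValueError("need at least 2 helices")
    edges = sorted({tuple(sorted((p.helix_a, p.helix_b))) for p in predictions})

    g = nx.Graph()
    g.add_nodes_from(names)
    g.add_edges_from(edges)
    comps = list(nx.connected_components(g))
    if len(comps) > 1:
        raise ValueError(
            "contact graph is disconnected; components: "
            + "; ".join(",".join(sorted(c)) for c in comps)
        )

    n = len(names)
    idx = {name: i for i, name in enumerate(names)}
    edge_idx = np.array([(idx[a], idx[b]) for a, b in edges])
    edge_set = set(edges)
    non_edges = np.array([
        (i, j) for i in range(n) for j in range(i + 1, n)
        if tuple(sorted((names[i], names[j]))) not in edge_set
    ]).reshape(-1, 2)
    D = contact_distance

    def stress_grad(x: np.ndarray):
        pos = x.reshape(n, 2)
        grad = np.zeros_like(pos)
        f = 0.0
        for pairs, repulsive in ((edge_idx, False), (non_edges, True)):
            if pairs.size == 0:
                continue
            delta = pos[pairs[:, 0]] - pos[pairs[:, 1]]
            dist = np.maximum(np.linalg.norm(delta, axis=1), 1e-9)
            if repulsive:
                viol = np.clip(D - dist, 0.0, None)
                f += float(np.sum(viol**2))
                coef = -2.0 * viol / dist
            else:
                f += float(np.sum((dist - D) ** 2))
                coef = 2.0 * (dist - D) / dist
            g_pairs = coef[:, None] * delta
            np.add.at(grad, pairs[:, 0], g_pairs)
            np.add.at(grad, pairs[:, 1], -g_pairs)
        return f, grad.ravel()

    rng = np.random.default_rng(seed)
    radius = D / (2 * np.sin(np.pi / n)) if n > 2 else D / 2
    starts = [
        np.column_stack([
            radius * np.cos(2 * np.pi * np.arange(n) / n),
            radius * np.sin(2 * np.pi * np.arange(n) / n),
        ]).ravel()
    ]
    for _ in range(n_starts - 1):
        starts.append(rng.normal(scale=D, size=2 * n))

    best = None
    for x0 in starts:
        res = minimize(stress_grad, x0, jac=True, method="L-BFGS-B",
                       options={"maxiter": 2000, "ftol": 1e-15, "gtol": 1e-12})
        if best is None or res.fun < best.fun:
            best = res
    pos = best.x.reshape(n, 2)

    # gauge fixing
    pos -= pos.mean(axis=0)
    theta = np.arctan2(pos[0, 1], pos[0, 0])
    c, s = np.cos(-theta), np.sin(-theta)
    pos = pos @ np.array([[c, -s], [s, c]]).T
    for i in range(1, n):
        if abs(pos[i, 1]) > 1e-6 * D:
            if pos[i, 1] < 0:
                pos[:, 1] = -pos[:, 1]
            break
    return {name: pos[idx[name]].copy() for name in names}


# ---------------------------------------------------------------------------
# rotation from exposure labels
# ---------------------------------------------------------------------------

def orient_by_exposure(
    cb_angles: np.ndarray,
    exposure: Sequence[str],
    axis_xy: np.ndarray,
    centroid_xy: np.ndarray,
) -> float:
    """Helix phase that faces lipid-labelled residues away from the bundle.

    Maximises ``sum_lipid cos(theta_r) - sum_protein cos(theta_r)`` where
    ``theta_r`` is the angle between residue r's radial Cβ direction
    (canonical angle ``cb_angles[r]`` rotated by the phase) and the
    outward direction from the bundle centroid to this helix axis.  Solved
    in closed form via the circular mean.  Returns the phase in radians,
    wrapped to (-π, π].
    """
    exposure = list(exposure)
    if len(exposure) != len(cb_angles):
        raise ValueError("one exposure label per residue required")
    signs = np.array([
        1.0 if e == "lipid" else (-1.0 if e == "protein" else 0.0)
        for e in exposure
    ])
    if np.all(signs == 0):
        raise ValueError("no labelled residue on the helix")
    outward = np.asarray(axis_xy, float) - np.asarray(centroid_xy, float)
    if np.linalg.norm(outward) < 1e-9:
        warnings.warn("helix axis coincides with the bundle centroid; "
                      "outward direction taken as +x")
        omega = 0.0
    else:
        omega = float(np.arctan2(outward[1], outward[0]))
    resultant = np.sum(signs * np.exp(1j * np.asarray(cb_angles)))
    if abs(resultant) < 1e-9:
        warnings.warn("exposure labels are rotationally uninformative; phase 0")
        return 0.0
    phase = omega - float(np.angle(resultant))
    return float((phase + np.pi) % (2 * np.pi) - np.pi)


# ---------------------------------------------------------------------------
# bundle assembly
# ---------------------------------------------------------------------------

@dataclass
class HelixAxis:
    origin: np.ndarray      # (3,) axis point at mid-membrane
    direction: np.ndarray   # unit vector, N->C along the axis
    phase: float            # rotation about the axis (radians)


@dataclass
class BundleModel:
    """Backbone + Cβ bundle with per-helix axis bookkeeping."""

    axes: dict[str, HelixAxis]
    structure: Structure

    def to_pdb(self, path: str | Path) -> None:
        self.structure.to_pdb(path)

    def placement_report(self, path: str | Path) -> None:
        lines = []
        for name, ax in self.axes.items():
            lines.append("[[helix]]")
            lines.append(f'name = "{name}"')
            lines.append(f"origin = [{ax.origin[0]:.3f}, {ax.origin[1]:.3f}, "
                         f"{ax.origin[2]:.3f}]")
            lines.append(f"direction = [{ax.direction[0]:.4f}, "
                         f"{ax.direction[1]:.4f}, {ax.direction[2]:.4f}]")
            lines.append(f"phase_deg = {np.rad2deg(ax.phase):.2f}")
            lines.append("")
        Path(path).write_text("\n".join(lines))


def build_ideal_bundle(
    placements: Mapping[str, np.ndarray],
    phases: Mapping[str, float],
    segments: HelixAnnotation | Sequence[Segment],
) -> BundleModel:
    """Assemble ideal helices at the given axis positions and phases.

    Helix axes are perpendicular to the membrane plane (z); each helix
    runs +z or -z according to its topology (``n_side``), with the
    cytoplasmic side at negative z.  Residues are numbered by the segment
    ranges, chain A, poly-alanine.
    """
    segs = (
        [s for s in segments if s.kind == "TM"]
        if isinstance(segments, HelixAnnotation)
        else list(segments)
    )
    if not segs:
        raise ValueError("no TM segments to build")
    axes: dict[str, HelixAxis] = {}
    atom_list = []
    for seg in segs:
        if seg.name not in placements:
            raise KeyError(f"missing placement for helix {seg.name}")
        if seg.name not in phases:
            raise KeyError(f"missing phase for helix {seg.name}")
        helix = ideal_helix(len(seg))
        coords = {k: v.copy() for k, v in helix.coords.items()}
        direction = np.array([0.0, 0.0, 1.0])
        if (seg.n_side or "cytoplasmic") == "periplasmic":
            # N-terminus on the periplasmic (+z) side: rotate by π about x
            for k in coords:
                coords[k][:, 1] *= -1
                coords[k][:, 2] *= -1
            direction = np.array([0.0, 0.0, -1.0])
        phase = float(phases[seg.name])
        c, s = np.cos(phase), np.sin(phase)
        rot = np.array([[c, -s, 0], [s, c, 0], [0, 0, 1.0]])
        xy = np.asarray(placements[seg.name], float)
        origin = np.array([xy[0], xy[1], 0.0])
        for k in coords:
            coords[k] = coords[k] @ rot.T + origin
        axes[seg.name] = HelixAxis(origin=origin, direction=direction, phase=phase)
        for r, resnum in enumerate(seg.residues):
            for atom_name, element in (("N", "N"), ("CA", "C"), ("C", "C"),
                                       ("O", "O"), ("CB", "C")):
                atom_list.append(struc.Atom(
                    coords[atom_name][r],
                    chain_id="A", res_id=int(resnum), res_name="ALA",
                    atom_name=atom_name, element=element,
                ))
    atoms = struc.array(atom_list)
    return BundleModel(axes=axes, structure=Structure(atoms))
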