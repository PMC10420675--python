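"""Parametric toy structures with known electrostatic ground truth.

Four motifs cover the regimes the pKa pipeline must get right without any
external structure download:

* ``model_compound`` — one fully exposed titratable residue: the ΔpKa = 0
  reference limit;
* ``charge_pair``    — two residues with charge centroids at a controlled
  separation: the screened-Coulomb coupling limit;
* ``buried_site``    — one residue inside a ball of neutral pseudo-atoms of
  tunable solid-angle completeness: the Born desolvation limit;
* ``clasp``          — carboxylates ringing a (removable) +2 ion with
  partial burial, plus a relaxed apo partner: the calcium-clasp motif whose
  holo/apo contrast drives the proton/calcium-coupling verdict.

Residue geometry comes from internal ideal templates (natural extended
rotamer, standard bond lengths/angles), built by torsion-space (NeRF)
chain extension; no rotamer library is involved.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .structure_io import CHARGE_ATOMS, Atom, Structure


def _place(a, b, c, length, angle_deg, dihedral_deg):
    """Position atom D from three predecessors by internal coordinates
    (bond C-D, angle B-C-D, dihedral A-B-C-D)."""
    a, b, c = (np.asarray(p, dtype=float) for p in (a, b, c))
    ang = np.deg2rad(angle_deg)
    dih = np.deg2rad(dihedral_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array(
        [
            -length * np.cos(ang),
            length * np.sin(ang) * np.cos(dih),
            length * np.sin(ang) * np.sin(dih),
        ]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def _backbone():
    n = np.array([0.0, 0.0, 0.0])
    ca = np.array([1.458, 0.0, 0.0])
    c = ca + 1.525 * np.array([np.cos(np.deg2rad(69.0)), np.sin(np.deg2rad(69.0)), 0.0])
    o = _place(n, ca, c, 1.231, 120.5, 0.0)
    cb = _place(c, n, ca, 1.530, 110.5, -122.0)
    return [("N", "N", n), ("CA", "C", ca), ("C", "C", c), ("O", "O", o), ("CB", "C", cb)]


def _sidechain(restype, atoms):
    pos = {name: xyz for name, _el, xyz in atoms}
    n, ca, cb = pos["N"], pos["CA"], pos["CB"]
    out = []

    def add(name, el, xyz):
        pos[name] = xyz
        out.append((name, el, xyz))

    if restype == "ASP":
        add("CG", "C", _place(n, ca, cb, 1.52, 113.0, 180.0))
        add("OD1", "O", _place(ca, cb, pos["CG"], 1.25, 118.5, 0.0))
        add("OD2", "O", _place(ca, cb, pos["CG"], 1.25, 118.5, 180.0))
    elif restype == "GLU":
        add("CG", "C", _place(n, ca, cb, 1.52, 114.0, 180.0))
        add("CD", "C", _place(ca, cb, pos["CG"], 1.52, 113.0, 180.0))
        add("OE1", "O", _place(cb, pos["CG"], pos["CD"], 1.25, 118.5, 0.0))
        add("OE2", "O", _place(cb, pos["CG"], pos["CD"], 1.25, 118.5, 180.0))
    elif restype == "HIS":
        add("CG", "C", _place(n, ca, cb, 1.50, 113.8, 180.0))
        add("ND1", "N", _place(ca, cb, pos["CG"], 1.38, 122.7, 0.0))
        add("CD2", "C", _place(ca, cb, pos["CG"], 1.36, 131.2, 180.0))
        add("CE1", "C", _place(cb, pos["CG"], pos["ND1"], 1.32, 109.3, 180.0))
        add("NE2", "N", _place(cb, pos["CG"], pos["CD2"], 1.37, 107.2, 180.0))
    elif restype == "LYS":
        add("CG", "C", _place(n, ca, cb, 1.52, 114.0, 180.0))
        add("CD", "C", _place(ca, cb, pos["CG"], 1.52, 111.0, 180.0))
        add("CE", "C", _place(cb, pos["CG"], pos["CD"], 1.52, 111.0, 180.0))
        add("NZ", "N", _place(pos["CG"], pos["CD"], pos["CE"], 1.49, 111.0, 180.0))
    elif restype == "ARG":
        add("CG", "C", _place(n, ca, cb, 1.52, 114.0, 180.0))
        add("CD", "C", _place(ca, cb, pos["CG"], 1.52, 111.0, 180.0))
        add("NE", "N", _place(cb, pos["CG"], pos["CD"], 1.46, 112.0, 180.0))
        add("CZ", "C", _place(pos["CG"], pos["CD"], pos["NE"], 1.33, 124.0, 180.0))
        add("NH1", "N", _place(pos["CD"], pos["NE"], pos["CZ"], 1.33, 120.0, 0.0))
        add("NH2", "N", _place(pos["CD"], pos["NE"], pos["CZ"], 1.33, 120.0, 180.0))
    else:
        raise ValueError(
            f"{restype!r} is not a titratable residue type "
            f"(one of {sorted(CHARGE_ATOMS)})"
        )
    return out


def residue_template(restype: str):
    """Ideal-geometry atom list [(name, element, xyz), ...] for one residue."""
    atoms = _backbone()
    atoms += _sidechain(restype, atoms)
    return atoms


def _charge_centroid(restype, atoms):
    pos = {name: xyz for name, _el, xyz in atoms}
    return np.mean([pos[n] for n, _q in CHARGE_ATOMS[restype]], axis=0)


def _rotation_to(u, v):
    """Rotation matrix taking unit vector u onto unit vector v (Rodrigues)."""
    u = u / np.linalg.norm(u)
    v = v / np.linalg.norm(v)
    c = float(np.dot(u, v))
    if c > 1.0 - 1e-12:
        return np.eye(3)
    if c < -1.0 + 1e-12:
        # pick any perpendicular axis for the half-turn
        axis = np.cross(u, [1.0, 0.0, 0.0])
        if np.linalg.norm(axis) < 1e-6:
            axis = np.cross(u, [0.0, 1.0, 0.0])
        axis /= np.linalg.norm(axis)
        K = np.array(
            [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
        )
        return np.eye(3) + 2.0 * K @ K
    axis = np.cross(u, v)
    s = np.linalg.norm(axis)
    axis /= s
    K = np.array(
        [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
    )
    return np.eye(3) + s * K + (1.0 - c) * K @ K


def _oriented_residue(restype, centroid_target, direction):
    """Template atoms moved so the charge centroid sits at ``centroid_target``
    with the CA→centroid axis along ``direction`` (sidechain points that way)."""
    atoms = residue_template(restype)
    cc = _charge_centroid(restype, atoms)
    ca = [xyz for n, _e, xyz in atoms if n == "CA"][0]
    rot = _rotation_to(cc - ca, np.asarray(direction, dtype=float))
    out = []
    for name, el, xyz in atoms:
        out.append((name, el, rot @ (xyz - cc) + np.asarray(centroid_target, float)))
    return out


def _add_residue(structure, atoms, res_name, chain_id, res_seq, hetero=False):
    for name, el, xyz in atoms:
        structure.atoms.append(
            Atom(
                serial=len(structure.atoms) + 1,
                name=name,
                element=el,
                res_name=res_name,
                chain_id=chain_id,
                res_seq=res_seq,
                insertion_code="",
                xyz=np.asarray(xyz, dtype=float),
                hetero=hetero,
            )
        )


def _pseudo_shell(structure, points, chain_id="S", start_seq=1):
    for i, p in enumerate(points):
        _add_residue(
            structure, [("C", "C", p)], "SHL", chain_id, start_seq + i, hetero=True
        )


# ---------------------------------------------------------------------------
# generators


def make_model_compound(restype: str) -> Structure:
    """A single blocked residue, ideal geometry, fully solvent exposed.

    Its computed pKa must recover the model-compound reference value: this
    is the zero point of every ΔpKa the pipeline reports.
    """
    st = Structure(source_id=f"model_compound_{restype}")
    _add_residue(st, residue_template(restype), restype, "A", 1)
    return st


def make_charge_pair(restype_a: str, restype_b: str, separation: float) -> Structure:
    """Two exposed residues with charge centroids ``separation`` apart."""
    if separation < 3.0:
        raise ValueError("separation below 3 A would clash charge groups")
    st = Structure(source_id=f"pair_{restype_a}_{restype_b}_{separation:g}")
    _add_residue(
        st, _oriented_residue(restype_a, (0.0, 0.0, 0.0), (-1.0, 0.0, 0.0)),
        restype_a, "A", 1,
    )
    _add_residue(
        st, _oriented_residue(restype_b, (separation, 0.0, 0.0), (1.0, 0.0, 0.0)),
        restype_b, "A", 2,
    )
    return st


def _lattice_ball(radius: float, spacing: float = 1.8) -> np.ndarray:
    n = int(np.floor(radius / spacing))
    ax = spacing * np.arange(-n, n + 1)
    gx, gy, gz = np.meshgrid(ax, ax, ax, indexing="ij")
    pts = np.stack([gx.ravel(), gy.ravel(), gz.ravel()], axis=1)
    return pts[np.linalg.norm(pts, axis=1) <= radius]


def _solid_angle_cap(points: np.ndarray, completeness: float) -> np.ndarray:
    """Keep the contiguous polar cap covering ``completeness`` of the solid
    angle (measured from -z): completeness 0 -> nothing, 1 -> everything."""
    if not 0.0 <= completeness <= 1.0:
        raise ValueError("completeness must lie in [0, 1]")
    if completeness == 0.0:
        return points[:0]
    r = np.linalg.norm(points, axis=1)
    with np.errstate(invalid="ignore"):
        cosz = np.where(r > 0, points[:, 2] / np.maximum(r, 1e-12), 1.0)
    return points[cosz <= 2.0 * completeness - 1.0]


def make_buried_site(
    restype: str, shell_radius: float = 12.0, completeness: float = 1.0
) -> Structure:
    """A titratable residue inside a ball of neutral carbon pseudo-atoms.

    ``completeness`` is the buried fraction of solid angle; 0 reduces to the
    model compound, 1 is full burial.  Pseudo-atoms are uncharged, so the
    only effect is dielectric: a clean desolvation probe.
    """
    if shell_radius <= 0:
        raise ValueError("shell_radius must be positive")
    st = Structure(source_id=f"buried_{restype}_{shell_radius:g}_{completeness:g}")
    res_atoms = _oriented_residue(restype, (0.0, 0.0, 0.0), (0.0, 0.0, -1.0))
    _add_residue(st, res_atoms, restype, "A", 1)
    pts = _solid_angle_cap(_lattice_ball(shell_radius), completeness)
    if len(pts):
        res_xyz = np.array([xyz for _n, _e, xyz in res_atoms])
        d = np.linalg.norm(pts[:, None, :] - res_xyz[None, :, :], axis=2).min(axis=1)
        pts = pts[d >= 2.6]
        _pseudo_shell(st, pts)
    return st


def make_clasp(
    n_acids: int = 4,
    ring_radius: float = 3.2,
    ion: bool = True,
    burial: float = 0.5,
    restype: str = "ASP",
) -> tuple[Structure, Structure]:
    """An idealised calcium clasp and its relaxed apo partner.

    Holo: ``n_acids`` carboxylates with charge centroids on a ring of
    ``ring_radius`` around the ion position (origin), sidechains pointing
    inward, partially buried by a neutral pseudo-atom cap; a +2 calcium is
    placed at the origin when ``ion`` is true.  Apo: the same residues
    displaced outward to twice the ring radius with no burial and no ion —
    the structural relaxation that a flexible site undergoes on calcium
    release.  Returns ``(holo, apo)``.
    """
    if not 2 <= n_acids <= 5:
        raise ValueError("n_acids must be between 2 and 5")
    if ring_radius < 2.0:
        raise ValueError("ring_radius below 2 A would overlap the ion")

    def build(radius, buried, with_ion, tag):
        st = Structure(source_id=f"clasp_{tag}_{n_acids}x{restype}")
        for k in range(n_acids):
            ang = 2.0 * np.pi * k / n_acids
            direction = -np.array([np.cos(ang), np.sin(ang), 0.0])
            centroid = -radius * direction
            _add_residue(
                st, _oriented_residue(restype, centroid, direction),
                restype, "A", 301 + k,
            )
        if buried > 0:
            pts = _solid_angle_cap(_lattice_ball(radius + 9.0), buried)
            if len(pts):
                res_xyz = st.coords()
                d = np.linalg.norm(
                    pts[:, None, :] - res_xyz[None, :, :], axis=2
                ).min(axis=1)
                keep = (d >= 2.8) & (np.linalg.norm(pts, axis=1) >= 2.6)
                _pseudo_shell(st, pts[keep])
        if with_ion:
            _add_residue(st, [("CA", "CA", np.zeros(3))], "CA", "A", 401, hetero=True)
        return st

    holo = build(ring_radius, burial, ion, "holo")
    apo = build(2.0 * ring_radius, 0.0, False, "apo")
    return holo, apo


@dataclass(frozen=True)
class MimicSpec:
    """Declarative description of a synthetic motif, used by the CLI."""

    motif: str  # model_compound | charge_pair | buried_site | clasp
    restype: str = "ASP"
    restype_b: str = "ASP"
    separation: float = 5.0
    shell_radius: float = 12.0
    completeness: float = 1.0
    n_acids: int = 4
    ring_radius: float = 3.2
    ion: bool = True
    burial: float = 0.5

    def build(self):
        if self.motif == "model_compound":
            return make_model_compound(self.restype)
        if self.motif == "charge_pair":
            return make_charge_pair(self.restype, self.restype_b, self.separation)
        if self.motif == "buried_site":
            return make_buried_site(self.restype, self.shell_radius, self.completeness)
        if self.motif == "clasp":
            return make_clasp(
                self.n_acids, self.ring_radius, self.ion, self.burial, self.restype
            )
        raise ValueError(f"unknown motif {self.motif!r}")
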