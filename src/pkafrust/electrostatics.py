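"""Continuum electrostatics: finite-difference Poisson-Boltzmann (FDPB)
grid solutions for short-range/desolvation terms, plus an analytic
Debye-Hueckel (DH) screened Coulomb term for long-range site-site
interactions.

The linearised PB equation

    div( eps(r) grad(phi) ) - eps_w * kappa^2(r) * phi = -4*pi*C*rho(r)

is discretised on a cubic grid with a 7-point stencil and harmonic-mean
edge dielectrics, and solved by preconditioned conjugate gradients.  With
C = 332.064 kcal*A/(mol*e^2), charges in e and lengths in Angstrom, the
potential comes out in kcal/mol/e.  In a uniform solvent the discrete
solution converges to Coulomb / screened-Coulomb away from the source,
which provides closed-form oracles for the solver.

Desolvation and background terms are differences between a calculation
with the full protein dielectric environment and a reference calculation
with only the titrating residue present (the model-compound state), on an
identical grid, so the singular grid self-energy cancels exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.linalg import LinearOperator, cg

from .structure_io import IonizableSite, Structure, retained_ion_charges

#: gas constant, kcal/(mol*K)
R_KCAL = 1.987204258640832e-3
#: Avogadro count per mol per litre, converted to per cubic Angstrom per mol/L
CONC_TO_PER_A3 = 6.02214076e-4

#: united-atom radii, Angstrom (hydrogens implicit)
ELEMENT_RADII = {"C": 1.7, "N": 1.5, "O": 1.4, "S": 1.85, "P": 1.9}
DEFAULT_RADIUS = 1.7


class ConvergenceError(RuntimeError):
    pass


@dataclass(frozen=True)
class PhysicsConfig:
    """Dielectric / ionic model of the continuum calculation."""

    eps_protein: float = 4.0
    eps_solvent: float = 78.4
    ionic_strength: float = 0.15  # mol/L
    temperature: float = 298.15  # K
    coulomb_const: float = 332.064  # kcal*A/(mol*e^2)
    stern: float = 2.0  # ion-exclusion layer beyond atom surface, A

    def __post_init__(self):
        if not (0 < self.eps_protein < self.eps_solvent):
            raise ValueError("require 0 < eps_protein < eps_solvent")
        if self.ionic_strength < 0 or self.temperature <= 0:
            raise ValueError("ionic strength and temperature must be non-negative")

    @property
    def rt(self) -> float:
        """RT in kcal/mol."""
        return R_KCAL * self.temperature

    @property
    def kt_log10(self) -> float:
        """ln(10)*RT in kcal/mol: 1 pKa unit of free energy (1.364 at 298 K)."""
        return np.log(10.0) * self.rt

    @property
    def bjerrum(self) -> float:
        return self.coulomb_const / (self.eps_solvent * self.rt)

    @property
    def kappa(self) -> float:
        """Inverse Debye length in 1/A (0.127 at I=0.15 M, 298.15 K)."""
        k2 = 8.0 * np.pi * self.bjerrum * self.ionic_strength * CONC_TO_PER_A3
        return float(np.sqrt(k2))


def dh_energy(q1: float, q2: float, r: float, physics: PhysicsConfig) -> float:
    """Screened-Coulomb interaction of two point charges in solvent, kcal/mol."""
    if r <= 0:
        raise ValueError("separation must be positive")
    k = physics.kappa
    return physics.coulomb_const * q1 * q2 * np.exp(-k * r) / (physics.eps_solvent * r)


def dh_potential(points: np.ndarray, charges_xyz: np.ndarray, charges_q: np.ndarray,
                 physics: PhysicsConfig) -> np.ndarray:
    """DH potential of a set of charges at given points, kcal/mol/e."""
    d = np.linalg.norm(points[:, None, :] - charges_xyz[None, :, :], axis=2)
    d = np.maximum(d, 1e-6)
    k = physics.kappa
    return (physics.coulomb_const / physics.eps_solvent) * (
        (charges_q[None, :] * np.exp(-k * d) / d).sum(axis=1)
    )


@dataclass(frozen=True)
class GridSpec:
    """Cubic grid geometry: centre, physical extent per side, node spacing."""

    centre: tuple[float, float, float]
    extent: float
    spacing: float

    def __post_init__(self):
        if self.spacing <= 0 or self.extent <= 0:
            raise ValueError("extent and spacing must be positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        n = int(round(self.extent / self.spacing)) + 1
        return (n, n, n)

    def axes(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        n = self.shape[0]
        half = (n - 1) * self.spacing / 2.0
        return tuple(
            np.asarray(self.centre)[i] - half + self.spacing * np.arange(n)
            for i in range(3)
        )


@dataclass
class GridConfig:
    """Focusing strategy: coarse pass over the whole molecule, fine pass on
    the site.  Small systems that fit in one fine grid skip the coarse pass."""

    fine_spacing: float = 0.6
    fine_extent: float = 30.0
    coarse_spacing: float = 1.2
    pad: float = 10.0
    single_level_max: float = 34.0
    cg_rtol: float = 1e-8
    cg_maxiter: int = 20000


@dataclass
class PotentialMap:
    grid: GridSpec
    phi: np.ndarray  # kcal/mol/e, shape = grid.shape
    provenance: str = ""

    def contains(self, points: np.ndarray, margin: float = 0.0) -> np.ndarray:
        ax = self.grid.axes()
        pts = np.atleast_2d(points)
        ok = np.ones(len(pts), dtype=bool)
        for i in range(3):
            ok &= (pts[:, i] >= ax[i][0] + margin) & (pts[:, i] <= ax[i][-1] - margin)
        return ok

    def at(self, points: np.ndarray) -> np.ndarray:
        """Trilinear interpolation of the potential at Cartesian points."""
        ax = self.grid.axes()
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        h = self.grid.spacing
        out = np.zeros(len(pts))
        f = (pts - np.array([ax[0][0], ax[1][0], ax[2][0]])) / h
        i0 = np.clip(np.floor(f).astype(int), 0, np.array(self.phi.shape) - 2)
        t = f - i0
        for dx in (0, 1):
            for dy in (0, 1):
                for dz in (0, 1):
                    w = (
                        (t[:, 0] if dx else 1 - t[:, 0])
                        * (t[:, 1] if dy else 1 - t[:, 1])
                        * (t[:, 2] if dz else 1 - t[:, 2])
                    )
                    out += w * self.phi[i0[:, 0] + dx, i0[:, 1] + dy, i0[:, 2] + dz]
        return out


@dataclass
class EnergyTerms:
    """Self-energy terms of one ionisable site, kcal/mol."""

    dG_desolv: float
    dG_back: float


# ---------------------------------------------------------------------------
# charge / radius assignment


def parameterize(structure: Structure, site: IonizableSite, state: str):
    """Charges (e) and positions for one titration state of a site.

    The ionised state places the formal charge on the site's charge-bearing
    atoms; the neutral state is all-zero (two-state model, no dipoles).
    """
    if state not in ("ionised", "neutral"):
        raise ValueError(f"unknown state {state!r}")
    key = site.residue_key()
    present = {a.name for a in structure.atoms if a.residue_key() == key}
    missing = [n for n, _ in site.charge_atoms if n not in present]
    if missing:
        raise ValueError(f"disordered site {site.label}: missing atoms {missing}")
    if state == "neutral":
        return site.charge_xyz.copy(), np.zeros(len(site.charge_atoms))
    return site.charge_xyz.copy(), site.charges.copy()


def atom_radii(structure: Structure) -> np.ndarray:
    return np.array(
        [ELEMENT_RADII.get(a.element.upper(), DEFAULT_RADIUS) for a in structure.atoms]
    )


# ---------------------------------------------------------------------------
# FDPB solver


def _surface_distance(axes, shape, xyz, radii, h, reach):
    """Per-node signed distance to the nearest atom surface (negative inside),
    clipped at +reach; computed in local windows around each atom."""
    x, y, z = axes
    nx, ny, nz = shape
    dist = np.full(shape, reach)
    for p, r in zip(xyz, radii):
        rr = r + reach
        i0 = max(0, int(np.ceil((p[0] - rr - x[0]) / h)))
        i1 = min(nx - 1, int(np.floor((p[0] + rr - x[0]) / h)))
        j0 = max(0, int(np.ceil((p[1] - rr - y[0]) / h)))
        j1 = min(ny - 1, int(np.floor((p[1] + rr - y[0]) / h)))
        k0 = max(0, int(np.ceil((p[2] - rr - z[0]) / h)))
        k1 = min(nz - 1, int(np.floor((p[2] + rr - z[0]) / h)))
        if i1 < i0 or j1 < j0 or k1 < k0:
            continue
        dx2 = (x[i0 : i1 + 1] - p[0]) ** 2
        dy2 = (y[j0 : j1 + 1] - p[1]) ** 2
        dz2 = (z[k0 : k1 + 1] - p[2]) ** 2
        d = np.sqrt(dx2[:, None, None] + dy2[None, :, None] + dz2[None, None, :]) - r
        win = dist[i0 : i1 + 1, j0 : j1 + 1, k0 : k1 + 1]
        np.minimum(win, d, out=win)
    return dist


def _spread_charges(shape, axes, h, xyz, q):
    """Trilinear assignment of point charges to grid nodes."""
    rho = np.zeros(shape)
    origin = np.array([axes[0][0], axes[1][0], axes[2][0]])
    f = (np.atleast_2d(xyz) - origin) / h
    i0 = np.clip(np.floor(f).astype(int), 0, np.array(shape) - 2)
    t = f - i0
    for n, qq in enumerate(np.atleast_1d(q)):
        for dx in (0, 1):
            for dy in (0, 1):
                for dz in (0, 1):
                    w = (
                        (t[n, 0] if dx else 1 - t[n, 0])
                        * (t[n, 1] if dy else 1 - t[n, 1])
                        * (t[n, 2] if dz else 1 - t[n, 2])
                    )
                    rho[i0[n, 0] + dx, i0[n, 1] + dy, i0[n, 2] + dz] += w * qq
    return rho


def solve_fdpb(
    charges_xyz: np.ndarray,
    charges_q: np.ndarray,
    grid: GridSpec,
    physics: PhysicsConfig,
    diel_xyz: np.ndarray | None = None,
    diel_radii: np.ndarray | None = None,
    boundary: np.ndarray | None = None,
    grid_cfg: GridConfig | None = None,
    provenance: str = "",
) -> PotentialMap:
    """Solve the linearised PB equation on one grid level.

    ``diel_xyz/diel_radii`` define the low-dielectric (protein) region as a
    union of spheres; omit them for a uniform-solvent calculation.  The
    Dirichlet boundary defaults to the analytic DH potential of the source
    charges; pass ``boundary`` (full-shape array, only faces used) when
    focusing from a coarser level.
    """
    grid_cfg = grid_cfg or GridConfig()
    charges_xyz = np.atleast_2d(np.asarray(charges_xyz, dtype=float))
    charges_q = np.atleast_1d(np.asarray(charges_q, dtype=float))
    shape = grid.shape
    axes = grid.axes()
    h = grid.spacing
    nx, ny, nz = shape

    # smoothed (antialiased) dielectric boundary: node protein-volume
    # fraction from the signed surface distance, mixed harmonically --
    # removes the O(h) staircase error of a binary in/out assignment
    if diel_xyz is not None and len(diel_xyz):
        reach = max(physics.stern, h) + h
        surf = _surface_distance(axes, shape, diel_xyz, diel_radii, h, reach)
        frac = np.clip(0.5 - surf / h, 0.0, 1.0)
        eps_node = frac * physics.eps_protein + (1.0 - frac) * physics.eps_solvent
        inside = surf < 0.0
        stern_excl = surf < physics.stern if physics.stern > 0 else inside
    else:
        inside = np.zeros(shape, dtype=bool)
        stern_excl = inside
        eps_node = np.full(shape, physics.eps_solvent)

    # harmonic-mean edge dielectrics
    ex = 2.0 * eps_node[:-1] * eps_node[1:] / (eps_node[:-1] + eps_node[1:])
    ey = 2.0 * eps_node[:, :-1] * eps_node[:, 1:] / (eps_node[:, :-1] + eps_node[:, 1:])
    ez = (
        2.0 * eps_node[:, :, :-1] * eps_node[:, :, 1:]
        / (eps_node[:, :, :-1] + eps_node[:, :, 1:])
    )

    kap2 = np.where(~stern_excl & ~inside, physics.eps_solvent * physics.kappa**2, 0.0)

    rho = _spread_charges(shape, axes, h, charges_xyz, charges_q)
    rhs = 4.0 * np.pi * physics.coulomb_const * rho / h

    phi = np.zeros(shape)
    if boundary is not None:
        phi[:] = boundary
    else:
        if np.any(charges_q):
            for axis, face in ((0, 0), (0, -1), (1, 0), (1, -1), (2, 0), (2, -1)):
                sl = [slice(None)] * 3
                sl[axis] = face
                gx, gy, gz = np.meshgrid(
                    axes[0][sl[0]], axes[1][sl[1]], axes[2][sl[2]], indexing="ij"
                )
                pts = np.stack([gx.ravel(), gy.ravel(), gz.ravel()], axis=1)
                vals = dh_potential(pts, charges_xyz, charges_q, physics)
                phi[tuple(sl)] = vals.reshape(gx.shape).squeeze(axis=axis)

    if not np.any(charges_q) and boundary is None:
        return PotentialMap(grid, phi, provenance)

    # assemble the SPD system on interior nodes
    idx = -np.ones(shape, dtype=np.int64)
    n_int = (nx - 2) * (ny - 2) * (nz - 2)
    idx[1:-1, 1:-1, 1:-1] = np.arange(n_int).reshape(nx - 2, ny - 2, nz - 2)

    diag = (
        ex[:-1, 1:-1, 1:-1] + ex[1:, 1:-1, 1:-1]
        + ey[1:-1, :-1, 1:-1] + ey[1:-1, 1:, 1:-1]
        + ez[1:-1, 1:-1, :-1] + ez[1:-1, 1:-1, 1:]
        + kap2[1:-1, 1:-1, 1:-1] * h * h
    ).ravel()

    rows, cols, vals = [], [], []
    # x-direction couplings between interior nodes
    r = idx[1:-2, 1:-1, 1:-1].ravel()
    c = idx[2:-1, 1:-1, 1:-1].ravel()
    v = -ex[1:-1, 1:-1, 1:-1].ravel()
    rows += [r, c]
    cols += [c, r]
    vals += [v, v]
    r = idx[1:-1, 1:-2, 1:-1].ravel()
    c = idx[1:-1, 2:-1, 1:-1].ravel()
    v = -ey[1:-1, 1:-1, 1:-1].ravel()
    rows += [r, c]
    cols += [c, r]
    vals += [v, v]
    r = idx[1:-1, 1:-1, 1:-2].ravel()
    c = idx[1:-1, 1:-1, 2:-1].ravel()
    v = -ez[1:-1, 1:-1, 1:-1].ravel()
    rows += [r, c]
    cols += [c, r]
    vals += [v, v]
    di = np.arange(n_int)
    rows.append(di)
    cols.append(di)
    vals.append(diag)
    A = coo_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n_int, n_int),
    ).tocsr()

    b = rhs[1:-1, 1:-1, 1:-1].copy()
    # Dirichlet boundary contributions folded into the RHS
    b[0] += ex[0, 1:-1, 1:-1] * phi[0, 1:-1, 1:-1]
    b[-1] += ex[-1, 1:-1, 1:-1] * phi[-1, 1:-1, 1:-1]
    b[:, 0] += ey[1:-1, 0, 1:-1] * phi[1:-1, 0, 1:-1]
    b[:, -1] += ey[1:-1, -1, 1:-1] * phi[1:-1, -1, 1:-1]
    b[:, :, 0] += ez[1:-1, 1:-1, 0] * phi[1:-1, 1:-1, 0]
    b[:, :, -1] += ez[1:-1, 1:-1, -1] * phi[1:-1, 1:-1, -1]
    b = b.ravel()

    dinv = 1.0 / diag
    M = LinearOperator((n_int, n_int), matvec=lambda x: dinv * x)
    x, info = cg(A, b, rtol=grid_cfg.cg_rtol, atol=0.0, maxiter=grid_cfg.cg_maxiter, M=M)
    if info != 0:
        res = np.linalg.norm(A @ x - b) / max(np.linalg.norm(b), 1e-30)
        raise ConvergenceError(
            f"FDPB CG failed to converge (info={info}, relative residual {res:.2e})"
        )
    phi[1:-1, 1:-1, 1:-1] = x.reshape(nx - 2, ny - 2, nz - 2)
    return PotentialMap(grid, phi, provenance)


def _focused_solve(
    charges_xyz,
    charges_q,
    centre,
    diel_xyz,
    diel_radii,
    physics,
    grid_cfg,
    provenance="",
):
    """One- or two-level (focused) FDPB solve around ``centre``.

    Returns ``(fine_map, coarse_map_or_None)``.  The global box is the
    dielectric extent plus solvent padding; if it fits inside the fine
    single-level limit, one grid with analytic DH boundaries is used.
    """
    grid_cfg = grid_cfg or GridConfig()
    pts = diel_xyz if diel_xyz is not None and len(diel_xyz) else np.atleast_2d(charges_xyz)
    lo = pts.min(axis=0) - grid_cfg.pad
    hi = pts.max(axis=0) + grid_cfg.pad
    global_extent = float(np.max(hi - lo))
    global_centre = tuple((lo + hi) / 2.0)

    if global_extent <= grid_cfg.single_level_max:
        grid = GridSpec(global_centre, global_extent, grid_cfg.fine_spacing)
        fine = solve_fdpb(
            charges_xyz, charges_q, grid, physics,
            diel_xyz, diel_radii, grid_cfg=grid_cfg, provenance=provenance,
        )
        return fine, None

    coarse_grid = GridSpec(global_centre, global_extent, grid_cfg.coarse_spacing)
    coarse = solve_fdpb(
        charges_xyz, charges_q, coarse_grid, physics,
        diel_xyz, diel_radii, grid_cfg=grid_cfg, provenance=provenance + "/coarse",
    )
    fine_grid = GridSpec(tuple(centre), grid_cfg.fine_extent, grid_cfg.fine_spacing)
    ax = fine_grid.axes()
    gx, gy, gz = np.meshgrid(ax[0], ax[1], ax[2], indexing="ij")
    pts_all = np.stack([gx.ravel(), gy.ravel(), gz.ravel()], axis=1)
    boundary = coarse.at(pts_all).reshape(fine_grid.shape)
    fine = solve_fdpb(
        charges_xyz, charges_q, fine_grid, physics,
        diel_xyz, diel_radii, boundary=boundary, grid_cfg=grid_cfg,
        provenance=provenance,
    )
    return fine, coarse


@dataclass
class SiteSolution:
    """Per-site FDPB products reused across energy terms and pair couplings."""

    site: IonizableSite
    terms: EnergyTerms
    protein_map: PotentialMap
    coarse_map: PotentialMap | None = None


def site_self_energy(
    site: IonizableSite,
    structure: Structure,
    physics: PhysicsConfig,
    grid_cfg: GridConfig | None = None,
) -> SiteSolution:
    """Desolvation and background energies of ionising one site in place.

    Two FDPB calculations share one grid: the site's ionised charges in the
    full protein dielectric environment, and the same charges with only the
    site's own residue present (the model-compound reference).  Their
    difference at the source charges gives the desolvation penalty; the
    protein-environment field evaluated at retained-ion formal charges
    gives the background term.
    """
    grid_cfg = grid_cfg or GridConfig()
    xyz, q = parameterize(structure, site, "ionised")
    all_xyz = structure.coords()
    all_radii = atom_radii(structure)
    centre = site.centroid

    prot_map, coarse = _focused_solve(
        xyz, q, centre, all_xyz, all_radii, physics, grid_cfg,
        provenance=f"{site.label}/protein",
    )

    key = site.residue_key()
    own = np.array([i for i, a in enumerate(structure.atoms) if a.residue_key() == key])
    ref_map = solve_fdpb(
        xyz, q, prot_map.grid, physics,
        all_xyz[own], all_radii[own], grid_cfg=grid_cfg,
        provenance=f"{site.label}/reference",
    )

    phi_diff = prot_map.at(xyz) - ref_map.at(xyz)
    dG_desolv = 0.5 * float(np.dot(q, phi_diff))

    dG_back = 0.0
    for q_bg, p_bg in retained_ion_charges(structure):
        p = np.atleast_2d(p_bg)
        if prot_map.contains(p, margin=prot_map.grid.spacing)[0]:
            phi = float(prot_map.at(p)[0])
        elif coarse is not None and coarse.contains(p, margin=coarse.grid.spacing)[0]:
            phi = float(coarse.at(p)[0])
        else:
            phi = float(dh_potential(p, xyz, q, physics)[0])
        dG_back += q_bg * phi

    return SiteSolution(site, EnergyTerms(dG_desolv, dG_back), prot_map, coarse)


def pair_energy_from_maps(
    sol_i: SiteSolution,
    sol_j: SiteSolution,
    physics: PhysicsConfig,
    crossover: float = 12.0,
) -> float:
    """Site-site interaction energy of the two ionised states, kcal/mol.

    Inside the crossover distance the FDPB field of each site is evaluated
    at the other's charges (and the two directions averaged, enforcing
    reciprocity); beyond it, where the dielectric environment no longer
    matters, the analytic DH energy between net site charges is used.
    """
    ci, cj = sol_i.site.centroid, sol_j.site.centroid
    r = float(np.linalg.norm(ci - cj))
    if r > crossover:
        return dh_energy(float(sol_i.site.gamma), float(sol_j.site.gamma), r, physics)
    xyz_j, q_j = sol_j.site.charge_xyz, sol_j.site.charges
    xyz_i, q_i = sol_i.site.charge_xyz, sol_i.site.charges
    w_ij = w_ji = None
    if sol_i.protein_map.contains(xyz_j, margin=sol_i.protein_map.grid.spacing).all():
        w_ij = float(np.dot(q_j, sol_i.protein_map.at(xyz_j)))
    if sol_j.protein_map.contains(xyz_i, margin=sol_j.protein_map.grid.spacing).all():
        w_ji = float(np.dot(q_i, sol_j.protein_map.at(xyz_i)))
    vals = [w for w in (w_ij, w_ji) if w is not None]
    if not vals:
        return dh_energy(float(sol_i.site.gamma), float(sol_j.site.gamma), r, physics)
    return float(np.mean(vals))


def pair_energy(
    site_i: IonizableSite,
    site_j: IonizableSite,
    structure: Structure,
    physics: PhysicsConfig,
    grid_cfg: GridConfig | None = None,
    crossover: float = 12.0,
) -> float:
    """Standalone pair interaction; prefer reusing :class:`SiteSolution`
    objects from :func:`site_self_energy` when computing a full matrix."""
    if site_i.residue_key() == site_j.residue_key():
        raise ValueError("pair energy requires two distinct sites")
    sol_i = site_self_energy(site_i, structure, physics, grid_cfg)
    sol_j = site_self_energy(site_j, structure, physics, grid_cfg)
    return pair_energy_from_maps(sol_i, sol_j, physics, crossover)
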