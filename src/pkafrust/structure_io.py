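"""Reading, normalising and writing protein structures.

Structures are held as flat lists of atoms with author numbering preserved
verbatim, which keeps residue labels (e.g. ``D301:A``) aligned with the
labels used in the structural-biology literature.  Input is PDB or mmCIF
(via gemmi); all output is fixed-column PDB because the B-factor field of
that format is used to carry frustration scores for visualisation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import gemmi
import numpy as np

# Model-compound reference pKas of the five titratable sidechain types.
MODEL_PKA: dict[str, float] = {
    "ASP": 4.0,
    "GLU": 4.4,
    "HIS": 6.3,
    "LYS": 10.4,
    "ARG": 12.0,
}

# Ionisation direction: -1 for acids (ionised form is the deprotonated
# anion), +1 for bases (ionised form is the protonated cation).
GAMMA: dict[str, int] = {"ASP": -1, "GLU": -1, "HIS": +1, "LYS": +1, "ARG": +1}

# Atoms carrying the formal charge of the ionised state, with partial
# charges (e).  Charges sum to gamma for each type.
CHARGE_ATOMS: dict[str, list[tuple[str, float]]] = {
    "ASP": [("OD1", -0.5), ("OD2", -0.5)],
    "GLU": [("OE1", -0.5), ("OE2", -0.5)],
    "HIS": [("ND1", +0.5), ("NE2", +0.5)],
    "LYS": [("NZ", +1.0)],
    "ARG": [("NE", 1.0 / 3.0), ("NH1", 1.0 / 3.0), ("NH2", 1.0 / 3.0)],
}

ONE_LETTER = {"ASP": "D", "GLU": "E", "HIS": "H", "LYS": "K", "ARG": "R"}

#: residue codes treated as strippable ions / solvent, with formal charges
ION_CHARGES: dict[str, float] = {
    "CA": +2.0, "ZN": +2.0, "MG": +2.0, "NA": +1.0, "K": +1.0, "CL": -1.0,
}
DEFAULT_ION_NAMES = frozenset(ION_CHARGES)


class StructureError(ValueError):
    """Raised for unreadable, empty or inconsistent structure input."""


@dataclass
class Atom:
    serial: int
    name: str
    element: str
    res_name: str
    chain_id: str
    res_seq: int
    insertion_code: str
    xyz: np.ndarray
    occupancy: float = 1.0
    altloc: str = ""
    bfactor_slot: float = 0.0
    hetero: bool = False

    def residue_key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.res_seq, self.insertion_code)


@dataclass
class Structure:
    atoms: list[Atom] = field(default_factory=list)
    source_id: str = ""
    removed_ions: list[tuple[str, str, int]] = field(default_factory=list)

    @property
    def chains(self) -> set[str]:
        return {a.chain_id for a in self.atoms}

    def coords(self) -> np.ndarray:
        return np.array([a.xyz for a in self.atoms], dtype=float).reshape(-1, 3)

    def residues(self) -> dict[tuple[str, int, str], list[Atom]]:
        """Atoms grouped by (chain, res_seq, insertion_code), input order."""
        out: dict[tuple[str, int, str], list[Atom]] = {}
        for a in self.atoms:
            out.setdefault(a.residue_key(), []).append(a)
        return out

    def copy(self) -> "Structure":
        return Structure(
            atoms=[replace(a, xyz=a.xyz.copy()) for a in self.atoms],
            source_id=self.source_id,
            removed_ions=list(self.removed_ions),
        )


@dataclass(frozen=True)
class IonizableSite:
    """One titratable sidechain treated as a two-state (neutral/ionised) unit."""

    chain_id: str
    res_seq: int
    insertion_code: str
    res_name: str
    model_pka: float
    gamma: int
    charge_atoms: tuple[tuple[str, float], ...]
    charge_xyz: np.ndarray  # (n_charge_atoms, 3), order matches charge_atoms
    label: str

    @property
    def charges(self) -> np.ndarray:
        return np.array([q for _, q in self.charge_atoms])

    @property
    def centroid(self) -> np.ndarray:
        return self.charge_xyz.mean(axis=0)

    def residue_key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.res_seq, self.insertion_code)


def site_label(res_name: str, res_seq: int, chain_id: str, icode: str = "") -> str:
    one = ONE_LETTER.get(res_name, res_name)
    return f"{one}{res_seq}{icode.strip()}:{chain_id}"


# ---------------------------------------------------------------------------
# reading


def read_structure(path, format_hint: str = "auto") -> Structure:
    """Load a PDB or mmCIF file into a :class:`Structure`.

    Altloc duplicates are resolved to the highest-occupancy conformer
    (ties broken by file order); all other records are kept verbatim.
    """
    path = str(path)
    try:
        if format_hint == "pdb":
            st = gemmi.read_pdb(path)
        elif format_hint == "mmcif":
            st = gemmi.read_structure(path, format=gemmi.CoorFormat.Mmcif)
        else:
            st = gemmi.read_structure(path, format=gemmi.CoorFormat.Detect)
    except (RuntimeError, ValueError, FileNotFoundError) as exc:
        raise StructureError(f"cannot parse structure file {path!r}: {exc}") from exc

    if len(st) == 0:
        raise StructureError(f"no models in {path!r}")
    model = st[0]

    atoms: list[Atom] = []
    serial = 0
    for chain in model:
        for res in chain:
            hetero = res.het_flag == "H"
            # resolve altlocs: best occupancy per atom name, tie -> first seen
            best: dict[str, gemmi.Atom] = {}
            order: list[str] = []
            for at in res:
                prev = best.get(at.name)
                if prev is None:
                    best[at.name] = at
                    order.append(at.name)
                elif at.occ > prev.occ:
                    best[at.name] = at
            for name in order:
                at = best[name]
                serial += 1
                altloc = at.altloc if at.altloc not in ("", "\x00") else ""
                atoms.append(
                    Atom(
                        serial=serial,
                        name=at.name,
                        element=at.element.name.upper(),
                        res_name=res.name.strip(),
                        chain_id=chain.name,
                        res_seq=res.seqid.num,
                        insertion_code=(res.seqid.icode or "").strip(),
                        xyz=np.array([at.pos.x, at.pos.y, at.pos.z]),
                        occupancy=float(at.occ),
                        altloc=altloc.strip(),
                        bfactor_slot=float(at.b_iso),
                        hetero=hetero,
                    )
                )
    if not atoms:
        raise StructureError(f"empty structure: no ATOM/HETATM records in {path!r}")
    return Structure(atoms=atoms, source_id=st.name or path)


# ---------------------------------------------------------------------------
# normalisation


def strip_ions(structure: Structure, ion_names=DEFAULT_ION_NAMES) -> Structure:
    """Remove matching HETATM residues, logging them in ``removed_ions``.

    Protein (ATOM) records are never touched; pass ``"HOH"`` in
    ``ion_names`` to drop crystallographic waters as well.
    """
    if not ion_names:
        raise ValueError("ion_names must be non-empty")
    ion_names = {n.upper() for n in ion_names}
    out = structure.copy()
    kept: list[Atom] = []
    for a in out.atoms:
        if a.hetero and a.res_name.upper() in ion_names:
            if a.res_name.upper() != "HOH":
                out.removed_ions.append((a.element, a.chain_id, a.res_seq))
        else:
            kept.append(a)
    out.atoms = kept
    return out


def retained_ion_charges(structure: Structure) -> list[tuple[float, np.ndarray]]:
    """Formal charges of HETATM ions still present (background charges)."""
    out = []
    for a in structure.atoms:
        if a.hetero and a.res_name.upper() in ION_CHARGES:
            out.append((ION_CHARGES[a.res_name.upper()], a.xyz))
    return out


# ---------------------------------------------------------------------------
# site selection


def _build_site(res_name, key, atoms) -> IonizableSite | None:
    """Assemble a site from residue atoms; None if charge atoms are missing."""
    chain_id, res_seq, icode = key
    spec = CHARGE_ATOMS[res_name]
    by_name = {a.name: a for a in atoms}
    try:
        xyz = np.array([by_name[n].xyz for n, _ in spec])
    except KeyError:
        return None
    return IonizableSite(
        chain_id=chain_id,
        res_seq=res_seq,
        insertion_code=icode,
        res_name=res_name,
        model_pka=MODEL_PKA[res_name],
        gamma=GAMMA[res_name],
        charge_atoms=tuple(spec),
        charge_xyz=xyz,
        label=site_label(res_name, res_seq, chain_id, icode),
    )


def resolve_centre(structure: Structure, centre) -> np.ndarray:
    """Turn a centre spec (3-vector or ``"chain:res_seq"`` label) into a point."""
    if not isinstance(centre, str):
        pt = np.asarray(centre, dtype=float)
        if pt.shape != (3,):
            raise ValueError(f"centre vector must be length 3, got {pt.shape}")
        return pt
    try:
        chain, seq = centre.split(":")
        seq_num = int(seq)
    except ValueError as exc:
        raise ValueError(f"centre label {centre!r} is not 'chain:res_seq'") from exc
    residues = structure.residues()
    for (ch, num, _icode), atoms in residues.items():
        if ch == chain and num == seq_num:
            res_name = atoms[0].res_name
            if res_name in CHARGE_ATOMS:
                site = _build_site(res_name, (ch, num, _icode), atoms)
                if site is not None:
                    return site.centroid
            return np.mean([a.xyz for a in atoms], axis=0)
    valid = sorted({f"{ch}:{num}" for (ch, num, _ic) in residues})
    raise ValueError(
        f"centre {centre!r} not found; valid labels include "
        f"{', '.join(valid[:20])}{' ...' if len(valid) > 20 else ''}"
    )


def select_sites(
    structure: Structure, centres, radius: float
) -> tuple[list[IonizableSite], list[str]]:
    """All Asp/Glu/His/Lys/Arg whose charge centroid lies within ``radius``
    of any centre (union of spheres).

    Returns ``(sites, disordered)`` where ``disordered`` lists residues in
    range whose charge-bearing atoms are missing from the model; these are
    excluded from the calculation but must be reported, since missing
    density is itself a structural signal.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    pts = np.array([resolve_centre(structure, c) for c in centres], dtype=float)
    if pts.size == 0:
        raise ValueError("at least one centre required")

    sites: list[IonizableSite] = []
    disordered: list[str] = []
    for key, atoms in structure.residues().items():
        res_name = atoms[0].res_name
        if res_name not in CHARGE_ATOMS or atoms[0].hetero:
            continue
        site = _build_site(res_name, key, atoms)
        if site is not None:
            probe = site.centroid
        else:
            probe = np.mean([a.xyz for a in atoms], axis=0)
        dist = np.min(np.linalg.norm(pts - probe, axis=1))
        if dist <= radius:
            if site is None:
                disordered.append(site_label(res_name, key[1], key[0], key[2]))
            else:
                sites.append(site)
    return sites, disordered


# ---------------------------------------------------------------------------
# writing


def _format_atom_name(name: str, element: str) -> str:
    # columns 13-16; 1-2 letter elements start at col 14 unless 4 chars
    if len(name) >= 4:
        return name[:4]
    if len(element) == 1:
        return f" {name:<3s}"
    return f"{name:<4s}"


def _pdb_line(a: Atom, serial: int, bfactor: float) -> str:
    record = "HETATM" if a.hetero else "ATOM  "
    name = _format_atom_name(a.name, a.element)
    icode = (a.insertion_code or " ")[:1]
    x, y, z = a.xyz
    return (
        f"{record}{serial:5d} {name}{(a.altloc or ' ')[:1]}"
        f"{a.res_name:>3s} {a.chain_id[:1]}{a.res_seq:4d}{icode}   "
        f"{x:8.3f}{y:8.3f}{z:8.3f}{a.occupancy:6.2f}{bfactor:6.2f}"
        f"          {a.element:>2s}"
    )


def write_pdb(structure: Structure, path) -> None:
    """Write the structure as fixed-column PDB, B-factors from bfactor_slot."""
    lines = []
    serial = 0
    prev_chain = None
    for a in structure.atoms:
        if prev_chain is not None and a.chain_id != prev_chain and not a.hetero:
            lines.append("TER")
        prev_chain = a.chain_id
        serial += 1
        lines.append(_pdb_line(a, serial, a.bfactor_slot))
    lines.append("END")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def write_annotated(structure: Structure, scores: dict[str, float], path) -> None:
    """Write a PDB whose B-factor column carries scaled frustration scores.

    ``scores`` maps site labels (``"D301:A"``) to scaled values in
    [-50, 50]; every atom of a scored residue carries the residue score,
    all other atoms carry 0.00.
    """
    for label, s in scores.items():
        if not (-50.0 <= s <= 50.0) or not math.isfinite(s):
            raise ValueError(f"score for {label} out of range [-50, 50]: {s}")
    by_key: dict[tuple[str, int, str], float] = {}
    for key, atoms in structure.residues().items():
        res_name = atoms[0].res_name
        label = site_label(res_name, key[1], key[0], key[2])
        if label in scores:
            by_key[key] = scores[label]
    missing = set(scores) - {
        site_label(ats[0].res_name, k[1], k[0], k[2])
        for k, ats in structure.residues().items()
    }
    if missing:
        raise ValueError(f"scored residues not in structure: {sorted(missing)}")
    out = structure.copy()
    for a in out.atoms:
        a.bfactor_slot = by_key.get(a.residue_key(), 0.0)
    write_pdb(out, path)
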