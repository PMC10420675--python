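"""Structure reading, normalisation, site selection and annotated output."""

import numpy as np
import pytest

from pkafrust.structure_io import (
    StructureError,
    read_structure,
    select_sites,
    strip_ions,
    write_annotated,
    write_pdb,
)
from pkafrust.synthetic import make_charge_pair, make_clasp, make_model_compound

ALTLOC_PDB = """\
ATOM      1  N   ASP A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA AASP A   1       1.458   0.000   0.000  0.60  0.00           C
ATOM      3  CA BASP A   1       1.500   0.100   0.000  0.40  0.00           C
END
"""


def _keyed(structure, ndigits=3):
    return {
        (a.chain_id, a.res_seq, a.insertion_code, a.name): tuple(
            np.round(a.xyz, ndigits)
        )
        for a in structure.atoms
    }


def test_round_trip_preserves_atoms_and_coordinates(tmp_path):
    holo, _ = make_clasp()
    p = tmp_path / "clasp.pdb"
    write_pdb(holo, p)
    back = read_structure(p, format_hint="pdb")
    assert _keyed(back) == _keyed(holo)
    # second round trip is exact at format precision
    p2 = tmp_path / "clasp2.pdb"
    write_pdb(back, p2)
    assert _keyed(read_structure(p2)) == _keyed(back)


def test_model_compound_round_trip_atom_set(tmp_path):
    st = make_model_compound("ASP")
    p = tmp_path / "asp.pdb"
    write_pdb(st, p)
    back = read_structure(p)
    assert {a.name for a in back.atoms} == {
        "N", "CA", "C", "O", "CB", "CG", "OD1", "OD2",
    }
    assert back.chains == {"A"}


def test_altloc_resolved_to_highest_occupancy(tmp_path):
    p = tmp_path / "alt.pdb"
    p.write_text(ALTLOC_PDB)
    st = read_structure(p)
    ca = [a for a in st.atoms if a.name == "CA"]
    assert len(ca) == 1
    assert ca[0].altloc == "A"
    assert ca[0].occupancy == pytest.approx(0.6)
    assert ca[0].xyz[0] == pytest.approx(1.458)


def test_unreadable_and_empty_files_raise(tmp_path):
    bad = tmp_path / "bad.pdb"
    bad.write_text("not a structure\n")
    with pytest.raises(StructureError):
        read_structure(bad, format_hint="pdb")
    with pytest.raises(StructureError):
        read_structure(tmp_path / "absent.pdb")


def test_strip_ions_logs_and_is_idempotent():
    holo, apo = make_clasp(ion=True)
    stripped = strip_ions(holo, {"CA"})
    assert stripped.removed_ions == [("CA", "A", 401)]
    assert not any(a.res_name == "CA" for a in stripped.atoms)
    # protein atoms untouched
    n_protein = sum(1 for a in holo.atoms if not a.hetero)
    assert sum(1 for a in stripped.atoms if not a.hetero) == n_protein
    again = strip_ions(stripped, {"CA"})
    assert again.removed_ions == stripped.removed_ions
    assert len(again.atoms) == len(stripped.atoms)
    # apo has no ion: identity, empty log
    apo_stripped = strip_ions(apo, {"CA"})
    assert apo_stripped.removed_ions == []
    assert len(apo_stripped.atoms) == len(apo.atoms)


def test_select_sites_union_and_monotonicity():
    st = make_model_compound("ASP")
    sites, dis = select_sites(st, ["A:1"], 10.0)
    assert [s.label for s in sites] == ["D1:A"] and dis == []
    # two overlapping spheres still list the residue once
    sites2, _ = select_sites(st, ["A:1", (0.0, 0.0, 2.0)], 10.0)
    assert len(sites2) == 1
    # monotone in radius
    pair = make_charge_pair("ASP", "LYS", 20.0)
    small, _ = select_sites(pair, ["A:1"], 5.0)
    large, _ = select_sites(pair, ["A:1"], 25.0)
    assert {s.label for s in small} <= {s.label for s in large}
    assert [s.label for s in small] == ["D1:A"]
    assert {s.label for s in large} == {"D1:A", "K2:A"}


def test_select_sites_counts_bounded_by_titratable_residues():
    holo, _ = make_clasp(n_acids=4)
    sites, _ = select_sites(holo, [(0.0, 0.0, 0.0)], 50.0)
    assert len(sites) == 4  # shell pseudo-residues are never sites


def test_select_sites_unresolvable_centre_lists_valid_labels():
    st = make_model_compound("GLU")
    with pytest.raises(ValueError, match="A:1"):
        select_sites(st, ["B:99"], 10.0)


def test_disordered_site_reported_not_silently_dropped():
    st = make_model_compound("ASP")
    st.atoms = [a for a in st.atoms if a.name != "OD2"]  # lost density
    sites, dis = select_sites(st, [(0.0, 0.0, 0.0)], 30.0)
    assert sites == []
    assert dis == ["D1:A"]


def test_write_annotated_bfactor_column(tmp_path):
    holo, _ = make_clasp()
    stripped = strip_ions(holo, {"CA"})
    p = tmp_path / "annot.pdb"
    write_annotated(stripped, {"D301:A": -40.0}, p)
    scored = [
        line
        for line in p.read_text().splitlines()
        if line.startswith("ATOM") and line[21] == "A" and int(line[22:26]) == 301
    ]
    assert scored and all(line[60:66] == "-40.00" for line in scored)
    back = read_structure(p)
    assert {a.bfactor_slot for a in back.atoms if a.chain_id == "A" and a.res_seq == 301} == {-40.0}
    others = {
        a.bfactor_slot
        for a in back.atoms
        if not (a.chain_id == "A" and a.res_seq == 301)
    }
    assert others == {0.0}


def test_write_annotated_rejects_out_of_range_scores(tmp_path):
    st = make_model_compound("ASP")
    with pytest.raises(ValueError):
        write_annotated(st, {"D1:A": 51.0}, tmp_path / "x.pdb")
    with pytest.raises(ValueError):
        write_annotated(st, {"Z9:A": 10.0}, tmp_path / "x.pdb")


def test_write_annotated_empty_map_zeroes_all(tmp_path):
    st = make_model_compound("HIS")
    p = tmp_path / "zero.pdb"
    write_annotated(st, {}, p)
    back = read_structure(p)
    assert {a.bfactor_slot for a in back.atoms} == {0.0}
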