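"""FDPB solver against analytic oracles, and the site energy terms."""

import numpy as np
import pytest

from pkafrust.electrostatics import (
    GridConfig,
    GridSpec,
    PhysicsConfig,
    dh_energy,
    pair_energy_from_maps,
    parameterize,
    site_self_energy,
    solve_fdpb,
)
from pkafrust.structure_io import select_sites
from pkafrust.synthetic import make_buried_site, make_charge_pair

ORIGIN = np.array([[0.0, 0.0, 0.0]])
UNIT = np.array([1.0])


@pytest.fixture(scope="module")
def uniform_maps():
    """One +1 charge in pure solvent: salt-free and physiological salt."""
    grid = GridSpec((0.0, 0.0, 0.0), 40.0, 0.6)
    salt_free = solve_fdpb(ORIGIN, UNIT, grid, PhysicsConfig(ionic_strength=0.0))
    salty = solve_fdpb(ORIGIN, UNIT, grid, PhysicsConfig())
    return salt_free, salty


def _radial_points(lo=5.0, hi=15.0, step=0.5):
    r = np.arange(lo, hi + 1e-9, step)
    return r, np.stack([r, np.zeros_like(r), np.zeros_like(r)], axis=1)


def test_kappa_matches_debye_length_formula():
    assert PhysicsConfig().kappa == pytest.approx(0.127, abs=5e-4)
    assert PhysicsConfig(ionic_strength=0.0).kappa == 0.0


def test_dh_energy_closed_form_and_symmetries():
    salt_free = PhysicsConfig(ionic_strength=0.0)
    assert dh_energy(1, 1, 10.0, salt_free) == pytest.approx(0.4236, abs=5e-5)
    assert dh_energy(0.0, 1.0, 7.0, salt_free) == 0.0
    phys = PhysicsConfig()
    assert dh_energy(1, -1, 6.0, phys) == pytest.approx(-dh_energy(1, 1, 6.0, phys))
    with pytest.raises(ValueError):
        dh_energy(1, 1, 0.0, phys)


def test_uniform_solvent_fdpb_matches_coulomb(uniform_maps):
    salt_free, _ = uniform_maps
    r, pts = _radial_points()
    analytic = 332.064 / (78.4 * r)
    assert np.max(np.abs(salt_free.at(pts) / analytic - 1.0)) < 0.05


def test_uniform_solvent_fdpb_matches_screened_coulomb(uniform_maps):
    _, salty = uniform_maps
    phys = PhysicsConfig()
    r, pts = _radial_points()
    analytic = 332.064 * np.exp(-phys.kappa * r) / (78.4 * r)
    assert np.max(np.abs(salty.at(pts) / analytic - 1.0)) < 0.05


def test_zero_charge_gives_zero_potential():
    grid = GridSpec((0.0, 0.0, 0.0), 20.0, 1.0)
    m = solve_fdpb(ORIGIN, np.array([0.0]), grid, PhysicsConfig())
    assert np.all(m.phi == 0.0)


def test_potential_linear_in_source_charge():
    grid = GridSpec((0.0, 0.0, 0.0), 24.0, 0.8)
    phys = PhysicsConfig()
    m1 = solve_fdpb(ORIGIN, np.array([1.0]), grid, phys)
    m2 = solve_fdpb(ORIGIN, np.array([2.0]), grid, phys)
    assert np.allclose(m2.phi, 2.0 * m1.phi, rtol=1e-6, atol=1e-8)


def test_parameterize_charge_assignments(model_reports):
    for rt, q_expected in (("ASP", -1.0), ("ARG", 1.0), ("HIS", 1.0)):
        rep = model_reports[rt]
        st = rep.structure
        sites, _ = select_sites(st, [st.atoms[0].xyz], 20.0)
        xyz, q = parameterize(st, sites[0], "ionised")
        assert q.sum() == pytest.approx(q_expected, abs=1e-6)
        _, q0 = parameterize(st, sites[0], "neutral")
        assert np.all(q0 == 0.0)
    with pytest.raises(ValueError, match="state"):
        parameterize(st, sites[0], "half")


def test_parameterize_missing_charge_atom_is_disordered_error(model_reports):
    st = model_reports["ASP"].structure.copy()
    sites, _ = select_sites(st, [(0.0, 0.0, 0.0)], 30.0)
    st.atoms = [a for a in st.atoms if a.name != "OD1"]
    with pytest.raises(ValueError, match="disordered"):
        parameterize(st, sites[0], "ionised")


def test_exposed_model_compound_has_no_self_energy(model_reports):
    for rt in ("ASP", "LYS"):
        rec = model_reports[rt].records[0]
        assert abs(rec.dG_desolv) < 0.4
        assert abs(rec.dG_back) < 1e-9


def test_desolvation_nonnegative_and_monotone_in_burial(buried_sweep):
    d = {c: rep.records[0].dG_desolv for c, rep in buried_sweep.items()}
    assert d[0.0] > -0.2
    assert d[1.0] > 2.7  # beyond one Born pKa-unit-equivalent at least
    assert d[0.0] - 0.2 < d[0.5] < d[1.0]


def test_buried_asp_desolvation_between_exposed_and_born_limits(buried_sweep):
    # full burial must stay below the infinite-medium Born transfer bound
    born_full = 166.03 * (1.0 / 4.0 - 1.0 / 78.4) / 2.0  # 19.7 kcal/mol at a=2
    d_full = buried_sweep[1.0].records[0].dG_desolv
    assert 2.7 < d_full < 2.0 * born_full


def test_desolvation_stable_under_grid_refinement():
    """Halving the default spacing moves the desolvation penalty of a
    part-buried Asp by less than half a pKa unit (0.7 kcal/mol)."""
    st = make_buried_site("ASP", shell_radius=6.0, completeness=0.5)
    phys = PhysicsConfig()
    sites, _ = select_sites(st, ["A:1"], 5.0)
    default = site_self_energy(
        sites[0], st, phys, GridConfig(fine_spacing=0.6, single_level_max=60.0)
    )
    halved = site_self_energy(
        sites[0], st, phys, GridConfig(fine_spacing=0.3, single_level_max=60.0)
    )
    assert abs(halved.terms.dG_desolv - default.terms.dG_desolv) < 0.7


@pytest.fixture(scope="module")
def asp_pair_solutions():
    phys = PhysicsConfig()
    st = make_charge_pair("ASP", "ASP", 5.0)
    sites, _ = select_sites(st, ["A:1", "A:2"], 10.0)
    return st, [site_self_energy(s, st, phys) for s in sites], phys


def test_like_charge_pair_repulsive_near_dh_oracle(asp_pair_solutions):
    _, sols, phys = asp_pair_solutions
    w = pair_energy_from_maps(sols[0], sols[1], phys)
    oracle = dh_energy(-1.0, -1.0, 5.0, phys)
    assert w > 0
    assert abs(w - oracle) / oracle < 0.30  # reaction-field correction allowed


def test_pair_reciprocity(asp_pair_solutions):
    _, sols, phys = asp_pair_solutions
    w_ij = float(np.dot(sols[1].site.charges, sols[0].protein_map.at(sols[1].site.charge_xyz)))
    w_ji = float(np.dot(sols[0].site.charges, sols[1].protein_map.at(sols[0].site.charge_xyz)))
    assert abs(w_ij - w_ji) < 0.05


def test_opposite_charge_pair_attractive():
    phys = PhysicsConfig()
    st = make_charge_pair("ASP", "LYS", 5.0)
    sites, _ = select_sites(st, ["A:1", "A:2"], 10.0)
    sols = [site_self_energy(s, st, phys) for s in sites]
    assert pair_energy_from_maps(sols[0], sols[1], phys) < 0


def test_distant_pair_uses_dh_and_decays_to_zero():
    phys = PhysicsConfig()
    st = make_charge_pair("ASP", "ASP", 30.0)
    sites, _ = select_sites(st, ["A:1", "A:2"], 40.0)
    sols = [site_self_energy(s, st, phys) for s in sites]
    w = pair_energy_from_maps(sols[0], sols[1], phys)
    assert w == pytest.approx(dh_energy(-1.0, -1.0, 30.0, phys))
    assert abs(w) / phys.kt_log10 < 0.05
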