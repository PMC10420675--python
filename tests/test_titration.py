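"""Intrinsic pKas, the multi-site partition function, and pKa-half reading."""

import numpy as np
import pytest

from pkafrust.electrostatics import EnergyTerms, PhysicsConfig
from pkafrust.structure_io import select_sites
from pkafrust.synthetic import make_model_compound
from pkafrust.titration import (
    DEFAULT_PH_GRID,
    IntrinsicPka,
    PkaValue,
    TitrationResult,
    capped_delta,
    delta_pka,
    intrinsic_pka,
    pka_half,
    titrate,
)

PHYS = PhysicsConfig()


def _site(restype):
    st = make_model_compound(restype)
    sites, _ = select_sites(st, [f"A:1"], 10.0)
    return sites[0]


def _intr(label, pka, gamma=-1, model=None):
    return IntrinsicPka(label, "ASP" if gamma < 0 else "HIS", gamma,
                        model if model is not None else pka, pka)


def test_intrinsic_pka_reference_and_shift_signs():
    asp = _site("ASP")
    assert intrinsic_pka(asp, EnergyTerms(0.0, 0.0), PHYS).pka_intr == 4.0
    # +1.364 kcal/mol is one pKa unit: up for acids, down for bases
    up = intrinsic_pka(asp, EnergyTerms(1.3642470130342401, 0.0), PHYS)
    assert up.pka_intr == pytest.approx(5.0, abs=1e-6)
    his = _site("HIS")
    down = intrinsic_pka(his, EnergyTerms(1.3642470130342401, 0.0), PHYS)
    assert down.pka_intr == pytest.approx(5.3, abs=1e-6)


def test_single_site_matches_henderson_hasselbalch():
    res = titrate([_intr("D1:A", 4.0)], np.zeros((1, 1)))
    hh = 1.0 / (1.0 + 10.0 ** (DEFAULT_PH_GRID - 4.0))
    assert np.max(np.abs(res.theta[:, 0] - hh)) < 1e-6
    assert res.theta_at("D1:A", 4.0) == pytest.approx(0.5, abs=1e-6)
    assert res.theta_at("D1:A", 2.0) == pytest.approx(0.990, abs=1e-3)
    # base: protonated fraction still decreases with pH
    resb = titrate([_intr("H1:A", 6.3, gamma=+1)], np.zeros((1, 1)))
    hhb = 1.0 / (1.0 + 10.0 ** (DEFAULT_PH_GRID - 6.3))
    assert np.max(np.abs(resb.theta[:, 0] - hhb)) < 1e-6


def test_noninteracting_sites_titrate_independently():
    intr = [_intr("D1:A", 5.0), _intr("D2:A", 5.0)]
    res = titrate(intr, np.zeros((2, 2)))
    for label in ("D1:A", "D2:A"):
        assert pka_half(res, label).value == pytest.approx(5.0, abs=1e-6)


def test_repulsive_coupling_is_anticooperative():
    intr = [_intr("D1:A", 4.0), _intr("D2:A", 4.0)]
    base = titrate(intr, np.zeros((2, 2)))
    coupled = titrate(intr, np.array([[0.0, 2.0], [2.0, 0.0]]))
    for label in ("D1:A", "D2:A"):
        assert pka_half(coupled, label).value > pka_half(base, label).value + 0.5


def test_monte_carlo_agrees_with_enumeration():
    intr = [_intr("D1:A", 4.0), _intr("D2:A", 4.0)]
    W = np.array([[0.0, 2.0], [2.0, 0.0]])
    exact = titrate(intr, W, method="enumeration")
    mc = titrate(intr, W, method="monte_carlo", seed=42)
    assert np.max(np.abs(exact.theta - mc.theta)) < 0.02


def test_monte_carlo_is_seed_reproducible():
    intr = [_intr("D1:A", 4.5), _intr("H2:A", 6.0, gamma=+1)]
    W = np.array([[0.0, -1.0], [-1.0, 0.0]])
    a = titrate(intr, W, method="monte_carlo", seed=7)
    b = titrate(intr, W, method="monte_carlo", seed=7)
    assert np.array_equal(a.theta, b.theta)


def test_fixed_positive_charge_lowers_carboxylate_pka(model_reports):
    """A +2 ion near a carboxylate stabilises the anion (calcium competition
    run in reverse): its computed pKa must drop below the reference."""
    from pkafrust import AnalysisConfig, run_site_analysis
    from pkafrust.structure_io import Atom, site_label

    st = model_reports["ASP"].structure.copy()
    sites, _ = select_sites(st, ["A:1"], 10.0)
    spot = sites[0].centroid + np.array([0.0, 0.0, 4.0])
    st.atoms.append(
        Atom(serial=99, name="CA", element="CA", res_name="CA", chain_id="A",
             res_seq=90, insertion_code="", xyz=spot, hetero=True)
    )
    cfg = AnalysisConfig(strip_ion_names=frozenset({"HOH"}))  # keep the ion
    rep = run_site_analysis(st, centres=["A:1"], radius=10.0, config=cfg)
    assert rep.records[0].pka_half.value < 4.0 - 0.5
    assert rep.records[0].dG_back < 0


def test_enumeration_refused_above_hard_cap():
    intr = [_intr(f"D{i}:A", 4.0) for i in range(26)]
    with pytest.raises(ValueError, match="enumeration refused"):
        titrate(intr, np.zeros((26, 26)), method="enumeration")


def test_pka_half_bounds_at_grid_edges():
    high = titrate([_intr("D1:A", 16.0, model=4.0)], np.zeros((1, 1)))
    hb = pka_half(high, "D1:A")
    assert hb.bound == ">" and hb.value == 14.0
    assert str(hb) == "> 14"
    low = titrate([_intr("D1:A", -3.0, model=4.0)], np.zeros((1, 1)))
    lb = pka_half(low, "D1:A")
    assert lb.bound == "<" and lb.value == 0.0


def test_delta_pka_and_display_cap():
    res = titrate([_intr("D1:A", 10.3, model=4.0)], np.zeros((1, 1)))
    d = delta_pka(res, "D1:A")
    assert d.value == pytest.approx(6.3, abs=0.05)
    display, capped = capped_delta(d)
    assert display == 5.0 and capped
    # the displayed pKa becomes the bound "model + 5"
    assert res.pka_model[0] + display == pytest.approx(9.0)


def test_nonmonotone_curve_beyond_noise_raises():
    theta = np.linspace(1.0, 0.0, len(DEFAULT_PH_GRID)).reshape(-1, 1)
    theta[30, 0] = theta[29, 0] + 0.2  # corrupt the curve
    res = TitrationResult(
        labels=["D1:A"], gammas=np.array([-1]), pka_model=np.array([4.0]),
        ph_grid=DEFAULT_PH_GRID, theta=theta, method="monte_carlo",
        noise_tol=0.02,
    )
    with pytest.raises(ValueError, match="non-monotone"):
        pka_half(res, "D1:A")


def test_asymmetric_interaction_matrix_rejected():
    intr = [_intr("D1:A", 4.0), _intr("D2:A", 4.0)]
    with pytest.raises(ValueError, match="symmetric"):
        titrate(intr, np.array([[0.0, 1.0], [0.0, 0.0]]))
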