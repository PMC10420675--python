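"""Shared fixtures: synthetic structures and their pipeline results.

The expensive FDPB-backed pipeline runs are session-scoped so the whole
suite pays for each grid solve once.
"""

import numpy as np
import pytest

from pkafrust import (
    AnalysisConfig,
    PhysicsConfig,
    make_buried_site,
    make_clasp,
    make_model_compound,
    run_site_analysis,
)

RESTYPES = ["ASP", "GLU", "HIS", "LYS", "ARG"]


@pytest.fixture(scope="session")
def physics():
    return PhysicsConfig()


@pytest.fixture(scope="session")
def physics_salt_free():
    return PhysicsConfig(ionic_strength=0.0)


@pytest.fixture(scope="session")
def model_reports():
    """Full-pipeline reports for the five exposed model compounds."""
    out = {}
    for rt in RESTYPES:
        st = make_model_compound(rt)
        out[rt] = run_site_analysis(st, centres=["A:1"], radius=10.0)
    return out


@pytest.fixture(scope="session")
def clasp_structures():
    return make_clasp()


@pytest.fixture(scope="session")
def clasp_reports(clasp_structures):
    holo, apo = clasp_structures
    centres = [f"A:{seq}" for seq in range(301, 305)]
    holo_rep = run_site_analysis(holo, centres=centres, radius=12.0)
    apo_rep = run_site_analysis(apo, centres=centres, radius=12.0)
    return holo_rep, apo_rep


@pytest.fixture(scope="session")
def buried_sweep():
    """Desolvation sweep of an Asp in shells of growing completeness."""
    out = {}
    for comp in (0.0, 0.5, 1.0):
        st = make_buried_site("ASP", shell_radius=12.0, completeness=comp)
        out[comp] = run_site_analysis(st, centres=["A:1"], radius=10.0)
    return out
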