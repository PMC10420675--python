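"""End-to-end analysis: single-structure frustration screening and the
two-arm holo/apo comparison that yields a proton/calcium-coupling verdict.

The chain for each structure is: read -> strip ions (metals are always
removed before the pKa calculation, so holo and apo conformations are
compared on equal footing) -> select ionisable sites around the chosen
centres -> FDPB self energies and coupling matrix -> multi-site titration
-> ΔpKa and frustration scores.  The comparison arm pairs sites by residue
label and asks whether the apo conformation still carries destabilising
shifts large enough to couple calcium binding to pH.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import structure_io
from .electrostatics import GridConfig, PhysicsConfig, site_self_energy
from .frustration import ACID, BASE, FrustrationScore, stabilization_score
from .structure_io import DEFAULT_ION_NAMES, Structure, read_structure, strip_ions
from .titration import (
    IntrinsicPka,
    PkaValue,
    TitrationResult,
    delta_pka,
    interaction_matrix_from_solutions,
    intrinsic_pka,
    pka_half,
    titrate,
)

#: smallest destabilising ΔpKa treated as functionally meaningful
DEFAULT_COUPLING_THRESHOLD = 1.5
DEFAULT_RADIUS = 15.0


@dataclass
class AnalysisConfig:
    physics: PhysicsConfig = field(default_factory=PhysicsConfig)
    grid: GridConfig = field(default_factory=GridConfig)
    # metals stripped before every pKa calculation; waters are represented
    # by the continuum and stripped too
    strip_ion_names: frozenset = frozenset(DEFAULT_ION_NAMES | {"HOH"})
    radius: float = DEFAULT_RADIUS
    method: str = "auto"
    seed: int = 42
    ph_grid: np.ndarray | None = None
    crossover: float = 12.0
    coupling_threshold: float = DEFAULT_COUPLING_THRESHOLD


@dataclass
class SiteRecord:
    label: str
    res_name: str
    residue_class: str
    pka_model: float
    dG_desolv: float
    dG_back: float
    pka_intr: float
    pka_half: PkaValue
    delta_pka: PkaValue
    score: FrustrationScore

    @property
    def destabilising(self) -> float:
        """Destabilising ΔpKa magnitude: positive shift for acids, negative
        for bases, floored at zero."""
        sign = 1.0 if self.residue_class == ACID else -1.0
        return max(0.0, sign * self.delta_pka.value)


@dataclass
class SiteReport:
    source_id: str
    records: list[SiteRecord]
    disordered_sites: list[str]
    titration: TitrationResult | None
    W: np.ndarray | None
    structure: Structure | None = None

    def record(self, label: str) -> SiteRecord:
        for r in self.records:
            if r.label == label:
                return r
        raise KeyError(f"no site {label!r} in report for {self.source_id}")

    def labels(self) -> list[str]:
        return [r.label for r in self.records]

    def scores(self) -> dict[str, float]:
        return {r.label: r.score.scaled for r in self.records}

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "site": r.label,
                "res_name": r.res_name,
                "class": r.residue_class,
                "pka_model": r.pka_model,
                "dG_desolv": r.dG_desolv,
                "dG_back": r.dG_back,
                "pka_intr": r.pka_intr,
                "pka_half": str(r.pka_half),
                "delta_pka_raw": r.delta_pka.value,
                "delta_pka_capped": r.score.delta_capped,
                "scaled": r.score.scaled,
                "category": r.score.category,
            }
            for r in self.records
        ]
        rows += [
            {
                "site": lbl,
                "res_name": "",
                "class": "",
                "pka_model": np.nan,
                "dG_desolv": np.nan,
                "dG_back": np.nan,
                "pka_intr": np.nan,
                "pka_half": "",
                "delta_pka_raw": np.nan,
                "delta_pka_capped": np.nan,
                "scaled": np.nan,
                "category": "disordered",
            }
            for lbl in self.disordered_sites
        ]
        columns = [
            "site", "res_name", "class", "pka_model", "dG_desolv", "dG_back",
            "pka_intr", "pka_half", "delta_pka_raw", "delta_pka_capped",
            "scaled", "category",
        ]
        return pd.DataFrame(rows, columns=columns)

    def titration_frame(self) -> pd.DataFrame:
        if self.titration is None:
            return pd.DataFrame(columns=["pH", "site", "theta"])
        t = self.titration
        rows = []
        for j, lbl in enumerate(t.labels):
            for k, ph in enumerate(t.ph_grid):
                rows.append({"pH": ph, "site": lbl, "theta": t.theta[k, j]})
        return pd.DataFrame(rows)


def run_site_analysis(
    structure, centres, radius: float | None = None, config: AnalysisConfig | None = None
) -> SiteReport:
    """Full per-structure analysis around the given centres.

    ``structure`` may be a path or a :class:`Structure`.  Deterministic for
    a fixed seed.  A sphere containing no ionisable residues yields an
    empty but valid report.
    """
    config = config or AnalysisConfig()
    radius = config.radius if radius is None else radius
    if not isinstance(structure, Structure):
        structure = read_structure(structure)
    stripped = strip_ions(structure, config.strip_ion_names)
    sites, disordered = structure_io.select_sites(stripped, centres, radius)
    if not sites:
        return SiteReport(stripped.source_id, [], disordered, None, None, stripped)

    sols = [site_self_energy(s, stripped, config.physics, config.grid) for s in sites]
    intr = [intrinsic_pka(s.site, s.terms, config.physics) for s in sols]
    W = interaction_matrix_from_solutions(sols, config.physics, config.crossover)
    result = titrate(
        intr, W, ph_grid=config.ph_grid, method=config.method, seed=config.seed
    )

    records = []
    for sol, ip in zip(sols, intr):
        half = pka_half(result, ip.label)
        delta = delta_pka(result, ip.label)
        cls = ACID if sol.site.gamma < 0 else BASE
        records.append(
            SiteRecord(
                label=ip.label,
                res_name=ip.res_name,
                residue_class=cls,
                pka_model=ip.pka_model,
                dG_desolv=sol.terms.dG_desolv,
                dG_back=sol.terms.dG_back,
                pka_intr=ip.pka_intr,
                pka_half=half,
                delta_pka=delta,
                score=stabilization_score(delta, cls, label=ip.label),
            )
        )
    return SiteReport(stripped.source_id, records, disordered, result, W, stripped)


# ---------------------------------------------------------------------------
# holo/apo comparison


@dataclass
class PairedSite:
    label: str
    apo_label: str
    holo_delta: PkaValue
    apo_delta: PkaValue | None  # None when apo side is disordered/absent
    holo_destab: float
    apo_destab: float
    relaxation_delta: float

    @property
    def apo_disordered(self) -> bool:
        return self.apo_delta is None


@dataclass
class ComparisonReport:
    holo_id: str
    apo_id: str
    rows: list[PairedSite]
    threshold: float
    verdict: str
    mixed_flag: bool = False

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "site": r.label,
                    "apo_site": r.apo_label,
                    "holo_delta_pka": r.holo_delta.value,
                    "apo_delta_pka": np.nan if r.apo_disordered else r.apo_delta.value,
                    "apo_state": "disordered" if r.apo_disordered else "ordered",
                    "holo_destabilising": r.holo_destab,
                    "apo_destabilising": r.apo_destab,
                    "relaxation_delta": r.relaxation_delta,
                }
                for r in self.rows
            ]
        )


def compare_holo_apo(
    holo: SiteReport,
    apo: SiteReport,
    pairing: dict[str, str] | None = None,
    threshold: float = DEFAULT_COUPLING_THRESHOLD,
) -> ComparisonReport:
    """Pair holo sites with apo sites by residue label (or an explicit map
    for renumbered homologues) and quantify relaxation per residue.

    ``relaxation_delta`` is the destabilising ΔpKa lost on going from the
    holo to the apo conformation (apo contributes 0 when disordered).
    """
    pairing = pairing or {}
    apo_by_label = {r.label: r for r in apo.records}
    apo_missing = set(apo.disordered_sites)

    rows = []
    for hr in holo.records:
        apo_label = pairing.get(hr.label, hr.label)
        ar = apo_by_label.get(apo_label)
        if ar is not None:
            rows.append(
                PairedSite(
                    label=hr.label,
                    apo_label=apo_label,
                    holo_delta=hr.delta_pka,
                    apo_delta=ar.delta_pka,
                    holo_destab=hr.destabilising,
                    apo_destab=ar.destabilising,
                    relaxation_delta=hr.destabilising - ar.destabilising,
                )
            )
        else:
            # absent from the apo model: missing density, i.e. disordered
            rows.append(
                PairedSite(
                    label=hr.label,
                    apo_label=apo_label if apo_label in apo_missing else apo_label,
                    holo_delta=hr.delta_pka,
                    apo_delta=None,
                    holo_destab=hr.destabilising,
                    apo_destab=0.0,
                    relaxation_delta=hr.destabilising,
                )
            )
    if not rows:
        raise ValueError(
            "no holo sites to pair; check centres/radius or provide a pairing map"
        )
    verdict, mixed = _verdict(rows, threshold)
    return ComparisonReport(
        holo_id=holo.source_id,
        apo_id=apo.source_id,
        rows=rows,
        threshold=threshold,
        verdict=verdict,
        mixed_flag=mixed,
    )


def _verdict(rows: list[PairedSite], threshold: float) -> tuple[str, bool]:
    frustrated_holo = [r for r in rows if r.holo_destab >= threshold]
    retained = [r for r in rows if not r.apo_disordered and r.apo_destab >= threshold]
    if retained:
        relaxed = [
            r for r in frustrated_holo
            if not r.apo_disordered and r.apo_destab < threshold
        ]
        return "pH-coupled", bool(relaxed)
    if frustrated_holo and all(r.apo_disordered for r in frustrated_holo):
        return "decoupled-by-disorder", False
    if all(not r.apo_disordered for r in rows):
        return "decoupled-by-relaxation", False
    return "mixed", False


def coupling_verdict(cmp: ComparisonReport, threshold: float | None = None) -> str:
    """Re-evaluate the verdict, optionally at a different threshold.

    pH-coupled: some apo site retains a destabilising shift >= threshold.
    decoupled-by-disorder: every holo-frustrated site is disordered in apo.
    decoupled-by-relaxation: apo sites all ordered with shifts < threshold.
    """
    if threshold is None:
        return cmp.verdict
    verdict, _ = _verdict(cmp.rows, threshold)
    return verdict


# ---------------------------------------------------------------------------
# output


def write_report(report: SiteReport, prefix: str) -> list[str]:
    """Write <prefix>.report.tsv, <prefix>.titration.tsv and
    <prefix>.annotated.pdb; returns the paths written."""
    paths = []
    p = f"{prefix}.report.tsv"
    report.to_frame().to_csv(p, sep="\t", index=False, float_format="%.4f")
    paths.append(p)
    p = f"{prefix}.titration.tsv"
    report.titration_frame().to_csv(p, sep="\t", index=False, float_format="%.4f")
    paths.append(p)
    if report.structure is not None:
        p = f"{prefix}.annotated.pdb"
        structure_io.write_annotated(report.structure, report.scores(), p)
        paths.append(p)
    return paths


def write_comparison(cmp: ComparisonReport, prefix: str) -> str:
    p = f"{prefix}.compare.tsv"
    cmp.to_frame().to_csv(p, sep="\t", index=False, float_format="%.4f")
    return p
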