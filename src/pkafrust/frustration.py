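"""Sign-adjusted, scaled frustration scores and net-protonation bookkeeping.

ΔpKa values are mapped onto the dynamic range of the PDB B-factor column:
multiplied by 10, sign-adjusted so negative always means destabilisation
of the ionised form (acids flip sign, bases keep it), and clamped to
[-50, 50].  A destabilised acid (ΔpKa +4.0) therefore scores -40; a
destabilised base (ΔpKa -4.0) also scores -40.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .titration import DISPLAY_CAP, PkaValue, TitrationResult, capped_delta

SCALE = 10.0
CLAMP = 50.0
#: |scaled| above which a site is called (de)stabilised: 0.5 pKa units
CATEGORY_BAND = 5.0

ACID, BASE = "acid", "base"


@dataclass(frozen=True)
class FrustrationScore:
    label: str
    residue_class: str
    delta_pka: float  # raw (bounds carried as their capped value)
    delta_capped: float
    is_bound: bool
    scaled: float  # in [-50, 50]
    category: str  # destabilised / neutral / stabilised


def _class_sign(residue_class: str) -> float:
    if residue_class == ACID:
        return -1.0
    if residue_class == BASE:
        return +1.0
    raise ValueError(f"unknown residue class {residue_class!r}")


def stabilization_score(
    delta_pka, residue_class: str, label: str = "", band: float = CATEGORY_BAND
) -> FrustrationScore:
    """Scaled B-factor score for one site.

    ``delta_pka`` may be a float or a :class:`PkaValue` bound; bounds enter
    the scaling at their capped magnitude (±5 → ±50 scaled).
    """
    s = _class_sign(residue_class)
    if isinstance(delta_pka, PkaValue):
        raw, is_bound = delta_pka.value, delta_pka.is_bound
        disp, _ = capped_delta(delta_pka)
    else:
        raw = float(delta_pka)
        if not np.isfinite(raw):
            raise ValueError("delta_pka must be finite or a PkaValue bound")
        is_bound = False
        disp = float(np.clip(raw, -DISPLAY_CAP, DISPLAY_CAP))
    scaled = float(np.clip(SCALE * raw * s, -CLAMP, CLAMP))
    if scaled < -band:
        category = "destabilised"
    elif scaled > band:
        category = "stabilised"
    else:
        category = "neutral"
    return FrustrationScore(
        label=label,
        residue_class=residue_class,
        delta_pka=raw,
        delta_capped=disp,
        is_bound=is_bound,
        scaled=scaled,
        category=category,
    )


def net_protonation(result: TitrationResult, labels, ph: float) -> float:
    """Sum of protonated fractions over a site subset at one pH.

    This is the proton count bound by e.g. the acidic ligands of a calcium
    clasp: ~0 when all pKas sit below physiological pH, ~2 when two
    carboxylates are forced protonated by the vacated site.
    """
    return float(sum(result.theta_at(label, ph) for label in labels))


def classify_report(scores: list[FrustrationScore]) -> pd.DataFrame:
    """Ranked table, most frustrated (lowest scaled score) first."""
    if not scores:
        raise ValueError("at least one score required")
    df = pd.DataFrame(
        {
            "label": [s.label for s in scores],
            "class": [s.residue_class for s in scores],
            "delta_pka_raw": [s.delta_pka for s in scores],
            "delta_pka_capped": [s.delta_capped for s in scores],
            "bound": [s.is_bound for s in scores],
            "scaled": [s.scaled for s in scores],
            "category": [s.category for s in scores],
        }
    )
    df = df.sort_values(["scaled", "label"], kind="stable").reset_index(drop=True)
    df.attrs["no_frustrated_sites"] = not (df["category"] == "destabilised").any()
    return df
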