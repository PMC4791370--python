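"""Molecular descriptors and compound classes for assigned DOM formulas.

For each CHNOSP formula the double bond equivalents (DBE), the modified
aromaticity index (AI_mod), the van Krevelen elemental ratios H/C and O/C,
and a compound-class label are computed; per-sample summaries
(intensity-weighted average mass, class relative abundances) are derived
from the normalized DOM table.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd

from .formula_pipeline import MolecularFormula


class CompoundClass(str, Enum):
    SATURATED_FATTY_ACID = "saturated_fatty_acid"
    UNSATURATED_ALIPHATIC = "unsaturated_aliphatic"
    HIGHLY_UNSATURATED = "highly_unsaturated"
    POLYPHENOL = "polyphenol"
    POLYCYCLIC_AROMATIC = "polycyclic_aromatic"
    PEPTIDE_LIKE = "peptide_like"
    UNSPECIFIED = "unspecified"


@dataclass(frozen=True)
class ClassBounds:
    """Configurable compound-class boundaries.

    Defaults: saturated fatty acids at H/C >= 2.0 or O/C >= 0.9; polycyclic
    aromatics at AI_mod > 0.66; polyphenols at 0.5 < AI_mod <= 0.66;
    aliphatic band 1.5 <= H/C < 2.0 (peptide-like when N is present);
    highly unsaturated at AI_mod <= 0.5 and H/C < 1.5.
    """

    fatty_acid_hc: float = 2.0
    fatty_acid_oc: float = 0.9
    polycyclic_ai: float = 0.66
    polyphenol_ai: float = 0.5
    aliphatic_hc: float = 1.5


DEFAULT_BOUNDS = ClassBounds()


def dbe(f: MolecularFormula) -> float:
    """Double bond equivalents, DBE = 1 + (2C - H + N + P) / 2."""
    return 1.0 + (2 * f.c - f.h + f.n + f.p) / 2.0


def ai_mod(f: MolecularFormula) -> float:
    """Modified aromaticity index.

    AI_mod = (1 + C - O/2 - S - H/2) / (C - O/2 - S - N - P).  When the
    denominator is <= 0 or the numerator < 0 the index is undefined for such
    aliphatic compositions and is clamped to 0.
    """
    num = 1.0 + f.c - 0.5 * f.o - f.s - 0.5 * f.h
    den = f.c - 0.5 * f.o - f.s - f.n - f.p
    if den <= 0 or num < 0:
        return 0.0
    return num / den


def van_krevelen(f: MolecularFormula) -> tuple[float, float]:
    """(O/C, H/C) elemental ratios for the van Krevelen plane."""
    if f.c < 1:
        raise ValueError("formula must contain carbon")
    return f.o / f.c, f.h / f.c


def classify_from_ratios(
    hc: float,
    oc: float,
    ai: float,
    n: int = 0,
    bounds: ClassBounds = DEFAULT_BOUNDS,
) -> CompoundClass:
    """Compound class from descriptor values; first matching rule wins."""
    if hc >= bounds.fatty_acid_hc or oc >= bounds.fatty_acid_oc:
        return CompoundClass.SATURATED_FATTY_ACID
    if ai > bounds.polycyclic_ai:
        return CompoundClass.POLYCYCLIC_AROMATIC
    if ai > bounds.polyphenol_ai:
        return CompoundClass.POLYPHENOL
    if bounds.aliphatic_hc <= hc < bounds.fatty_acid_hc:
        return CompoundClass.PEPTIDE_LIKE if n > 0 else CompoundClass.UNSATURATED_ALIPHATIC
    if ai <= bounds.polyphenol_ai and hc < bounds.aliphatic_hc:
        return CompoundClass.HIGHLY_UNSATURATED
    return CompoundClass.UNSPECIFIED


def classify_compound(
    f: MolecularFormula, bounds: ClassBounds = DEFAULT_BOUNDS
) -> CompoundClass:
    """Assign exactly one compound class to a formula."""
    oc, hc = van_krevelen(f)
    return classify_from_ratios(hc, oc, ai_mod(f), f.n, bounds)


def weighted_average_mass(row: pd.Series, masses: pd.Series) -> float:
    """Intensity-weighted average neutral mass of one sample row."""
    masses = masses.reindex(row.index)
    return float(np.dot(row.to_numpy(), masses.to_numpy()))


def descriptor_table(
    formulas: dict[str, MolecularFormula], bounds: ClassBounds = DEFAULT_BOUNDS
) -> pd.DataFrame:
    """Per-formula descriptor rows (mass, DBE, AI_mod, H/C, O/C, class)."""
    rows = []
    for key, f in formulas.items():
        oc, hc = van_krevelen(f)
        rows.append(
            {
                "formula": key,
                "neutral_mass": f.neutral_mass,
                "dbe": dbe(f),
                "ai_mod": ai_mod(f),
                "hc_ratio": hc,
                "oc_ratio": oc,
                "compound_class": classify_compound(f, bounds).value,
            }
        )
    return pd.DataFrame(rows).set_index("formula")


def sample_summaries(
    dom_table: pd.DataFrame,
    formulas: dict[str, MolecularFormula],
    bounds: ClassBounds = DEFAULT_BOUNDS,
) -> pd.DataFrame:
    """Per-sample weighted average mass and compound-class abundances.

    Class columns hold the summed relative intensity of formulas in each
    class, i.e. the intensity-weighted class composition per sample.
    """
    desc = descriptor_table(formulas, bounds)
    masses = desc["neutral_mass"].reindex(dom_table.columns)
    out = pd.DataFrame(index=dom_table.index)
    out["weighted_avg_mass"] = dom_table.to_numpy() @ masses.to_numpy()
    classes = desc["compound_class"].reindex(dom_table.columns)
    for cls in CompoundClass:
        cols = classes[classes == cls.value].index
        out[cls.value] = dom_table[cols].sum(axis=1) if len(cols) else 0.0
    return out
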