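"""Molecular formula assignment for negative-mode FT-ICR-MS peak lists.

Implements the full filter cascade used for marine dissolved organic matter
(DOM): signal-to-noise screening, cross-sample mass alignment, occurrence
filtering, CHNOSP candidate enumeration within a ppm tolerance, chemical
plausibility rules, exclusion of implausible heteroatom combinations,
removal of ambiguous (double) assignments, contaminant / homologous-series /
isotopolog removal, and per-sample sum normalization of peak intensities.

The shipped cascade order is: S/N >= 4 -> align -> occurrence filter ->
isotopolog screen -> enumerate -> chemical filters -> heteroatom exclusion ->
double-assignment drop -> contaminant removal -> normalize.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

# Monoisotopic atomic masses (Da), CODATA/IUPAC values.
MASS_C = 12.0
MASS_H = 1.00782503207
MASS_N = 14.0030740048
MASS_O = 15.9949146196
MASS_S = 31.97207100
MASS_P = 30.97376163

#: Mass of a proton (Da).  Neutral mass of a singly charged deprotonated ion
#: [M-H]- is m/z + PROTON_MASS; the electron mass is folded into this constant.
PROTON_MASS = 1.007276466

#: Spacing of a 13C isotopolog relative to the monoisotopic peak (Da).
C13_SPACING = 1.003355

#: Mass of a CH2 homologous-series step (Da).
CH2_MASS = MASS_C + 2 * MASS_H  # 14.01565006414

#: m/z window (Da) evaluated by the instrument method.
MASS_WINDOW = (150.0, 2000.0)

_ELEMENT_MASSES = np.array([MASS_C, MASS_H, MASS_N, MASS_O, MASS_S, MASS_P])


@dataclass(frozen=True)
class MolecularFormula:
    """A neutral CHNOSP molecular formula with integer element counts."""

    c: int
    h: int
    n: int = 0
    o: int = 0
    s: int = 0
    p: int = 0

    def __post_init__(self) -> None:
        for name in ("c", "h", "n", "o", "s", "p"):
            if getattr(self, name) < 0:
                raise ValueError(f"negative {name.upper()} count")

    @property
    def neutral_mass(self) -> float:
        """Neutral monoisotopic mass in Da."""
        return (
            self.c * MASS_C
            + self.h * MASS_H
            + self.n * MASS_N
            + self.o * MASS_O
            + self.s * MASS_S
            + self.p * MASS_P
        )

    @property
    def mz_neg(self) -> float:
        """m/z of the singly charged [M-H]- ion."""
        return self.neutral_mass - PROTON_MASS

    def __str__(self) -> str:
        parts = []
        for sym, count in (
            ("C", self.c),
            ("H", self.h),
            ("N", self.n),
            ("O", self.o),
            ("P", self.p),
            ("S", self.s),
        ):
            if count == 1:
                parts.append(sym)
            elif count > 1:
                parts.append(f"{sym}{count}")
        return "".join(parts) or "empty"

    @classmethod
    def from_string(cls, text: str) -> "MolecularFormula":
        """Parse a formula string such as ``C27H30O15`` back to counts."""
        import re

        counts = {"C": 0, "H": 0, "N": 0, "O": 0, "S": 0, "P": 0}
        pos = 0
        for m in re.finditer(r"([CHNOSP])(\d*)", text):
            if m.start() != pos:
                raise ValueError(f"cannot parse formula {text!r}")
            pos = m.end()
            counts[m.group(1)] += int(m.group(2) or 1)
        if pos != len(text):
            raise ValueError(f"cannot parse formula {text!r}")
        return cls(
            c=counts["C"], h=counts["H"], n=counts["N"],
            o=counts["O"], s=counts["S"], p=counts["P"],
        )


@dataclass(frozen=True)
class ElementRanges:
    """Inclusive per-element count bounds for candidate enumeration.

    Defaults follow common DOM assignment practice for CHNOSP formulas.
    """

    c: tuple[int, int] = (1, 100)
    h: tuple[int, int] = (1, 200)
    n: tuple[int, int] = (0, 4)
    o: tuple[int, int] = (0, 50)
    s: tuple[int, int] = (0, 2)
    p: tuple[int, int] = (0, 1)

    def contains(self, f: MolecularFormula) -> bool:
        return all(
            lo <= getattr(f, e) <= hi
            for e, (lo, hi) in (
                ("c", self.c), ("h", self.h), ("n", self.n),
                ("o", self.o), ("s", self.s), ("p", self.p),
            )
        )


DEFAULT_RANGES = ElementRanges()


@dataclass(frozen=True)
class MassPeak:
    """One exported mass peak of a calibrated negative-mode spectrum."""

    mz: float
    intensity: float
    resolution: float
    sn: float
    sample_id: str

    def __post_init__(self) -> None:
        if self.intensity <= 0:
            raise ValueError("intensity must be > 0")
        if self.sn < 0:
            raise ValueError("S/N must be >= 0")


@dataclass(frozen=True)
class FormulaAssignment:
    """A peak resolved to a unique molecular formula."""

    peak: MassPeak
    formula: MolecularFormula
    mass_error_ppm: float


def neutral_mass_from_mz(mz: float) -> float:
    """Neutral mass (Da) of a singly charged deprotonated ion [M-H]-."""
    if mz <= 0:
        raise ValueError("m/z must be positive")
    return mz + PROTON_MASS


@lru_cache(maxsize=8)
def _base_grid(ranges: ElementRanges):
    """Grid of (c, n, o, s, p) counts and their partial masses (H excluded)."""
    c = np.arange(ranges.c[0], ranges.c[1] + 1)
    n = np.arange(ranges.n[0], ranges.n[1] + 1)
    o = np.arange(ranges.o[0], ranges.o[1] + 1)
    s = np.arange(ranges.s[0], ranges.s[1] + 1)
    p = np.arange(ranges.p[0], ranges.p[1] + 1)
    C, N, O, S, P = np.meshgrid(c, n, o, s, p, indexing="ij")
    counts = np.stack([a.ravel() for a in (C, N, O, S, P)], axis=1)
    base = (
        counts[:, 0] * MASS_C
        + counts[:, 1] * MASS_N
        + counts[:, 2] * MASS_O
        + counts[:, 3] * MASS_S
        + counts[:, 4] * MASS_P
    )
    return counts, base


def enumerate_candidates(
    neutral_mass: float,
    tolerance_ppm: float = 0.5,
    ranges: ElementRanges = DEFAULT_RANGES,
) -> list[MolecularFormula]:
    """All CHNOSP formulas within ``tolerance_ppm`` of a neutral mass.

    Equivalent to exhaustive nested enumeration over the element ranges;
    the hydrogen count is solved analytically, which keeps the search
    vectorized.  Results are sorted by absolute mass error (ties by formula
    string for determinism).
    """
    if tolerance_ppm <= 0:
        raise ValueError("tolerance must be > 0")
    counts, base = _base_grid(ranges)
    keep = base + ranges.h[0] * MASS_H <= neutral_mass + 1.0
    counts, base = counts[keep], base[keep]
    tol_da = tolerance_ppm * 1e-6 * neutral_mass
    h_float = (neutral_mass - base) / MASS_H
    out: list[tuple[float, str, MolecularFormula]] = []
    for h_round in (np.floor(h_float), np.ceil(h_float)):
        h = h_round.astype(int)
        ok = (h >= ranges.h[0]) & (h <= ranges.h[1])
        err = neutral_mass - (base + h * MASS_H)
        ok &= np.abs(err) <= tol_da
        for idx in np.nonzero(ok)[0]:
            f = MolecularFormula(
                c=int(counts[idx, 0]), h=int(h[idx]), n=int(counts[idx, 1]),
                o=int(counts[idx, 2]), s=int(counts[idx, 3]),
                p=int(counts[idx, 4]),
            )
            ppm = (f.neutral_mass - neutral_mass) / neutral_mass * 1e6
            out.append((abs(ppm), str(f), f))
    seen: set[str] = set()
    result = []
    for _, key, f in sorted(out, key=lambda t: (t[0], t[1])):
        if key not in seen:
            seen.add(key)
            result.append(f)
    return result


def dbe_value(f: MolecularFormula) -> float:
    """Double bond equivalents: DBE = 1 + (2C - H + N + P) / 2."""
    return 1.0 + (2 * f.c - f.h + f.n + f.p) / 2.0


def chemical_filters(
    f: MolecularFormula, ranges: ElementRanges = DEFAULT_RANGES
) -> bool:
    """Chemical plausibility of a candidate formula.

    Requires an integer, non-negative DBE, 0.3 <= H/C <= 2.5, O/C <= 1.2,
    and element counts inside ``ranges``.
    """
    if f.c < 1 or f.h < 1:
        return False
    if not ranges.contains(f):
        return False
    d = dbe_value(f)
    if d < 0 or d != int(d):
        return False
    hc = f.h / f.c
    oc = f.o / f.c
    return 0.3 <= hc <= 2.5 and oc <= 1.2


# Excluded (N, S, P) signatures: exact heteroatom combinations considered
# chemically implausible for marine DOM: N2S, N3S, N4S, N2P, N3P, N4P,
# NS2, N2S2, N3S2, N4S2, PS2 -- plus NSP meaning "all three present".
_EXCLUDED_NSP: frozenset[tuple[int, int, int]] = frozenset(
    [
        (2, 1, 0), (3, 1, 0), (4, 1, 0),
        (2, 0, 1), (3, 0, 1), (4, 0, 1),
        (1, 2, 0), (2, 2, 0), (3, 2, 0), (4, 2, 0),
        (0, 2, 1),
    ]
)


def heteroatom_exclusion(f: MolecularFormula) -> bool:
    """True if the formula carries an excluded heteroatom combination."""
    if f.n >= 1 and f.s >= 1 and f.p >= 1:
        return True
    return (f.n, f.s, f.p) in _EXCLUDED_NSP


@dataclass
class AlignedMassTable:
    """Peaks aligned across samples into mass columns.

    ``intensity`` is a samples x columns DataFrame (0 where a sample lacks
    the mass); columns are labelled by the mean member m/z.  ``max_sn`` holds
    the per-column maximum S/N and ``members`` the contributing peaks.
    """

    intensity: pd.DataFrame
    mz: np.ndarray
    max_sn: np.ndarray
    members: list[list[MassPeak]]

    @property
    def n_samples(self) -> int:
        return self.intensity.shape[0]

    def occurrence(self) -> np.ndarray:
        return (self.intensity.to_numpy() > 0).sum(axis=0)

    def subset(self, keep: np.ndarray) -> "AlignedMassTable":
        idx = np.nonzero(keep)[0]
        return AlignedMassTable(
            intensity=self.intensity.iloc[:, idx],
            mz=self.mz[idx],
            max_sn=self.max_sn[idx],
            members=[self.members[i] for i in idx],
        )


def align_masses(
    peak_lists: Mapping[str, Sequence[MassPeak]], tolerance_ppm: float = 0.5
) -> AlignedMassTable:
    """Single-linkage alignment of m/z values across samples.

    Peaks are pooled, sorted, and chained into one column while consecutive
    gaps stay within ``tolerance_ppm``.  If a chain captures two peaks of the
    same sample, the higher-intensity peak is kept and the conflict logged.
    """
    samples = list(peak_lists)
    if not samples:
        raise ValueError("need at least one sample")
    pool = [pk for s in samples for pk in peak_lists[s]]
    pool.sort(key=lambda pk: pk.mz)
    clusters: list[list[MassPeak]] = []
    for pk in pool:
        if clusters and (pk.mz - clusters[-1][-1].mz) <= tolerance_ppm * 1e-6 * clusters[-1][-1].mz:
            clusters[-1].append(pk)
        else:
            clusters.append([pk])

    n_cols = len(clusters)
    inten = np.zeros((len(samples), n_cols))
    sn = np.zeros(n_cols)
    mz = np.zeros(n_cols)
    sample_idx = {s: i for i, s in enumerate(samples)}
    members: list[list[MassPeak]] = []
    for j, cl in enumerate(clusters):
        best: dict[str, MassPeak] = {}
        for pk in cl:
            prev = best.get(pk.sample_id)
            if prev is not None:
                logger.warning(
                    "alignment conflict at m/z %.6f in sample %s; keeping the "
                    "higher-intensity peak", pk.mz, pk.sample_id,
                )
                if pk.intensity <= prev.intensity:
                    continue
            best[pk.sample_id] = pk
        kept = list(best.values())
        members.append(kept)
        mz[j] = float(np.mean([pk.mz for pk in kept]))
        sn[j] = max(pk.sn for pk in kept)
        for pk in kept:
            inten[sample_idx[pk.sample_id], j] = pk.intensity
    return AlignedMassTable(
        intensity=pd.DataFrame(inten, index=samples, columns=mz),
        mz=mz,
        max_sn=sn,
        members=members,
    )


def cross_sample_filter(
    t: AlignedMassTable, min_sn_single: float = 20.0
) -> AlignedMassTable:
    """Occurrence-based mass filter.

    A mass is kept when detected in more than two samples, or — if present in
    fewer than 20% of the samples — when its S/N exceeds ``min_sn_single`` in
    at least one sample.
    """
    occ = t.occurrence()
    n = t.n_samples
    keep = (occ > 2) | ((occ < 0.2 * n) & (t.max_sn > min_sn_single))
    return t.subset(keep)


def remove_isotopolog_columns(
    t: AlignedMassTable, tolerance_ppm: float = 0.5
) -> AlignedMassTable:
    """Drop columns that are 13C isotopologs of a stronger column.

    A column is flagged when its m/z sits one 13C spacing (±tolerance) above
    another column with higher maximum intensity.
    """
    order = np.argsort(t.mz)
    mz = t.mz[order]
    peak_height = t.intensity.to_numpy().max(axis=0)[order]
    keep_sorted = np.ones(len(mz), dtype=bool)
    target = mz - C13_SPACING
    lo = np.searchsorted(mz, target - tolerance_ppm * 1e-6 * mz)
    hi = np.searchsorted(mz, target + tolerance_ppm * 1e-6 * mz, side="right")
    for j in range(len(mz)):
        if hi[j] > lo[j] and peak_height[lo[j]:hi[j]].max() > peak_height[j]:
            keep_sorted[j] = False
    keep = np.ones(len(mz), dtype=bool)
    keep[order] = keep_sorted
    return t.subset(keep)


def assign_and_resolve(
    t: AlignedMassTable,
    tolerance_ppm: float = 0.5,
    ranges: ElementRanges = DEFAULT_RANGES,
    min_sn: float = 4.0,
) -> list[FormulaAssignment]:
    """Assign formulas to aligned masses and drop ambiguous columns.

    Candidates per column are enumerated from the neutral mass, screened by
    :func:`chemical_filters` and :func:`heteroatom_exclusion`; only columns
    with exactly one surviving candidate yield assignments (one per member
    peak).  Member peaks below ``min_sn`` are never assigned.
    """
    out: list[FormulaAssignment] = []
    for j in range(len(t.mz)):
        neutral = neutral_mass_from_mz(t.mz[j])
        cands = [
            f
            for f in enumerate_candidates(neutral, tolerance_ppm, ranges)
            if chemical_filters(f, ranges) and not heteroatom_exclusion(f)
        ]
        if len(cands) != 1:
            continue
        f = cands[0]
        for pk in t.members[j]:
            if pk.sn < min_sn:
                continue
            err = (neutral_mass_from_mz(pk.mz) - f.neutral_mass) / f.neutral_mass * 1e6
            out.append(FormulaAssignment(peak=pk, formula=f, mass_error_ppm=err))
    return out


def _contaminant_mass_set(
    contaminant_masses: Iterable[float],
    mass_window: tuple[float, float] = MASS_WINDOW,
) -> np.ndarray:
    """Expand contaminant neutral masses by CH2 series and 13C isotopologs."""
    lo, hi = mass_window
    series: list[float] = []
    for m in contaminant_masses:
        series.append(m)
        k = 1
        while m + k * CH2_MASS <= hi:
            series.append(m + k * CH2_MASS)
            k += 1
        k = 1
        while m - k * CH2_MASS >= lo:
            series.append(m - k * CH2_MASS)
            k += 1
    series = series + [m + C13_SPACING for m in series]
    return np.sort(np.array(series)) if series else np.empty(0)


def remove_contaminants(
    assignments: Sequence[FormulaAssignment],
    contaminant_masses: Iterable[float] = (),
    tolerance_ppm: float = 0.5,
    mass_window: tuple[float, float] = MASS_WINDOW,
) -> list[FormulaAssignment]:
    """Remove assignments matching known contaminant masses.

    The removal set contains every listed contaminant neutral mass, its CH2
    homologous series within the mass window, and the 13C isotopolog of every
    removed mass, all matched within ``tolerance_ppm``.
    """
    removal = _contaminant_mass_set(contaminant_masses, mass_window)
    if removal.size == 0:
        return list(assignments)
    out = []
    for a in assignments:
        m = a.formula.neutral_mass
        i = np.searchsorted(removal, m)
        near = [removal[k] for k in (i - 1, i) if 0 <= k < removal.size]
        if any(abs(m - r) <= tolerance_ppm * 1e-6 * m for r in near):
            continue
        out.append(a)
    return out


def normalize_intensities(
    assignments: Sequence[FormulaAssignment],
    samples: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Build the sample x formula table of sum-normalized intensities.

    Each sample's retained peak intensities are divided by their sum so rows
    sum to one and entries are relative abundances.
    """
    if samples is None:
        samples = sorted({a.peak.sample_id for a in assignments})
    cols = sorted({str(a.formula) for a in assignments})
    table = pd.DataFrame(0.0, index=list(samples), columns=cols)
    for a in assignments:
        table.loc[a.peak.sample_id, str(a.formula)] += a.peak.intensity
    sums = table.sum(axis=1)
    empty = sums[sums <= 0]
    if not empty.empty:
        raise ValueError(
            f"no retained assignments for sample(s): {', '.join(map(str, empty.index))}"
        )
    return table.div(sums, axis=0)


@dataclass
class PipelineResult:
    """Output of the full assignment cascade."""

    dom_table: pd.DataFrame
    assignments: list[FormulaAssignment]
    formulas: dict[str, MolecularFormula] = field(default_factory=dict)

    @property
    def formula_masses(self) -> pd.Series:
        return pd.Series({k: f.neutral_mass for k, f in self.formulas.items()})


def run_pipeline(
    peak_lists: Mapping[str, Sequence[MassPeak]],
    tolerance_ppm: float = 0.5,
    ranges: ElementRanges = DEFAULT_RANGES,
    contaminant_masses: Iterable[float] = (),
    min_sn: float = 4.0,
    min_sn_single: float = 20.0,
) -> PipelineResult:
    """Run the complete peak-list -> DOM-table cascade."""
    screened = {
        s: [pk for pk in pks if pk.sn >= min_sn]
        for s, pks in peak_lists.items()
    }
    aligned = align_masses(screened, tolerance_ppm)
    aligned = cross_sample_filter(aligned, min_sn_single)
    aligned = remove_isotopolog_columns(aligned, tolerance_ppm)
    assignments = assign_and_resolve(aligned, tolerance_ppm, ranges, min_sn)
    assignments = remove_contaminants(assignments, contaminant_masses, tolerance_ppm)
    dom = normalize_intensities(assignments, samples=list(peak_lists))
    formulas = {str(a.formula): a.formula for a in assignments}
    return PipelineResult(dom_table=dom, assignments=assignments, formulas=formulas)
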