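"""Synthetic inputs with known ground truth for the whole pipeline.

Emulates the three data streams of a coupled DOM / bacterioplankton time
series: calibrated negative-mode FT-ICR-MS peak lists generated from a known
formula universe (with ppm mass error, unassignable noise peaks, 13C
isotopolog partners and a CH2-homologous contaminant series), an OTU count
table with a planted two-group structure, and a positive environmental-
covariate table with planted multicollinearity.  OTU-molecule correlations
can be planted at chosen strengths.  Identical seed and configuration give
identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .community_prep import OtuTable
from .formula_pipeline import (
    DEFAULT_RANGES,
    C13_SPACING,
    ElementRanges,
    MassPeak,
    MolecularFormula,
    chemical_filters,
    enumerate_candidates,
    heteroatom_exclusion,
)

#: Default environmental variables (a subset of a coastal time series) and
#: the planted pairwise correlations among them, mirroring the observed
#: multicollinearity structure (temperature-TDN, temperature-nitrite,
#: salinity-DOC and salinity-oxygen).
DEFAULT_ENV_VARIABLES = (
    "temperature", "salinity", "TDN", "DOC", "O2", "NO2", "PO4", "chl_a",
)
DEFAULT_COLLINEARITY = (
    ("temperature", "TDN", 0.51),
    ("temperature", "NO2", 0.65),
    ("salinity", "DOC", -0.60),
    ("salinity", "O2", -0.56),
)

#: Known laboratory contaminants (neutral masses, Da): palmitic acid
#: (C16H32O2) and dioctyl phthalate (C24H38O4), both with CH2 series.
DEFAULT_CONTAMINANT_BASES = (256.240230, 390.277009)


@dataclass
class SimulationConfig:
    """Study-design parameters of the synthetic data generator.

    Defaults mirror a daily coastal surface-water series: 17 samples split
    into two groups, 98 OTUs (5 of them organelle-derived to exercise taxon
    filtering), sequencing depth log-normal around 1e5 reads, and a
    desk-scale DOM universe of 200 formulas between 150 and 800 Da.
    """

    n_samples: int = 17
    seed: int = 0

    # DOM / peak lists
    n_true_formulas: int = 200
    n_noise_peaks_per_sample: int = 50
    mass_error_sd: float = 0.1  # ppm
    mass_window: tuple[float, float] = (150.0, 800.0)
    element_ranges: ElementRanges = field(default_factory=lambda: DEFAULT_RANGES)
    assignment_tolerance_ppm: float = 0.5
    presence_prob: float = 0.8
    isotopolog_fraction: float = 0.3
    contaminant_base_masses: tuple[float, ...] = DEFAULT_CONTAMINANT_BASES
    contaminant_series_steps: int = 4
    sn_meanlog: float = float(np.log(50.0))
    sn_sdlog: float = 1.0
    noise_sn_meanlog: float = float(np.log(6.0))
    noise_sn_sdlog: float = 0.8

    # OTU table
    n_otus: int = 98
    n_organelle_otus: int = 5
    n_differential_otus: int = 10
    log_fold_effect: float = float(np.log(10.0))
    dirichlet_concentration: float = 50.0
    depth_meanlog: float = float(np.log(1e5))
    depth_sdlog: float = 0.3
    group_assignment: Mapping[str, str] | None = None

    # environment
    env_variables: tuple[str, ...] = DEFAULT_ENV_VARIABLES
    collinearity_spec: tuple[tuple[str, str, float], ...] = DEFAULT_COLLINEARITY
    env_sdlog: float = 0.25

    # planted OTU-molecule associations
    planted_edges: tuple[tuple[str, str, float], ...] = ()

    def __post_init__(self) -> None:
        for name in (
            "n_samples", "n_true_formulas", "n_otus",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_noise_peaks_per_sample < 0 or self.n_differential_otus < 0:
            raise ValueError("counts must be non-negative")
        if self.mass_error_sd < 0:
            raise ValueError("mass_error_sd must be >= 0")
        for a, b, r in tuple(self.collinearity_spec) + tuple(self.planted_edges):
            if abs(r) > 1:
                raise ValueError(f"target correlation |r| > 1 for ({a}, {b})")
        if not 0 <= self.presence_prob <= 1 or not 0 <= self.isotopolog_fraction <= 1:
            raise ValueError("fractions must lie in [0, 1]")

    @property
    def sample_ids(self) -> list[str]:
        return [f"S{i + 1:02d}" for i in range(self.n_samples)]

    def groups(self) -> pd.Series:
        """Planted two-group sample partition (A first half, B second)."""
        if self.group_assignment is not None:
            s = pd.Series(dict(self.group_assignment))
            return s.reindex(self.sample_ids)
        half = (self.n_samples + 1) // 2
        return pd.Series(
            ["A"] * half + ["B"] * (self.n_samples - half), index=self.sample_ids
        )


# ---------------------------------------------------------------------------
# formula universe and peak lists


def _is_uniquely_assignable(f: MolecularFormula, cfg: SimulationConfig) -> bool:
    cands = [
        c
        for c in enumerate_candidates(
            f.neutral_mass, cfg.assignment_tolerance_ppm, cfg.element_ranges
        )
        if chemical_filters(c, cfg.element_ranges) and not heteroatom_exclusion(c)
    ]
    return len(cands) == 1 and cands[0] == f


def generate_formula_universe(cfg: SimulationConfig) -> list[MolecularFormula]:
    """Random chemically valid CHNOSP formulas inside the mass window.

    Every formula passes the assignment pipeline's chemical filters, avoids
    the excluded heteroatom combinations, and is uniquely assignable at the
    configured tolerance, so that planted peaks constitute unambiguous
    ground truth for recovery tests.
    """
    rng = np.random.default_rng(cfg.seed)
    ranges = cfg.element_ranges
    lo, hi = cfg.mass_window
    out: list[MolecularFormula] = []
    seen: set[str] = set()
    attempts, max_attempts = 0, 500 * cfg.n_true_formulas
    het_vals = {
        "n": (np.arange(ranges.n[0], ranges.n[1] + 1), None),
        "s": (np.arange(ranges.s[0], ranges.s[1] + 1), None),
        "p": (np.arange(ranges.p[0], ranges.p[1] + 1), None),
    }

    def _draw_het(vals: np.ndarray) -> int:
        w = np.array([4.0] + [0.5**i for i in range(1, len(vals))])[: len(vals)]
        return int(rng.choice(vals, p=w / w.sum()))

    while len(out) < cfg.n_true_formulas:
        attempts += 1
        if attempts > max_attempts:
            raise ValueError(
                "mass window / element ranges too narrow to host "
                f"{cfg.n_true_formulas} distinct valid formulas"
            )
        c = int(rng.integers(max(ranges.c[0], 6), min(ranges.c[1], 45) + 1))
        h = int(round(c * rng.uniform(0.5, 2.2)))
        o = int(round(c * rng.uniform(0.1, 1.0)))
        n = _draw_het(het_vals["n"][0])
        s = _draw_het(het_vals["s"][0])
        p = _draw_het(het_vals["p"][0])
        # enforce integer DBE: H + N + P must be even
        if (h + n + p) % 2 == 1:
            h += 1
        h = int(np.clip(h, ranges.h[0], ranges.h[1]))
        o = int(np.clip(o, ranges.o[0], ranges.o[1]))
        if (h + n + p) % 2 == 1:
            continue
        try:
            f = MolecularFormula(c=c, h=h, n=n, o=o, s=s, p=p)
        except ValueError:
            continue
        if not (lo <= f.neutral_mass <= hi):
            continue
        if not chemical_filters(f, ranges) or heteroatom_exclusion(f):
            continue
        key = str(f)
        if key in seen:
            continue
        if not _is_uniquely_assignable(f, cfg):
            continue
        seen.add(key)
        out.append(f)
    return out


@dataclass
class PeakListTruth:
    """Ground truth accompanying generated peak lists."""

    formulas: list[str]
    formula_masses: dict[str, float]
    presence: pd.DataFrame  # samples x formulas, bool
    intensities: pd.DataFrame  # samples x formulas, raw (0 where absent)
    isotopolog_formulas: list[str]
    contaminant_masses: list[float]
    noise_mz: dict[str, list[float]]


def _noise_is_safe(mz: float, cfg: SimulationConfig) -> bool:
    """True when no assignable candidate lies within 5 ppm of the peak."""
    neutral = mz + 1.007276466
    cands = enumerate_candidates(neutral, 5.0, cfg.element_ranges)
    return not any(
        chemical_filters(c, cfg.element_ranges) and not heteroatom_exclusion(c)
        for c in cands
    )


def generate_peak_lists(
    universe: Sequence[MolecularFormula], cfg: SimulationConfig
) -> tuple[dict[str, list[MassPeak]], PeakListTruth]:
    """Per-sample peak lists from a formula universe.

    Each formula appears in a random subset of samples (presence probability
    ``cfg.presence_prob``) as its [M-H]- ion with Gaussian ppm mass error; a
    fraction of formulas carries a +1.00336 Da 13C partner at isotope-ratio
    intensity; a CH2-homologous contaminant series is injected in every
    sample; noise peaks are placed at least 5 ppm away from any assignable
    candidate mass.  S/N values are log-normal.
    """
    if not universe:
        raise ValueError("formula universe is empty")
    rng = np.random.default_rng(cfg.seed + 1)
    samples = cfg.sample_ids
    keys = [str(f) for f in universe]
    nf = len(universe)

    presence = rng.random((cfg.n_samples, nf)) < cfg.presence_prob
    base_inten = rng.lognormal(np.log(1e6), 1.0, size=nf)
    sample_factor = rng.lognormal(0.0, 0.3, size=(cfg.n_samples, nf))
    inten = presence * base_inten[None, :] * sample_factor
    sn = rng.lognormal(cfg.sn_meanlog, cfg.sn_sdlog, size=(cfg.n_samples, nf))
    iso_flags = rng.random(nf) < cfg.isotopolog_fraction
    mz_theory = np.array([f.mz_neg for f in universe])

    peak_lists: dict[str, list[MassPeak]] = {s: [] for s in samples}
    noise_mz: dict[str, list[float]] = {s: [] for s in samples}
    for i, s in enumerate(samples):
        for j in range(nf):
            if not presence[i, j]:
                continue
            err = rng.normal(0.0, cfg.mass_error_sd) if cfg.mass_error_sd > 0 else 0.0
            mz = mz_theory[j] * (1.0 + err * 1e-6)
            pk = MassPeak(
                mz=mz, intensity=float(inten[i, j]),
                resolution=float(4e5), sn=float(sn[i, j]), sample_id=s,
            )
            peak_lists[s].append(pk)
            if iso_flags[j]:
                ratio = 0.011 * universe[j].c
                peak_lists[s].append(
                    MassPeak(
                        mz=mz + 1.00336,
                        intensity=float(inten[i, j] * ratio),
                        resolution=float(4e5),
                        sn=float(sn[i, j]),
                        sample_id=s,
                    )
                )

    # contaminant CH2 series, present in every sample with isotopologs
    contaminant_masses: list[float] = []
    ch2 = 14.015650
    for base in cfg.contaminant_base_masses:
        for k in range(cfg.contaminant_series_steps):
            m = base + k * ch2
            if not cfg.mass_window[0] <= m <= cfg.mass_window[1]:
                continue
            contaminant_masses.append(m)
            for i, s in enumerate(samples):
                inten_c = float(rng.lognormal(np.log(5e6), 0.2))
                for dm, factor in ((0.0, 1.0), (C13_SPACING, 0.15)):
                    peak_lists[s].append(
                        MassPeak(
                            mz=m - 1.007276466 + dm,
                            intensity=inten_c * factor,
                            resolution=float(4e5),
                            sn=float(rng.lognormal(cfg.sn_meanlog, 0.3)),
                            sample_id=s,
                        )
                    )

    # unassignable noise peaks
    for s in samples:
        placed = 0
        while placed < cfg.n_noise_peaks_per_sample:
            mz = float(rng.uniform(*cfg.mass_window))
            if not _noise_is_safe(mz, cfg):
                continue
            peak_lists[s].append(
                MassPeak(
                    mz=mz,
                    intensity=float(rng.lognormal(np.log(2e5), 0.8)),
                    resolution=float(4e5),
                    sn=float(rng.lognormal(cfg.noise_sn_meanlog, cfg.noise_sn_sdlog)),
                    sample_id=s,
                )
            )
            noise_mz[s].append(mz)
            placed += 1

    for s in samples:
        peak_lists[s].sort(key=lambda pk: pk.mz)
    truth = PeakListTruth(
        formulas=keys,
        formula_masses={k: f.neutral_mass for k, f in zip(keys, universe)},
        presence=pd.DataFrame(presence, index=samples, columns=keys),
        intensities=pd.DataFrame(inten, index=samples, columns=keys),
        isotopolog_formulas=[k for k, fl in zip(keys, iso_flags) if fl],
        contaminant_masses=contaminant_masses,
        noise_mz=noise_mz,
    )
    return peak_lists, truth


def generate_dom_table(
    universe: Sequence[MolecularFormula], cfg: SimulationConfig
) -> pd.DataFrame:
    """Sum-normalized sample x formula table drawn from the intensity model.

    Shortcut for downstream statistical tests that do not need the mass-
    spectrometric layer: the same log-normal intensity model as
    :func:`generate_peak_lists`, all formulas present, rows normalized to 1.
    """
    rng = np.random.default_rng(cfg.seed + 2)
    keys = [str(f) for f in universe]
    base = rng.lognormal(np.log(1e6), 1.0, size=len(universe))
    inten = base[None, :] * rng.lognormal(0.0, 0.3, size=(cfg.n_samples, len(universe)))
    table = pd.DataFrame(inten, index=cfg.sample_ids, columns=keys)
    return table.div(table.sum(axis=1), axis=0)


# ---------------------------------------------------------------------------
# OTU table


_ORGANELLE_PATHS = (
    "Bacteria;Cyanobacteria;Chloroplast",
    "Bacteria;Proteobacteria;Alphaproteobacteria;Mitochondria",
    "Eukaryota;Stramenopiles",
)

_PHYLA = (
    "Proteobacteria;Alphaproteobacteria",
    "Proteobacteria;Gammaproteobacteria",
    "Bacteroidetes;Flavobacteriia",
    "Bacteroidetes;Cytophagia",
    "Actinobacteria;Acidimicrobiia",
    "Verrucomicrobia;Verrucomicrobiae",
)


def generate_otu_table(cfg: SimulationConfig) -> tuple[OtuTable, pd.DataFrame]:
    """Dirichlet-multinomial OTU counts with a planted group effect.

    Base OTU proportions are log-normal; per-sample compositions are drawn
    from a Dirichlet around them (overdispersion controlled by
    ``dirichlet_concentration``) and counts from a multinomial with
    log-normal depth.  The first ``n_differential_otus`` (non-organelle)
    OTUs have their expected abundance multiplied by exp(log_fold_effect) in
    group B.  The last ``n_organelle_otus`` OTUs carry organelle/eukaryote
    taxonomy labels.  Returns the table and a ground-truth frame listing the
    differential OTUs.
    """
    rng = np.random.default_rng(cfg.seed + 3)
    groups = cfg.groups()
    if groups.isna().any() or groups.empty:
        raise ValueError("group assignment must cover all samples")
    n_bact = cfg.n_otus - cfg.n_organelle_otus
    if n_bact <= cfg.n_differential_otus:
        raise ValueError("too many differential OTUs for the table size")
    names = [f"OTU_{i + 1:03d}" for i in range(cfg.n_otus)]
    taxonomy = pd.Series(
        [
            f"Bacteria;{_PHYLA[i % len(_PHYLA)]};Genus_{i + 1}"
            for i in range(n_bact)
        ]
        + [
            f"{_ORGANELLE_PATHS[i % len(_ORGANELLE_PATHS)]};OTU_{n_bact + i + 1}"
            for i in range(cfg.n_organelle_otus)
        ],
        index=names,
    )
    base = rng.lognormal(0.0, 1.2, size=cfg.n_otus)
    base /= base.sum()
    differential = names[: cfg.n_differential_otus]

    counts = np.zeros((cfg.n_samples, cfg.n_otus), dtype=int)
    for i, s in enumerate(cfg.sample_ids):
        p = base.copy()
        if groups[s] == "B" and cfg.n_differential_otus > 0:
            p[: cfg.n_differential_otus] *= np.exp(cfg.log_fold_effect)
        p /= p.sum()
        alpha = p * cfg.dirichlet_concentration
        comp = rng.dirichlet(alpha)
        depth = int(rng.lognormal(cfg.depth_meanlog, cfg.depth_sdlog))
        counts[i] = rng.multinomial(depth, comp)

    table = OtuTable(
        counts=pd.DataFrame(counts, index=cfg.sample_ids, columns=names),
        taxonomy=taxonomy,
    )
    truth = pd.DataFrame(
        {
            "otu": differential,
            "log_fold_effect": cfg.log_fold_effect,
            "enriched_group": "B",
        }
    )
    return table, truth


# ---------------------------------------------------------------------------
# environmental covariates


_ENV_BASELINES = {
    "temperature": 18.0, "salinity": 32.5, "TDN": 16.0, "DOC": 150.0,
    "O2": 280.0, "NO2": 0.3, "PO4": 0.4, "chl_a": 0.8,
}


def _target_correlation_matrix(cfg: SimulationConfig) -> np.ndarray:
    names = list(cfg.env_variables)
    idx = {v: i for i, v in enumerate(names)}
    c = np.eye(len(names))
    for a, b, r in cfg.collinearity_spec:
        if a not in idx or b not in idx:
            raise ValueError(f"unknown variable in collinearity spec: {a}, {b}")
        c[idx[a], idx[b]] = c[idx[b], idx[a]] = r
    if np.linalg.eigvalsh(c).min() < -1e-10:
        raise ValueError("collinearity targets are not positive semidefinite")
    return c


def generate_env_table(cfg: SimulationConfig) -> pd.DataFrame:
    """Positive environmental covariates with planted multicollinearity.

    A Gaussian copula realizes the target correlations; marginals are
    exponentiated (log-normal around realistic baselines) so every value is
    positive and the downstream log transform is defined.
    """
    rng = np.random.default_rng(cfg.seed + 4)
    c = _target_correlation_matrix(cfg)
    chol = np.linalg.cholesky(c + 1e-12 * np.eye(len(c)))
    z = rng.standard_normal((cfg.n_samples, len(c))) @ chol.T
    data = {}
    for j, v in enumerate(cfg.env_variables):
        mu = np.log(_ENV_BASELINES.get(v, 1.0))
        data[v] = np.exp(mu + cfg.env_sdlog * z[:, j])
    return pd.DataFrame(data, index=cfg.sample_ids)


# ---------------------------------------------------------------------------
# planted OTU-molecule correlations


def plant_correlations(
    otu: OtuTable, dom: pd.DataFrame, cfg: SimulationConfig
) -> tuple[OtuTable, pd.DataFrame]:
    """Overwrite chosen OTU and formula columns with correlated draws.

    All nodes named in ``cfg.planted_edges`` are redrawn jointly from a
    Gaussian copula whose pairwise correlations equal the targets (zero for
    unlisted pairs), then mapped to each column's original scale with a
    small log-normal spread so realized Pearson correlations stay close to
    the targets.  Untouched columns are returned unchanged up to the final
    row renormalization of the DOM table.
    """
    edges = list(cfg.planted_edges)
    if not edges:
        return otu, dom
    seen: dict[tuple[str, str], float] = {}
    for a, b, r in edges:
        if (a, b) in seen and seen[(a, b)] != r:
            raise ValueError(f"conflicting targets for edge ({a}, {b})")
        seen[(a, b)] = r
        if a not in otu.counts.columns:
            raise ValueError(f"unknown OTU {a!r}")
        if b not in dom.columns:
            raise ValueError(f"unknown formula {b!r}")

    nodes = sorted({a for a, _, _ in edges} | {b for _, b, _ in edges})
    idx = {v: i for i, v in enumerate(nodes)}
    c = np.eye(len(nodes))
    for (a, b), r in seen.items():
        c[idx[a], idx[b]] = c[idx[b], idx[a]] = r
    if np.linalg.eigvalsh(c).min() < -1e-10:
        raise ValueError("planted edge targets are not jointly feasible")

    rng = np.random.default_rng(cfg.seed + 5)
    chol = np.linalg.cholesky(c + 1e-12 * np.eye(len(c)))
    z = rng.standard_normal((otu.counts.shape[0], len(nodes))) @ chol.T

    counts = otu.counts.copy()
    dom_new = dom.copy()
    sdlog = 0.1  # small spread keeps exp() near-linear, |r| attenuation < 0.05
    for v, j in idx.items():
        col = np.exp(sdlog * z[:, j])
        if v in counts.columns and any(a == v for a, _, _ in edges):
            scale = max(float(counts[v].mean()), 100.0)
            counts[v] = np.round(scale * col).astype(int)
        else:
            scale = float(dom_new[v].mean())
            dom_new[v] = scale * col
    dom_new = dom_new.div(dom_new.sum(axis=1), axis=0)
    return OtuTable(counts=counts, taxonomy=otu.taxonomy), dom_new


def truth_manifest(cfg: SimulationConfig, **extra) -> dict:
    """Serializable ground-truth manifest for a simulation run."""
    manifest = {
        "config": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in asdict(cfg).items()
            if k != "element_ranges"
        },
        "groups": cfg.groups().to_dict(),
    }
    manifest.update(extra)
    return manifest
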