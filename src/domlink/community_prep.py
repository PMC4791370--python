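"""Preparation of OTU and environmental tables for multivariate analysis.

The OTU table is cleaned of eukaryote-, chloroplast- and mitochondria-derived
taxa, restricted to taxa with average relative abundance >= 0.1%, and
converted to relative abundances.  Environmental variables are log
transformed and normalized (z-scored) prior to any distance-based analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Taxonomy-path substrings marking non-bacterial / organelle-derived taxa.
DEFAULT_ORGANELLE_LABELS = ("Chloroplast", "Mitochondria", "Eukaryota")


@dataclass
class OtuTable:
    """Samples x taxa abundance table with taxonomy-path labels.

    ``counts`` may hold read counts or relative abundances; ``taxonomy`` maps
    each taxon column to its taxonomic path string.
    """

    counts: pd.DataFrame
    taxonomy: pd.Series = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.taxonomy is None:
            self.taxonomy = pd.Series(
                {c: str(c) for c in self.counts.columns}, dtype=object
            )
        self.taxonomy = self.taxonomy.reindex(self.counts.columns)
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("abundances must be non-negative")


def to_relative(counts: pd.DataFrame) -> pd.DataFrame:
    """Row-normalize an abundance table so each sample sums to one."""
    sums = counts.sum(axis=1)
    zero = sums[sums <= 0]
    if not zero.empty:
        raise ValueError(
            f"all-zero sample(s): {', '.join(map(str, zero.index))}"
        )
    return counts.div(sums, axis=0)


def filter_taxa(
    t: OtuTable,
    min_abundance: float = 0.001,
    organelle_labels: tuple[str, ...] = DEFAULT_ORGANELLE_LABELS,
) -> OtuTable:
    """Remove organelle/eukaryote taxa, then rare taxa.

    Organelle-derived taxa are dropped by substring match on the taxonomy
    path.  Relative abundances are recomputed on the remaining taxa before
    the mean-abundance test; taxa with mean relative abundance below
    ``min_abundance`` (inclusive threshold: exactly ``min_abundance`` is
    kept) are then removed without renormalizing.
    """
    tax = t.taxonomy.fillna("")
    organelle = tax.str.contains("|".join(organelle_labels), regex=True)
    kept = t.counts.loc[:, ~organelle.to_numpy()]
    if kept.shape[1] == 0:
        raise ValueError("no taxa left after organelle filtering")
    rel = to_relative(kept)
    abundant = rel.mean(axis=0) >= min_abundance
    out = kept.loc[:, abundant.to_numpy()]
    if out.shape[1] == 0:
        raise ValueError("no taxa left after abundance filtering")
    return OtuTable(counts=out, taxonomy=t.taxonomy.reindex(out.columns))


def transform_env(
    env: pd.DataFrame, offset: float | None = None
) -> pd.DataFrame:
    """Natural-log transform then per-column z-score of environmental data.

    Values must be positive unless an ``offset`` is supplied (added before the
    log; its use is logged in the returned frame's attrs).  Normalization uses
    the population standard deviation, so each output column has mean 0 and
    variance 1.
    """
    x = env.astype(float)
    if offset is not None:
        x = x + offset
    if (x.to_numpy() <= 0).any():
        bad = x.columns[(x <= 0).any(axis=0)]
        raise ValueError(
            f"non-positive values in column(s) {', '.join(map(str, bad))}; "
            "supply a positive offset"
        )
    logged = np.log(x)
    sd = logged.std(axis=0, ddof=0)
    degenerate = sd[sd <= 0]
    if not degenerate.empty:
        raise ValueError(
            f"zero-variance column(s): {', '.join(map(str, degenerate.index))}"
        )
    out = (logged - logged.mean(axis=0)) / sd
    out.attrs["log_offset"] = offset
    return out
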