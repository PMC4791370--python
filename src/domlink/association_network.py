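"""Pairwise OTU / DOM-formula / environment correlations and their network.

All between-block (and optionally within-block) pairwise correlations are
computed with Pearson or Spearman coefficients and two-sided p-values,
optionally Holm-Bonferroni adjusted; significant coefficients are summarized
in a pivot table of |r| bins, and high correlations (|r| >= 0.9 by default)
are exported as a graph for visualization in standard GUIs.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from functools import lru_cache
from typing import Mapping

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

#: |r| bin edges of the pivot table; half-open [lo, hi) except the last bin,
#: which is closed at 1.
PIVOT_BINS = (0.0, 0.5, 0.6, 0.7, 0.8, 0.9, 1.0)
PIVOT_LABELS = ("<0.5", "0.5-0.6", "0.6-0.7", "0.7-0.8", "0.8-0.9", "0.9-1")


def _pearson_p(r: np.ndarray, n: int) -> np.ndarray:
    """Two-sided p for a correlation via the t distribution (n-2 df)."""
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / (1.0 - r**2))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    return np.where(np.abs(r) >= 1.0, 0.0, p)


@lru_cache(maxsize=4)
def _spearman_exact_null(n: int) -> np.ndarray:
    """Sorted null distribution of Spearman rho over all n! rank orders."""
    base = np.arange(1, n + 1, dtype=float)
    rhos = [
        _corr(base, np.array(perm, dtype=float))
        for perm in itertools.permutations(range(1, n + 1))
    ]
    return np.sort(np.asarray(rhos))


def _corr(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    return float(a @ b / np.sqrt((a @ a) * (b @ b)))


def _spearman_p(rho: float, ranks_a: np.ndarray, ranks_b: np.ndarray) -> float:
    """Two-sided Spearman p: exact enumeration for n < 10 (no ties), else t."""
    n = len(ranks_a)
    ties = len(set(ranks_a)) < n or len(set(ranks_b)) < n
    if n < 10 and not ties:
        null = _spearman_exact_null(n)
        count = np.sum(np.abs(null) >= abs(rho) - 1e-12)
        return float(count / len(null))
    return float(_pearson_p(np.array([rho]), n)[0])


def pairwise_correlations(
    blocks: Mapping[str, pd.DataFrame],
    method: str = "pearson",
    within: bool = True,
) -> pd.DataFrame:
    """Pairwise correlations among features of named blocks.

    ``blocks`` maps a node kind (e.g. ``otu``, ``formula``, ``env``) to a
    samples x features table; all tables must share sample labels.  Returns
    one row per feature pair with columns node_a, kind_a, node_b, kind_b,
    r, p, method.  Zero-variance features are skipped (logged).
    """
    if method not in ("pearson", "spearman"):
        raise ValueError("method must be pearson or spearman")
    names = list(blocks)
    index = blocks[names[0]].index
    n = len(index)
    if n < 4:
        raise ValueError("need at least 4 shared samples")
    for name in names[1:]:
        if not blocks[name].index.equals(index):
            raise ValueError(f"block {name!r} has mismatched sample labels")

    cols: list[tuple[str, str]] = []
    mats = []
    for name in names:
        df = blocks[name]
        for c in df.columns:
            v = df[c].to_numpy(dtype=float)
            if np.ptp(v) == 0:
                logger.warning("skipping zero-variance feature %s/%s", name, c)
                continue
            cols.append((name, str(c)))
            mats.append(v)
    x = np.array(mats)  # features x samples
    if method == "spearman":
        ranks = np.apply_along_axis(stats.rankdata, 1, x)
        rmat = np.corrcoef(ranks)
    else:
        rmat = np.corrcoef(x)

    rows = []
    for i in range(len(cols)):
        for j in range(i + 1, len(cols)):
            kind_a, node_a = cols[i]
            kind_b, node_b = cols[j]
            if not within and kind_a == kind_b:
                continue
            r = float(rmat[i, j])
            if method == "spearman":
                ra = stats.rankdata(x[i])
                rb = stats.rankdata(x[j])
                p = _spearman_p(r, ra, rb)
            else:
                p = float(_pearson_p(np.array([r]), n)[0])
            rows.append(
                {
                    "node_a": node_a, "kind_a": kind_a,
                    "node_b": node_b, "kind_b": kind_b,
                    "r": r, "p": p, "method": method,
                }
            )
    return pd.DataFrame(
        rows, columns=["node_a", "kind_a", "node_b", "kind_b", "r", "p", "method"]
    )


def holm_bonferroni(pvals) -> np.ndarray:
    """Holm step-down adjusted p-values (monotone, clipped at 1)."""
    pvals = np.asarray(pvals, dtype=float)
    if pvals.size == 0:
        return pvals
    if ((pvals < 0) | (pvals > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(pvals, method="holm")[1]


def pivot_bins(edges: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Counts of significant correlations per |r| bin, kind pair and sign.

    Rows are (kind pair, sign); columns the |r| bins plus a Total column.
    Bins are half-open [lo, hi) except the last, closed at 1.
    """
    sig = edges[edges["p"] < alpha]
    kinds = [tuple(sorted((a, b))) for a, b in zip(sig["kind_a"], sig["kind_b"])]
    signs = np.where(sig["r"] >= 0, "positive", "negative")
    absr = sig["r"].abs().to_numpy()
    bin_idx = np.digitize(absr, PIVOT_BINS[1:], right=False)
    bin_idx = np.minimum(bin_idx, len(PIVOT_LABELS) - 1)  # |r| = 1 in last bin

    pairs = sorted(set(kinds)) or []
    rows = []
    for pair in pairs:
        for sign in ("positive", "negative"):
            mask = np.array(
                [k == pair and s == sign for k, s in zip(kinds, signs)]
            )
            counts = np.bincount(bin_idx[mask], minlength=len(PIVOT_LABELS))
            rows.append(
                {
                    "pair": f"{pair[0]}-{pair[1]}",
                    "sign": sign,
                    **dict(zip(PIVOT_LABELS, counts.tolist())),
                    "Total": int(mask.sum()),
                }
            )
    out = pd.DataFrame(
        rows, columns=["pair", "sign", *PIVOT_LABELS, "Total"]
    )
    return out.set_index(["pair", "sign"]) if len(out) else out


def multicollinearity_report(
    edges: pd.DataFrame, r_threshold: float = 0.6, alpha: float = 0.05
) -> pd.DataFrame:
    """Environment-variable pairs flagged as collinear (|r| > threshold).

    Returns the candidate pairs; which variable to drop remains the
    analyst's decision.
    """
    env = edges[(edges["kind_a"] == "env") & (edges["kind_b"] == "env")]
    flagged = env[(env["r"].abs() > r_threshold) & (env["p"] < alpha)]
    return flagged.sort_values("r", key=np.abs, ascending=False).reset_index(drop=True)


def build_network(
    edges: pd.DataFrame,
    r_threshold: float = 0.9,
    alpha: float = 0.05,
    node_attrs: Mapping[str, Mapping[str, object]] | None = None,
) -> nx.Graph:
    """Graph of high correlations (p < alpha and |r| >= r_threshold).

    Nodes are features incident to a surviving edge and carry their kind plus
    any supplied attributes (e.g. mean abundance for node size, compound
    class for color); edges carry weight |r| and a sign attribute.
    """
    g = nx.Graph()
    keep = edges[(edges["p"] < alpha) & (edges["r"].abs() >= r_threshold)]
    for row in keep.itertuples(index=False):
        for node, kind in ((row.node_a, row.kind_a), (row.node_b, row.kind_b)):
            if not g.has_node(node):
                attrs = dict(node_attrs.get(node, {})) if node_attrs else {}
                g.add_node(node, kind=kind, **attrs)
        g.add_edge(
            row.node_a,
            row.node_b,
            weight=float(abs(row.r)),
            r=float(row.r),
            sign="positive" if row.r >= 0 else "negative",
            p=float(row.p),
        )
    return g


def export_network(g: nx.Graph, prefix: str) -> None:
    """Write GraphML plus node-attribute and edge-list TSVs."""
    nx.write_graphml(g, f"{prefix}.graphml")
    nodes = pd.DataFrame.from_dict(dict(g.nodes(data=True)), orient="index")
    nodes.index.name = "node"
    nodes.to_csv(f"{prefix}.nodes.tsv", sep="\t")
    edges = nx.to_pandas_edgelist(g)
    edges.to_csv(f"{prefix}.edges.tsv", sep="\t", index=False)
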