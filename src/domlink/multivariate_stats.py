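"""Distance-based multivariate statistics for community and DOM tables.

Covers distance construction (Euclidean, Bray-Curtis, Hellinger), principal
coordinates analysis (PCoA), the ANOSIM R statistic and the non-hierarchical
k-R clustering that maximizes it, one-way PERMANOVA with permutation
p-values, classical one-way ANOVA, a two-class LDA effect-size feature
ranking (Kruskal-Wallis screen followed by bootstrap LDA scoring), distance-
based linear models (DistLM) with stepwise selection on adjusted R², their
constrained ordination (dbRDA), and the RELATE matrix rank correlation.

All permutation tests use B label permutations and report
p = (#{stat_perm >= stat_obs} + 1) / (B + 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform
from skbio.stats.distance import DistanceMatrix
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis


# ---------------------------------------------------------------------------
# distances and unconstrained ordination


def distance(
    table: pd.DataFrame,
    metric: str = "bray_curtis",
    transform: str = "none",
) -> DistanceMatrix:
    """Sample-by-sample dissimilarity matrix.

    ``transform`` is applied first: ``sqrt`` takes square roots of the
    values (the customary transform for intensity data ahead of
    Bray-Curtis), ``hellinger`` converts rows to proportions and takes
    square roots (so the Euclidean metric yields the Hellinger distance).
    """
    x = table.to_numpy(dtype=float)
    if metric in ("bray_curtis", "hellinger") and (x < 0).any():
        raise ValueError(f"{metric} requires non-negative data")
    if transform == "sqrt":
        x = np.sqrt(x)
    elif transform == "hellinger":
        x = np.sqrt(x / x.sum(axis=1, keepdims=True))
    elif transform != "none":
        raise ValueError(f"unknown transform {transform!r}")
    if metric == "euclidean":
        d = pdist(x, "euclidean")
    elif metric == "bray_curtis":
        d = pdist(x, "braycurtis")
    elif metric == "hellinger":
        if transform == "none":
            x = np.sqrt(
                table.to_numpy(dtype=float)
                / table.to_numpy(dtype=float).sum(axis=1, keepdims=True)
            )
        d = pdist(x, "euclidean")
    else:
        raise ValueError(f"unknown metric {metric!r}")
    return DistanceMatrix(squareform(d), ids=[str(i) for i in table.index])


def _gower_center(d2: np.ndarray) -> np.ndarray:
    """Gower-centered matrix G = -0.5 J D^2 J with J the centering matrix."""
    n = d2.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    return -0.5 * j @ d2 @ j


@dataclass
class OrdinationResult:
    """Sample coordinates and eigenvalues of a (constrained) ordination."""

    coordinates: pd.DataFrame
    eigenvalues: np.ndarray
    constrained: bool = False

    @property
    def proportion_explained(self) -> np.ndarray:
        pos = self.eigenvalues[self.eigenvalues > 0].sum()
        return self.eigenvalues / pos if pos > 0 else self.eigenvalues * 0.0


def pcoa(dm: DistanceMatrix) -> OrdinationResult:
    """Principal coordinates analysis.

    Eigen-decomposition of the Gower-centered squared distance matrix;
    axes are sorted by decreasing eigenvalue.  Negative eigenvalues (possible
    for semi-metric input such as Bray-Curtis) are reported unmodified;
    coordinates are returned for positive axes only.
    """
    g = _gower_center(np.asarray(dm.data) ** 2)
    evals, evecs = np.linalg.eigh(g)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    pos = evals > 1e-10 * max(abs(evals[0]), 1.0)
    coords = evecs[:, pos] * np.sqrt(evals[pos])
    frame = pd.DataFrame(
        coords,
        index=list(dm.ids),
        columns=[f"PCo{i + 1}" for i in range(coords.shape[1])],
    )
    return OrdinationResult(coordinates=frame, eigenvalues=evals, constrained=False)


# ---------------------------------------------------------------------------
# groups, ANOSIM R and k-R clustering


@dataclass
class GroupPartition:
    """Assignment of every sample to one of k non-empty groups."""

    assignment: pd.Series

    def __post_init__(self) -> None:
        self.assignment = pd.Series(self.assignment)
        counts = self.assignment.value_counts()
        if (counts < 1).any() or len(counts) < 1:
            raise ValueError("every group must be non-empty")

    @property
    def k(self) -> int:
        return self.assignment.nunique()

    def codes(self, ids) -> np.ndarray:
        aligned = self.assignment.reindex(list(ids))
        if aligned.isna().any():
            raise ValueError("samples missing from group assignment")
        return pd.factorize(aligned)[0]


def _as_codes(dm: DistanceMatrix, groups) -> np.ndarray:
    if isinstance(groups, GroupPartition):
        return groups.codes(dm.ids)
    arr = np.asarray(pd.factorize(pd.Series(list(groups)))[0])
    if arr.shape[0] != dm.shape[0]:
        raise ValueError("group vector length mismatch")
    return arr


def _rank_matrix(dm: DistanceMatrix) -> np.ndarray:
    """Square matrix of average-tie ranks of the condensed distances."""
    condensed = squareform(np.asarray(dm.data), checks=False)
    return squareform(stats.rankdata(condensed))


def _anosim_from_ranks(rank_sq: np.ndarray, codes: np.ndarray) -> float:
    n = rank_sq.shape[0]
    same = codes[:, None] == codes[None, :]
    iu = np.triu_indices(n, 1)
    within_mask = same[iu]
    ranks = rank_sq[iu]
    if not within_mask.any() or within_mask.all():
        raise ValueError("need both within- and between-group pairs")
    m = n * (n - 1) / 2
    r_within = ranks[within_mask].mean()
    r_between = ranks[~within_mask].mean()
    return float((r_between - r_within) / (m / 2.0))


def anosim_r(dm: DistanceMatrix, groups) -> float:
    """ANOSIM R statistic in [-1, 1] (average ranks on ties).

    R = (mean between-group rank - mean within-group rank) / (M/2) with
    M = n(n-1)/2 the number of sample pairs.
    """
    return _anosim_from_ranks(_rank_matrix(dm), _as_codes(dm, groups))


def kr_cluster(
    dm: DistanceMatrix,
    k: int = 2,
    restarts: int = 50,
    seed: int | None = None,
) -> tuple[GroupPartition, float]:
    """Non-hierarchical k-R clustering: partition maximizing ANOSIM R.

    Greedy single-sample reallocation from random initial partitions; a move
    that would empty a group is forbidden.  The best of ``restarts`` local
    optima is returned together with its R value.
    """
    n = dm.shape[0]
    if not 2 <= k <= n - 1:
        raise ValueError("need 2 <= k <= n-1")
    rank_sq = _rank_matrix(dm)
    if np.allclose(np.asarray(dm.data), 0):
        raise ValueError("degenerate distance matrix (all zeros)")
    rng = np.random.default_rng(seed)
    best_r, best_codes = -np.inf, None
    for _ in range(restarts):
        codes = _random_partition(rng, n, k)
        r = _anosim_from_ranks(rank_sq, codes)
        improved = True
        while improved:
            improved = False
            for i in range(n):
                current = codes[i]
                if (codes == current).sum() == 1:
                    continue  # would empty the group
                for g in range(k):
                    if g == current:
                        continue
                    codes[i] = g
                    r_new = _anosim_from_ranks(rank_sq, codes)
                    if r_new > r + 1e-12:
                        r = r_new
                        current = g
                        improved = True
                    else:
                        codes[i] = current
        if r > best_r:
            best_r, best_codes = r, codes.copy()
    assignment = pd.Series(
        [f"G{c + 1}" for c in best_codes], index=list(dm.ids)
    )
    return GroupPartition(assignment=assignment), float(best_r)


def _random_partition(rng: np.random.Generator, n: int, k: int) -> np.ndarray:
    """Random assignment of n samples to k groups, all groups non-empty."""
    codes = rng.integers(0, k, size=n)
    missing = set(range(k)) - set(codes.tolist())
    for g in missing:
        # steal a sample from some group with >= 2 members
        donors = [i for i in range(n) if (codes == codes[i]).sum() > 1]
        codes[rng.choice(donors)] = g
    return codes


# ---------------------------------------------------------------------------
# permutation tests


@dataclass
class PermutationTestResult:
    statistic: float
    p_value: float
    n_permutations: int
    seed: int | None = None
    name: str = ""


def permanova(
    dm: DistanceMatrix,
    groups,
    permutations: int = 999,
    seed: int | None = None,
) -> PermutationTestResult:
    """One-way PERMANOVA with raw label permutation.

    SS_total = (1/n) sum_{i<j} d_ij^2, SS_within = sum_g (1/n_g)
    sum_{i<j in g} d_ij^2, pseudo-F = ((SS_T - SS_W)/(k-1)) / (SS_W/(n-k)).
    """
    codes = _as_codes(dm, groups)
    d2 = np.asarray(dm.data) ** 2
    n = d2.shape[0]
    k = codes.max() + 1
    if k < 2 or n <= k:
        raise ValueError("need k >= 2 groups and n > k samples")

    f_obs = _permanova_f(d2, codes, k)
    rng = np.random.default_rng(seed)
    perms = np.array([rng.permutation(n) for _ in range(permutations)])
    f_perm = _permanova_f_batch(d2, codes, k, perms)
    p = (np.sum(f_perm >= f_obs) + 1) / (permutations + 1)
    return PermutationTestResult(
        statistic=float(f_obs), p_value=float(p),
        n_permutations=permutations, seed=seed, name="PERMANOVA pseudo-F",
    )


def _permanova_f(d2: np.ndarray, codes: np.ndarray, k: int) -> float:
    n = d2.shape[0]
    ss_total = d2[np.triu_indices(n, 1)].sum() / n
    ss_within = 0.0
    for g in range(k):
        mask = codes == g
        ng = mask.sum()
        ss_within += d2[np.ix_(mask, mask)][np.triu_indices(ng, 1)].sum() / ng
    return ((ss_total - ss_within) / (k - 1)) / (ss_within / (n - k))


def _permanova_f_batch(
    d2: np.ndarray, codes: np.ndarray, k: int, perms: np.ndarray
) -> np.ndarray:
    """Pseudo-F for many label permutations at once (vectorized)."""
    n = d2.shape[0]
    ss_total = d2[np.triu_indices(n, 1)].sum() / n
    perm_codes = codes[perms]
    ss_within = np.zeros(perms.shape[0])
    for g in range(k):
        m = (perm_codes == g).astype(float)  # B x n
        ng = m.sum(axis=1)
        quad = np.einsum("bi,ij,bj->b", m, d2, m) / 2.0
        ss_within += quad / ng
    return ((ss_total - ss_within) / (k - 1)) / (ss_within / (n - k))


def anova_oneway(values, groups) -> tuple[float, float]:
    """Classical one-way ANOVA F test on a single variable."""
    values = pd.Series(values)
    if isinstance(groups, GroupPartition):
        labels = groups.assignment.reindex(values.index)
    else:
        labels = pd.Series(list(groups), index=values.index)
    samples = [values[labels == g].to_numpy() for g in labels.unique()]
    if len(samples) < 2:
        raise ValueError("need at least two groups")
    f, p = stats.f_oneway(*samples)
    return float(f), float(p)


def relate(
    dm1: DistanceMatrix,
    dm2: DistanceMatrix,
    permutations: int = 999,
    seed: int | None = None,
) -> PermutationTestResult:
    """RELATE-style matrix correlation.

    Spearman rank correlation of corresponding off-diagonal dissimilarities;
    significance by permuting the sample identities of the second matrix.
    """
    if list(dm1.ids) != list(dm2.ids):
        raise ValueError("distance matrices must share sample labels")
    n = dm1.shape[0]
    iu = np.triu_indices(n, 1)
    r1 = stats.rankdata(np.asarray(dm1.data)[iu])
    rank2_sq = squareform(stats.rankdata(np.asarray(dm2.data)[iu]))
    rho_obs = _pearson(r1, rank2_sq[iu])
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(permutations):
        p = rng.permutation(n)
        rho = _pearson(r1, rank2_sq[np.ix_(p, p)][iu])
        if rho >= rho_obs:
            count += 1
    return PermutationTestResult(
        statistic=float(rho_obs), p_value=float((count + 1) / (permutations + 1)),
        n_permutations=permutations, seed=seed, name="RELATE rho",
    )


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    return float(a @ b / np.sqrt((a @ a) * (b @ b)))


# ---------------------------------------------------------------------------
# LDA effect-size ranking (two-class, LEfSe-style)


@dataclass
class EffectSizeResult:
    feature: str
    kw_p: float
    lda_score: float
    enriched_group: str


def effect_size_ranking(
    features: pd.DataFrame,
    groups,
    alpha: float = 0.05,
    lda_threshold: float = 2.0,
    n_boot: int = 30,
    seed: int | None = None,
) -> list[EffectSizeResult]:
    """Two-class differential-feature ranking by LDA effect size.

    Features are scaled to a per-sample sum of 10^6, screened per feature by
    the Kruskal-Wallis test at ``alpha``, and the surviving features scored
    by log10 of the bootstrap-averaged LDA-derived between-group difference
    (``n_boot`` rounds of 2/3 subsampling per class).  Features with score >=
    ``lda_threshold`` are reported with the group of higher mean.
    """
    if isinstance(groups, GroupPartition):
        labels = groups.assignment.reindex(features.index)
    else:
        labels = pd.Series(list(groups), index=features.index)
    uniq = list(pd.unique(labels))
    if len(uniq) != 2:
        raise ValueError("effect-size ranking supports exactly two groups")
    mask_a = (labels == uniq[0]).to_numpy()
    mask_b = ~mask_a
    if mask_a.sum() < 3 or mask_b.sum() < 3:
        raise ValueError("need at least 3 samples per group")

    x = features.to_numpy(dtype=float)
    x = x / x.sum(axis=1, keepdims=True) * 1e6

    kept: list[int] = []
    kw_ps: dict[int, float] = {}
    for j in range(x.shape[1]):
        a, b = x[mask_a, j], x[mask_b, j]
        if np.ptp(x[:, j]) == 0:
            continue
        _, p = stats.kruskal(a, b)
        if p < alpha:
            kept.append(j)
            kw_ps[j] = float(p)
    if not kept:
        return []

    xk = x[:, kept]
    rng = np.random.default_rng(seed)
    idx_a, idx_b = np.nonzero(mask_a)[0], np.nonzero(mask_b)[0]
    n_sub_a = max(2, int(np.floor(len(idx_a) * 2 / 3)))
    n_sub_b = max(2, int(np.floor(len(idx_b) * 2 / 3)))
    scores = np.zeros(len(kept))
    for _ in range(n_boot):
        sa = rng.choice(idx_a, size=n_sub_a, replace=False)
        sb = rng.choice(idx_b, size=n_sub_b, replace=False)
        sub = np.concatenate([sa, sb])
        y = np.concatenate([np.zeros(n_sub_a), np.ones(n_sub_b)])
        xs = xk[sub]
        gm = np.abs(xs[: n_sub_a].mean(axis=0) - xs[n_sub_a:].mean(axis=0))
        try:
            lda = LinearDiscriminantAnalysis(solver="lsqr", shrinkage="auto")
            lda.fit(xs, y)
            w = lda.coef_[0]
            norm = np.linalg.norm(w)
            w_unit = w / norm if norm > 0 else w
            proj = xs @ w_unit
            es = abs(proj[: n_sub_a].mean() - proj[n_sub_a:].mean())
            coeff = np.abs(w_unit) * es
        except np.linalg.LinAlgError:  # degenerate subsample
            coeff = np.zeros(len(kept))
        scores += (gm + coeff) / 2.0
    scores /= n_boot
    lda_scores = np.log10(1.0 + scores)

    results = []
    for pos, j in enumerate(kept):
        if lda_scores[pos] < lda_threshold:
            continue
        enriched = uniq[0] if x[mask_a, j].mean() >= x[mask_b, j].mean() else uniq[1]
        results.append(
            EffectSizeResult(
                feature=str(features.columns[j]),
                kw_p=kw_ps[j],
                lda_score=float(lda_scores[pos]),
                enriched_group=str(enriched),
            )
        )
    results.sort(key=lambda r: -r.lda_score)
    return results


# ---------------------------------------------------------------------------
# DistLM and dbRDA


@dataclass
class DistLMStep:
    action: str
    predictor: str
    pseudo_f: float
    p_value: float
    r2: float
    adj_r2: float


@dataclass
class DistLMResult:
    selected: list[str]
    steps: list[DistLMStep]
    marginal: pd.DataFrame
    r2: float
    adj_r2: float
    n_permutations: int
    seed: int | None = None


def _check_full_rank(x: pd.DataFrame) -> None:
    xc = x.to_numpy(dtype=float)
    xc = xc - xc.mean(axis=0)
    if np.linalg.matrix_rank(xc) < xc.shape[1]:
        # name a minimal set of offending columns via QR pivoting
        from scipy.linalg import qr

        _, r, piv = qr(xc, pivoting=True)
        diag = np.abs(np.diag(r)) if r.size else np.array([])
        rank = int((diag > 1e-8 * (diag.max() if diag.size else 1)).sum())
        bad = [str(x.columns[j]) for j in piv[rank:]]
        raise ValueError(
            "collinear predictor columns (drop before modelling): "
            + ", ".join(bad)
        )


def _hat(xc: np.ndarray) -> np.ndarray:
    q, _ = np.linalg.qr(xc)
    return q @ q.T


def _r2_f(g: np.ndarray, xc: np.ndarray) -> tuple[float, float, float]:
    """(R2, adjusted R2, pseudo-F) for a centered predictor matrix."""
    n, m = xc.shape
    h = _hat(xc)
    tr_g = np.trace(g)
    tr_hgh = float(np.sum(h * g))  # tr(HGH) = tr(GH) for idempotent H
    r2 = tr_hgh / tr_g
    denom_df = n - m - 1
    resid = tr_g - tr_hgh
    if denom_df <= 0:  # saturated model: no residual degrees of freedom
        return r2, -np.inf, np.inf
    f = (tr_hgh / m) / (resid / denom_df) if resid > 1e-12 else np.inf
    adj = 1.0 - (1.0 - r2) * (n - 1) / denom_df
    return r2, adj, f


def distlm(
    dm: DistanceMatrix,
    x: pd.DataFrame,
    permutations: int = 999,
    seed: int | None = None,
) -> DistLMResult:
    """Distance-based linear model with stepwise selection on adjusted R².

    For a predictor set with hat matrix H and Gower-centered G:
    R² = tr(HGH)/tr(G); pseudo-F = (tr(HGH)/m) / (tr((I-H)G(I-H))/(n-m-1)).
    Marginal tests per single predictor and sequential tests per accepted
    step use permutation of the sample identities of G.  Stepwise selection
    alternates forward additions and backward drops accepted when they
    increase adjusted R², stopping at a local optimum.
    """
    ids = list(dm.ids)
    lookup = {str(i): i for i in x.index}
    if all(i in lookup for i in ids):
        x = x.loc[[lookup[i] for i in ids]]
    elif x.shape[0] != len(ids):
        raise ValueError("predictor table must cover all samples")
    if x.shape[1] >= len(ids) - 1:
        raise ValueError("too many predictors for the sample size")
    _check_full_rank(x)

    g = _gower_center(np.asarray(dm.data) ** 2)
    n = g.shape[0]
    xc_all = x.to_numpy(dtype=float)
    xc_all = xc_all - xc_all.mean(axis=0)
    rng = np.random.default_rng(seed)
    perms = np.array([rng.permutation(n) for _ in range(permutations)])
    g_perm = g[perms[:, :, None], perms[:, None, :]]  # B x n x n

    # marginal tests
    rows = []
    for j, name in enumerate(x.columns):
        xc = xc_all[:, [j]]
        r2, adj, f = _r2_f(g, xc)
        h = _hat(xc)
        tr_hgh_p = np.einsum("ij,bij->b", h, g_perm)
        tr_gp = np.trace(g)
        resid_p = tr_gp - tr_hgh_p
        f_p = np.where(
            resid_p > 1e-12,
            (tr_hgh_p / 1) / (resid_p / (n - 2)),
            np.inf,
        )
        p = (np.sum(f_p >= f - 1e-12) + 1) / (permutations + 1)
        rows.append(
            {"predictor": str(name), "pseudo_f": f, "p_value": float(p), "r2": r2}
        )
    marginal = pd.DataFrame(rows).set_index("predictor")

    # stepwise selection on adjusted R2
    selected: list[int] = []
    steps: list[DistLMStep] = []
    current_adj = 0.0
    improved = True
    while improved:
        improved = False
        # forward
        best_j, best_adj = None, current_adj
        for j in range(x.shape[1]):
            if j in selected:
                continue
            r2, adj, _ = _r2_f(g, xc_all[:, selected + [j]])
            if adj > best_adj + 1e-12:
                best_j, best_adj = j, adj
        if best_j is not None:
            new_sel = selected + [best_j]
            r2, adj, f_step = _seq_stats(g, xc_all, selected, best_j)
            p = _seq_perm_p(g, g_perm, xc_all, selected, best_j, f_step, n)
            selected = new_sel
            current_adj = best_adj
            steps.append(
                DistLMStep(
                    action="add", predictor=str(x.columns[best_j]),
                    pseudo_f=f_step, p_value=p, r2=r2, adj_r2=adj,
                )
            )
            improved = True
        # backward
        if len(selected) > 1:
            best_drop, best_adj = None, current_adj
            for j in selected:
                rest = [s for s in selected if s != j]
                r2, adj, _ = _r2_f(g, xc_all[:, rest])
                if adj > best_adj + 1e-12:
                    best_drop, best_adj = j, adj
            if best_drop is not None:
                selected = [s for s in selected if s != best_drop]
                current_adj = best_adj
                r2, adj, _ = _r2_f(g, xc_all[:, selected])
                steps.append(
                    DistLMStep(
                        action="drop", predictor=str(x.columns[best_drop]),
                        pseudo_f=np.nan, p_value=np.nan, r2=r2, adj_r2=adj,
                    )
                )
                improved = True

    if selected:
        r2, adj, _ = _r2_f(g, xc_all[:, selected])
    else:
        r2, adj = 0.0, 0.0
    return DistLMResult(
        selected=[str(x.columns[j]) for j in selected],
        steps=steps,
        marginal=marginal,
        r2=float(r2),
        adj_r2=float(adj),
        n_permutations=permutations,
        seed=seed,
    )


def _seq_stats(g, xc_all, selected, j):
    """R2/adjusted-R2 of the extended model and the sequential pseudo-F."""
    n = g.shape[0]
    new = selected + [j]
    r2_new, adj_new, _ = _r2_f(g, xc_all[:, new])
    tr_g = np.trace(g)
    tr_new = r2_new * tr_g
    tr_old = (
        _r2_f(g, xc_all[:, selected])[0] * tr_g if selected else 0.0
    )
    m_new = len(new)
    resid = tr_g - tr_new
    f = ((tr_new - tr_old) / 1) / (resid / (n - m_new - 1)) if resid > 1e-12 else np.inf
    return r2_new, adj_new, f


def _seq_perm_p(g, g_perm, xc_all, selected, j, f_obs, n):
    new = selected + [j]
    h_new = _hat(xc_all[:, new])
    h_old = _hat(xc_all[:, selected]) if selected else np.zeros_like(g)
    tr_gp = np.trace(g)
    tr_new_p = np.einsum("ij,bij->b", h_new, g_perm)
    tr_old_p = (
        np.einsum("ij,bij->b", h_old, g_perm) if selected else np.zeros(len(g_perm))
    )
    resid_p = tr_gp - tr_new_p
    f_p = np.where(
        resid_p > 1e-12,
        (tr_new_p - tr_old_p) / (resid_p / (n - len(new) - 1)),
        np.inf,
    )
    return float((np.sum(f_p >= f_obs - 1e-12) + 1) / (len(g_perm) + 1))


def dbrda(dm: DistanceMatrix, x_selected: pd.DataFrame) -> OrdinationResult:
    """Distance-based redundancy analysis of the fitted DistLM model.

    Eigen-decomposition of HGH with H the hat matrix of the (centered)
    selected predictors; constrained axes are those with eigenvalue above
    numerical tolerance.
    """
    if x_selected.shape[1] == 0:
        raise ValueError("empty predictor selection")
    _check_full_rank(x_selected)
    g = _gower_center(np.asarray(dm.data) ** 2)
    xc = x_selected.to_numpy(dtype=float)
    xc = xc - xc.mean(axis=0)
    h = _hat(xc)
    hgh = h @ g @ h
    evals, evecs = np.linalg.eigh((hgh + hgh.T) / 2)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    tol = 1e-8 * max(abs(evals).max(), 1.0)
    pos = evals > tol
    coords = evecs[:, pos] * np.sqrt(evals[pos])
    frame = pd.DataFrame(
        coords,
        index=list(dm.ids),
        columns=[f"dbRDA{i + 1}" for i in range(coords.shape[1])],
    )
    return OrdinationResult(coordinates=frame, eigenvalues=evals, constrained=True)
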