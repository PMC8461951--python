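"""Sample-level statistics: PCA, sample clustering, serum-marker group tests.

The group tests mirror common serum-marker practice: Mann-Whitney U for
two groups (exact enumeration at small sample sizes, normal approximation
with tie correction otherwise), Kruskal-Wallis with Dunn's post test for
three or more groups, and Welch's t with a recorded Shapiro normality
check when a parametric test is requested.

The asymptotic Mann-Whitney path deliberately omits the continuity
correction so that for two groups its p-value coincides exactly with the
Kruskal-Wallis chi-square p (H = z^2 with matching tie correction).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .containers import ExpressionMatrix, ValidationError
from .refmap import upgma_linkage

__all__ = [
    "PCAResult",
    "GroupTestResult",
    "pca_explained_variance",
    "cluster_samples",
    "two_group_test",
    "multi_group_test",
    "EXACT_MAX_N",
]

# both groups at or below this size -> exact permutation enumeration
EXACT_MAX_N = 8


@dataclass
class PCAResult:
    explained_variance_ratio: np.ndarray
    scores: pd.DataFrame  # samples x components
    loadings: pd.DataFrame  # features x components


@dataclass
class GroupTestResult:
    test: str
    statistic: float
    p: float
    group_sizes: dict[str, int]
    normality: dict[str, float] | None = None
    posthoc: pd.DataFrame | None = None
    notes: list[str] = field(default_factory=list)


def pca_explained_variance(
    matrix: ExpressionMatrix, n_components: int = 3, scale: bool = False
) -> PCAResult:
    """PCA of samples using the given (signature-restricted) matrix.

    Features are centered (optionally unit-scaled) before decomposition.
    Sign convention: within each component the largest-magnitude feature
    loading is made positive, so scores are deterministic.
    """
    from sklearn.decomposition import PCA

    X = matrix.values.to_numpy(float).T  # samples x features
    n_samples, n_features = X.shape
    if n_samples < 3:
        raise ValidationError("PCA needs >= 3 samples")
    if n_components > min(n_samples, n_features):
        raise ValidationError(
            f"n_components={n_components} exceeds min(n_samples, n_features)="
            f"{min(n_samples, n_features)}"
        )
    if scale:
        sd = X.std(axis=0)
        sd[sd == 0] = 1.0
        X = X / sd
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(X)
    components = pca.components_
    for i in range(n_components):
        j = np.argmax(np.abs(components[i]))
        if components[i, j] < 0:
            components[i] *= -1.0
            scores[:, i] *= -1.0
    cols = [f"PC{i + 1}" for i in range(n_components)]
    return PCAResult(
        explained_variance_ratio=pca.explained_variance_ratio_,
        scores=pd.DataFrame(scores, index=matrix.samples, columns=cols),
        loadings=pd.DataFrame(components.T, index=matrix.features, columns=cols),
    )


def cluster_samples(matrix: ExpressionMatrix, zscale: bool = True) -> tuple[np.ndarray, list[str]]:
    """UPGMA dendrogram over samples (Euclidean on z-scaled feature vectors).

    Returns the linkage matrix and the sample IDs in leaf order.  Uses the
    same clustering engine as the co-expression mapping.
    """
    from scipy.cluster import hierarchy

    X = matrix.values.to_numpy(float)
    if X.shape[1] < 2:
        raise ValidationError("need >= 2 samples to cluster")
    if zscale:
        mean = X.mean(axis=1, keepdims=True)
        sd = X.std(axis=1, keepdims=True)
        sd[sd == 0] = 1.0
        X = (X - mean) / sd
    Z = upgma_linkage(X.T)
    leaves = [matrix.samples[i] for i in hierarchy.leaves_list(Z)]
    return Z, leaves


def _two_groups(values, labels) -> tuple[np.ndarray, np.ndarray, str, str]:
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    levels = list(dict.fromkeys(labels))
    if len(levels) != 2:
        raise ValidationError(f"need exactly 2 groups, got {levels}")
    a, b = levels
    x = values[labels == a]
    y = values[labels == b]
    if len(x) < 2 or len(y) < 2:
        raise ValidationError("need >= 2 values per group")
    return x, y, a, b


def _mannwhitney_u(x: np.ndarray, y: np.ndarray) -> float:
    """U statistic for x vs y with half-credit for ties."""
    ranks = stats.rankdata(np.concatenate([x, y]))
    n = len(x)
    return float(ranks[:n].sum() - n * (n + 1) / 2.0)


def exact_mannwhitney_p(x, y) -> tuple[float, float]:
    """Exact two-sided Mann-Whitney p by full permutation enumeration.

    Enumerates all C(n+m, n) relabelings; the two-sided p is the null
    probability of a U at least as far from nm/2 as observed.  Under
    exchangeability the permutation distribution of U is symmetric about
    nm/2 (swapping labels maps U to nm - U), so this coincides with the
    doubled single tail in the tie-free case.  Valid with ties.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n, m = len(x), len(y)
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    offset = n * (n + 1) / 2.0
    u_obs = float(ranks[:n].sum() - offset)
    center = n * m / 2.0
    idx = np.fromiter(
        (i for comb in combinations(range(n + m), n) for i in comb), dtype=np.intp
    ).reshape(-1, n)
    u_all = ranks[idx].sum(axis=1) - offset
    p = float(np.mean(np.abs(u_all - center) >= abs(u_obs - center) - 1e-9))
    return u_obs, p


def two_group_test(
    values,
    labels,
    test: str = "mannwhitney",
    normality_gate: bool = False,
) -> GroupTestResult:
    """Two-group comparison of a serum marker or any scalar readout.

    ``test="mannwhitney"`` uses exact enumeration when both groups have at
    most ``EXACT_MAX_N`` observations, otherwise the tie-corrected normal
    approximation (no continuity correction).  ``test="t_welch"`` runs
    Welch's t; with ``normality_gate`` a per-group Shapiro-Wilk p is
    recorded alongside (the gate is advisory, not a hard switch).
    """
    x, y, a, b = _two_groups(values, labels)
    sizes = {a: len(x), b: len(y)}
    notes: list[str] = []
    normality = None
    if np.ptp(np.concatenate([x, y])) == 0:
        notes.append("constant data in both groups; p set to 1")
        return GroupTestResult(test, 0.0, 1.0, sizes, None, None, notes)

    if test == "mannwhitney":
        if len(x) <= EXACT_MAX_N and len(y) <= EXACT_MAX_N:
            u, p = exact_mannwhitney_p(x, y)
            notes.append("exact permutation enumeration")
        else:
            res = stats.mannwhitneyu(
                x, y, alternative="two-sided", method="asymptotic", use_continuity=False
            )
            u, p = float(res.statistic), float(res.pvalue)
            notes.append("normal approximation with tie correction")
        return GroupTestResult("mannwhitney", u, p, sizes, None, None, notes)
    if test == "t_welch":
        if normality_gate:
            normality = {
                a: float(stats.shapiro(x).pvalue),
                b: float(stats.shapiro(y).pvalue),
            }
            if min(normality.values()) < 0.05:
                notes.append("Shapiro normality check failed at alpha=0.05 for >=1 group")
        t, p = stats.ttest_ind(x, y, equal_var=False)
        return GroupTestResult("t_welch", float(t), float(p), sizes, normality, None, notes)
    raise ValidationError(f"unknown test {test!r}")


def _dunn_posthoc(values: np.ndarray, labels: np.ndarray, adjust: str) -> pd.DataFrame:
    """Dunn's pairwise z-tests on mean ranks with tie correction."""
    from statsmodels.stats.multitest import multipletests

    N = len(values)
    ranks = stats.rankdata(values)
    levels = list(dict.fromkeys(labels))
    mean_rank = {g: ranks[labels == g].mean() for g in levels}
    ns = {g: int((labels == g).sum()) for g in levels}
    _, tie_counts = np.unique(values, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts)) / (12.0 * (N - 1))
    var_unit = N * (N + 1) / 12.0 - tie_term
    rows = []
    for g1, g2 in combinations(levels, 2):
        se = np.sqrt(var_unit * (1.0 / ns[g1] + 1.0 / ns[g2]))
        z = (mean_rank[g1] - mean_rank[g2]) / se
        rows.append({"group_a": g1, "group_b": g2, "z": z, "p": 2.0 * stats.norm.sf(abs(z))})
    table = pd.DataFrame(rows)
    if adjust == "bonferroni":
        table["p_adj"] = np.minimum(table["p"] * len(table), 1.0)
    elif adjust == "holm":
        table["p_adj"] = multipletests(table["p"], method="holm")[1]
    elif adjust == "none":
        table["p_adj"] = table["p"]
    else:
        raise ValidationError(f"unknown adjustment {adjust!r}")
    return table


def multi_group_test(values, labels, adjust: str = "bonferroni") -> GroupTestResult:
    """Kruskal-Wallis omnibus test with Dunn's post-hoc pairwise table.

    Requires >= 3 groups, each of size >= 2.  All-equal data yields H=0,
    p=1.  The post-hoc adjustment defaults to Bonferroni over pairs.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    levels = list(dict.fromkeys(labels))
    if len(levels) < 3:
        raise ValidationError(f"need >= 3 groups, got {len(levels)}")
    sizes = {g: int((labels == g).sum()) for g in levels}
    small = [g for g, n in sizes.items() if n < 2]
    if small:
        raise ValidationError(f"groups of size < 2: {small}")
    notes: list[str] = []
    if np.ptp(values) == 0:
        posthoc = pd.DataFrame(
            [
                {"group_a": g1, "group_b": g2, "z": 0.0, "p": 1.0, "p_adj": 1.0}
                for g1, g2 in combinations(levels, 2)
            ]
        )
        notes.append("all values equal; H=0")
        return GroupTestResult("kruskal_wallis", 0.0, 1.0, sizes, None, posthoc, notes)
    groups = [values[labels == g] for g in levels]
    h, p = stats.kruskal(*groups)
    posthoc = _dunn_posthoc(values, labels, adjust)
    return GroupTestResult("kruskal_wallis", float(h), float(p), sizes, None, posthoc, notes)
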