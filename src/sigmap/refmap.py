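"""Signature-to-reference co-expression mapping: the core procedure.

Given an up- or down-signature and a labeled reference compendium, the
chain is:

1. quantile-normalize the compendium so every sample shares the common
   mean distribution of order statistics;
2. restrict the compendium to the signature features;
3. compute the Pearson gene-gene correlation matrix across the reference
   samples;
4. hierarchically cluster the correlation matrix with average linkage
   (UPGMA), each feature represented by its row of correlations and
   distances taken as Euclidean between those rows (a 1-r dissimilarity
   mode is available behind a flag);
5. cut the dendrogram into clusters (fixed k, height, or silhouette-chosen
   k) and attribute each cluster to the reference group in which its
   features are most highly expressed, using per-feature z-scaled
   intensities clipped to [-2, +2];
6. render the ordered relative-intensity heatmap and export its matrix.

Cluster-to-group attribution makes the usual visual readout ("this
co-expression cluster is high in late granulopoiesis and neutrophils")
quantitative and testable.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform

from .containers import (
    CoexpressionResult,
    ExpressionMatrix,
    ReferenceCompendium,
    Signature,
    ValidationError,
)

logger = logging.getLogger(__name__)

__all__ = [
    "quantile_normalize",
    "extract_signature_submatrix",
    "gene_gene_correlation",
    "cluster_correlation_matrix",
    "cut_clusters",
    "choose_k_silhouette",
    "scale_display",
    "attribute_clusters",
    "render_ordered_heatmap",
    "map_signature",
    "upgma_linkage",
    "linkage_to_newick",
]


def quantile_normalize(compendium: ReferenceCompendium) -> ReferenceCompendium:
    """Force every sample onto the common mean distribution of order statistics.

    After normalization the sorted value vector of each sample equals the
    across-sample mean of order statistics.  Tied values within a sample
    all receive the mean of the order statistics their positions span.
    Idempotent; labels preserved.
    """
    X = compendium.expr.values.to_numpy(float)
    if X.shape[1] < 2:
        raise ValidationError("quantile normalization needs >= 2 samples")
    if not np.isfinite(X).all():
        bad = np.argwhere(~np.isfinite(X))
        cells = [
            (compendium.expr.features[i], compendium.expr.samples[j]) for i, j in bad[:10]
        ]
        raise ValidationError(f"non-finite values at cells: {cells}")
    sorted_X = np.sort(X, axis=0)
    if (sorted_X == sorted_X[:, [0]]).all():
        # already harmonized: the mean of identical order statistics is the
        # column itself; taking it directly keeps idempotence bit-exact
        ref = sorted_X[:, 0].copy()
    else:
        ref = sorted_X.mean(axis=1)
    out = np.empty_like(X)
    for j in range(X.shape[1]):
        col = X[:, j]
        order = np.argsort(col, kind="stable")
        assigned = np.empty_like(ref)
        assigned[order] = ref
        # ties: every tied value gets the mean of the order statistics it spans
        out[:, j] = pd.Series(assigned).groupby(col, sort=False).transform("mean").to_numpy()
    values = pd.DataFrame(out, index=compendium.expr.features, columns=compendium.expr.samples)
    return ReferenceCompendium(
        ExpressionMatrix(values, scale=compendium.expr.scale), compendium.sample_meta.copy()
    )


def extract_signature_submatrix(
    compendium: ReferenceCompendium, features
) -> tuple[ExpressionMatrix, list[str]]:
    """Restrict the compendium to signature features, in signature order.

    Returns the submatrix and the list of signature features absent from
    the compendium.  Zero overlap is an error (nothing to map).
    """
    if isinstance(features, Signature):
        features = features.features
    features = list(features)
    present = [f for f in features if f in compendium.expr.features]
    missing = [f for f in features if f not in compendium.expr.features]
    if not present:
        raise ValidationError("no signature feature is present in the compendium")
    if missing:
        logger.info("%d signature features missing from compendium", len(missing))
    sub = compendium.expr.values.loc[present]
    return ExpressionMatrix(sub, scale=compendium.expr.scale), missing


def gene_gene_correlation(submatrix: ExpressionMatrix) -> tuple[pd.DataFrame, list[str]]:
    """Pearson correlation of every feature pair across reference samples.

    Zero-variance features cannot be correlated; they are excluded and
    returned as the second element.  Requires >= 3 samples.
    """
    X = submatrix.values.to_numpy(float)
    if X.shape[1] < 3:
        raise ValidationError("gene-gene correlation needs >= 3 reference samples")
    sd = X.std(axis=1)
    flat = sd == 0
    excluded = submatrix.features[flat].tolist()
    keep = submatrix.features[~flat]
    if len(keep) < 2:
        raise ValidationError("fewer than 2 features with nonzero variance")
    R = np.corrcoef(X[~flat])
    np.fill_diagonal(R, 1.0)
    return pd.DataFrame(R, index=keep, columns=keep), excluded


def upgma_linkage(X: np.ndarray) -> np.ndarray:
    """Average-linkage (UPGMA) merge history on Euclidean row distances."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValidationError("need a 2-D array with >= 2 rows")
    return hierarchy.linkage(pdist(X, metric="euclidean"), method="average")


def cluster_correlation_matrix(
    R: pd.DataFrame, representation: str = "rows"
) -> tuple[np.ndarray, list[str]]:
    """UPGMA clustering of the gene-gene correlation matrix.

    ``representation="rows"`` (default) treats each feature as its vector
    of correlations to all features and uses Euclidean distance between
    those rows.  ``representation="dissimilarity"`` uses 1 - r directly as
    the pairwise dissimilarity.  Returns the SciPy linkage matrix and the
    dendrogram leaf order (feature IDs).
    """
    if R.shape[0] != R.shape[1]:
        raise ValidationError(f"correlation matrix must be square, got {R.shape}")
    X = R.to_numpy(float)
    if not np.isfinite(X).all():
        raise ValidationError("correlation matrix contains non-finite values")
    if representation == "rows":
        Z = upgma_linkage(X)
    elif representation == "dissimilarity":
        D = 1.0 - X
        np.fill_diagonal(D, 0.0)
        Z = hierarchy.linkage(squareform(D, checks=False), method="average")
    else:
        raise ValidationError(f"unknown representation {representation!r}")
    leaves = [R.index[i] for i in hierarchy.leaves_list(Z)]
    return Z, leaves


def cut_clusters(Z: np.ndarray, k: int | None = None, height: float | None = None) -> np.ndarray:
    """Cut a dendrogram into flat clusters.

    Exactly one of ``k`` (number of clusters) or ``height`` (merge-height
    threshold) must be given.  Labels are 1-based and relabeled by first
    occurrence, so they are stable across runs.
    """
    n = Z.shape[0] + 1
    if (k is None) == (height is None):
        raise ValidationError("give exactly one of k or height")
    if k is not None:
        if not 1 <= k <= n:
            raise ValidationError(f"k must be in [1, {n}], got {k}")
        labels = hierarchy.cut_tree(Z, n_clusters=k).ravel()
    else:
        labels = hierarchy.fcluster(Z, t=height, criterion="distance")
    relabel: dict[int, int] = {}
    out = np.empty(n, dtype=int)
    for i, lab in enumerate(labels):
        if lab not in relabel:
            relabel[lab] = len(relabel) + 1
        out[i] = relabel[lab]
    return out


def choose_k_silhouette(X: np.ndarray, Z: np.ndarray, k_range=range(2, 11)) -> int:
    """Pick the cut size k maximizing the mean silhouette over ``k_range``.

    ``X`` is the representation the clustering ran on (rows of the
    correlation matrix).  k values exceeding n-1 are skipped.
    """
    from sklearn.metrics import silhouette_score

    n = X.shape[0]
    best_k, best_s = 2, -np.inf
    for k in k_range:
        if k >= n:
            break
        labels = cut_clusters(Z, k=k)
        s = silhouette_score(X, labels, metric="euclidean")
        if s > best_s:
            best_k, best_s = k, s
    return best_k


def scale_display(submatrix: ExpressionMatrix, clip: float = 2.0) -> pd.DataFrame:
    """Per-feature z-score across reference samples, clipped to +-clip.

    The heatmap convention: red is above the feature mean (max +2), blue
    below (min -2).  Zero-variance features map to all-zero rows.
    """
    X = submatrix.values.to_numpy(float)
    mean = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        Z = (X - mean) / sd
    Z[np.isnan(Z)] = 0.0
    Z = np.clip(Z, -clip, clip)
    return pd.DataFrame(Z, index=submatrix.features, columns=submatrix.samples)


def attribute_clusters(
    clusters: pd.Series, display: pd.DataFrame, groups: pd.Series
) -> tuple[pd.DataFrame, pd.Series]:
    """Score every (cluster, reference group) pair and rank groups.

    score(c, g) = mean over features of cluster c of the mean scaled
    intensity over the samples of group g.  Returns the full score table
    (clusters x groups) and the top-scoring group per cluster.  Clusters
    with no features in the display matrix are dropped with a warning.
    """
    groups = groups.reindex(display.columns)
    if groups.isna().any():
        raise ValidationError("group labels missing for some reference samples")
    group_levels = list(dict.fromkeys(groups))
    # mean scaled intensity per feature per group
    per_group = {
        g: display.loc[:, groups.index[groups == g]].mean(axis=1) for g in group_levels
    }
    per_group_df = pd.DataFrame(per_group)
    rows = {}
    for c in sorted(clusters.unique()):
        members = clusters.index[clusters == c]
        members = members.intersection(display.index)
        if len(members) == 0:
            warnings.warn(f"cluster {c} has no features in the display matrix; skipped")
            continue
        rows[c] = per_group_df.loc[members].mean(axis=0)
    if not rows:
        raise ValidationError("no non-empty cluster to attribute")
    table = pd.DataFrame(rows).T
    table.index.name = "cluster"
    top = table.idxmax(axis=1)
    top.name = "top_group"
    return table, top


def render_ordered_heatmap(
    display: pd.DataFrame,
    leaf_order,
    sample_order=None,
    image_path=None,
    matrix_path=None,
    clip: float = 2.0,
    dpi: int = 150,
):
    """Render the leaf-ordered relative-intensity heatmap.

    Rows follow the dendrogram leaf order; columns follow the declared
    reference sample order (default: current column order).  The color
    scale is fixed to [-clip, +clip] with red high and blue low, and the
    ordered numeric matrix is exported alongside so the figure can be
    regenerated bit-exactly.  Returns the ordered matrix.
    """
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    ordered = display.loc[list(leaf_order)]
    if sample_order is not None:
        ordered = ordered[list(sample_order)]
    if matrix_path is not None:
        ordered.to_csv(matrix_path, sep="\t", index_label="feature_id")
    if image_path is not None:
        fig, ax = plt.subplots(
            figsize=(max(4.0, ordered.shape[1] * 0.12), max(3.0, ordered.shape[0] * 0.02))
        )
        im = ax.imshow(
            ordered.to_numpy(float), aspect="auto", cmap="RdBu_r", vmin=-clip, vmax=clip,
            interpolation="nearest",
        )
        ax.set_xticks([])
        ax.set_yticks([])
        ax.set_xlabel("reference samples")
        ax.set_ylabel("signature features (leaf order)")
        fig.colorbar(im, ax=ax, label="scaled intensity")
        fig.savefig(image_path, dpi=dpi)
        plt.close(fig)
    return ordered


def linkage_to_newick(Z: np.ndarray, leaf_names) -> str:
    """Serialize a SciPy linkage matrix as a Newick string with heights."""
    tree = hierarchy.to_tree(Z)
    leaf_names = list(leaf_names)

    def recurse(node, parent_height: float) -> str:
        length = max(parent_height - node.dist, 0.0)
        if node.is_leaf():
            return f"{leaf_names[node.id]}:{length:g}"
        left = recurse(node.left, node.dist)
        right = recurse(node.right, node.dist)
        return f"({left},{right}):{length:g}"

    return recurse(tree, tree.dist) + ";"


def map_signature(
    features,
    compendium: ReferenceCompendium,
    *,
    already_normalized: bool = False,
    representation: str = "rows",
    k: int | None = None,
    height: float | None = None,
    clip: float = 2.0,
) -> CoexpressionResult:
    """Run the full chain from feature list to attributed co-expression clusters.

    If neither ``k`` nor ``height`` is given, k is chosen by maximum mean
    silhouette over k in [2, 10].
    """
    if not already_normalized:
        compendium = quantile_normalize(compendium)
    sub, missing = extract_signature_submatrix(compendium, features)
    R, zero_var = gene_gene_correlation(sub)
    Z, leaves = cluster_correlation_matrix(R, representation=representation)
    if k is None and height is None:
        k = choose_k_silhouette(R.to_numpy(float), Z)
    labels = cut_clusters(Z, k=k, height=height)
    clusters = pd.Series(labels, index=R.index, name="cluster")
    kept = ExpressionMatrix(sub.values.loc[R.index], scale=sub.scale)
    display = scale_display(kept, clip=clip)
    attribution, top = attribute_clusters(clusters, display, compendium.groups)
    return CoexpressionResult(
        features=list(R.index),
        correlation=R,
        linkage=Z,
        leaf_order=leaves,
        clusters=clusters,
        attribution=attribution,
        top_groups=top,
        display=display,
        missing_features=missing,
        zero_variance_features=zero_var,
    )
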