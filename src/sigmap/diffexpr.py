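"""Two-group differential-expression scoring and signature construction.

Two scorers are provided.  ``score_two_group`` is a standard per-feature
Welch t or rank-sum test with Benjamini-Hochberg control and linear fold
changes of group means.  ``score_pairwise_concordance`` scores each
feature by the fraction of case x control pairs in which the case value
exceeds the control value, mapped to a signed score in [-100, 100]; it is
distribution-free and invariant under strictly monotone transforms, and
echoes the score-thresholding idiom of pairwise chip-data scoring schemes
whose exact internals are not published.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import ExpressionMatrix, Signature, ValidationError

__all__ = [
    "score_two_group",
    "score_pairwise_concordance",
    "center_batches",
    "signature_from_scores",
]


def _split_columns(matrix: ExpressionMatrix, labels: pd.Series) -> tuple[list[str], list[str], str, str]:
    labels = labels.reindex(matrix.samples)
    if labels.isna().any():
        missing = matrix.samples[labels.isna()].tolist()
        raise ValidationError(f"labels missing for samples: {missing[:10]}")
    levels = list(dict.fromkeys(labels))
    if len(levels) != 2:
        raise ValidationError(f"need exactly 2 groups, got {levels}")
    a, b = levels
    ga = labels.index[labels == a].tolist()
    gb = labels.index[labels == b].tolist()
    if len(ga) < 2 or len(gb) < 2:
        raise ValidationError("need >= 2 samples per group")
    return ga, gb, a, b


def _fold_change(matrix: ExpressionMatrix, group_a, group_b) -> np.ndarray:
    """Linear-scale ratio of group means (log input exponentiated first)."""
    linear = matrix.linear()
    mean_a = linear[group_a].mean(axis=1).to_numpy(float)
    mean_b = linear[group_b].mean(axis=1).to_numpy(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        return mean_a / mean_b


def score_two_group(
    matrix: ExpressionMatrix,
    labels: pd.Series,
    method: str = "welch_t",
    alpha: float = 0.05,
    mt_procedure: str = "bh",
    contrast: str | None = None,
) -> tuple[Signature, pd.DataFrame]:
    """Score every feature for a two-group contrast and build a signature.

    The first label level (in column order) is treated as the case group;
    fold changes are case over control.  Features with zero variance in
    both groups get statistic 0 and p 1 rather than an exception.

    Returns the Signature (features with adjusted p < alpha, split by
    direction) and the full per-feature score table.
    """
    if method not in ("welch_t", "rank_sum"):
        raise ValidationError(f"unknown method {method!r}")
    ga, gb, label_a, label_b = _split_columns(matrix, labels)
    A = matrix.values[ga].to_numpy(float)
    B = matrix.values[gb].to_numpy(float)

    flat = (A.var(axis=1) == 0) & (B.var(axis=1) == 0)
    if method == "welch_t":
        with np.errstate(divide="ignore", invalid="ignore"):
            stat, p = stats.ttest_ind(A, B, axis=1, equal_var=False)
    else:
        res = stats.mannwhitneyu(A, B, axis=1, alternative="two-sided", method="asymptotic")
        stat, p = res.statistic, res.pvalue
    stat = np.asarray(stat, dtype=float)
    p = np.asarray(p, dtype=float)
    stat[flat] = 0.0
    p[flat] = 1.0
    p = np.where(np.isnan(p), 1.0, p)

    if mt_procedure == "bh":
        p_adj = multipletests(p, method="fdr_bh")[1]
    elif mt_procedure == "bonferroni":
        p_adj = multipletests(p, method="bonferroni")[1]
    elif mt_procedure == "none":
        p_adj = p.copy()
    else:
        raise ValidationError(f"unknown mt_procedure {mt_procedure!r}")

    fc = _fold_change(matrix, ga, gb)
    scores = pd.DataFrame(
        {
            "feature_id": matrix.features,
            "score": stat,
            "p": p,
            "p_adj": p_adj,
            "fold_change": fc,
        }
    )
    contrast = contrast or f"{label_a}_vs_{label_b}"
    return signature_from_scores(scores, alpha=alpha, contrast=contrast), scores


def signature_from_scores(scores: pd.DataFrame, alpha: float, contrast: str) -> Signature:
    """Keep features with p_adj < alpha and a non-unit fold change."""
    sig = scores[(scores["p_adj"] < alpha) & (scores["fold_change"] != 1.0)].copy()
    sig["direction"] = np.where(sig["fold_change"] > 1.0, "up", "down")
    sig = sig[["feature_id", "direction", "score", "p", "p_adj", "fold_change"]]
    return Signature(contrast, sig.reset_index(drop=True))


def score_pairwise_concordance(
    matrix: ExpressionMatrix,
    case_samples,
    control_samples,
) -> pd.Series:
    """Signed concordance score in [-100, 100] per feature.

    For each feature the fraction f of all case x control pairs with
    case > control is computed (ties count as half a pair) and mapped to
    200 * (f - 0.5).  +100 means every case exceeds every control.
    """
    case_samples = list(case_samples)
    control_samples = list(control_samples)
    if not case_samples or not control_samples:
        raise ValidationError("need >= 1 case and >= 1 control")
    A = matrix.values[case_samples].to_numpy(float)
    B = matrix.values[control_samples].to_numpy(float)
    n1, n2 = A.shape[1], B.shape[1]
    # Mann-Whitney identity: U (with half-credit ties) = R_case - n1(n1+1)/2
    combined = np.concatenate([A, B], axis=1)
    ranks = stats.rankdata(combined, axis=1)
    u = ranks[:, :n1].sum(axis=1) - n1 * (n1 + 1) / 2.0
    frac = u / (n1 * n2)
    return pd.Series(200.0 * (frac - 0.5), index=matrix.features, name="concordance")


def center_batches(matrix: ExpressionMatrix, batches: pd.Series) -> ExpressionMatrix:
    """Per-feature, per-batch mean centering (grand mean added back).

    A light covariate-adjustment hook for inputs pooled across sequencing
    or hybridization batches, applied before two-group scoring.
    """
    batches = batches.reindex(matrix.samples)
    if batches.isna().any():
        raise ValidationError("batch labels missing for some samples")
    values = matrix.values
    grand = values.mean(axis=1)
    out = values.copy()
    for batch in dict.fromkeys(batches):
        cols = batches.index[batches == batch]
        out[cols] = values[cols].sub(values[cols].mean(axis=1), axis=0)
    out = out.add(grand, axis=0)
    return ExpressionMatrix(out, scale=matrix.scale)
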