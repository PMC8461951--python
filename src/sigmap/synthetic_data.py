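"""Synthetic expression and serum-marker data with known planted truth.

Real monocyte cohort data and the labeled reference compendium this kind of
analysis runs on are not redistributable, so every downstream stage is
exercised on generated data instead.  The generator plants structure the
pipeline is supposed to recover:

* a reference compendium with block-structured cell-state marker expression
  (features elevated in a declared subset of reference groups),
* case/control matrices with a planted signature of configurable mean fold
  change (default 1.20, the magnitude typical of purified-monocyte disease
  signatures),
* serum-marker tables with group shifts.

All randomness flows through a single :class:`numpy.random.Generator`
(PCG64) seeded per spec object; fixed seed implies bit-identical output.
Expression is generated on log2 scale with additive Gaussian noise; a
Poisson count transform is provided for RNA-seq-like inputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix, ReferenceCompendium, ValidationError

__all__ = [
    "BlockSpec",
    "CompendiumSpec",
    "CaseControlSpec",
    "generate_compendium",
    "generate_case_control",
    "generate_serum_markers",
    "to_counts",
    "default_compendium_spec",
    "DEFAULT_REFERENCE_FAMILIES",
]


@dataclass(frozen=True)
class BlockSpec:
    """A co-expression block: features elevated in a subset of groups."""

    feature_indices: tuple[int, ...]
    high_groups: tuple[str, ...]
    effect_log2: float = 2.0

    def __post_init__(self) -> None:
        if len(self.feature_indices) == 0:
            raise ValidationError("block has no features")
        if len(set(self.feature_indices)) != len(self.feature_indices):
            raise ValidationError("block feature indices must be unique")
        if len(self.high_groups) == 0:
            raise ValidationError("block must name at least one high group")
        if self.effect_log2 <= 0:
            raise ValidationError(f"effect_log2 must be > 0, got {self.effect_log2}")


@dataclass(frozen=True)
class CompendiumSpec:
    """Recipe for a reference compendium with planted marker blocks."""

    groups: tuple[tuple[str, int], ...]  # (group label, n_samples)
    n_features: int
    blocks: tuple[BlockSpec, ...] = ()
    noise_sd: float = 0.25
    baseline_mean: float = 7.0
    seed: int = 0
    datasets: dict[str, str] = field(default_factory=dict)  # group -> dataset label

    def __post_init__(self) -> None:
        if len(self.groups) == 0:
            raise ValidationError("at least one group required")
        labels = [g for g, _ in self.groups]
        if len(set(labels)) != len(labels):
            raise ValidationError("group labels must be unique")
        for g, n in self.groups:
            if n < 1:
                raise ValidationError(f"group {g!r} needs n_samples >= 1, got {n}")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")
        seen: dict[int, int] = {}
        for b_i, block in enumerate(self.blocks):
            for idx in block.feature_indices:
                if not 0 <= idx < self.n_features:
                    raise ValidationError(
                        f"block {b_i} feature index {idx} outside [0, {self.n_features})"
                    )
                if idx in seen:
                    raise ValidationError(
                        f"blocks {seen[idx]} and {b_i} overlap at feature index {idx}"
                    )
                seen[idx] = b_i
            unknown = set(block.high_groups) - set(labels)
            if unknown:
                raise ValidationError(f"block {b_i} high_groups not in groups: {sorted(unknown)}")
            if set(block.high_groups) == set(labels):
                raise ValidationError(
                    f"block {b_i} high_groups must be a proper subset of groups"
                )
        total_block = sum(len(b.feature_indices) for b in self.blocks)
        if self.n_features < total_block:
            raise ValidationError("n_features smaller than total block features")


@dataclass(frozen=True)
class CaseControlSpec:
    """Recipe for a case/control matrix with a planted signature.

    ``signature_features`` maps feature index -> direction ("up"/"down",
    relative to cases).  ``mean_fc`` is the target mean fold change of the
    planted features on linear scale; per-feature fold changes are drawn as
    ``mean_fc + Normal(0, fc_dispersion)`` truncated just above 1.
    """

    n_cases: int
    n_controls: int
    n_features: int
    signature_features: dict[int, str] = field(default_factory=dict)
    mean_fc: float = 1.20
    fc_dispersion: float = 0.0
    noise_sd: float = 0.15
    baseline_mean: float = 7.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cases < 1 or self.n_controls < 1:
            raise ValidationError("need at least one case and one control")
        if not 1 < self.mean_fc < 4:
            raise ValidationError(f"mean_fc must lie in (1, 4), got {self.mean_fc}")
        if self.fc_dispersion < 0 or self.noise_sd < 0:
            raise ValidationError("fc_dispersion and noise_sd must be >= 0")
        for idx, direction in self.signature_features.items():
            if not 0 <= idx < self.n_features:
                raise ValidationError(f"signature feature index {idx} out of range")
            if direction not in ("up", "down"):
                raise ValidationError(f"direction must be 'up'/'down', got {direction!r}")


def _feature_ids(n: int) -> list[str]:
    width = max(4, len(str(n - 1)))
    return [f"PS_{i:0{width}d}_at" for i in range(n)]


def generate_compendium(spec: CompendiumSpec) -> ReferenceCompendium:
    """Generate a labeled reference compendium on log2 scale.

    Features in a block have mean ``baseline_mean + effect_log2`` in that
    block's high groups and ``baseline_mean`` elsewhere; i.i.d. Gaussian
    noise of sd ``noise_sd`` is added on top.
    """
    rng = np.random.default_rng(spec.seed)
    n_samples = sum(n for _, n in spec.groups)
    mean = np.full((spec.n_features, n_samples), spec.baseline_mean, dtype=float)

    sample_ids: list[str] = []
    group_of: list[str] = []
    col = 0
    col_ranges: dict[str, slice] = {}
    for g, n in spec.groups:
        col_ranges[g] = slice(col, col + n)
        for i in range(n):
            sample_ids.append(f"{g}_{i + 1:02d}")
            group_of.append(g)
        col += n

    for block in spec.blocks:
        rows = np.fromiter(block.feature_indices, dtype=int)
        for g in block.high_groups:
            mean[np.ix_(rows, np.arange(*col_ranges[g].indices(n_samples)))] += block.effect_log2

    noise = rng.normal(0.0, spec.noise_sd, size=mean.shape) if spec.noise_sd > 0 else 0.0
    values = pd.DataFrame(mean + noise, index=_feature_ids(spec.n_features), columns=sample_ids)
    meta = pd.DataFrame(
        {
            "group": group_of,
            "dataset": [spec.datasets.get(g, "synthetic") for g in group_of],
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    return ReferenceCompendium(ExpressionMatrix(values, scale="log2"), meta)


def generate_case_control(
    spec: CaseControlSpec,
) -> tuple[ExpressionMatrix, pd.Series, pd.DataFrame]:
    """Generate a case/control matrix plus labels and a planted truth table.

    Returns
    -------
    matrix:
        log2-scale ExpressionMatrix, cases first then controls.
    labels:
        Series sample -> "case"/"control".
    truth:
        One row per planted feature: feature_id, direction, planted fold
        change (case/control linear ratio) and the realized fold change
        recomputed from the emitted matrix.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_cases + spec.n_controls
    mean = np.full((spec.n_features, n), spec.baseline_mean, dtype=float)
    case_cols = np.arange(spec.n_cases)

    fids = _feature_ids(spec.n_features)
    rows = []
    for idx in sorted(spec.signature_features):
        direction = spec.signature_features[idx]
        fc = spec.mean_fc
        if spec.fc_dispersion > 0:
            fc = max(1.0 + 1e-9, fc + rng.normal(0.0, spec.fc_dispersion))
        planted = fc if direction == "up" else 1.0 / fc
        shift = np.log2(fc)
        if direction == "up":
            mean[idx, case_cols] += shift
        else:
            mean[idx, case_cols] -= shift
        rows.append({"feature_id": fids[idx], "direction": direction, "planted_fc": planted})

    noise = rng.normal(0.0, spec.noise_sd, size=mean.shape) if spec.noise_sd > 0 else 0.0
    sample_ids = [f"case_{i + 1:02d}" for i in range(spec.n_cases)] + [
        f"control_{i + 1:02d}" for i in range(spec.n_controls)
    ]
    values = pd.DataFrame(mean + noise, index=fids, columns=sample_ids)
    matrix = ExpressionMatrix(values, scale="log2")
    labels = pd.Series(
        ["case"] * spec.n_cases + ["control"] * spec.n_controls,
        index=values.columns,
        name="group",
    )

    truth = pd.DataFrame(rows, columns=["feature_id", "direction", "planted_fc"])
    if len(truth):
        linear = matrix.linear()
        case_mean = linear.iloc[:, : spec.n_cases].mean(axis=1)
        ctrl_mean = linear.iloc[:, spec.n_cases :].mean(axis=1)
        realized = (case_mean / ctrl_mean).loc[truth["feature_id"]]
        truth["realized_fc"] = realized.to_numpy()
    else:
        truth["realized_fc"] = pd.Series(dtype=float)
    return matrix, labels, truth


def generate_serum_markers(
    group_means: dict[str, float],
    group_sds: dict[str, float],
    group_ns: dict[str, int],
    distribution: str = "lognormal",
    seed: int = 0,
    analyte: str = "marker",
) -> pd.DataFrame:
    """Generate a sample x analyte serum-marker table with group labels.

    ``distribution`` is ``"normal"`` or ``"lognormal"``; for the lognormal
    the given mean/sd are matched on the natural (linear) scale.  A zero sd
    is the degenerate limit (all values equal the group mean); negative sds
    are rejected.
    """
    if distribution not in ("normal", "lognormal"):
        raise ValidationError(f"unknown distribution {distribution!r}")
    if set(group_means) != set(group_sds) or set(group_means) != set(group_ns):
        raise ValidationError("group_means/group_sds/group_ns must share keys")
    rng = np.random.default_rng(seed)
    rows = []
    for g in group_means:
        mu, sd, n = group_means[g], group_sds[g], group_ns[g]
        if sd < 0:
            raise ValidationError(f"group {g!r} sd must be >= 0, got {sd}")
        if n < 2:
            raise ValidationError(f"group {g!r} needs n >= 2, got {n}")
        if sd == 0:
            vals = np.full(n, float(mu))
        elif distribution == "normal":
            vals = rng.normal(mu, sd, size=n)
        else:
            if mu <= 0:
                raise ValidationError(f"lognormal needs positive mean, got {mu}")
            sigma2 = np.log1p((sd / mu) ** 2)
            vals = rng.lognormal(np.log(mu) - sigma2 / 2.0, np.sqrt(sigma2), size=n)
        for i, v in enumerate(vals):
            rows.append(
                {"sample_id": f"{g}_{i + 1:03d}", "group": g, "analyte": analyte, "value": v}
            )
    return pd.DataFrame(rows, columns=["sample_id", "group", "analyte", "value"])


def to_counts(matrix: ExpressionMatrix, depth: float = 1.0, seed: int = 0) -> ExpressionMatrix:
    """Poisson-sample an RNA-seq-like count matrix from log2 intensities.

    Each entry becomes ``Poisson(depth * 2**x)``; ``depth`` scales the
    sequencing depth.
    """
    if matrix.scale != "log2":
        raise ValidationError("to_counts expects a log2-scale matrix")
    if depth <= 0:
        raise ValidationError("depth must be > 0")
    rng = np.random.default_rng(seed)
    lam = depth * np.exp2(matrix.values.to_numpy(float))
    counts = rng.poisson(lam).astype(float)
    return ExpressionMatrix(
        pd.DataFrame(counts, index=matrix.features, columns=matrix.samples), scale="count"
    )


# Default reference-family template: four families of labeled profiles
# mirroring a myeloid compendium -- a bone-marrow differentiation series,
# blood subsets (DCs, neutrophils, classical/non-classical monocytes),
# G-CSF-treated leukocytes, and in-vitro stimulated monocytes.
DEFAULT_REFERENCE_FAMILIES: tuple[tuple[str, str, int], ...] = (
    # (group, dataset/family, n_samples)
    ("bm_early_myelopoiesis", "bm_differentiation", 12),
    ("bm_late_granulopoiesis", "bm_differentiation", 12),
    ("bm_pmn", "bm_differentiation", 10),
    ("dc_bdca1", "blood_subsets", 3),
    ("dc_bdca3", "blood_subsets", 3),
    ("pmn_cd15", "blood_subsets", 3),
    ("mono_cd16neg", "blood_subsets", 3),
    ("mono_cd16pos", "blood_subsets", 3),
    ("gcsf_pre", "gcsf_leukocytes", 3),
    ("gcsf_post", "gcsf_leukocytes", 3),
    ("mono_unstim", "stimulated_monocytes", 4),
    ("mono_lps", "stimulated_monocytes", 2),
    ("mono_tnf", "stimulated_monocytes", 2),
    ("mono_ifng", "stimulated_monocytes", 2),
    ("mono_ifna", "stimulated_monocytes", 2),
)


def default_compendium_spec(
    n_features: int = 2000,
    blocks: tuple[BlockSpec, ...] = (),
    noise_sd: float = 0.25,
    seed: int = 0,
) -> CompendiumSpec:
    """A CompendiumSpec using the shipped reference-family template."""
    groups = tuple((g, n) for g, _, n in DEFAULT_REFERENCE_FAMILIES)
    datasets = {g: d for g, d, _ in DEFAULT_REFERENCE_FAMILIES}
    return CompendiumSpec(
        groups=groups,
        n_features=n_features,
        blocks=blocks,
        noise_sd=noise_sd,
        seed=seed,
        datasets=datasets,
    )
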