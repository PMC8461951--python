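"""Orchestrate the full analysis from a single YAML config.

One run covers any number of two-group contrasts (e.g. patients vs
controls, active vs inactive disease, non-radiographic vs radiographic
stage).  Per contrast: differential-expression scoring, separate
co-expression mapping of the up- and down-signatures onto the reference
compendium, gene-set over-representation, and optional serum-marker group
tests.  A manifest records the config hash, seed, and library versions;
re-running an identical config reproduces identical numeric outputs.

``make_demo`` writes a complete synthetic dataset (compendium with four
reference families, case/control matrix with planted up/down signatures
drawn from compendium blocks, serum-marker table, small GMT collection,
annotation map and a ready-to-run config) so the whole pipeline can be
exercised end-to-end in seconds.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .containers import ReferenceCompendium, Signature, ValidationError
from .diffexpr import score_two_group
from .enrichment import overrepresentation
from .io_formats import (
    AnnotationMap,
    read_annotation,
    read_compendium,
    read_expression_matrix,
    read_gmt,
    read_sample_meta,
    write_annotation,
    write_expression_matrix,
    write_gmt,
    write_sample_meta,
    write_signature,
    GeneSetCollection,
)
from .refmap import linkage_to_newick, map_signature, quantile_normalize, render_ordered_heatmap
from .cohort_stats import multi_group_test, two_group_test

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "ContrastSpec", "load_config", "run_pipeline", "make_demo"]


@dataclass(frozen=True)
class ContrastSpec:
    """A named two-group contrast over a metadata column."""

    name: str
    column: str
    group_a: tuple[str, ...]  # case side
    group_b: tuple[str, ...]  # control side


@dataclass
class PipelineConfig:
    matrix: Path
    metadata: Path
    compendium: Path
    compendium_meta: Path
    gmt: Path
    outdir: Path
    contrasts: list[ContrastSpec]
    annotation: Path | None = None
    markers: Path | None = None
    de_method: str = "welch_t"
    alpha: float = 0.05
    mt_procedure: str = "bh"
    cut_k: int | None = None
    representation: str = "rows"
    min_signature: int = 5
    seed: int = 0

    def validate(self) -> None:
        for attr in ("matrix", "metadata", "compendium", "compendium_meta", "gmt"):
            path = getattr(self, attr)
            if not Path(path).exists():
                raise ValidationError(f"config path {attr} does not exist: {path}")
        for attr in ("annotation", "markers"):
            path = getattr(self, attr)
            if path is not None and not Path(path).exists():
                raise ValidationError(f"config path {attr} does not exist: {path}")
        if not self.contrasts:
            raise ValidationError("config defines no contrasts")
        meta = read_sample_meta(self.metadata)
        for contrast in self.contrasts:
            if contrast.column not in meta.columns:
                raise ValidationError(
                    f"contrast {contrast.name!r}: column {contrast.column!r} not in metadata"
                )
            levels = set(meta[contrast.column])
            unknown = (set(contrast.group_a) | set(contrast.group_b)) - levels
            if unknown:
                raise ValidationError(
                    f"contrast {contrast.name!r}: unknown levels {sorted(unknown)}"
                )


def load_config(path) -> PipelineConfig:
    path = Path(path)
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    base = path.parent

    def resolve(p):
        return None if p is None else (base / p if not Path(p).is_absolute() else Path(p))

    contrasts = [
        ContrastSpec(
            name=c["name"],
            column=c["column"],
            group_a=tuple(c["group_a"]),
            group_b=tuple(c["group_b"]),
        )
        for c in raw.get("contrasts", [])
    ]
    de = raw.get("de", {})
    refmap_cfg = raw.get("refmap", {})
    cfg = PipelineConfig(
        matrix=resolve(raw["matrix"]),
        metadata=resolve(raw["metadata"]),
        compendium=resolve(raw["compendium"]),
        compendium_meta=resolve(raw["compendium_meta"]),
        gmt=resolve(raw["gmt"]),
        outdir=resolve(raw.get("outdir", "results")),
        contrasts=contrasts,
        annotation=resolve(raw.get("annotation")),
        markers=resolve(raw.get("markers")),
        de_method=de.get("method", "welch_t"),
        alpha=float(de.get("alpha", 0.05)),
        mt_procedure=de.get("mt", "bh"),
        cut_k=refmap_cfg.get("k"),
        representation=refmap_cfg.get("representation", "rows"),
        min_signature=int(raw.get("min_signature", 5)),
        seed=int(raw.get("seed", 0)),
    )
    cfg.validate()
    return cfg


def _config_hash(cfg: PipelineConfig) -> str:
    payload = json.dumps(
        {k: str(v) for k, v in vars(cfg).items() if k != "outdir"}, sort_keys=True
    )
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _signature_genes(features, annotation: AnnotationMap | None) -> list[str]:
    if annotation is None:
        return list(dict.fromkeys(features))
    return annotation.genes_for(features)


def _map_and_write(
    features: list[str],
    direction: str,
    compendium_qn: ReferenceCompendium,
    outdir: Path,
    cfg: PipelineConfig,
) -> None:
    result = map_signature(
        features,
        compendium_qn,
        already_normalized=True,
        representation=cfg.representation,
        k=cfg.cut_k,
    )
    prefix = outdir / direction
    result.correlation.to_csv(f"{prefix}_correlation.tsv", sep="\t", index_label="feature_id")
    with open(f"{prefix}_dendrogram.nwk", "w") as fh:
        fh.write(linkage_to_newick(result.linkage, result.features) + "\n")
    result.clusters.rename("cluster").to_csv(
        f"{prefix}_clusters.tsv", sep="\t", index_label="feature_id"
    )
    attribution = result.attribution.copy()
    attribution["top_group"] = result.top_groups
    attribution.to_csv(f"{prefix}_attribution.tsv", sep="\t", index_label="cluster")
    sample_order = compendium_qn.sample_meta.sort_values(
        ["dataset", "group"], kind="stable"
    ).index
    render_ordered_heatmap(
        result.display,
        result.leaf_order,
        sample_order=sample_order,
        image_path=f"{prefix}_heatmap.png",
        matrix_path=f"{prefix}_display.tsv",
    )
    if result.missing_features:
        pd.Series(result.missing_features, name="feature_id").to_csv(
            f"{prefix}_missing_features.tsv", sep="\t", index=False
        )


def _marker_stats(markers_path: Path, outdir: Path) -> None:
    table = pd.read_csv(markers_path, sep="\t")
    rows = []
    for analyte, sub in table.groupby("analyte", sort=False):
        groups = list(dict.fromkeys(sub["group"]))
        if len(groups) == 2:
            res = two_group_test(sub["value"], sub["group"], test="mannwhitney")
        elif len(groups) >= 3:
            res = multi_group_test(sub["value"], sub["group"])
            res.posthoc.assign(analyte=analyte).to_csv(
                outdir / f"markers_{analyte}_posthoc.tsv", sep="\t", index=False
            )
        else:
            continue
        rows.append(
            {
                "analyte": analyte,
                "test": res.test,
                "statistic": res.statistic,
                "p": res.p,
                "groups": ";".join(f"{g}={n}" for g, n in res.group_sizes.items()),
            }
        )
    if rows:
        pd.DataFrame(rows).to_csv(outdir / "marker_tests.tsv", sep="\t", index=False)


def run_pipeline(cfg: PipelineConfig) -> Path:
    """Run every configured contrast; returns the output directory."""
    cfg.validate()
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    matrix = read_expression_matrix(cfg.matrix)
    meta = read_sample_meta(cfg.metadata)
    compendium = read_compendium(cfg.compendium, cfg.compendium_meta)
    compendium_qn = quantile_normalize(compendium)
    collection = read_gmt(cfg.gmt)
    annotation = read_annotation(cfg.annotation) if cfg.annotation else None
    universe = _signature_genes(list(matrix.features), annotation)

    counts: dict[str, dict] = {}
    for contrast in cfg.contrasts:
        cdir = outdir / contrast.name
        cdir.mkdir(exist_ok=True)
        col = meta[contrast.column]
        keep_a = col.index[col.isin(contrast.group_a)]
        keep_b = col.index[col.isin(contrast.group_b)]
        sub = matrix.subset_samples(list(keep_a) + list(keep_b))
        labels = pd.Series(
            ["A"] * len(keep_a) + ["B"] * len(keep_b), index=sub.samples, name="group"
        )
        signature, scores = score_two_group(
            sub,
            labels,
            method=cfg.de_method,
            alpha=cfg.alpha,
            mt_procedure=cfg.mt_procedure,
            contrast=contrast.name,
        )
        scores.to_csv(cdir / "scores.tsv", sep="\t", index=False)
        write_signature(signature, cdir / "signature.tsv")
        logger.info(
            "%s: %d significant features (%d up, %d down)",
            contrast.name,
            len(signature),
            len(signature.up),
            len(signature.down),
        )
        counts[contrast.name] = {
            "significant": len(signature),
            "up": len(signature.up),
            "down": len(signature.down),
        }
        for direction, features in (("up", signature.up), ("down", signature.down)):
            if len(features) >= cfg.min_signature:
                _map_and_write(features, direction, compendium_qn, cdir, cfg)
                genes = _signature_genes(features, annotation)
                enr = overrepresentation(genes, collection, universe)
                enr.to_csv(cdir / f"{direction}_enrichment.tsv", sep="\t", index=False)
            else:
                logger.info(
                    "%s/%s: %d features < min_signature=%d; mapping skipped",
                    contrast.name,
                    direction,
                    len(features),
                    cfg.min_signature,
                )

    if cfg.markers is not None:
        _marker_stats(cfg.markers, outdir)

    manifest = {
        "sigmap_version": __version__,
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "seed": cfg.seed,
        "config_hash": _config_hash(cfg),
        "feature_counts": counts,
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return outdir


# ---------------------------------------------------------------------------
# demo dataset


def make_demo(outdir, seed: int = 0, force: bool = False) -> Path:
    """Write a complete synthetic dataset plus a ready-to-run config.

    The compendium carries four planted co-expression blocks (late
    granulopoiesis, blood neutrophils, stimulated monocytes, dendritic
    cells); the case/control matrix plants the first three blocks' features
    as upregulated and the DC block as downregulated at mean fold change
    1.20, emulating a weak disease signature over cohort-sized groups
    (25 cases vs 10 controls).
    """
    from .synthetic_data import (
        BlockSpec,
        CaseControlSpec,
        default_compendium_spec,
        generate_case_control,
        generate_compendium,
        generate_serum_markers,
    )

    outdir = Path(outdir)
    if outdir.exists() and any(outdir.iterdir()) and not force:
        raise ValidationError(f"target directory {outdir} is not empty (use force)")
    outdir.mkdir(parents=True, exist_ok=True)

    n_features = 2000
    block_defs = [
        ("late_granulopoiesis", ("bm_late_granulopoiesis", "bm_pmn"), range(0, 40), "up"),
        ("blood_pmn", ("pmn_cd15",), range(40, 80), "up"),
        ("stimulated_mono", ("mono_lps", "mono_tnf"), range(80, 120), "up"),
        ("dendritic", ("dc_bdca1", "dc_bdca3"), range(120, 160), "down"),
    ]
    blocks = tuple(
        BlockSpec(feature_indices=tuple(idx), high_groups=groups, effect_log2=2.0)
        for _, groups, idx, _ in block_defs
    )
    comp_spec = default_compendium_spec(
        n_features=n_features, blocks=blocks, noise_sd=0.25, seed=seed
    )
    compendium = generate_compendium(comp_spec)
    write_expression_matrix(compendium.expr, outdir / "compendium.tsv")
    write_sample_meta(compendium.sample_meta, outdir / "compendium_meta.tsv")

    signature_features = {
        i: direction for _, _, idx, direction in block_defs for i in idx
    }
    cc_spec = CaseControlSpec(
        n_cases=25,
        n_controls=10,
        n_features=n_features,
        signature_features=signature_features,
        mean_fc=1.20,
        fc_dispersion=0.0,
        noise_sd=0.15,
        seed=seed + 1,
    )
    matrix, labels, truth = generate_case_control(cc_spec)
    write_expression_matrix(matrix, outdir / "matrix.tsv")
    meta = pd.DataFrame(
        {"group": labels, "dataset": "demo_cohort"}, index=labels.index
    )
    write_sample_meta(meta, outdir / "metadata.tsv")
    truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)

    # annotation: one gene per probe-set, shared prefix
    genes = [f"GENE{i:04d}" for i in range(n_features)]
    annotation = AnnotationMap(
        pd.DataFrame({"probe_set_id": list(matrix.features), "gene_symbol": genes})
    )
    write_annotation(annotation, outdir / "annotation.tsv")

    # GMT: one set per planted block plus random decoys
    rng = np.random.default_rng(seed + 2)
    sets: dict[str, frozenset] = {}
    descriptions: dict[str, str] = {}
    for name, _, idx, _ in block_defs:
        sets[f"PLANTED_{name.upper()}"] = frozenset(genes[i] for i in idx)
        descriptions[f"PLANTED_{name.upper()}"] = f"planted {name} block"
    for d in range(6):
        members = rng.choice(n_features, size=40, replace=False)
        sets[f"DECOY_{d}"] = frozenset(genes[i] for i in members)
        descriptions[f"DECOY_{d}"] = "random decoy set"
    write_gmt(GeneSetCollection(sets, descriptions), outdir / "genesets.gmt")

    markers = generate_serum_markers(
        group_means={"case": 12.0, "control": 8.0},
        group_sds={"case": 3.0, "control": 2.0},
        group_ns={"case": 25, "control": 10},
        distribution="lognormal",
        seed=seed + 3,
        analyte="LBP",
    )
    markers.to_csv(outdir / "markers.tsv", sep="\t", index=False)

    config = {
        "matrix": "matrix.tsv",
        "metadata": "metadata.tsv",
        "compendium": "compendium.tsv",
        "compendium_meta": "compendium_meta.tsv",
        "gmt": "genesets.gmt",
        "annotation": "annotation.tsv",
        "markers": "markers.tsv",
        "outdir": "results",
        "seed": seed,
        "de": {"method": "welch_t", "alpha": 0.05, "mt": "bh"},
        "refmap": {"representation": "rows"},
        "contrasts": [
            {
                "name": "case_vs_control",
                "column": "group",
                "group_a": ["case"],
                "group_b": ["control"],
            }
        ],
    }
    with open(outdir / "config.yaml", "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=False)
    return outdir
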