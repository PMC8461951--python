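"""Readers/writers for the tab-delimited artifacts the pipeline touches.

Formats: expression matrix TSV (features in rows, header row of sample
IDs), sample metadata TSV (sample_id, group[, dataset]), GMT gene-set
collections, probe-set/gene annotation TSV, and signature TSV.  Readers
reject malformed input with positional diagnostics rather than silently
coercing; write/read round trips are lossless for IDs and values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import (
    SIGNATURE_COLUMNS,
    ExpressionMatrix,
    ReferenceCompendium,
    Signature,
    ValidationError,
)

logger = logging.getLogger(__name__)

__all__ = [
    "ParseError",
    "AnnotationMap",
    "GeneSetCollection",
    "read_expression_matrix",
    "write_expression_matrix",
    "read_sample_meta",
    "write_sample_meta",
    "read_compendium",
    "read_gmt",
    "write_gmt",
    "read_annotation",
    "write_annotation",
    "map_genes_to_probesets",
    "read_signature",
    "write_signature",
]


class ParseError(ValueError):
    """Malformed input file; message carries the line number."""


# float format chosen so round trips are exact (shortest repr of a double)
def _write_tsv(df: pd.DataFrame, path, index_label: str) -> None:
    df.to_csv(path, sep="\t", index_label=index_label)


def read_expression_matrix(
    path, scale: str = "log2", duplicate_policy: str = "error"
) -> ExpressionMatrix:
    """Read a features x samples TSV into an ExpressionMatrix.

    ``duplicate_policy`` controls duplicated feature IDs: ``"error"``
    (default), ``"first"`` (keep first occurrence) or ``"mean"`` (average).
    Ragged rows and non-numeric cells raise :class:`ParseError` with the
    offending line number.
    """
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
        if not header:
            raise ParseError(f"{path}: empty file or missing header")
        n_samples = len(header.split("\t")) - 1
        ids: list[str] = []
        data: list[np.ndarray] = []
        for lineno, line in enumerate(fh, start=2):
            parts = line.rstrip("\n").split("\t")
            if len(parts) != n_samples + 1:
                raise ParseError(
                    f"{path}:{lineno}: expected {n_samples + 1} fields, got {len(parts)}"
                )
            ids.append(parts[0])
            try:
                data.append(np.array(parts[1:], dtype=float))
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-numeric cell ({exc})") from None
    columns = header.split("\t")[1:]
    df = pd.DataFrame(
        np.vstack(data) if data else np.empty((0, n_samples)),
        index=pd.Index(ids, name="feature_id"),
        columns=columns,
    )
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        if duplicate_policy == "error":
            raise ValidationError(f"{path}: duplicated feature IDs: {dups[:10]}")
        if duplicate_policy == "first":
            df = df[~df.index.duplicated(keep="first")]
        elif duplicate_policy == "mean":
            df = df.groupby(level=0, sort=False).mean()
        else:
            raise ValidationError(f"unknown duplicate_policy {duplicate_policy!r}")
    logger.info("read %s: %d features x %d samples", path, df.shape[0], df.shape[1])
    return ExpressionMatrix(df, scale=scale)


def write_expression_matrix(matrix: ExpressionMatrix, path) -> None:
    _write_tsv(matrix.values, path, index_label="feature_id")


def read_sample_meta(path) -> pd.DataFrame:
    """Read sample metadata TSV (sample_id, group[, dataset])."""
    meta = pd.read_csv(path, sep="\t", dtype=str)
    if "sample_id" not in meta.columns or "group" not in meta.columns:
        raise ParseError(f"{path}: needs columns sample_id and group")
    if "dataset" not in meta.columns:
        meta["dataset"] = "unspecified"
    if meta["sample_id"].duplicated().any():
        raise ValidationError(f"{path}: duplicated sample IDs")
    return meta.set_index("sample_id")


def write_sample_meta(meta: pd.DataFrame, path) -> None:
    meta.to_csv(path, sep="\t", index_label="sample_id")


def read_compendium(matrix_path, meta_path, scale: str = "log2") -> ReferenceCompendium:
    expr = read_expression_matrix(matrix_path, scale=scale)
    meta = read_sample_meta(meta_path)
    return ReferenceCompendium(expr, meta)


@dataclass
class GeneSetCollection:
    """Named, non-empty gene sets with optional descriptions."""

    sets: dict[str, frozenset[str]]
    descriptions: dict[str, str]

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not name:
                raise ValidationError("gene set name must be non-empty")
            if not members:
                raise ValidationError(f"gene set {name!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name: str) -> frozenset[str]:
        return self.sets[name]

    def names(self) -> list[str]:
        return list(self.sets)


def read_gmt(path) -> GeneSetCollection:
    """Parse a GMT file (tab-delimited: name, description, members...)."""
    path = Path(path)
    sets: dict[str, frozenset[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ParseError(f"{path}:{lineno}: GMT line needs >= 3 fields")
            name, desc, *members = parts
            members = [m for m in members if m]
            if not members:
                raise ParseError(f"{path}:{lineno}: gene set {name!r} has no members")
            if name in sets:
                raise ParseError(f"{path}:{lineno}: duplicated set name {name!r}")
            sets[name] = frozenset(members)
            descriptions[name] = desc
    return GeneSetCollection(sets, descriptions)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for name in collection.names():
            desc = collection.descriptions.get(name, "")
            members = sorted(collection.sets[name])
            fh.write("\t".join([name, desc, *members]) + "\n")


@dataclass
class AnnotationMap:
    """Many-to-many probe-set <-> gene-symbol pairing (case-preserving)."""

    pairs: pd.DataFrame  # columns: probe_set_id, gene_symbol

    def __post_init__(self) -> None:
        missing = {"probe_set_id", "gene_symbol"} - set(self.pairs.columns)
        if missing:
            raise ValidationError(f"annotation missing columns: {sorted(missing)}")
        empty = (self.pairs["probe_set_id"] == "") | (self.pairs["gene_symbol"] == "")
        if empty.any() or self.pairs[["probe_set_id", "gene_symbol"]].isna().any().any():
            raise ValidationError("annotation contains empty IDs")

    def genes_for(self, probe_sets) -> list[str]:
        """Unique gene symbols for the given probe-sets (order of first hit)."""
        wanted = set(probe_sets)
        hit = self.pairs[self.pairs["probe_set_id"].isin(wanted)]
        return list(dict.fromkeys(hit["gene_symbol"]))


def read_annotation(path) -> AnnotationMap:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return AnnotationMap(df)


def write_annotation(annotation: AnnotationMap, path) -> None:
    annotation.pairs.to_csv(path, sep="\t", index=False)


def map_genes_to_probesets(
    genes, annotation: AnnotationMap, case_fold: bool = False
) -> tuple[list[str], float, list[str]]:
    """Expand gene symbols to probe-sets via the annotation.

    Returns (probe-set list, coverage fraction, unmapped genes).  Coverage
    is the fraction of input genes with at least one probe-set; for an
    empty input it is reported as NaN.  Matching is exact-string unless
    ``case_fold`` is set.
    """
    genes = list(genes)
    if not genes:
        return [], float("nan"), []
    pairs = annotation.pairs
    key = pairs["gene_symbol"].str.casefold() if case_fold else pairs["gene_symbol"]
    lookup: dict[str, list[str]] = {}
    for ps, g in zip(pairs["probe_set_id"], key):
        lookup.setdefault(g, []).append(ps)
    probe_sets: list[str] = []
    unmapped: list[str] = []
    for g in genes:
        g_key = g.casefold() if case_fold else g
        hits = lookup.get(g_key)
        if hits:
            probe_sets.extend(hits)
        else:
            unmapped.append(g)
    coverage = (len(genes) - len(unmapped)) / len(genes)
    return list(dict.fromkeys(probe_sets)), coverage, unmapped


def read_signature(path, contrast: str | None = None) -> Signature:
    table = pd.read_csv(path, sep="\t", dtype={"feature_id": str})
    missing = set(SIGNATURE_COLUMNS) - set(table.columns)
    if missing:
        raise ParseError(f"{path}: signature TSV missing columns: {sorted(missing)}")
    return Signature(contrast or str(path), table[SIGNATURE_COLUMNS].copy())


def write_signature(signature: Signature, path) -> None:
    signature.table.to_csv(path, sep="\t", index=False)
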