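"""On-disk formats and cohort assembly.

Expression matrices are tab-separated text with genes in rows (first column
``gene_id``) and samples in columns; empty cells encode missing values.
Sample annotations are tab-separated tables with columns ``sample_id``,
``cancer_type``, ``cohort`` and optionally ``subtype``. Gene sets use the
standard GMT format, with an optional polarity companion table assigning
up/down direction per gene.

Gene identifiers are opaque strings matched by exact equality in a single
namespace (Entrez-style ids or symbols); an optional two-column alias map can
translate identifiers before matching.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

PLATFORMS = ("protein", "phospho", "mrna", "rppa")
NORM_STATES = ("raw", "profile_normalized", "fully_normalized")

ANNOTATION_COLUMNS = ("sample_id", "cancer_type", "cohort", "subtype")


class FormatError(ValueError):
    """Malformed input file or inconsistent matrix/annotation content."""


@dataclass
class ExpressionMatrix:
    """Gene × sample log2 expression values.

    ``values`` is a float DataFrame indexed by gene id with sample ids as
    columns; NaN encodes missing. ``platform`` is one of ``protein``,
    ``phospho``, ``mrna``, ``rppa``; ``norm_state`` tracks the normalization
    stage (``raw`` → ``profile_normalized`` → ``fully_normalized``).
    """

    values: pd.DataFrame
    platform: str = "protein"
    norm_state: str = "raw"

    def __post_init__(self) -> None:
        if self.platform not in PLATFORMS:
            raise FormatError(f"unknown platform {self.platform!r}")
        if self.norm_state not in NORM_STATES:
            raise FormatError(f"unknown norm_state {self.norm_state!r}")
        if self.values.index.has_duplicates:
            dupes = self.values.index[self.values.index.duplicated()].unique()
            raise FormatError(f"duplicate gene ids: {list(dupes[:5])}")
        if self.values.columns.has_duplicates:
            dupes = self.values.columns[self.values.columns.duplicated()].unique()
            raise FormatError(f"duplicate sample ids: {list(dupes[:5])}")
        self.values = self.values.astype(float)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def n_missing(self) -> int:
        return int(self.values.isna().sum().sum())

    def copy(self) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.copy(), self.platform, self.norm_state)

    def with_values(self, values: pd.DataFrame, norm_state: str | None = None) -> "ExpressionMatrix":
        return ExpressionMatrix(values, self.platform, norm_state or self.norm_state)


@dataclass
class GeneSet:
    """A named gene set, optionally signed (up/down) with a scoring method."""

    name: str
    up: list[str]
    down: list[str] = field(default_factory=list)
    method: str = "mean"  # mean | tscore | composite

    def __post_init__(self) -> None:
        if not self.up:
            raise FormatError(f"gene set {self.name!r} has an empty up list")
        if set(self.up) & set(self.down):
            raise FormatError(f"gene set {self.name!r}: up and down overlap")


@dataclass
class GeneSetCollection:
    sets: dict[str, GeneSet]

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.values())

    def __getitem__(self, name: str) -> GeneSet:
        return self.sets[name]


# ---------------------------------------------------------------------------
# expression TSV


def read_expression_tsv(path: str | Path, platform: str = "protein") -> ExpressionMatrix:
    """Read a genes-in-rows expression TSV; empty cells become missing.

    Raises :class:`FormatError` on duplicate gene or sample ids and on
    non-numeric non-empty cells (reported with row and column).
    """
    raw = pd.read_csv(path, sep="\t", dtype=str, index_col=0, keep_default_na=False)
    if raw.columns.has_duplicates:
        dupes = raw.columns[raw.columns.duplicated()].unique()
        raise FormatError(f"{path}: duplicate sample ids {list(dupes[:5])}")
    if raw.index.has_duplicates:
        dupes = raw.index[raw.index.duplicated()].unique()
        raise FormatError(f"{path}: duplicate gene ids {list(dupes[:5])}")
    values = pd.DataFrame(index=raw.index.astype(str), columns=raw.columns, dtype=float)
    for col in raw.columns:
        cells = raw[col].str.strip()
        converted = pd.to_numeric(cells.replace("", np.nan), errors="coerce")
        bad = converted.isna() & (cells != "")
        if bad.any():
            gene = raw.index[bad.to_numpy()][0]
            raise FormatError(
                f"{path}: non-numeric value {cells[bad].iloc[0]!r} at gene {gene!r}, sample {col!r}"
            )
        values[col] = converted
    values.index.name = "gene_id"
    return ExpressionMatrix(values, platform=platform, norm_state="raw")


def write_expression_tsv(matrix: ExpressionMatrix, path: str | Path) -> None:
    """Write an expression TSV (first column ``gene_id``; missing → empty cell)."""
    out = matrix.values.copy()
    out.index.name = "gene_id"
    out.to_csv(path, sep="\t", na_rep="", float_format="%.10g")


# ---------------------------------------------------------------------------
# sample annotation


def check_annotation(annotation: pd.DataFrame) -> pd.DataFrame:
    """Validate a sample annotation table and normalize its columns."""
    if "sample_id" not in annotation.columns or "cancer_type" not in annotation.columns:
        raise FormatError("annotation needs sample_id and cancer_type columns")
    ann = annotation.copy()
    if "cohort" not in ann.columns:
        ann["cohort"] = ""
    if "subtype" not in ann.columns:
        ann["subtype"] = pd.NA
    ann = ann[list(ANNOTATION_COLUMNS)]
    if ann["sample_id"].duplicated().any():
        dupes = ann.loc[ann["sample_id"].duplicated(), "sample_id"].unique()
        raise FormatError(f"duplicate sample ids in annotation: {list(dupes[:5])}")
    if ann["cancer_type"].isna().any() or (ann["cancer_type"].astype(str) == "").any():
        raise FormatError("annotation has empty cancer_type entries")
    return ann.reset_index(drop=True)


def read_annotation_tsv(path: str | Path) -> pd.DataFrame:
    return check_annotation(pd.read_csv(path, sep="\t", dtype=str))


def write_annotation_tsv(annotation: pd.DataFrame, path: str | Path) -> None:
    check_annotation(annotation).to_csv(path, sep="\t", index=False, na_rep="")


def types_of(annotation: pd.DataFrame, sample_ids: Sequence[str]) -> pd.Series:
    """Cancer type per sample id, erroring on samples absent from annotation."""
    ann = check_annotation(annotation).set_index("sample_id")
    missing = [s for s in sample_ids if s not in ann.index]
    if missing:
        raise FormatError(f"annotation missing samples: {missing[:5]}")
    return ann.loc[list(sample_ids), "cancer_type"]


# ---------------------------------------------------------------------------
# GMT gene sets


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT file: one set per line, name / description / gene ids.

    Genes are deduplicated preserving first occurrence; lines with fewer than
    three fields are format errors.
    """
    sets: dict[str, GeneSet] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise FormatError(f"{path}:{lineno}: GMT line has fewer than 3 fields")
        name = fields[0]
        if name in sets:
            raise FormatError(f"{path}:{lineno}: duplicate set name {name!r}")
        genes = list(dict.fromkeys(g for g in fields[2:] if g))
        sets[name] = GeneSet(name=name, up=genes)
    return GeneSetCollection(sets)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    lines = []
    for gs in collection:
        lines.append("\t".join([gs.name, "na", *gs.up, *gs.down]))
    Path(path).write_text("\n".join(lines) + "\n")


def apply_polarity(collection: GeneSetCollection, polarity: pd.DataFrame) -> GeneSetCollection:
    """Apply a polarity companion table (set_name, gene_id, direction).

    Genes marked ``down`` move to the set's down list; sets acquiring a down
    list default to the ``tscore`` method.
    """
    required = {"set_name", "gene_id", "direction"}
    if not required <= set(polarity.columns):
        raise FormatError(f"polarity table needs columns {sorted(required)}")
    sets: dict[str, GeneSet] = {}
    for name, gs in collection.sets.items():
        rows = polarity[polarity["set_name"] == name]
        down = [g for g in rows.loc[rows["direction"] == "down", "gene_id"] if g in gs.up or g in gs.down]
        if down:
            up = [g for g in gs.up if g not in down]
            sets[name] = GeneSet(name=name, up=up, down=down, method="tscore")
        else:
            sets[name] = GeneSet(name=name, up=list(gs.up), down=list(gs.down), method=gs.method)
    return GeneSetCollection(sets)


def read_polarity_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype=str)


# ---------------------------------------------------------------------------
# cohort assembly


def apply_alias_map(matrix: ExpressionMatrix, alias: Mapping[str, str]) -> ExpressionMatrix:
    """Translate gene ids through a two-column alias map before matching."""
    new_index = [alias.get(g, g) for g in matrix.gene_ids]
    values = matrix.values.copy()
    values.index = pd.Index(new_index, name="gene_id")
    if values.index.has_duplicates:
        values = values.groupby(level=0, sort=False).mean()
    return matrix.with_values(values)


def merge_cohorts(
    matrices: Sequence[ExpressionMatrix],
    annotations: Sequence[pd.DataFrame],
) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Assemble per-cancer-type matrices into one cohort on the gene union.

    Genes absent from a contributing matrix are missing for all its samples.
    Sample ids must be globally unique; annotation rows are concatenated.
    """
    if not matrices:
        raise FormatError("merge_cohorts needs at least one matrix")
    platform = matrices[0].platform
    if any(m.platform != platform for m in matrices):
        raise FormatError("merge_cohorts: matrices mix platforms")
    seen: dict[str, int] = {}
    for i, m in enumerate(matrices):
        for s in m.sample_ids:
            if s in seen:
                raise FormatError(f"sample id {s!r} appears in inputs {seen[s]} and {i}")
            seen[s] = i
    genes: list[str] = list(dict.fromkeys(g for m in matrices for g in m.gene_ids))
    blocks = [m.values.reindex(index=genes) for m in matrices]
    merged = pd.concat(blocks, axis=1)
    merged.index.name = "gene_id"
    ann = check_annotation(pd.concat([check_annotation(a) for a in annotations], ignore_index=True))
    matrix = ExpressionMatrix(merged, platform=platform, norm_state=matrices[0].norm_state)
    return matrix, ann


def detection_filter(
    matrix: ExpressionMatrix,
    annotation: pd.DataFrame,
    min_types: int = 3,
    min_case_fraction: float = 0.0,
) -> ExpressionMatrix:
    """Keep genes detected in at least ``min_types`` cancer types.

    A gene counts as detected in a type when its non-missing fraction among
    that type's samples exceeds ``min_case_fraction`` (any non-missing value
    when the fraction is 0). Total protein uses (3, 0); phospho-protein uses
    (3, 0.5), i.e. detection in more than half of cases for ≥3 types.
    """
    if not 0 <= min_case_fraction <= 1:
        raise ValueError("min_case_fraction must be in [0, 1]")
    types = types_of(annotation, matrix.sample_ids)
    unique_types = types.unique()
    if min_types > len(unique_types):
        raise ValueError(f"min_types={min_types} exceeds {len(unique_types)} cancer types")
    detected = pd.DataFrame(index=matrix.values.index, columns=unique_types, dtype=bool)
    for t in unique_types:
        block = matrix.values.loc[:, (types == t).to_numpy()]
        frac = block.notna().mean(axis=1)
        detected[t] = frac > min_case_fraction if min_case_fraction > 0 else frac > 0
    keep = detected.sum(axis=1) >= min_types
    return matrix.with_values(matrix.values.loc[keep])


def detected_types_table(matrix: ExpressionMatrix, annotation: pd.DataFrame) -> pd.DataFrame:
    """Per (gene, cancer type) detection flags (any non-missing value)."""
    types = types_of(annotation, matrix.sample_ids)
    out = {}
    for t in types.unique():
        block = matrix.values.loc[:, (types == t).to_numpy()]
        out[t] = block.notna().any(axis=1)
    return pd.DataFrame(out)
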