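"""Two-stage "standard deviations from the median" normalization.

Stage 1 normalizes each sample profile: x' = (x − median) / SD, computed over
the profile's non-missing values. Stage 2 normalizes each gene across the
samples of one cancer type. After both stages, values are in SD-from-median
units and within-type comparable, so neither tissue-dominant differences nor
per-sample location/scale batch effects drive downstream unsupervised
analysis. "SD" is the classical sample standard deviation (n−1 denominator)
about the mean; a robust MAD alternative is selectable via ``scale="mad"``.

External datasets to be classified get the single-stage per-gene within-type
normalization only (:func:`normalize_per_gene_within_type` on raw values).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import ExpressionMatrix, types_of

logger = logging.getLogger(__name__)

_MAD_TO_SD = 1.4826  # consistency factor for normal data


class NormalizationError(ValueError):
    pass


@dataclass
class NormalizationReport:
    """Audit record of the center/scale parameters used per entity.

    ``per_profile`` is indexed by sample_id with columns (median, sd);
    ``per_gene`` is indexed by (cancer_type, gene_id) with columns
    (median, sd), covering exactly the entities that were normalized.
    """

    per_profile: pd.DataFrame = field(default_factory=pd.DataFrame)
    per_gene: pd.DataFrame = field(default_factory=pd.DataFrame)

    def write_tsv(self, path) -> None:
        rows = []
        for sample, row in self.per_profile.iterrows():
            rows.append(("profile", "", str(sample), row["median"], row["sd"]))
        for (ctype, gene), row in self.per_gene.iterrows():
            rows.append(("gene", str(ctype), str(gene), row["median"], row["sd"]))
        pd.DataFrame(rows, columns=["stage", "cancer_type", "entity", "median", "sd"]).to_csv(
            path, sep="\t", index=False
        )


def _scale_of(values: np.ndarray, scale: str) -> float:
    if scale == "sd":
        return float(np.std(values, ddof=1))
    if scale == "mad":
        med = np.median(values)
        return float(_MAD_TO_SD * np.median(np.abs(values - med)))
    raise ValueError(f"unknown scale {scale!r}")


def normalize_within_profile(
    matrix: ExpressionMatrix, scale: str = "sd"
) -> tuple[ExpressionMatrix, NormalizationReport]:
    """Stage 1: per sample profile, (x − median) / SD over non-missing values.

    Requires raw input with ≥3 non-missing values per profile; a constant
    (zero-SD) profile is an error naming the sample. The output profile has
    median exactly 0 and sample SD exactly 1.
    """
    if matrix.norm_state != "raw":
        raise NormalizationError(f"expected raw matrix, got {matrix.norm_state}")
    values = matrix.values.to_numpy(copy=True)
    stats = {}
    for j, sample in enumerate(matrix.sample_ids):
        col = values[:, j]
        ok = ~np.isnan(col)
        if ok.sum() < 3:
            raise NormalizationError(f"profile {sample!r} has <3 non-missing values")
        med = float(np.median(col[ok]))
        sd = _scale_of(col[ok], scale)
        if sd == 0:
            raise NormalizationError(f"profile {sample!r} has zero {scale.upper()}")
        values[:, j] = (col - med) / sd
        stats[sample] = (med, sd)
    out = pd.DataFrame(values, index=matrix.values.index, columns=matrix.values.columns)
    report = NormalizationReport(
        per_profile=pd.DataFrame.from_dict(stats, orient="index", columns=["median", "sd"])
    )
    return matrix.with_values(out, norm_state="profile_normalized"), report


def normalize_per_gene_within_type(
    matrix: ExpressionMatrix,
    annotation: pd.DataFrame,
    scale: str = "sd",
    min_values: int = 3,
) -> tuple[ExpressionMatrix, NormalizationReport]:
    """Stage 2: per gene, within each cancer type, (x − median) / SD.

    Genes with fewer than ``min_values`` non-missing values in a type become
    missing there; a zero-SD (flat) gene within a type is set to missing and
    logged rather than raising, so a bulk run does not die on one flat gene.
    Accepts profile-normalized input (discovery data) or raw input (external
    datasets, which get this single stage only).
    """
    if matrix.norm_state == "fully_normalized":
        raise NormalizationError("matrix is already fully normalized")
    types = types_of(annotation, matrix.sample_ids)
    values = matrix.values.to_numpy(copy=True)
    gene_ids = matrix.gene_ids
    records: dict[tuple[str, str], tuple[float, float]] = {}
    for ctype in types.unique():
        cols = (types == ctype).to_numpy()
        block = values[:, cols]
        ok = ~np.isnan(block)
        counts = ok.sum(axis=1)
        too_few = counts < min_values
        block[too_few, :] = np.nan
        med = np.full(block.shape[0], np.nan)
        sd = np.full(block.shape[0], np.nan)
        rows = ~too_few
        if rows.any():
            med[rows] = np.nanmedian(block[rows], axis=1)
            if scale == "sd":
                sd[rows] = np.nanstd(block[rows], axis=1, ddof=1)
            else:
                sd[rows] = _MAD_TO_SD * np.nanmedian(
                    np.abs(block[rows] - med[rows, None]), axis=1
                )
        flat = (sd == 0) & ~too_few
        if flat.any():
            for g in np.asarray(gene_ids)[flat][:20]:
                logger.warning("gene %s constant within type %s; set to missing", g, ctype)
            block[flat, :] = np.nan
        usable = ~too_few & ~flat
        block[usable, :] = (block[usable, :] - med[usable, None]) / sd[usable, None]
        values[:, cols] = block
        for g, m, s, u in zip(gene_ids, med, sd, usable):
            if u:
                records[(ctype, g)] = (float(m), float(s))
    out = pd.DataFrame(values, index=matrix.values.index, columns=matrix.values.columns)
    per_gene = pd.DataFrame.from_dict(records, orient="index", columns=["median", "sd"])
    if len(per_gene):
        per_gene.index = pd.MultiIndex.from_tuples(per_gene.index, names=["cancer_type", "gene_id"])
    return matrix.with_values(out, norm_state="fully_normalized"), NormalizationReport(per_gene=per_gene)


def normalize_two_stage(
    matrix: ExpressionMatrix, annotation: pd.DataFrame, scale: str = "sd"
) -> tuple[ExpressionMatrix, ExpressionMatrix, NormalizationReport]:
    """Run both stages; returns (stage-1 matrix, stage-2 matrix, merged report)."""
    stage1, rep1 = normalize_within_profile(matrix, scale=scale)
    stage2, rep2 = normalize_per_gene_within_type(stage1, annotation, scale=scale)
    return stage1, stage2, NormalizationReport(per_profile=rep1.per_profile, per_gene=rep2.per_gene)


def average_duplicate_profiles(
    matrix: ExpressionMatrix, duplicate_map: dict[str, str]
) -> ExpressionMatrix:
    """Collapse duplicate profiles of the same sample to their mean.

    ``duplicate_map`` sends sample ids to group ids; samples not in the map
    keep their own column. Means are missing-aware (missing only when all
    group members are missing). Applied after normalization. A group id that
    collides with an unrelated existing sample id is an error.
    """
    sample_set = set(matrix.sample_ids)
    for sample, gid in duplicate_map.items():
        # a group may only reuse an existing sample id if that sample is
        # itself explicitly mapped into the group
        if gid in sample_set and gid != sample and duplicate_map.get(gid) != gid:
            raise ValueError(f"group id {gid!r} collides with an existing sample id")
    groups: dict[str, list[str]] = {}
    for sample in matrix.sample_ids:
        gid = duplicate_map.get(sample, sample)
        groups.setdefault(gid, []).append(sample)
    cols = {}
    for gid, members in groups.items():
        cols[gid] = matrix.values[members].mean(axis=1, skipna=True)
    out = pd.DataFrame(cols)
    out.index.name = "gene_id"
    return matrix.with_values(out)


def top_variable_features(
    matrices_stage1: list[ExpressionMatrix],
    n: int = 2000,
    candidates: list[str] | None = None,
) -> list[str]:
    """Top ``n`` genes by average within-type SD across per-type matrices.

    Per gene and per-type matrix, the SD over that type's samples is computed
    where the gene is detected (≥2 non-missing values); the average over
    detected types ranks the genes. Ties break lexicographically on gene id.
    ``candidates`` restricts the ranking (e.g. to detection-filtered genes).
    The default n of 2000 matches the discovery analysis feature count.
    """
    if n < 1:
        raise ValueError("n must be ≥ 1")
    per_type = []
    for m in matrices_stage1:
        vals = m.values
        counts = vals.notna().sum(axis=1)
        sd = vals.std(axis=1, ddof=1)
        sd[counts < 2] = np.nan
        per_type.append(sd)
    table = pd.concat(per_type, axis=1)
    avg_sd = table.mean(axis=1, skipna=True).dropna()
    if candidates is not None:
        avg_sd = avg_sd[avg_sd.index.isin(set(candidates))]
    if n > len(avg_sd):
        logger.warning("requested %d features but only %d candidates; returning all", n, len(avg_sd))
        n = len(avg_sd)
    order = avg_sd.to_frame("sd")
    order["gene"] = order.index
    order = order.sort_values(["sd", "gene"], ascending=[False, True])
    return list(order.index[:n])
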