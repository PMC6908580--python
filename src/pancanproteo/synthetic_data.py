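"""Synthetic multi-cancer cohorts with planted pan-cancer subtypes.

The generator emulates the structure of a multi-center proteomic compendium:
five tissue-based cancer types of unequal size (125/97/100/110/100 = 532
cases), ten planted pan-cancer subtypes that span cancer types (two of them
tissue-restricted, mirroring a basal-like-breast-only and a renal-only
subtype), disjoint over-expressed marker blocks per subtype, per-(gene, type)
tissue main effects, per-sample affine location/scale distortions (the
batch-like effects stage-1 normalization must remove), and per-(gene, type)
dropout so a gene can be undetected in an entire cancer type. Derived views
give an mRNA platform with per-gene correlation attenuation and an RPPA-like
platform restricted to a small antibody panel (169 genes by default).

All outputs are deterministic functions of the configuration and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import ExpressionMatrix, check_annotation

DEFAULT_TYPE_SIZES = {"breast": 125, "colon": 97, "ovarian": 100, "renal": 110, "uterine": 100}


@dataclass
class CohortConfig:
    """Study conditions for the synthetic cohort generator.

    ``effect_size`` is the marker over-expression in noise-SD units;
    ``tissue_effect_sd`` scales per-(gene, type) main effects;
    ``sample_shift_range``/``sample_scale_range`` bound the per-sample affine
    distortion x → scale·x + shift; ``missing_type_prob`` is the chance a gene
    goes undetected in a given cancer type; ``type_restricted_subtypes`` maps
    subtype index (0-based) to the cancer types it may occur in.
    """

    type_sizes: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_TYPE_SIZES))
    n_genes: int = 12000
    n_subtypes: int = 10
    markers_per_subtype: int = 120
    effect_size: float = 2.0
    tissue_effect_sd: float = 1.0
    sample_shift_range: tuple[float, float] = (-2.0, 2.0)
    sample_scale_range: tuple[float, float] = (0.5, 2.0)
    noise_sd: float = 1.0
    missing_type_prob: float = 0.1
    type_restricted_subtypes: dict[int, tuple[str, ...]] = field(
        default_factory=lambda: {3: ("breast",), 8: ("renal",)}
    )
    seed: int = 0

    def validate(self) -> None:
        if self.n_subtypes * self.markers_per_subtype > self.n_genes:
            raise ValueError("marker blocks exceed gene count")
        if not 0 <= self.missing_type_prob <= 1:
            raise ValueError("missing_type_prob must be in [0, 1]")
        for lo, hi in (self.sample_shift_range, self.sample_scale_range):
            if lo > hi:
                raise ValueError("range bounds out of order")
        if self.sample_scale_range[0] <= 0:
            raise ValueError("sample scales must be positive")
        if self.noise_sd < 0 or self.tissue_effect_sd < 0:
            raise ValueError("SDs must be non-negative")
        for s, types in self.type_restricted_subtypes.items():
            if not 0 <= s < self.n_subtypes:
                raise ValueError(f"restricted subtype index {s} out of range")
            unknown = set(types) - set(self.type_sizes)
            if unknown:
                raise ValueError(f"restricted subtype {s} names unknown types {unknown}")


@dataclass
class TruthLabels:
    """Ground truth: per-sample subtype, per-gene marker block, detection flags."""

    sample_subtype: pd.Series  # sample_id -> subtype index (0-based)
    gene_marker: pd.Series  # gene_id -> subtype index or -1
    detected: pd.DataFrame  # genes x cancer types, bool

    def subtype_name(self) -> pd.Series:
        return self.sample_subtype.map(lambda i: f"s{i + 1}")


def _allowed_subtypes(config: CohortConfig, ctype: str) -> list[int]:
    allowed = []
    for s in range(config.n_subtypes):
        restriction = config.type_restricted_subtypes.get(s)
        if restriction is None or ctype in restriction:
            allowed.append(s)
    return allowed


def generate_cohort(config: CohortConfig) -> tuple[ExpressionMatrix, pd.DataFrame, TruthLabels]:
    """Simulate a raw multi-type cohort with planted subtype structure.

    value(g, s) = tissue_effect(type(s), g) + effect_size·[g marks subtype(s)]
    + N(0, noise_sd²), then x → scale_s·x + shift_s per sample, then
    per-(gene, type) dropout. Subtypes are drawn uniformly over the subtypes
    allowed for each sample's cancer type.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    genes = [f"G{i:05d}" for i in range(config.n_genes)]
    gene_marker = np.full(config.n_genes, -1)
    for s in range(config.n_subtypes):
        lo = s * config.markers_per_subtype
        gene_marker[lo : lo + config.markers_per_subtype] = s

    sample_ids: list[str] = []
    sample_types: list[str] = []
    subtypes: list[int] = []
    for ctype, size in config.type_sizes.items():
        allowed = _allowed_subtypes(config, ctype)
        draws = rng.choice(allowed, size=size)
        for i in range(size):
            sample_ids.append(f"{ctype}_{i + 1:03d}")
            sample_types.append(ctype)
            subtypes.append(int(draws[i]))

    n = len(sample_ids)
    values = rng.normal(0.0, config.noise_sd, size=(config.n_genes, n))
    # tissue main effects, shared by all samples of a type
    tissue = {
        t: rng.normal(0.0, config.tissue_effect_sd, size=config.n_genes)
        for t in config.type_sizes
    }
    type_arr = np.array(sample_types)
    for t, eff in tissue.items():
        values[:, type_arr == t] += eff[:, None]
    # planted subtype marker blocks
    for j, s in enumerate(subtypes):
        block = gene_marker == s
        values[block, j] += config.effect_size
    # per-sample affine distortion (exercises stage-1 normalization)
    shifts = rng.uniform(*config.sample_shift_range, size=n)
    scales = rng.uniform(*config.sample_scale_range, size=n)
    values = values * scales[None, :] + shifts[None, :]
    # per-(gene, type) dropout
    detected = pd.DataFrame(True, index=genes, columns=list(config.type_sizes))
    for t in config.type_sizes:
        drop = rng.random(config.n_genes) < config.missing_type_prob
        detected[t] = ~drop
        values[np.ix_(drop, type_arr == t)] = np.nan

    frame = pd.DataFrame(values, index=pd.Index(genes, name="gene_id"), columns=sample_ids)
    matrix = ExpressionMatrix(frame, platform="protein", norm_state="raw")
    annotation = check_annotation(
        pd.DataFrame(
            {
                "sample_id": sample_ids,
                "cancer_type": sample_types,
                "cohort": [f"synthetic-{t}" for t in sample_types],
            }
        )
    )
    truth = TruthLabels(
        sample_subtype=pd.Series(subtypes, index=sample_ids),
        gene_marker=pd.Series(gene_marker, index=genes),
        detected=detected,
    )
    return matrix, annotation, truth


def derive_mrna_view(
    matrix: ExpressionMatrix,
    attenuation: float | Sequence[float] | Mapping[str, float] = 0.7,
    seed: int = 0,
) -> ExpressionMatrix:
    """Attenuated mRNA view: mrna = r·x + sqrt(1−r²)·z, z standard normal.

    ``attenuation`` is the target per-gene protein–mRNA correlation, scalar or
    per gene; for standardized input the expected empirical correlation per
    gene equals r. Missing entries stay missing.
    """
    g, n = matrix.shape
    if isinstance(attenuation, Mapping):
        r = np.array([attenuation[gid] for gid in matrix.gene_ids], dtype=float)
    else:
        r = np.broadcast_to(np.asarray(attenuation, dtype=float), (g,)).copy()
    if np.any((r < 0) | (r > 1)):
        raise ValueError("attenuation r must be in [0, 1]")
    rng = np.random.default_rng(seed)
    z = rng.normal(size=(g, n))
    vals = matrix.values.to_numpy()
    out = r[:, None] * vals + np.sqrt(1 - r[:, None] ** 2) * z
    out[np.isnan(vals)] = np.nan
    frame = pd.DataFrame(out, index=matrix.values.index, columns=matrix.values.columns)
    return ExpressionMatrix(frame, platform="mrna", norm_state=matrix.norm_state)


def derive_rppa_view(
    matrix: ExpressionMatrix,
    panel_size: int = 169,
    seed: int = 0,
    extra_noise_sd: float = 0.0,
) -> ExpressionMatrix:
    """RPPA-like view: a random antibody panel of ``panel_size`` genes.

    The default panel size mirrors the ~169 unique genes of a targeted
    protein array. Values carry over, with optional extra measurement noise.
    """
    if panel_size <= 0:
        raise ValueError("panel_size must be positive")
    g = matrix.shape[0]
    if panel_size > g:
        raise ValueError("panel_size exceeds gene count")
    rng = np.random.default_rng(seed)
    panel = rng.choice(g, size=panel_size, replace=False)
    vals = matrix.values.iloc[panel].copy()
    if extra_noise_sd > 0:
        noise = rng.normal(0.0, extra_noise_sd, size=vals.shape)
        vals = vals + pd.DataFrame(noise, index=vals.index, columns=vals.columns)
    return ExpressionMatrix(vals, platform="rppa", norm_state=matrix.norm_state)


def generate_pvalue_mixture(
    m: int, pi0: float, alt_beta_shape: float = 0.1, seed: int = 0
) -> np.ndarray:
    """p-value mixture: fraction pi0 Uniform(0,1), rest Beta(shape, 1).

    With shape < 1 the alternative component concentrates near 0; the mixture
    is the standard harness for FDR estimator calibration.
    """
    if not 0 <= pi0 <= 1:
        raise ValueError("pi0 must be in [0, 1]")
    if alt_beta_shape <= 0:
        raise ValueError("alt_beta_shape must be positive")
    rng = np.random.default_rng(seed)
    n_null = int(round(pi0 * m))
    nulls = rng.uniform(size=n_null)
    alts = rng.beta(alt_beta_shape, 1.0, size=m - n_null)
    p = np.concatenate([nulls, alts])
    rng.shuffle(p)
    return p
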