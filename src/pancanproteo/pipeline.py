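"""End-to-end orchestration: simulate → normalize → discover → classify.

`run_discovery_pipeline` executes the discovery arm on one cohort:
two-stage within-type normalization, detection filtering, top-variable
feature selection, consensus-clustering subtype discovery, per-subtype
marker selection, centroid construction, and differential-expression /
enrichment characterization. `run_transfer_validation` takes a built
classifier and external platform views, assigns subtypes per view, and
validates the transfer with overlap significance and permutation testing.
All randomness flows from a single root seed; every output file is hashed
into a manifest so a re-run with the same config is bitwise comparable.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .classifier import SubtypeClassifier, assign_subtypes, build_centroids, select_subtype_markers
from .consensus_cluster import ConsensusResult, discover_subtypes
from .io_formats import (
    ExpressionMatrix,
    check_annotation,
    detection_filter,
    read_annotation_tsv,
    read_expression_tsv,
    write_annotation_tsv,
    write_expression_tsv,
)
from .normalize import normalize_per_gene_within_type, normalize_two_stage, top_variable_features
from .stats import diffexp_table, overlap_significance, permutation_association_test
from .synthetic_data import CohortConfig, generate_cohort

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Configuration of the discovery pipeline (YAML-loadable)."""

    out_dir: str = "pipeline_out"
    expression: str | None = None  # raw expression TSV (genes × samples)
    annotation: str | None = None  # sample annotation TSV
    simulate: dict | None = None  # CohortConfig overrides; used when no expression path
    min_types: int = 3
    min_case_fraction: float = 0.0
    n_top_variable: int = 2000
    k_min: int = 2
    k_max: int = 15
    chosen_k: int = 10
    auto_k: bool = False
    reps: int = 100
    p_item: float = 0.8
    p_feature: float = 1.0
    markers_per_subtype: int = 100
    fallback_threshold: float = 0.05
    min_overlap: int = 10
    n_perm: int = 199
    seed: int = 0

    def validate(self) -> None:
        if not (self.k_min <= self.chosen_k <= self.k_max):
            raise ValueError("chosen_k outside k_range")
        for path in (self.expression, self.annotation):
            if path is not None and not Path(path).exists():
                raise FileNotFoundError(path)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_manifest(out_dir: Path, params: dict, files: list[Path]) -> Path:
    manifest = {
        "package": "pancanproteo",
        "version": __version__,
        "params": params,
        "files": {f.name: _sha256(f) for f in sorted(files)},
    }
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return path


def _split_by_type(matrix: ExpressionMatrix, annotation: pd.DataFrame) -> list[ExpressionMatrix]:
    from .io_formats import types_of

    types = types_of(annotation, matrix.sample_ids)
    return [
        matrix.with_values(matrix.values.loc[:, (types == t).to_numpy()])
        for t in types.unique()
    ]


def run_discovery_pipeline(config: PipelineConfig) -> dict:
    """Run the full discovery arm; returns the artifact bundle.

    Outputs written to ``config.out_dir``: labels.tsv, model.json,
    diffexp.tsv, consensus_diagnostics.tsv, truth.tsv (when simulated),
    and manifest.json with parameters and file hashes.
    """
    config.validate()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    truth = None
    if config.expression is not None:
        matrix = read_expression_tsv(config.expression)
        annotation = read_annotation_tsv(config.annotation)
    else:
        sim_kwargs = dict(config.simulate or {})
        sim_kwargs.setdefault("seed", config.seed)
        cohort_cfg = CohortConfig(**sim_kwargs)
        matrix, annotation, truth = generate_cohort(cohort_cfg)
        logger.info("simulated cohort: %d genes × %d samples", *matrix.shape)

    stage1, stage2, report = normalize_two_stage(matrix, annotation)
    filtered = detection_filter(matrix, annotation, config.min_types, config.min_case_fraction)
    candidates = filtered.gene_ids
    top_genes = top_variable_features(
        _split_by_type(stage1, annotation), n=config.n_top_variable, candidates=candidates
    )
    cluster_matrix = stage2.with_values(stage2.values.loc[top_genes])
    result, labeled_ann = discover_subtypes(
        cluster_matrix,
        annotation,
        k_range=range(config.k_min, config.k_max + 1),
        chosen_k=config.chosen_k,
        reps=config.reps,
        p_item=config.p_item,
        p_feature=config.p_feature,
        seed=config.seed,
        auto_k=config.auto_k,
    )
    labels = labeled_ann.set_index("sample_id")["subtype"].loc[stage2.sample_ids]

    marker_matrix = stage2.with_values(stage2.values.loc[candidates])
    features = select_subtype_markers(marker_matrix, labels, n_per_subtype=config.markers_per_subtype)
    model = build_centroids(
        stage2, labels, features,
        markers_per_subtype=config.markers_per_subtype,
        fallback_threshold=config.fallback_threshold,
        min_overlap=config.min_overlap,
    )
    diffexp = diffexp_table(marker_matrix, labels)

    files = []
    write_annotation_tsv(labeled_ann, out_dir / "labels.tsv")
    files.append(out_dir / "labels.tsv")
    model.to_json(out_dir / "model.json")
    files.append(out_dir / "model.json")
    diffexp.to_csv(out_dir / "diffexp.tsv", sep="\t", index=False, float_format="%.6g")
    files.append(out_dir / "diffexp.tsv")
    diag = pd.DataFrame(
        {
            "k": result.k_values,
            "cdf_area": [result.cdf_area[k] for k in result.k_values],
            "delta_area": [result.delta_area[k] for k in result.k_values],
        }
    )
    diag.to_csv(out_dir / "consensus_diagnostics.tsv", sep="\t", index=False, float_format="%.8g")
    files.append(out_dir / "consensus_diagnostics.tsv")
    report.write_tsv(out_dir / "normalization_report.tsv")
    files.append(out_dir / "normalization_report.tsv")
    if truth is not None:
        truth_table = pd.DataFrame(
            {"sample_id": truth.sample_subtype.index, "subtype_index": truth.sample_subtype.to_numpy()}
        )
        truth_table.to_csv(out_dir / "truth.tsv", sep="\t", index=False)
        files.append(out_dir / "truth.tsv")

    params = dataclasses.asdict(config)
    manifest_path = _write_manifest(out_dir, params, files)
    return {
        "matrix_raw": matrix,
        "annotation": annotation,
        "stage1": stage1,
        "stage2": stage2,
        "filtered_genes": candidates,
        "top_genes": top_genes,
        "consensus": result,
        "labels": labels,
        "features": features,
        "classifier": model,
        "diffexp": diffexp,
        "truth": truth,
        "manifest": manifest_path,
    }


def run_transfer_validation(
    model: SubtypeClassifier,
    views: dict[str, tuple[ExpressionMatrix, pd.DataFrame]],
    out_dir: str | Path | None = None,
    n_perm: int = 199,
    seed: int = 0,
) -> dict:
    """Classify external platform views and validate the transfer.

    Each view is a (matrix, annotation) pair; raw matrices get the external
    single-stage per-gene within-type normalization before assignment.
    Produces per-view assignment tables, pairwise overlap significance over
    shared samples, and a permutation p-value per view.
    """
    if not views:
        raise ValueError("run_transfer_validation needs ≥1 view")
    assignments: dict[str, pd.DataFrame] = {}
    perm: dict[str, tuple[float, float]] = {}
    rng = np.random.default_rng(seed)
    for name, (matrix, annotation) in views.items():
        if matrix.norm_state == "raw":
            matrix, _ = normalize_per_gene_within_type(matrix, annotation)
        assignments[name] = assign_subtypes(model, matrix, annotation)
        perm[name] = permutation_association_test(
            model, matrix, annotation, n_perm=n_perm, seed=int(rng.integers(2**31))
        )
    overlaps = {}
    names = list(views)
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            shared = assignments[a].index.intersection(assignments[b].index)
            if len(shared) == 0:
                logger.warning("views %s and %s share no samples; overlap skipped", a, b)
                continue
            overlaps[(a, b)] = overlap_significance(
                assignments[a]["best_subtype"], assignments[b]["best_subtype"]
            )
    report = {"assignments": assignments, "overlaps": overlaps, "permutation": perm}
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        files = []
        for name, table in assignments.items():
            path = out_dir / f"assignments_{name}.tsv"
            table.to_csv(path, sep="\t", float_format="%.6g")
            files.append(path)
        summary = {
            "permutation": {name: {"statistic": s, "p": p} for name, (s, p) in perm.items()},
            "overlap_min_p": {
                f"{a}|{b}": float(o.p.to_numpy().min()) for (a, b), o in overlaps.items()
            },
        }
        (out_dir / "transfer_report.json").write_text(json.dumps(summary, indent=1))
        files.append(out_dir / "transfer_report.json")
        _write_manifest(out_dir, {"n_perm": n_perm, "seed": seed}, files)
    return report
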