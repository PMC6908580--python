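"""Shared fixtures: tiny matrix builders and one full discovery run.

The session-scoped ``discovery`` fixture executes the whole discovery arm
once on the default synthetic cohort (normalization → detection filter →
top-variable selection → consensus k-scan → marker selection → centroids)
so that the recovery, classifier and transfer tests can all interrogate the
same run instead of each paying for their own.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import pancanproteo as pp
from pancanproteo.consensus_cluster import cdf_and_delta, consensus_scan, final_labels
from pancanproteo.io_formats import ExpressionMatrix, check_annotation, types_of
from pancanproteo.normalize import top_variable_features

COHORT_SEED = 5
SCAN_SEED = 7
SCAN_REPS = 100


def make_matrix(values, genes=None, samples=None, platform="protein", norm_state="raw"):
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{j}" for j in range(values.shape[1])]
    frame = pd.DataFrame(values, index=pd.Index(genes, name="gene_id"), columns=samples)
    return ExpressionMatrix(frame, platform=platform, norm_state=norm_state)


def make_annotation(sample_ids, cancer_types, cohort="c0"):
    return check_annotation(
        pd.DataFrame(
            {"sample_id": sample_ids, "cancer_type": cancer_types, "cohort": cohort}
        )
    )


@pytest.fixture(scope="session")
def default_cohort():
    matrix, annotation, truth = pp.generate_cohort(pp.CohortConfig(seed=COHORT_SEED))
    return {"matrix": matrix, "annotation": annotation, "truth": truth}


@pytest.fixture(scope="session")
def discovery(default_cohort):
    matrix = default_cohort["matrix"]
    annotation = default_cohort["annotation"]
    stage1, stage2, report = pp.normalize_two_stage(matrix, annotation)
    filtered = pp.detection_filter(matrix, annotation, min_types=3, min_case_fraction=0.0)
    types = types_of(annotation, matrix.sample_ids)
    per_type = [
        stage1.with_values(stage1.values.loc[:, (types == t).to_numpy()])
        for t in types.unique()
    ]
    top = top_variable_features(per_type, n=2000, candidates=filtered.gene_ids)
    cluster_matrix = stage2.with_values(stage2.values.loc[top])
    consensus = consensus_scan(cluster_matrix, range(2, 16), reps=SCAN_REPS, seed=SCAN_SEED)
    areas, delta = cdf_and_delta(consensus)
    labels = pd.Series(final_labels(consensus[10], 10), index=matrix.sample_ids).map(
        lambda c: f"k{c}"
    )
    marker_matrix = stage2.with_values(stage2.values.loc[filtered.gene_ids])
    features = pp.select_subtype_markers(marker_matrix, labels, n_per_subtype=100)
    clf = pp.build_centroids(stage2, labels, features, markers_per_subtype=100)
    self_assign = pp.assign_subtypes(clf, stage2)
    return {
        **default_cohort,
        "stage1": stage1,
        "stage2": stage2,
        "report": report,
        "filtered": filtered,
        "top_genes": top,
        "cluster_matrix": cluster_matrix,
        "consensus": consensus,
        "cdf_area": areas,
        "delta_area": delta,
        "labels": labels,
        "features": features,
        "classifier": clf,
        "self_assign": self_assign,
    }


@pytest.fixture(scope="session")
def label_to_truth(discovery):
    """Majority-vote map from discovered subtype name to planted subtype index."""
    truth = discovery["truth"]
    conf = pd.crosstab(discovery["labels"], truth.sample_subtype.loc[discovery["labels"].index])
    return conf.idxmax(axis=1).to_dict()
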