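"""Centroid-based pan-cancer subtype classifier.

For each discovered subtype, the top-n over-expressed genes (subtype vs rest
t-tests on within-type normalized values, positive mean difference, ranked
by t) define the marker set; a disjointness-with-refill rule awards a gene
claimed by several subtypes to the one with the larger t and refills the
displaced subtypes from their next-ranked candidates, so K subtypes × n
markers yield exactly K·n unique features (1000 at the defaults of 10
subtypes × 100). Per-subtype centroids are the missing-aware means of the
normalized values over the subtype's samples. An external profile —
normalized per gene within its own cancer types, on any platform whose ids
match — is assigned to the subtype whose centroid shows the highest Pearson
correlation over mutually non-missing classifier features, with an
"unclassified" fallback for degenerate profiles.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .io_formats import ExpressionMatrix
from .stats import qvalues, ttest_groups

logger = logging.getLogger(__name__)

SCHEMA_VERSION = 1
UNCLASSIFIED = "unclassified"


@dataclass
class SubtypeClassifier:
    """Marker features, per-subtype centroid profiles, and assignment rules.

    ``features`` has columns (gene_id, subtype, t, q, rank); ``centroids``
    is features × subtypes in SD-from-median units. ``fallback_threshold``
    is the minimum best correlation below which a profile is considered
    patternless (only enforced when assignment runs with the fallback rule
    on); ``min_overlap`` is the minimum number of shared non-missing
    features needed to attempt a correlation.
    """

    subtype_names: list[str]
    features: pd.DataFrame
    centroids: pd.DataFrame
    markers_per_subtype: int
    fallback_threshold: float = 0.05
    min_overlap: int = 10

    def __post_init__(self) -> None:
        if self.features["gene_id"].duplicated().any():
            raise ValueError("classifier features must be disjoint across subtypes")
        if list(self.centroids.index) != list(self.features["gene_id"]):
            raise ValueError("centroid rows must match the feature list")
        if list(self.centroids.columns) != list(self.subtype_names):
            raise ValueError("centroid columns must match subtype names")

    def to_json(self, path: str | Path) -> None:
        payload = {
            "version": SCHEMA_VERSION,
            "subtype_names": self.subtype_names,
            "markers_per_subtype": self.markers_per_subtype,
            "fallback_threshold": self.fallback_threshold,
            "min_overlap": self.min_overlap,
            "features": [
                {
                    "gene": row.gene_id,
                    "subtype": row.subtype,
                    "t": None if pd.isna(row.t) else float(row.t),
                    "q": None if pd.isna(row.q) else float(row.q),
                }
                for row in self.features.itertuples()
            ],
            "centroids": [
                [None if pd.isna(v) else float(v) for v in row]
                for row in self.centroids.to_numpy()
            ],
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "SubtypeClassifier":
        payload = json.loads(Path(path).read_text())
        if payload.get("version") != SCHEMA_VERSION:
            raise ValueError(f"unsupported classifier schema version {payload.get('version')}")
        features = pd.DataFrame(
            {
                "gene_id": [f["gene"] for f in payload["features"]],
                "subtype": [f["subtype"] for f in payload["features"]],
                "t": [np.nan if f["t"] is None else f["t"] for f in payload["features"]],
                "q": [np.nan if f["q"] is None else f["q"] for f in payload["features"]],
            }
        )
        centroids = pd.DataFrame(
            [[np.nan if v is None else v for v in row] for row in payload["centroids"]],
            index=features["gene_id"].to_list(),
            columns=payload["subtype_names"],
        )
        return cls(
            subtype_names=list(payload["subtype_names"]),
            features=features,
            centroids=centroids,
            markers_per_subtype=int(payload["markers_per_subtype"]),
            fallback_threshold=float(payload["fallback_threshold"]),
            min_overlap=int(payload["min_overlap"]),
        )


# ---------------------------------------------------------------------------
# marker selection


def _subtype_tests(
    matrix: ExpressionMatrix, labels: pd.Series, subtype_names: list[str], welch: bool = False
) -> dict[str, pd.DataFrame]:
    values = matrix.values.to_numpy()
    labels = labels.loc[matrix.sample_ids]
    out = {}
    for subtype in subtype_names:
        mask = (labels == subtype).to_numpy()
        res = ttest_groups(values, mask, welch=welch)
        ok = ~np.isnan(res["p"])
        q = np.full(res["p"].shape, np.nan)
        if ok.any():
            q[ok] = qvalues(res["p"][ok])
        out[subtype] = pd.DataFrame(
            {
                "gene_id": matrix.gene_ids,
                "t": res["t"],
                "p": res["p"],
                "q": q,
                "mean_in": res["mean_in"],
                "mean_out": res["mean_out"],
            }
        )
    return out


def select_subtype_markers(
    matrix: ExpressionMatrix,
    labels: pd.Series,
    n_per_subtype: int = 100,
    welch: bool = False,
) -> pd.DataFrame:
    """Top-n over-expressed genes per subtype, disjoint with refill.

    Candidates per subtype require a positive subtype-vs-rest mean difference
    and are ranked by t descending; a gene wanted by several subtypes goes to
    the subtype with the larger t (ties: earlier subtype in label order), and
    displaced subtypes refill from their next candidates. Subtypes with <3
    samples are excluded with a warning; a subtype with fewer positive
    candidates than ``n_per_subtype`` contributes a shorter list.
    """
    labels = labels.loc[matrix.sample_ids]
    counts = labels.dropna().value_counts()
    subtype_names = [s for s in sorted(counts.index) if counts[s] >= 3]
    skipped = sorted(set(counts.index) - set(subtype_names))
    if skipped:
        logger.warning("subtypes with <3 samples excluded from marker selection: %s", skipped)
    tests = _subtype_tests(matrix, labels, subtype_names, welch=welch)

    ranked: dict[str, list[tuple[str, float]]] = {}
    for s in subtype_names:
        tab = tests[s]
        cand = tab[(tab["mean_in"] - tab["mean_out"] > 0) & tab["t"].notna()]
        cand = cand.sort_values(["t", "gene_id"], ascending=[False, True], kind="stable")
        ranked[s] = list(zip(cand["gene_id"], cand["t"]))

    # greedy claim resolution: each subtype proposes down its ranked list; a
    # contested gene goes to the larger t, losers continue proposing
    order = {s: i for i, s in enumerate(subtype_names)}
    pointer = {s: 0 for s in subtype_names}
    holdings: dict[str, list[str]] = {s: [] for s in subtype_names}
    owner: dict[str, tuple[str, float]] = {}
    active = list(subtype_names)
    while active:
        s = active.pop(0)
        while len(holdings[s]) < n_per_subtype and pointer[s] < len(ranked[s]):
            gene, t = ranked[s][pointer[s]]
            pointer[s] += 1
            if gene not in owner:
                owner[gene] = (s, t)
                holdings[s].append(gene)
            else:
                o, ot = owner[gene]
                if t > ot or (t == ot and order[s] < order[o]):
                    holdings[o].remove(gene)
                    owner[gene] = (s, t)
                    holdings[s].append(gene)
                    if o not in active:
                        active.append(o)
        if len(holdings[s]) < n_per_subtype and pointer[s] >= len(ranked[s]):
            logger.warning(
                "subtype %s: only %d positive candidates (< %d requested)",
                s, len(holdings[s]), n_per_subtype,
            )

    rows = []
    for s in subtype_names:
        tab = tests[s].set_index("gene_id")
        for rank, gene in enumerate(holdings[s], start=1):
            rows.append(
                {
                    "gene_id": gene,
                    "subtype": s,
                    "t": tab.loc[gene, "t"],
                    "p": tab.loc[gene, "p"],
                    "q": tab.loc[gene, "q"],
                    "rank": rank,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# centroids


def build_centroids(
    matrix: ExpressionMatrix,
    labels: pd.Series,
    features: pd.DataFrame,
    markers_per_subtype: int | None = None,
    fallback_threshold: float = 0.05,
    min_overlap: int = 10,
) -> SubtypeClassifier:
    """Per-subtype mean normalized profiles over the classifier features."""
    missing = [g for g in features["gene_id"] if g not in set(matrix.gene_ids)]
    if missing:
        raise ValueError(f"features absent from matrix: {missing[:5]}")
    labels = labels.loc[matrix.sample_ids]
    subtype_names = sorted(labels.dropna().unique())
    sub = matrix.values.loc[features["gene_id"].to_list()]
    cols = {}
    for s in subtype_names:
        block = sub.loc[:, (labels == s).to_numpy()]
        cols[s] = block.mean(axis=1, skipna=True)
        empty = cols[s].isna()
        if empty.any():
            logger.warning("subtype %s: %d centroid entries missing", s, int(empty.sum()))
    centroids = pd.DataFrame(cols)
    if markers_per_subtype is None:
        markers_per_subtype = int(features.groupby("subtype").size().max())
    return SubtypeClassifier(
        subtype_names=subtype_names,
        features=features.reset_index(drop=True),
        centroids=centroids,
        markers_per_subtype=markers_per_subtype,
        fallback_threshold=fallback_threshold,
        min_overlap=min_overlap,
    )


# ---------------------------------------------------------------------------
# assignment


def assign_subtypes(
    classifier: SubtypeClassifier,
    target: ExpressionMatrix,
    annotation: pd.DataFrame | None = None,
    apply_fallback: bool = False,
) -> pd.DataFrame:
    """Assign each target profile to its highest-correlation centroid.

    Pearson correlation is computed over the classifier features present and
    non-missing in both the profile and the centroid. A profile falls back to
    "unclassified" when fewer than ``min_overlap`` features are usable for
    its best centroid, when it has zero variance on the shared features, or —
    with ``apply_fallback`` — when the best correlation is below the
    classifier's fallback threshold. Ties go to the lower-indexed subtype.

    Returns a table indexed by sample id with one correlation column per
    subtype plus best_subtype, best_r, n_features_used, fallback.
    """
    shared = [g for g in classifier.centroids.index if g in set(target.gene_ids)]
    if not shared:
        raise ValueError("no shared features between classifier and target")
    C = classifier.centroids.loc[shared].to_numpy()  # features x subtypes
    X = target.values.loc[shared].to_numpy()  # features x samples
    n_sub = C.shape[1]
    n_samp = X.shape[1]
    r = np.full((n_samp, n_sub), np.nan)
    n_used = np.zeros((n_samp, n_sub), dtype=int)
    for s in range(n_sub):
        c = C[:, s]
        ok = ~np.isnan(c)
        Mx = ~np.isnan(X[ok])
        cs = c[ok]
        Xs = np.where(Mx, X[ok], 0.0)
        n = Mx.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            sum_x = Xs.sum(axis=0)
            sum_c = (cs[:, None] * Mx).sum(axis=0)
            sum_xx = (Xs**2).sum(axis=0)
            sum_cc = ((cs**2)[:, None] * Mx).sum(axis=0)
            sum_xc = (Xs * cs[:, None]).sum(axis=0)
            cov = sum_xc - sum_x * sum_c / n
            vx = sum_xx - sum_x**2 / n
            vc = sum_cc - sum_c**2 / n
            rs = cov / np.sqrt(vx * vc)
        rs[(n < 2) | ~np.isfinite(rs)] = np.nan
        r[:, s] = np.clip(rs, -1.0, 1.0)
        n_used[:, s] = n

    rows = []
    for i, sample in enumerate(target.sample_ids):
        corr = r[i]
        if np.all(np.isnan(corr)):
            best, best_r, used, fb = UNCLASSIFIED, np.nan, int(n_used[i].max()), True
        else:
            j = int(np.nanargmax(corr))
            best, best_r, used = classifier.subtype_names[j], float(corr[j]), int(n_used[i, j])
            fb = used < classifier.min_overlap or (
                apply_fallback and best_r < classifier.fallback_threshold
            )
            if fb:
                best = UNCLASSIFIED
        row = {"sample_id": sample, "best_subtype": best, "best_r": best_r,
               "n_features_used": used, "fallback": bool(fb)}
        for j, name in enumerate(classifier.subtype_names):
            row[f"r_{name}"] = r[i, j]
        rows.append(row)
    table = pd.DataFrame(rows).set_index("sample_id")
    if annotation is not None:
        from .io_formats import types_of

        table["cancer_type"] = types_of(annotation, list(table.index)).to_numpy()
    return table


def build_panel_classifier(
    matrix: ExpressionMatrix,
    labels: pd.Series,
    panel: Sequence[str],
    p_threshold: float = 0.001,
    fallback_threshold: float = 0.05,
    min_overlap: int = 10,
) -> SubtypeClassifier:
    """Classifier restricted to a feature panel (e.g. an RPPA antibody set).

    Keeps panel genes significantly associated with ≥1 subtype (subtype-vs-
    rest t-test p below ``p_threshold``, the conventional 0.001 screen for
    targeted panels); each kept gene is attributed to the subtype where it is
    most over-expressed. Centroids are built over the surviving features.
    """
    if len(panel) == 0:
        raise ValueError("panel must be non-empty")
    present = [g for g in panel if g in set(matrix.gene_ids)]
    if not present:
        raise ValueError("no panel genes present in matrix")
    sub = ExpressionMatrix(matrix.values.loc[present], matrix.platform, matrix.norm_state)
    labels = labels.loc[matrix.sample_ids]
    counts = labels.dropna().value_counts()
    subtype_names = [s for s in sorted(counts.index) if counts[s] >= 3]
    tests = _subtype_tests(sub, labels, subtype_names)
    best_t = pd.Series(-np.inf, index=present)
    best_sub = pd.Series("", index=present)
    min_p = pd.Series(np.nan, index=present)
    qs = pd.Series(np.nan, index=present)
    for s in subtype_names:
        tab = tests[s].set_index("gene_id")
        over = tab["t"] > best_t
        best_t[over] = tab.loc[over, "t"]
        best_sub[over] = s
        qs[over] = tab.loc[over, "q"]
        min_p = pd.concat([min_p, tab["p"]], axis=1).min(axis=1)
    keep = [g for g in present if min_p[g] < p_threshold]
    if not keep:
        raise ValueError(f"no panel features significant at p < {p_threshold}")
    features = pd.DataFrame(
        {
            "gene_id": keep,
            "subtype": [best_sub[g] for g in keep],
            "t": [best_t[g] for g in keep],
            "q": [qs[g] for g in keep],
            "rank": range(1, len(keep) + 1),
        }
    )
    return build_centroids(
        matrix, labels, features,
        markers_per_subtype=int(features.groupby("subtype").size().max()),
        fallback_threshold=fallback_threshold, min_overlap=min_overlap,
    )
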