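"""Gene-signature scoring of normalized expression matrices.

Pathway activity per sample is summarized either as the mean of the
signature genes' normalized values (hypoxia, WNT, NOTCH, NRF2/KEAP1,
KEGG metabolic sets), as a composite summing antagonist/agonist/target
component means (WNT composite), or as a within-profile t-score: a Welch
t-statistic contrasting the profile's values on the signature's up genes
against its down genes (or against all remaining genes when no down set is
given), used for oncogenic signatures such as k-ras, MYC and YAP1. Scores
can be display-normalized to SD-from-median units across samples, and
summarized per subtype as subtype-vs-rest t-statistics.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .io_formats import ExpressionMatrix, GeneSet, GeneSetCollection
from .stats import qvalues, ttest_groups

logger = logging.getLogger(__name__)

_TSCORE_EPS = 1e-8


class SignatureError(ValueError):
    pass


def mean_signature_score(matrix: ExpressionMatrix, gene_set: GeneSet | list[str]) -> pd.Series:
    """Per-sample mean of available normalized values of the signature genes."""
    genes = gene_set.up if isinstance(gene_set, GeneSet) else list(gene_set)
    name = gene_set.name if isinstance(gene_set, GeneSet) else "signature"
    present = [g for g in genes if g in set(matrix.gene_ids)]
    if not present:
        raise SignatureError(f"signature {name!r} matches no genes in the matrix")
    scores = matrix.values.loc[present].mean(axis=0, skipna=True)
    scores.name = name
    return scores


def composite_wnt_score(
    matrix: ExpressionMatrix,
    antagonist_set: list[str],
    agonist_set: list[str],
    target_set: list[str],
) -> pd.Series:
    """Composite pathway score: sum of component mean scores.

    A component with no matched genes contributes 0 (flagged in the log);
    all three components unmatched is an error.
    """
    total = None
    matched = 0
    for label, genes in (
        ("antagonist", antagonist_set),
        ("agonist", agonist_set),
        ("target", target_set),
    ):
        if not genes:
            continue
        try:
            part = mean_signature_score(matrix, list(genes))
        except SignatureError:
            logger.warning("WNT composite: %s component matched no genes", label)
            continue
        matched += 1
        total = part if total is None else total.add(part, fill_value=0.0)
    if matched == 0:
        raise SignatureError("WNT composite: no component matched any gene")
    total.name = "WNT_composite"
    return total


def t_score(profile: pd.Series, up_set: list[str], down_set: list[str] | None = None) -> float:
    """Within-profile t-score: Welch t of up-gene values vs down-gene values.

    With an empty down set, the up genes are contrasted against all other
    genes in the profile. A variance floor of 1e-8 guards constant groups;
    fewer than 2 usable genes in a compared group yields NaN (flagged).
    """
    up = [g for g in up_set if g in profile.index]
    if down_set:
        down = [g for g in down_set if g in profile.index]
    else:
        up_lookup = set(up)
        down = [g for g in profile.index if g not in up_lookup]
    x = profile.loc[up].dropna().to_numpy()
    y = profile.loc[down].dropna().to_numpy() if down else np.array([])
    if x.size < 2 or y.size < 2:
        logger.warning("t_score: <2 usable genes in a group (up=%d, down=%d)", x.size, y.size)
        return float("nan")
    vx = np.var(x, ddof=1) + _TSCORE_EPS
    vy = np.var(y, ddof=1) + _TSCORE_EPS
    return float((x.mean() - y.mean()) / np.sqrt(vx / x.size + vy / y.size))


def score_collection(matrix: ExpressionMatrix, collection: GeneSetCollection) -> pd.DataFrame:
    """Score every signature in a collection; rows = signatures, cols = samples.

    The per-set ``method`` picks the metric: ``mean`` (average expression),
    ``tscore`` (up-vs-down within-profile t), or ``composite`` (sum of up and
    down component means — for composites encoded as a single signed set).
    """
    rows = {}
    for gs in collection:
        if gs.method == "mean":
            rows[gs.name] = mean_signature_score(matrix, gs)
        elif gs.method == "tscore":
            rows[gs.name] = pd.Series(
                {s: t_score(matrix.values[s], gs.up, gs.down) for s in matrix.sample_ids},
                name=gs.name,
            )
        elif gs.method == "composite":
            rows[gs.name] = composite_wnt_score(matrix, [], gs.down, gs.up)
        else:
            raise SignatureError(f"unknown scoring method {gs.method!r} for {gs.name!r}")
    return pd.DataFrame(rows).T


def subtype_signature_tstats(scores: pd.DataFrame, labels: pd.Series) -> pd.DataFrame:
    """Per (signature, subtype) t-statistic of scores, subtype vs rest.

    Returns a long table (signature, subtype, t, p, q); q-values computed per
    signature. Subtypes with fewer than 3 samples are skipped with a warning.
    """
    labels = labels.loc[scores.columns]
    counts = labels.dropna().value_counts()
    subtypes = [s for s in sorted(counts.index) if counts[s] >= 3]
    for s in sorted(set(counts.index) - set(subtypes)):
        logger.warning("subtype %s below size threshold; skipped", s)
    values = scores.to_numpy()
    frames = []
    for s in subtypes:
        mask = (labels == s).to_numpy()
        res = ttest_groups(values, mask)
        frames.append(
            pd.DataFrame(
                {"signature": scores.index, "subtype": s, "t": res["t"], "p": res["p"]}
            )
        )
    table = pd.concat(frames, ignore_index=True)
    table["q"] = np.nan
    for sig in scores.index:
        rows = table["signature"] == sig
        ok = rows & table["p"].notna()
        if ok.any():
            table.loc[ok, "q"] = qvalues(table.loc[ok, "p"].to_numpy())
    return table


def display_normalize_scores(scores: pd.DataFrame) -> pd.DataFrame:
    """Normalize each signature's scores across samples to SD-from-median units.

    Signatures with zero SD (constant scores) become all-missing and are
    logged. Requires ≥3 samples.
    """
    if scores.shape[1] < 3:
        raise SignatureError("display normalization needs ≥3 samples")
    out = scores.copy().astype(float)
    for sig in out.index:
        row = out.loc[sig]
        ok = row.notna()
        sd = row[ok].std(ddof=1)
        if not np.isfinite(sd) or sd == 0:
            logger.warning("signature %s constant across samples; set to missing", sig)
            out.loc[sig] = np.nan
            continue
        out.loc[sig] = (row - row[ok].median()) / sd
    return out
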