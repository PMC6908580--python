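"""Differential expression, FDR estimation, enrichment, and overlap tests.

Differential expression uses two-sample t-tests on log2-scale (normalized)
values, pooled-variance by default with a Welch option. False discovery
rates follow the Storey–Tibshirani q-value estimator: the null proportion
π0 is estimated from the p-value distribution over a λ grid and folded into
step-up monotonized q-values (π0 forced to 1 recovers Benjamini–Hochberg).
Gene-category enrichment and classification-overlap significance use
one-sided Fisher's exact (hypergeometric tail) tests against an explicit
background universe. The permutation test checks that cross-cohort subtype
assignment strength (mean best-centroid correlation) beats a gene-identity-
destroyed null.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

logger = logging.getLogger(__name__)

DEFAULT_LAMBDA_GRID = np.round(np.arange(0.0, 0.901, 0.05), 2)


# ---------------------------------------------------------------------------
# t-tests


def ttest_groups(
    values: np.ndarray, in_mask: np.ndarray, welch: bool = False
) -> dict[str, np.ndarray]:
    """Vectorized two-sample t-tests, one per row, group vs rest.

    ``values`` is genes × samples (NaN-aware); ``in_mask`` flags the "in"
    group columns. Pooled-variance Student t by default (df = n1 + n2 − 2);
    Welch–Satterthwaite when ``welch``. Rows with <2 usable values in either
    group get NaN. Zero pooled variance yields t=0, p=1 at equal means and
    ±inf, p=0 otherwise.
    """
    values = np.asarray(values, dtype=float)
    in_mask = np.asarray(in_mask, dtype=bool)
    x = values[:, in_mask]
    y = values[:, ~in_mask]
    def _moments(a: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        ok = ~np.isnan(a)
        n = ok.sum(axis=1)
        af = np.where(ok, a, 0.0)
        with np.errstate(invalid="ignore", divide="ignore"):
            m = af.sum(axis=1) / n
            dev = np.where(ok, a - m[:, None], 0.0)
            v = (dev**2).sum(axis=1) / (n - 1)
        return n, m, v

    n1, m1, v1 = _moments(x)
    n2, m2, v2 = _moments(y)
    ok = (n1 >= 2) & (n2 >= 2)
    t = np.full(values.shape[0], np.nan)
    p = np.full(values.shape[0], np.nan)
    df = np.full(values.shape[0], np.nan)
    with np.errstate(invalid="ignore", divide="ignore"):
        if welch:
            se2 = v1 / n1 + v2 / n2
            df_ok = se2**2 / (
                (v1 / n1) ** 2 / np.maximum(n1 - 1, 1) + (v2 / n2) ** 2 / np.maximum(n2 - 1, 1)
            )
            denom = np.sqrt(se2)
        else:
            sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / np.maximum(n1 + n2 - 2, 1)
            df_ok = (n1 + n2 - 2).astype(float)
            denom = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
        diff = m1 - m2
        t_ok = diff / denom
    df[ok] = df_ok[ok]
    t[ok] = t_ok[ok]
    zero_var = ok & (denom == 0)
    if zero_var.any():
        same = zero_var & (diff == 0)
        t[same] = 0.0
        t[zero_var & ~same] = np.sign(diff[zero_var & ~same]) * np.inf
        if (zero_var & ~same).any():
            logger.warning("%d rows with zero variance and unequal means", int((zero_var & ~same).sum()))
    finite = ok & np.isfinite(t)
    p[finite] = 2.0 * sps.t.sf(np.abs(t[finite]), df[finite])
    p[ok & np.isposinf(np.abs(t))] = 0.0
    p[ok & (t == 0) & (denom == 0)] = 1.0
    return {"t": t, "p": p, "mean_in": m1, "mean_out": m2, "n_in": n1, "n_out": n2}


def two_sample_t(x: Sequence[float], y: Sequence[float], welch: bool = False) -> tuple[float, float]:
    """Two-sample t-test (pooled by default) on two value vectors; NaNs dropped."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    values = np.full((1, x.size + y.size), np.nan)
    values[0, : x.size] = x
    values[0, x.size :] = y
    mask = np.zeros(x.size + y.size, dtype=bool)
    mask[: x.size] = True
    res = ttest_groups(values, mask, welch=welch)
    t, p = float(res["t"][0]), float(res["p"][0])
    if np.isnan(t):
        raise ValueError("each group needs ≥2 non-missing values")
    return t, p


# ---------------------------------------------------------------------------
# Storey–Tibshirani q-values


def estimate_pi0(
    p: np.ndarray,
    lambda_grid: Sequence[float] | None = None,
    method: str = "spline",
    fixed_lambda: float = 0.5,
) -> float:
    """Estimate the null proportion π0 from a p-value distribution.

    π̂0(λ) = #{p > λ} / (m(1 − λ)). The ``spline`` method smooths π̂0(λ)
    over the grid with a least-squares cubic fit and takes the value at the
    largest λ; ``fixed`` uses a single λ. The estimate is clamped to (0, 1].
    """
    p = np.asarray(p, dtype=float)
    m = p.size
    if m == 0:
        return 1.0
    if method == "fixed":
        lam = float(fixed_lambda)
        pi0 = np.sum(p > lam) / (m * (1.0 - lam))
    elif method == "spline":
        grid = np.asarray(DEFAULT_LAMBDA_GRID if lambda_grid is None else lambda_grid, dtype=float)
        pi0_lambda = np.array([np.sum(p > lam) / (m * (1.0 - lam)) for lam in grid])
        coeffs = np.polyfit(grid, pi0_lambda, deg=3)
        pi0 = float(np.polyval(coeffs, grid.max()))
    else:
        raise ValueError(f"unknown pi0 method {method!r}")
    return float(min(1.0, max(pi0, 1.0 / m)))


def qvalues(
    p: Sequence[float],
    lambda_grid: Sequence[float] | None = None,
    pi0_method: str = "spline",
    fixed_lambda: float = 0.5,
    pi0: float | None = None,
) -> np.ndarray:
    """Storey–Tibshirani q-values for a vector of p-values.

    q_(i) = π̂0 · p_(i) · m / i with step-up monotonization from the largest
    p downward. Passing ``pi0=1`` reproduces Benjamini–Hochberg adjusted
    p-values exactly.
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return np.array([])
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if pi0 is None:
        pi0 = estimate_pi0(p, lambda_grid, method=pi0_method, fixed_lambda=fixed_lambda)
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order]
    q = pi0 * ranked * m / np.arange(1, m + 1)
    q = np.minimum.accumulate(q[::-1])[::-1]
    q = np.minimum(q, 1.0)
    out = np.empty(m)
    out[order] = q
    return out


# ---------------------------------------------------------------------------
# Fisher-exact enrichment


def fisher_enrichment(
    list_genes: Iterable[str], category_genes: Iterable[str], background: Iterable[str]
) -> tuple[dict[str, int], float]:
    """One-sided over-representation test of a gene list in a category.

    Hypergeometric tail P(X ≥ overlap) with population the background
    universe (e.g. the detection-filtered gene set). List genes outside the
    background are an error naming the first offender.
    """
    bg = set(background)
    lst = set(list_genes)
    outside = lst - bg
    if outside:
        raise ValueError(f"list gene {sorted(outside)[0]!r} not in background")
    cat = set(category_genes) & bg
    overlap = len(lst & cat)
    counts = {
        "n_list_in_cat": overlap,
        "n_list": len(lst),
        "n_bg_in_cat": len(cat),
        "n_bg": len(bg),
    }
    p = float(sps.hypergeom.sf(overlap - 1, len(bg), len(cat), len(lst)))
    return counts, min(p, 1.0)


def enrichment_table(list_genes, collection, background) -> pd.DataFrame:
    """Fisher enrichment of a gene list against every set in a collection."""
    rows = []
    for gs in collection:
        counts, p = fisher_enrichment(list_genes, gs.up + gs.down, background)
        rows.append({"category": gs.name, **counts, "p": p})
    table = pd.DataFrame(rows)
    if len(table):
        table = table.sort_values("p", kind="stable").reset_index(drop=True)
    return table


# ---------------------------------------------------------------------------
# classification overlap


@dataclass
class ConfusionOverlap:
    """Co-assignment counts between two labelings and per-cell Fisher p-values."""

    counts: pd.DataFrame  # classes of A × classes of B
    p: pd.DataFrame
    n_shared: int
    permutation_p: float | None = None


def overlap_significance(labels_a: pd.Series, labels_b: pd.Series) -> ConfusionOverlap:
    """Significance of overlap between two subtype assignments.

    For each (a, b) class pair, a one-sided Fisher's exact test of the 2×2
    table (in a vs not) × (in b vs not) over the samples shared by the two
    labelings.
    """
    shared = labels_a.index.intersection(labels_b.index)
    if len(shared) == 0:
        raise ValueError("labelings share no sample ids")
    a = labels_a.loc[shared].astype(str)
    b = labels_b.loc[shared].astype(str)
    counts = pd.crosstab(a, b)
    n = len(shared)
    p = pd.DataFrame(index=counts.index, columns=counts.columns, dtype=float)
    for ca in counts.index:
        for cb in counts.columns:
            x = counts.loc[ca, cb]
            K = counts.loc[ca].sum()
            nn = counts[cb].sum()
            p.loc[ca, cb] = float(min(sps.hypergeom.sf(x - 1, n, K, nn), 1.0))
    return ConfusionOverlap(counts=counts, p=p, n_shared=n)


# ---------------------------------------------------------------------------
# permutation validation of cross-cohort association


def assignment_strength(assignments: pd.DataFrame) -> float:
    """Mean best-centroid correlation over classified samples."""
    return float(assignments["best_r"].mean())


def permutation_association_test(
    classifier,
    target,
    annotation: pd.DataFrame,
    n_perm: int = 999,
    seed: int = 0,
    scheme: str = "gene",
    return_null: bool = False,
):
    """Permutation test of overall subtype-association strength.

    Statistic: mean over samples of the best-centroid Pearson correlation.
    Null: re-assign after destroying gene identity — permuting gene labels of
    the target matrix within each cancer type (``scheme="gene"``, an
    interpretation that preserves per-sample value distributions) or
    permuting sample labels within type (``scheme="sample"``).
    permutation_p = (1 + #{null ≥ observed}) / (n_perm + 1).
    """
    from .classifier import assign_subtypes
    from .io_formats import types_of

    if n_perm < 1:
        raise ValueError("n_perm must be ≥ 1")
    observed = assignment_strength(assign_subtypes(classifier, target))
    types = types_of(annotation, target.sample_ids)
    rng = np.random.default_rng(seed)
    nulls = []
    vals = target.values
    for _ in range(n_perm):
        perm = vals.copy()
        if scheme == "gene":
            for t in types.unique():
                cols = (types == t).to_numpy()
                idx = rng.permutation(len(perm.index))
                block = perm.loc[:, cols].to_numpy()[idx, :]
                perm.loc[:, cols] = block
        elif scheme == "sample":
            for t in types.unique():
                cols = np.flatnonzero((types == t).to_numpy())
                perm.iloc[:, cols] = perm.iloc[:, rng.permutation(cols)].to_numpy()
        else:
            raise ValueError(f"unknown permutation scheme {scheme!r}")
        null_target = target.with_values(perm)
        nulls.append(assignment_strength(assign_subtypes(classifier, null_target)))
    p = (1 + sum(s >= observed for s in nulls)) / (n_perm + 1)
    if return_null:
        return observed, p, nulls
    return observed, p


# ---------------------------------------------------------------------------
# differential expression tables


def diffexp_table(matrix, labels: pd.Series, welch: bool = False) -> pd.DataFrame:
    """Subtype-vs-rest differential expression for every subtype.

    Returns rows (gene_id, subtype, mean_in, mean_out, t, p, q); q-values are
    computed per subtype contrast (each contrast is its own multiple-testing
    universe).
    """
    values = matrix.values.to_numpy()
    labels = labels.loc[matrix.sample_ids]
    frames = []
    for subtype in sorted(labels.dropna().unique()):
        mask = (labels == subtype).to_numpy()
        if mask.sum() < 3:
            logger.warning("subtype %s has <3 samples; skipped", subtype)
            continue
        res = ttest_groups(values, mask, welch=welch)
        ok = ~np.isnan(res["p"])
        q = np.full(res["p"].shape, np.nan)
        q[ok] = qvalues(res["p"][ok])
        frames.append(
            pd.DataFrame(
                {
                    "gene_id": matrix.gene_ids,
                    "subtype": subtype,
                    "mean_in": res["mean_in"],
                    "mean_out": res["mean_out"],
                    "t": res["t"],
                    "p": res["p"],
                    "q": q,
                }
            )
        )
    return pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()


def prevalence_percentages(labels: pd.Series) -> pd.Series:
    """Per-subtype prevalence in percent of the labeled cohort."""
    counts = labels.dropna().value_counts()
    return 100.0 * counts / counts.sum()
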