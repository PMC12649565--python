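"""Timepoint-specific correlation structure, PCA and the unified HRV index.

Metric intercorrelations in this setting change over gestation, so a
single pooled decomposition would mix regimes.  Each timepoint gets its
own PCA on the adjusted (residualized, z-scored) matrix; the components
retained are the minimal set explaining at least 80% of cumulative
variance, and the unified HRV index is the unweighted sum of a subject's
scores on those components.  Correlation structure is summarized by the
mean absolute pairwise correlation and the count of highly collinear
pairs (|r| >= 0.8), and compared across timepoints with a
subject-permutation test.

With far fewer subjects than metrics the decomposition is rank-deficient
by construction; the selected component count is capped at the matrix
rank and the cap is recorded, not treated as an error.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

logger = logging.getLogger(__name__)

__all__ = [
    "CorrelationSummary",
    "PCAResultSet",
    "correlation_summary",
    "compare_structures",
    "fit_pca",
    "select_k",
    "unified_index",
    "domain_contributions",
]

VARIANCE_THRESHOLD = 0.80
HIGH_CORR = 0.8


@dataclass
class CorrelationSummary:
    timepoint: str
    mean_abs_r: float
    high_pair_count: int
    n_pairs: int
    matrix: pd.DataFrame = field(repr=False, default=None)


@dataclass
class PCAResultSet:
    timepoint: str
    loadings: pd.DataFrame  # metrics x components
    explained_ratio: np.ndarray
    k_selected: int
    scores: pd.DataFrame  # subjects x components
    rank_capped: bool = False


def correlation_summary(
    adjusted: pd.DataFrame,
    timepoint: str = "",
    high_corr: float = HIGH_CORR,
) -> CorrelationSummary:
    """Pairwise-complete Pearson correlation structure of the metrics."""
    if adjusted.shape[0] < 4:
        raise ValueError("need at least 4 subjects for a correlation summary")
    sds = adjusted.std(ddof=0)
    keep = sds[sds > 0].index
    excluded = [c for c in adjusted.columns if c not in set(keep)]
    if excluded:
        logger.info("excluding constant columns from correlations: %s", excluded)
    corr = adjusted[keep].corr()
    a = corr.to_numpy()
    iu = np.triu_indices(a.shape[0], k=1)
    vals = a[iu]
    vals = vals[np.isfinite(vals)]
    m = len(keep)
    return CorrelationSummary(
        timepoint=timepoint,
        mean_abs_r=float(np.mean(np.abs(vals))),
        high_pair_count=int(np.sum(np.abs(vals) >= high_corr)),
        n_pairs=m * (m - 1) // 2,
        matrix=corr,
    )


def compare_structures(
    adj_a: pd.DataFrame,
    adj_b: pd.DataFrame,
    n_perm: int = 1000,
    seed: int = 0,
) -> dict:
    """Permutation test for a difference in overall correlation structure.

    Observed statistic: |mean_abs_r(A) - mean_abs_r(B)|.  The null is built
    by pooling the subject rows of both timepoints and randomly
    re-assigning them to two groups of the original sizes.  The p-value
    uses the add-one convention, so a self-comparison yields p = 1.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be at least 100 for a usable null")
    cols = [c for c in adj_a.columns if c in set(adj_b.columns)]
    if not cols:
        raise ValueError("no shared metrics between the two matrices")
    a = adj_a[cols].to_numpy(dtype=float)
    b = adj_b[cols].to_numpy(dtype=float)

    def stat(x: np.ndarray, y: np.ndarray) -> float:
        def mar(z):
            c = np.corrcoef(z, rowvar=False)
            iu = np.triu_indices(c.shape[0], k=1)
            v = c[iu]
            return np.nanmean(np.abs(v))
        return abs(mar(x) - mar(y))

    observed = stat(a, b)
    pooled = np.vstack([a, b])
    na = a.shape[0]
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        idx = rng.permutation(pooled.shape[0])
        if stat(pooled[idx[:na]], pooled[idx[na:]]) >= observed:
            exceed += 1
    return {
        "statistic": float(observed),
        "p_value": float((exceed + 1) / (n_perm + 1)),
        "n_perm": n_perm,
        "seed": seed,
    }


def select_k(explained_ratio: np.ndarray,
             threshold: float = VARIANCE_THRESHOLD) -> int:
    """Minimal k whose cumulative explained variance reaches the threshold."""
    cum = np.cumsum(explained_ratio)
    reached = np.flatnonzero(cum >= threshold - 1e-12)
    return int(reached[0]) + 1 if reached.size else len(explained_ratio)


def fit_pca(
    adjusted: pd.DataFrame,
    timepoint: str = "",
    variance_threshold: float = VARIANCE_THRESHOLD,
) -> PCAResultSet:
    """PCA of the standardized residual matrix with the 80% rule.

    Input columns are already z-scored, so this is a correlation-matrix
    PCA.  Sign convention: each component is oriented so that its
    largest-|loading| metric has a positive loading, making results
    invariant to the underlying solver's sign choices.  k_selected is
    capped at the matrix rank when the cumulative variance never reaches
    the threshold (intrinsic with fewer subjects than metrics).
    """
    cc = adjusted.dropna(axis=0, how="any")
    if cc.shape[0] < 2:
        raise ValueError("need at least 2 complete-case subjects for PCA")
    x = cc.to_numpy(dtype=float)
    n_comp = min(x.shape[0] - 1, x.shape[1])
    pca = PCA(n_components=n_comp)
    scores = pca.fit_transform(x)
    loadings = pca.components_.T  # metrics x components
    # deterministic sign convention
    for j in range(n_comp):
        lead = int(np.argmax(np.abs(loadings[:, j])))
        if loadings[lead, j] < 0:
            loadings[:, j] *= -1.0
            scores[:, j] *= -1.0
    ratios = pca.explained_variance_ratio_
    k = select_k(ratios, variance_threshold)
    capped = bool(np.cumsum(ratios)[k - 1] < variance_threshold - 1e-12)
    if capped:
        logger.info("%s: cumulative variance reaches only %.3f at rank %d; "
                    "k_selected capped", timepoint, float(np.sum(ratios)), k)
    comp_names = [f"PC{j + 1}" for j in range(n_comp)]
    return PCAResultSet(
        timepoint=timepoint,
        loadings=pd.DataFrame(loadings, index=cc.columns, columns=comp_names),
        explained_ratio=ratios,
        k_selected=k,
        scores=pd.DataFrame(scores, index=cc.index, columns=comp_names),
        rank_capped=capped,
    )


def unified_index(pca: PCAResultSet, weighted: bool = False) -> pd.Series:
    """Composite score per subject: sum of the selected PC scores.

    The sum is unweighted by default; ``weighted=True`` weights each
    component by its explained-variance ratio (off by default, fidelity
    to the plain-sum definition first).
    """
    if pca.k_selected < 1:
        raise ValueError("no components selected")
    sel = pca.scores.iloc[:, : pca.k_selected]
    if weighted:
        w = pca.explained_ratio[: pca.k_selected]
        return (sel * w).sum(axis=1).rename("unified_hrv_index")
    return sel.sum(axis=1).rename("unified_hrv_index")


def domain_contributions(
    pca: PCAResultSet,
    registry: dict,
    other: PCAResultSet | None = None,
) -> pd.DataFrame:
    """Mean |loading| per physiological domain, on PC1 and on the selected
    components; with ``other`` given (an earlier timepoint), percentage
    change (this - other) / other x 100 is added per domain.
    """
    domains: dict[str, list[str]] = {}
    for m in pca.loadings.index:
        spec = registry.get(m)
        if spec is None:
            continue
        domains.setdefault(spec.domain, []).append(m)
    rows = []
    for dom, metrics in sorted(domains.items()):
        if not metrics:
            logger.info("domain %r empty, excluded", dom)
            continue
        sub = pca.loadings.loc[metrics]
        row = {
            "domain": dom,
            "mean_abs_loading_pc1": float(sub.iloc[:, 0].abs().mean()),
            "mean_abs_loading_selected": float(
                sub.iloc[:, : pca.k_selected].abs().to_numpy().mean()),
        }
        if other is not None:
            osub = other.loadings.loc[[m for m in metrics
                                       if m in other.loadings.index]]
            for key, kcol in (("pc1", 0), ("selected", None)):
                if kcol == 0:
                    early = float(osub.iloc[:, 0].abs().mean())
                    late = row["mean_abs_loading_pc1"]
                else:
                    early = float(osub.iloc[:, : other.k_selected]
                                  .abs().to_numpy().mean())
                    late = row["mean_abs_loading_selected"]
                row[f"pct_change_{key}"] = (
                    100.0 * (late - early) / early if early > 0 else np.nan)
        rows.append(row)
    return pd.DataFrame(rows)
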