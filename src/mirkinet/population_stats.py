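"""Sliding-window single-cell statistics and target-panel utilities.

Implements the population-level read-outs of miRNA activity: the
coefficient of variation (C_V = SD/mean) of target expression and the mean
pairwise Pearson correlation of log2 target levels, both computed in
sliding windows of cells with the most similar miRNA proxy and normalized
to a non-target background.  Repression by a shared miRNA is expected to
raise both read-outs specifically in the proxy region where targets
titrate the miRNA: the C_V of each target spikes where its response is
steepest, and co-regulated targets correlate most at intermediate miRNA.

Also provides the target-panel selection filter (prediction score ranking
plus expression and down-regulation thresholds) and the cumulative
fold-change-by-rank curves used to compare ranking criteria.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._sliding import nearest_window_starts, windowed_mean_var
from .inference import EmptyPanelError, ReferenceLevels
from .synthetic_data import ExpressionMatrix

logger = logging.getLogger("mirkinet")

__all__ = [
    "SlidingStatCurve",
    "sliding_cv",
    "sliding_pairwise_correlation",
    "select_targets",
    "fold_change_by_rank",
]


@dataclass
class SlidingStatCurve:
    """A per-reference-cell statistic along the proxy axis.

    ``value`` is the background-normalized statistic (difference of log2
    mean C_V, or ratio of mean pairwise correlations); ``target_value``
    and ``background_value`` keep the unnormalized pieces.  ``se`` is the
    standard error across targets (C_V) or target pairs (correlation).
    """

    proxy: np.ndarray
    value: np.ndarray
    se: np.ndarray
    window: int
    statistic: str
    target_value: np.ndarray
    background_value: np.ndarray
    background_descriptor: str = ""


def _gene_indices(matrix: ExpressionMatrix, genes) -> np.ndarray:
    """Resolve a gene selection (ids, indices or boolean mask) to indices."""
    genes = np.asarray(genes)
    if genes.dtype == bool:
        return np.flatnonzero(genes)
    if np.issubdtype(genes.dtype, np.integer):
        return genes.astype(int)
    lookup = {str(g): i for i, g in enumerate(matrix.gene_ids)}
    try:
        return np.array([lookup[str(g)] for g in genes])
    except KeyError as exc:
        raise KeyError(f"gene id {exc.args[0]!r} not in matrix") from exc


def sliding_cv(
    matrix: ExpressionMatrix,
    target_genes,
    background_genes,
    window: int = 200,
) -> SlidingStatCurve:
    """Windowed coefficient of variation of targets vs. background.

    For every reference cell (in proxy order) the ``window - 1``
    nearest-proxy cells plus the reference form the window; each gene's
    C_V (SD/mean, on the linear values) is computed, log2-transformed, and
    averaged separately over the target and background sets.  The curve is
    the difference of the two log2 means (log2 of the C_V ratio), with the
    standard error taken over targets.  Genes with non-positive window
    mean or zero variance are skipped in that window.
    """
    t_idx = _gene_indices(matrix, target_genes)
    b_idx = _gene_indices(matrix, background_genes)
    if np.intersect1d(t_idx, b_idx).size and not np.array_equal(np.sort(t_idx), np.sort(b_idx)):
        raise ValueError("target and background sets must be disjoint (or identical)")
    order = matrix.proxy_order()
    proxy = matrix.proxy[order]
    starts = nearest_window_starts(proxy, window)

    def log2_cv(idx: np.ndarray) -> np.ndarray:
        x = matrix.values[np.ix_(order, idx)]
        mean, var = windowed_mean_var(x, starts, window)
        cv = np.full(mean.shape, np.nan)
        ok = (mean > 0) & (var > 0)
        if not ok.all():
            logger.debug("sliding_cv: %d gene-windows skipped", int((~ok).sum()))
        cv[ok] = np.sqrt(var[ok]) / mean[ok]
        return np.log2(cv)

    t_cv = log2_cv(t_idx)
    b_cv = log2_cv(b_idx)
    t_mean = np.nanmean(t_cv, axis=1)
    b_mean = np.nanmean(b_cv, axis=1)
    n_ok = np.sum(~np.isnan(t_cv), axis=1)
    se = np.nanstd(t_cv, axis=1, ddof=1) / np.sqrt(np.maximum(n_ok, 1))
    return SlidingStatCurve(
        proxy=proxy,
        value=t_mean - b_mean,
        se=se,
        window=window,
        statistic="log2_cv_ratio",
        target_value=t_mean,
        background_value=b_mean,
        background_descriptor=f"{b_idx.size} non-target genes",
    )


def _windowed_mean_pairwise_r(x: np.ndarray, starts: np.ndarray, w: int):
    """Mean (and SD over pairs) of pairwise Pearson r per sliding window.

    ``x`` holds log2 expression, cells (sorted by proxy) on axis 0.  The
    per-window Gram matrix is maintained incrementally as the window
    slides, so the cost is O(n g^2).  Zero-variance genes are excluded
    from the pair average in that window.
    """
    n, g = x.shape
    w = min(w, n)
    s1 = x[:w].sum(axis=0)
    gram = x[:w].T @ x[:w]
    lo = 0
    iu = np.triu_indices(g, k=1)
    mean_r = np.empty(n)
    sd_r = np.empty(n)
    for j in range(n):
        s = starts[j]
        while lo < s:
            row = x[lo + w]
            gram += np.outer(row, row)
            s1 += row
            row = x[lo]
            gram -= np.outer(row, row)
            s1 -= row
            lo += 1
        cov = (gram - np.outer(s1, s1) / w) / (w - 1)
        d = np.sqrt(np.clip(np.diag(cov), 0.0, None))
        denom = np.outer(d, d)
        with np.errstate(divide="ignore", invalid="ignore"):
            r = np.where(denom > 0, cov / denom, np.nan)
        pairs = r[iu]
        mean_r[j] = np.nanmean(pairs)
        sd_r[j] = np.nanstd(pairs, ddof=1)
    return mean_r, sd_r


def sliding_pairwise_correlation(
    matrix: ExpressionMatrix,
    target_genes,
    window: int = 200,
    n_background_draws: int = 50,
    background_genes=None,
    seed: int = 0,
) -> SlidingStatCurve:
    """Windowed mean pairwise correlation of targets over background.

    Computes, per sliding window, the mean Pearson correlation of log2
    expression over all target pairs, and divides it by the corresponding
    mean over ``n_background_draws`` random non-target gene sets of the
    same size.  The standard error is over target pairs.
    """
    if n_background_draws < 1:
        raise ValueError("need at least one background draw")
    t_idx = _gene_indices(matrix, target_genes)
    if background_genes is None:
        pool = np.flatnonzero(~matrix.target_mask)
    else:
        pool = _gene_indices(matrix, background_genes)
    pool = np.setdiff1d(pool, t_idx)
    if pool.size < t_idx.size:
        raise ValueError("background pool smaller than the target set")

    order = matrix.proxy_order()
    proxy = matrix.proxy[order]
    starts = nearest_window_starts(proxy, window)
    logx = np.log2(np.clip(matrix.values[order], 1e-300, None))

    t_mean, t_sd = _windowed_mean_pairwise_r(logx[:, t_idx], starts, window)
    rng = np.random.default_rng(seed)
    b_mean = np.zeros_like(t_mean)
    for _ in range(n_background_draws):
        draw = rng.choice(pool, size=t_idx.size, replace=False)
        m, _ = _windowed_mean_pairwise_r(logx[:, draw], starts, window)
        b_mean += m
    b_mean /= n_background_draws

    n_pairs = t_idx.size * (t_idx.size - 1) // 2
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = t_mean / b_mean
    return SlidingStatCurve(
        proxy=proxy,
        value=ratio,
        se=t_sd / np.sqrt(n_pairs),
        window=window,
        statistic="pairwise_r_ratio",
        target_value=t_mean,
        background_value=b_mean,
        background_descriptor=f"{n_background_draws} draws of {t_idx.size} genes",
    )


def select_targets(
    scores: pd.Series | dict,
    refs: ReferenceLevels,
    gene_ids: np.ndarray,
    top_n: int = 300,
    min_expression: float = 8.0,
    max_log2_ratio: float = -0.12,
) -> list[str]:
    """Rank predicted targets and apply expression/response filters.

    Keeps, among genes with a prediction score, those with baseline
    ``T0 >= min_expression`` and ``log2(Tinf/T0) < max_log2_ratio``
    (the default -0.12 corresponds to at least ~8% down-regulation at
    saturating miRNA, since 2**-0.12 ~ 0.92), then returns the ``top_n``
    highest-scoring gene ids in score order.
    """
    scores = pd.Series(scores, dtype=float)
    ids = np.asarray(gene_ids)[refs.gene_indices]
    fc = np.log2(refs.tinf / refs.t0)
    table = pd.DataFrame({"t0": refs.t0, "log2_ratio": fc}, index=[str(g) for g in ids])
    table = table.join(scores.rename("score"), how="inner")
    passed = table[(table.t0 >= min_expression) & (table.log2_ratio < max_log2_ratio)]
    if passed.empty:
        raise EmptyPanelError("no gene passes the expression/down-regulation filters")
    ranked = passed.sort_values("score", ascending=False, kind="stable")
    return list(ranked.index[:top_n])


def fold_change_by_rank(
    log2_fold_changes: np.ndarray,
    key: np.ndarray,
    ascending: bool = False,
) -> np.ndarray:
    """Running mean of log2 fold changes over the top-x targets by a key.

    Sorts targets by ``key`` (descending by default, e.g. prediction score
    or K_M; ascending for the critical concentration) and returns the mean
    ``log2(Tinf/T0)`` of the top ``x`` targets for ``x = 1..n``.
    """
    fc = np.asarray(log2_fold_changes, dtype=float)
    key = np.asarray(key, dtype=float)
    if fc.shape != key.shape:
        raise ValueError("fold changes and ranking key must align")
    order = np.argsort(key, kind="stable")
    if not ascending:
        order = order[::-1]
    sorted_fc = fc[order]
    return np.cumsum(sorted_fc) / np.arange(1, fc.size + 1)
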