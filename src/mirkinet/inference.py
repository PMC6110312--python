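"""Inference of per-cell free Ago-miRNA and per-target K_M from expression.

Given a cells-by-targets matrix with a per-cell miRNA proxy, the pipeline

1. estimates each target's plateau levels ``T0`` (no miRNA) and ``Tinf``
   (saturating miRNA) from reference subpopulations at the extremes of the
   proxy range;
2. selects the responsive cells -- those where the summed log2 target
   level falls with the proxy (finite-difference gradient below a
   threshold) and sits away from both plateaus;
3. smooths expression over proxy-neighbour cells in two passes so every
   retained entry lies strictly inside ``(Tinf + c, T0 - c)`` with safety
   margin ``c``;
4. maps each entry through the steady-state model to
   ``Ttilde_ji = (T0/Tinf - 1) / (T0/T_ji - 1) - 1``, which on exact model
   data equals ``K_M_i / A_F_j`` -- a rank-1 matrix;
5. extracts per-cell ``A_F`` and per-target ``K_M`` from the leading
   singular triplet (the best rank-1 fit in Frobenius norm), then refines
   ``K_M`` by averaging ``A_F_j * Ttilde_ji`` over cells;
6. reports each target's critical concentration
   ``A_F^C = K_M * Tinf / T0``.

The factorization is identified only up to a global scale ``a`` (``a K_M``
with ``a A_F`` fits identically); results are reported at ``a = 1`` and
flagged, with :func:`resolve_scale` available when a ground-truth free-Ago
vector exists (synthetic data).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .kinetic_core import TargetParams, critical_free_ago, params_to_arrays
from ._sliding import nearest_window_starts as _nearest_window_starts, running_mean as _running_mean
from .synthetic_data import ExpressionMatrix

logger = logging.getLogger("mirkinet")

__all__ = [
    "EmptyPanelError",
    "NoResponsiveRegionError",
    "TildeDomainError",
    "InferenceConfig",
    "ReferenceLevels",
    "SmoothedExpression",
    "TildeMatrix",
    "RankOneFit",
    "InferenceResult",
    "estimate_reference_levels",
    "estimate_reference_levels_by_threshold",
    "reference_levels_from_params",
    "select_responsive_cells",
    "smooth_expression",
    "build_tilde_matrix",
    "rank_one_decompose",
    "refine_km",
    "run_inference",
    "resolve_scale",
]


class EmptyPanelError(ValueError):
    """No target survived a filtering step."""


class NoResponsiveRegionError(ValueError):
    """No cells pass the responsiveness criteria."""


class TildeDomainError(ValueError):
    """An expression entry violates the open interval (Tinf, T0)."""


@dataclass(frozen=True)
class InferenceConfig:
    """All pipeline thresholds, at their standard defaults."""

    n_low: int = 1600
    n_high: int = 200
    margin_fraction: float = 0.10
    gradient_threshold: float = -0.01
    smooth_span: int = 50
    first_window: int = 50
    second_window_start: int = 10
    reference_mode: str = "pool"  # "pool" | "threshold"
    zero_proxy_max: float = 0.0
    high_proxy_min: float = 6.8


@dataclass
class ReferenceLevels:
    """Per-target plateau levels with the safety margin.

    ``gene_indices`` maps the retained targets back into the matrix's gene
    axis; ``low_cells``/``high_cells`` record the reference subpopulations
    (empty when the levels come from ground-truth parameters).
    """

    t0: np.ndarray
    tinf: np.ndarray
    gene_indices: np.ndarray
    margin_fraction: float
    low_cells: np.ndarray
    high_cells: np.ndarray
    dropped_genes: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.t0.size == 0:
            raise EmptyPanelError("no down-regulated targets retained")
        if np.any(self.t0 <= self.tinf) or np.any(self.tinf <= 0):
            raise EmptyPanelError("reference levels must satisfy T0 > Tinf > 0")

    @property
    def c(self) -> np.ndarray:
        """Safety margin, ``margin_fraction * (T0 - Tinf)`` per target."""
        return self.margin_fraction * (self.t0 - self.tinf)

    def subset(self, keep: np.ndarray) -> "ReferenceLevels":
        return ReferenceLevels(
            t0=self.t0[keep],
            tinf=self.tinf[keep],
            gene_indices=self.gene_indices[keep],
            margin_fraction=self.margin_fraction,
            low_cells=self.low_cells,
            high_cells=self.high_cells,
            dropped_genes=list(self.dropped_genes),
        )


def _build_refs(
    matrix: ExpressionMatrix,
    low_cells: np.ndarray,
    high_cells: np.ndarray,
    margin_fraction: float,
) -> ReferenceLevels:
    gene_idx = np.flatnonzero(matrix.target_mask)
    t0 = matrix.values[np.ix_(low_cells, gene_idx)].mean(axis=0)
    tinf = matrix.values[np.ix_(high_cells, gene_idx)].mean(axis=0)
    keep = (t0 > tinf) & (tinf > 0)
    dropped = [str(g) for g in matrix.gene_ids[gene_idx[~keep]]]
    if dropped:
        logger.info("reference estimation dropped %d non-down-regulated targets", len(dropped))
    if not keep.any():
        raise EmptyPanelError("all targets dropped: no T0 > Tinf")
    return ReferenceLevels(
        t0=t0[keep],
        tinf=tinf[keep],
        gene_indices=gene_idx[keep],
        margin_fraction=margin_fraction,
        low_cells=low_cells,
        high_cells=high_cells,
        dropped_genes=dropped,
    )


def estimate_reference_levels(
    matrix: ExpressionMatrix,
    n_low: int = 1600,
    n_high: int = 200,
    margin_fraction: float = 0.10,
) -> ReferenceLevels:
    """Plateau levels from the proxy extremes.

    ``T0`` is each target's mean over the ``n_low`` lowest-proxy cells,
    ``Tinf`` the mean over the ``n_high`` highest-proxy cells.  Targets
    without net down-regulation (``T0 <= Tinf``) are dropped.
    """
    if n_low + n_high >= matrix.n_cells:
        raise ValueError("reference pools exceed the number of cells")
    order = matrix.proxy_order()
    return _build_refs(matrix, order[:n_low], order[-n_high:], margin_fraction)


def estimate_reference_levels_by_threshold(
    matrix: ExpressionMatrix,
    zero_proxy_max: float = 0.0,
    high_proxy_min: float = 6.8,
    margin_fraction: float = 0.10,
) -> ReferenceLevels:
    """Plateau levels from proxy-value pools (real-data convention).

    Cells with proxy <= ``zero_proxy_max`` (reporter not captured) define
    ``T0``; cells with proxy > ``high_proxy_min`` define ``Tinf``.
    """
    low = np.flatnonzero(matrix.proxy <= zero_proxy_max)
    high = np.flatnonzero(matrix.proxy > high_proxy_min)
    if low.size == 0 or high.size == 0:
        raise NoResponsiveRegionError("empty reference pool at a proxy threshold")
    return _build_refs(matrix, low, high, margin_fraction)


def reference_levels_from_params(
    params: Sequence[TargetParams],
    matrix: ExpressionMatrix,
    margin_fraction: float = 0.10,
) -> ReferenceLevels:
    """Ground-truth plateau levels (synthetic data oracle mode)."""
    arr = params_to_arrays(params)
    ids = {str(g): i for i, g in enumerate(matrix.gene_ids)}
    gene_idx = np.array([ids[p.id] for p in params])
    keep = arr["t0"] > arr["tinf"]
    return ReferenceLevels(
        t0=arr["t0"][keep],
        tinf=arr["tinf"][keep],
        gene_indices=gene_idx[keep],
        margin_fraction=margin_fraction,
        low_cells=np.empty(0, dtype=int),
        high_cells=np.empty(0, dtype=int),
    )


def select_responsive_cells(
    matrix: ExpressionMatrix,
    refs: ReferenceLevels,
    gradient_threshold: float = -0.01,
    smooth_span: int = 50,
) -> np.ndarray:
    """Cells in the proxy region where targets respond to the miRNA.

    The summed log2 target level per cell is smoothed over proxy-neighbour
    windows; cells are eligible where its central-difference gradient with
    respect to log2 proxy falls below ``gradient_threshold`` (per log2
    proxy unit) and where the smoothed total level sits outside the safety
    margin of both plateaus.  The longest contiguous (in proxy order) run
    of eligible cells is returned, as matrix cell indices ordered by proxy.

    Reference-pool cells and zero-proxy cells are never selected.
    """
    order = matrix.proxy_order()
    in_pool = np.zeros(matrix.n_cells, dtype=bool)
    in_pool[refs.low_cells] = True
    in_pool[refs.high_cells] = True
    cand = order[~in_pool[order] & (matrix.proxy[order] > 0) & ~matrix.zero_proxy[order]]
    if cand.size < 3:
        raise NoResponsiveRegionError("fewer than 3 candidate cells")

    x = np.log2(matrix.proxy[cand])
    vals = matrix.values[np.ix_(cand, refs.gene_indices)]
    s = np.log2(np.clip(vals, 1e-300, None)).sum(axis=1)
    total = vals.sum(axis=1)

    starts = _nearest_window_starts(matrix.proxy[cand], smooth_span)
    s_smooth = _running_mean(s, starts, smooth_span)
    total_smooth = _running_mean(total, starts, smooth_span)

    # central differences at the smoothing half-span: differencing adjacent
    # cells would difference windows sharing almost all their members and
    # amplify noise far beyond the threshold scale
    n = cand.size
    h = max(1, min(smooth_span // 2, (n - 1) // 2))
    grad = np.zeros(n)
    dx = x[2 * h :] - x[: -2 * h]
    with np.errstate(divide="ignore", invalid="ignore"):
        core = np.where(dx > 0, (s_smooth[2 * h :] - s_smooth[: -2 * h]) / dx, 0.0)
    grad[h : n - h] = core
    grad[:h] = grad[h]
    grad[n - h :] = grad[n - h - 1]

    hi_total = float(np.sum(refs.t0 - refs.c))
    lo_total = float(np.sum(refs.tinf + refs.c))
    eligible = (grad < gradient_threshold) & (total_smooth < hi_total) & (total_smooth > lo_total)
    if not eligible.any():
        raise NoResponsiveRegionError("no cells pass the gradient/margin criteria")

    # longest contiguous run of eligible cells
    best_len, best_start, run_start = 0, 0, None
    for j, e in enumerate(np.append(eligible, False)):
        if e and run_start is None:
            run_start = j
        elif not e and run_start is not None:
            if j - run_start > best_len:
                best_len, best_start = j - run_start, run_start
            run_start = None
    return cand[best_start : best_start + best_len]


@dataclass
class SmoothedExpression:
    """Two-pass-smoothed expression restricted to responsive cells."""

    values: np.ndarray  # (n_cells, n_targets) for the retained targets
    cells: np.ndarray  # matrix cell indices, proxy order
    refs: ReferenceLevels  # restricted to the retained targets
    n_pass2_entries: int
    dropped_targets: list


def smooth_expression(
    matrix: ExpressionMatrix,
    cells: np.ndarray,
    refs: ReferenceLevels,
    first_window: int = 50,
    second_window_start: int = 10,
) -> SmoothedExpression:
    """Replace each entry by a proxy-neighbour running mean, margin-safe.

    Pass 1 replaces each entry by the mean over the ``first_window``
    nearest-proxy cells.  Entries still outside the open interval
    ``(Tinf + c, T0 - c)`` are re-estimated in pass 2: a window of
    ``second_window_start`` raw values around the cell is pruned by
    repeatedly discarding the value deviating most from the window mean
    until the mean enters the interval; a window that empties is doubled
    (locally) and pruning restarts.  Targets with entries that cannot be
    brought inside even from the maximal window are dropped.
    """
    p = matrix.proxy[cells]
    raw = matrix.values[np.ix_(cells, refs.gene_indices)]
    n, m = raw.shape
    lo = refs.tinf + refs.c
    hi = refs.t0 - refs.c

    starts1 = _nearest_window_starts(p, first_window)
    smoothed = _running_mean(raw, starts1, first_window)

    starts_cache: dict[int, np.ndarray] = {min(first_window, n): starts1}

    def window_starts(w: int) -> np.ndarray:
        if w not in starts_cache:
            starts_cache[w] = _nearest_window_starts(p, w)
        return starts_cache[w]

    n_pass2 = 0
    dropped: list[str] = []
    keep = np.ones(m, dtype=bool)
    bad_j, bad_i = np.nonzero((smoothed <= lo) | (smoothed >= hi))
    for j, i in zip(bad_j, bad_i):
        if not keep[i]:
            continue
        n_pass2 += 1
        fixed = False
        w = min(second_window_start, n)
        while True:
            s0 = window_starts(w)[j]
            vals = np.sort(raw[s0 : s0 + w, i])
            csum = np.concatenate([[0.0], np.cumsum(vals)])
            a, b = 0, w - 1
            while a <= b:
                mean = (csum[b + 1] - csum[a]) / (b - a + 1)
                if lo[i] < mean < hi[i]:
                    smoothed[j, i] = mean
                    fixed = True
                    break
                # discard the strongest outlier: one of the two extremes
                if mean - vals[a] > vals[b] - mean:
                    a += 1
                else:
                    b -= 1
            if fixed or w == n:
                break
            w = min(2 * w, n)
        if not fixed:
            keep[i] = False
            dropped.append(str(matrix.gene_ids[refs.gene_indices[i]]))
    if dropped:
        logger.info("smoothing dropped %d targets: %s", len(dropped), dropped[:10])
    if not keep.any():
        raise EmptyPanelError("smoothing dropped every target")
    refs_kept = refs.subset(keep)
    return SmoothedExpression(
        values=smoothed[:, keep],
        cells=np.asarray(cells),
        refs=refs_kept,
        n_pass2_entries=n_pass2,
        dropped_targets=dropped,
    )


@dataclass
class TildeMatrix:
    """The model-transformed matrix whose ideal structure is rank 1.

    ``values[j, i] = (T0_i/Tinf_i - 1) / (T0_i/T_ji - 1) - 1``, equal to
    ``K_M_i / A_F_j`` on exact steady-state data.
    """

    values: np.ndarray
    cells: np.ndarray
    refs: ReferenceLevels


def build_tilde_matrix(smoothed: SmoothedExpression) -> TildeMatrix:
    """Map smoothed levels through the inverted steady-state relation."""
    t = smoothed.values
    refs = smoothed.refs
    bad = (t <= refs.tinf) | (t >= refs.t0)
    if bad.any():
        j, i = np.argwhere(bad)[0]
        raise TildeDomainError(
            f"entry (cell {smoothed.cells[j]}, target "
            f"{refs.gene_indices[i]}) = {t[j, i]:.6g} outside "
            f"({refs.tinf[i]:.6g}, {refs.t0[i]:.6g})"
        )
    ratio = refs.t0 / refs.tinf
    values = (ratio - 1.0) / (refs.t0 / t - 1.0) - 1.0
    return TildeMatrix(values=values, cells=smoothed.cells, refs=refs)


@dataclass
class RankOneFit:
    """Best rank-1 factorization of a positive matrix, x y^T."""

    x: np.ndarray  # per cell; 1/A_F up to the global scale
    y: np.ndarray  # per target; K_M up to the global scale
    residual: float  # Frobenius-norm fraction left unexplained
    negative_cells: np.ndarray
    negative_targets: np.ndarray


def rank_one_decompose(tilde: TildeMatrix | np.ndarray) -> RankOneFit:
    """Leading singular triplet of the transformed matrix.

    The rank-1 minimizer of ``||B - x y^T||_F`` is given by the leading
    singular value/vectors: ``x = sqrt(s1) u1``, ``y = sqrt(s1) v1``.
    Signs are fixed so both vectors are entrywise positive (the leading
    vectors of a positive matrix are one-signed); entries that remain
    non-positive indicate structurally non-rank-1 data and are reported,
    never clipped.
    """
    b = tilde.values if isinstance(tilde, TildeMatrix) else np.asarray(tilde, dtype=float)
    u, s, vt = np.linalg.svd(b, full_matrices=False)
    x = np.sqrt(s[0]) * u[:, 0]
    y = np.sqrt(s[0]) * vt[0]
    if x.sum() < 0:
        x, y = -x, -y
    neg_cells = np.flatnonzero(x <= 0)
    neg_targets = np.flatnonzero(y <= 0)
    if neg_cells.size or neg_targets.size:
        warnings.warn(
            f"leading singular vectors have {neg_cells.size} non-positive cell "
            f"and {neg_targets.size} non-positive target entries: data are "
            "structurally not rank-1",
            RuntimeWarning,
            stacklevel=2,
        )
    residual = float(np.linalg.norm(b - np.outer(x, y)) / np.linalg.norm(b))
    return RankOneFit(x=x, y=y, residual=residual, negative_cells=neg_cells, negative_targets=neg_targets)


def refine_km(tilde: TildeMatrix | np.ndarray, a_f: np.ndarray) -> np.ndarray:
    """Re-estimate K_M by averaging ``A_F_j * Ttilde_ji`` over cells.

    ``A_F`` is inferred more precisely than ``K_M`` (smoothing acts along
    the cell dimension), so this average tightens the per-target constants;
    on exact rank-1 data it reproduces the SVD estimate.
    """
    b = tilde.values if isinstance(tilde, TildeMatrix) else np.asarray(tilde, dtype=float)
    a_f = np.asarray(a_f, dtype=float)
    if np.any(a_f <= 0):
        raise ValueError("A_F estimates must be positive")
    return (a_f[:, None] * b).mean(axis=0)


@dataclass
class InferenceResult:
    """Inferred per-cell free Ago-miRNA and per-target constants.

    ``a_f`` and ``km`` (hence ``a_f_c``) are identified only up to the
    global factor ``scale``; it is reported as 1 with
    ``scale_identified=False`` unless :func:`resolve_scale` was applied.
    """

    cells: np.ndarray
    cell_ids: np.ndarray
    proxy: np.ndarray
    a_f: np.ndarray
    gene_indices: np.ndarray
    gene_ids: np.ndarray
    t0: np.ndarray
    tinf: np.ndarray
    km_svd: np.ndarray
    km: np.ndarray
    a_f_c: np.ndarray
    residual: float
    scale: float
    scale_identified: bool
    config: InferenceConfig
    n_pass2_entries: int
    dropped_targets: list
    dropped_reference_targets: list


def run_inference(
    matrix: ExpressionMatrix,
    config: InferenceConfig = InferenceConfig(),
    refs: ReferenceLevels | None = None,
) -> InferenceResult:
    """End-to-end parameter inference on an expression matrix.

    Chains reference estimation, responsive-cell selection, two-pass
    smoothing, the steady-state transform, the rank-1 SVD fit, the K_M
    refinement and the critical-concentration computation.  Deterministic
    given matrix and configuration.  Pass ``refs`` to override reference
    estimation (e.g. ground-truth plateaus on synthetic data).
    """
    if refs is None:
        if config.reference_mode == "pool":
            refs = estimate_reference_levels(
                matrix, config.n_low, config.n_high, config.margin_fraction
            )
        elif config.reference_mode == "threshold":
            refs = estimate_reference_levels_by_threshold(
                matrix, config.zero_proxy_max, config.high_proxy_min, config.margin_fraction
            )
        else:
            raise ValueError(f"unknown reference_mode {config.reference_mode!r}")
    cells = select_responsive_cells(
        matrix, refs, config.gradient_threshold, config.smooth_span
    )
    smoothed = smooth_expression(
        matrix, cells, refs, config.first_window, config.second_window_start
    )
    tilde = build_tilde_matrix(smoothed)
    fit = rank_one_decompose(tilde)
    with np.errstate(divide="ignore"):
        a_f = 1.0 / fit.x
    km = refine_km(tilde, a_f)
    sub = tilde.refs
    a_f_c = critical_free_ago(km, sub.t0, sub.tinf)
    return InferenceResult(
        cells=cells,
        cell_ids=matrix.cell_ids[cells],
        proxy=matrix.proxy[cells],
        a_f=a_f,
        gene_indices=sub.gene_indices,
        gene_ids=matrix.gene_ids[sub.gene_indices],
        t0=sub.t0,
        tinf=sub.tinf,
        km_svd=fit.y,
        km=km,
        a_f_c=a_f_c,
        residual=fit.residual,
        scale=1.0,
        scale_identified=False,
        config=config,
        n_pass2_entries=smoothed.n_pass2_entries,
        dropped_targets=smoothed.dropped_targets,
        dropped_reference_targets=list(refs.dropped_genes),
    )


def resolve_scale(result: InferenceResult, a_f_true: np.ndarray) -> InferenceResult:
    """Fix the global scale using a known free-Ago vector.

    ``a`` is the geometric mean of ``a_f_true / a_f`` over the retained
    cells; the per-cell ``A_F``, the ``K_M`` values and the critical
    concentrations all scale jointly by ``a``.
    """
    a_f_true = np.asarray(a_f_true, dtype=float)
    if a_f_true.shape != result.a_f.shape:
        raise ValueError("a_f_true must match the retained cells")
    if np.any(a_f_true <= 0):
        raise ValueError("a_f_true must be positive")
    a = float(np.exp(np.mean(np.log(a_f_true) - np.log(result.a_f))))
    return replace(
        result,
        a_f=result.a_f * a,
        km=result.km * a,
        km_svd=result.km_svd * a,
        a_f_c=result.a_f_c * a,
        scale=a,
        scale_identified=True,
    )
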