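"""In-silico single-cell benchmark for the parameter-inference pipeline.

Generates a virtual population of cells, each with its own total Ago-miRNA
abundance ``A`` drawn uniformly in log2 over a wide range (default
2^-40 .. 2^14, so a large subpopulation carries effectively no miRNA), and
a panel of targets with kinetic rates drawn from log-normal distributions.
Per cell, steady-state total target levels follow the competing-target
model (:mod:`mirkinet.kinetic_core`); multiplicative log-normal measurement
noise with median 1 is then applied per entry, at a magnitude calibrated so
the total target level spreads about twofold among cells of similar miRNA
level -- the noise scale observed in droplet single-cell data.

Optionally, a shared per-cell technical factor (capture-efficiency
variation) and constitutive non-target background genes can be added; both
are off by default.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .kinetic_core import (
    InvalidParameterError,
    SolverError,
    TargetParams,
    critical_free_ago,
    params_to_arrays,
    solve_free_ago,
)

logger = logging.getLogger("mirkinet")

__all__ = [
    "DEFAULT_NOISE_SIGMA",
    "BenchmarkSpec",
    "ExpressionMatrix",
    "Benchmark",
    "draw_target_params",
    "draw_cell_mirna_levels",
    "generate_expression_matrix",
    "generate_benchmark",
    "calibrate_noise_sigma",
    "example_four_target_params",
    "mirna_gradient",
]

#: Default per-entry log-normal noise scale (natural-log sigma).  Frozen
#: output of :func:`calibrate_noise_sigma` at the default benchmark: the
#: central-90% interval of total target level across no-miRNA cells spans
#: a factor of two.
DEFAULT_NOISE_SIGMA = 1.533


@dataclass(frozen=True)
class BenchmarkSpec:
    """Study conditions of the in-silico benchmark.

    Rate distributions are log-normal, parameterized by the median and a
    shared log2-scale standard deviation.  ``noise_sigma`` is the
    natural-log scale of the median-1 multiplicative measurement noise;
    ``cell_factor_sigma`` adds a shared per-cell log-normal technical
    factor (0 = none).  Cells with ``A < zero_threshold`` molecules are
    flagged as effectively miRNA-free.
    """

    n_targets: int = 300
    n_cells: int = 4000
    alpha_median: float = 2.0
    delta_median: float = 0.1
    kon_median: float = 0.2
    koff_median: float = 0.1
    kcat_median: float = 0.4
    rate_log2_sd: float = 1.0
    kon_log2_sd: float | None = None  # None: use rate_log2_sd
    log2_a_low: float = -40.0
    log2_a_high: float = 14.0
    noise_sigma: float = DEFAULT_NOISE_SIGMA
    cell_factor_sigma: float = 0.0
    zero_threshold: float = 1.0
    n_background: int = 0
    seed: int = 0
    resample_budget: int = 200

    def __post_init__(self) -> None:
        if self.n_targets < 2:
            raise InvalidParameterError("need at least 2 targets")
        if self.n_cells < 10:
            raise InvalidParameterError("need at least 10 cells")
        if self.noise_sigma < 0 or self.cell_factor_sigma < 0:
            raise InvalidParameterError("noise scales must be >= 0")
        if not self.log2_a_low < self.log2_a_high:
            raise InvalidParameterError("log2 miRNA range must have low < high")


@dataclass
class ExpressionMatrix:
    """Cells-by-genes abundance table with a per-cell miRNA proxy.

    ``proxy`` is the per-cell scalar the inference sorts on: the true total
    Ago-miRNA abundance for synthetic data, or a reporter-gene level (GFP)
    for real data.  ``target_mask`` flags which genes belong to the target
    panel; ``zero_proxy`` flags cells with effectively no miRNA.
    """

    values: np.ndarray
    cell_ids: np.ndarray
    gene_ids: np.ndarray
    proxy: np.ndarray
    target_mask: np.ndarray = field(default=None)  # type: ignore[assignment]
    zero_proxy: np.ndarray = field(default=None)  # type: ignore[assignment]
    proxy_gene: str | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.cell_ids = np.asarray(self.cell_ids)
        self.gene_ids = np.asarray(self.gene_ids)
        self.proxy = np.asarray(self.proxy, dtype=float)
        n, g = self.values.shape
        if self.cell_ids.size != n or self.gene_ids.size != g or self.proxy.size != n:
            raise InvalidParameterError("matrix/id/proxy dimensions disagree")
        if np.any(self.values < 0):
            raise InvalidParameterError("expression values must be >= 0")
        if np.any(self.proxy < 0):
            raise InvalidParameterError("proxy values must be >= 0")
        if self.target_mask is None:
            self.target_mask = np.ones(g, dtype=bool)
        else:
            self.target_mask = np.asarray(self.target_mask, dtype=bool)
        if self.zero_proxy is None:
            self.zero_proxy = self.proxy == 0
        else:
            self.zero_proxy = np.asarray(self.zero_proxy, dtype=bool)

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    def proxy_order(self) -> np.ndarray:
        """Cell indices sorted by proxy, ties broken by original order."""
        return np.argsort(self.proxy, kind="stable")


@dataclass
class Benchmark:
    """A generated benchmark with its ground truth attached."""

    spec: BenchmarkSpec
    params: list[TargetParams]
    matrix: ExpressionMatrix
    a_total: np.ndarray
    a_free: np.ndarray
    noiseless: np.ndarray

    @property
    def true_km(self) -> np.ndarray:
        return params_to_arrays(self.params)["km"]

    @property
    def true_afc(self) -> np.ndarray:
        arr = params_to_arrays(self.params)
        return critical_free_ago(arr["km"], arr["t0"], arr["tinf"])


def _child_rngs(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def _lognormal(rng, median: float, log2_sd: float, size: int) -> np.ndarray:
    return median * np.exp(np.log(2.0) * log2_sd * rng.standard_normal(size))


def draw_target_params(spec: BenchmarkSpec, rng: np.random.Generator | None = None) -> list[TargetParams]:
    """Draw the target panel's kinetic rates from the spec's log-normals.

    Rates are drawn independently per target; draws with ``k_cat <= delta``
    (no net down-regulation, Tinf >= T0) are resampled so every benchmark
    target has a well-defined critical concentration.
    """
    if rng is None:
        rng = _child_rngs(spec.seed, 4)[0]
    m = spec.n_targets
    alpha = _lognormal(rng, spec.alpha_median, spec.rate_log2_sd, m)
    delta = _lognormal(rng, spec.delta_median, spec.rate_log2_sd, m)
    kon_sd = spec.rate_log2_sd if spec.kon_log2_sd is None else spec.kon_log2_sd
    kon = _lognormal(rng, spec.kon_median, kon_sd, m)
    koff = _lognormal(rng, spec.koff_median, spec.rate_log2_sd, m)
    kcat = _lognormal(rng, spec.kcat_median, spec.rate_log2_sd, m)
    for _ in range(spec.resample_budget):
        bad = kcat <= delta
        if not bad.any():
            break
        k = int(bad.sum())
        delta[bad] = _lognormal(rng, spec.delta_median, spec.rate_log2_sd, k)
        kcat[bad] = _lognormal(rng, spec.kcat_median, spec.rate_log2_sd, k)
    else:
        raise InvalidParameterError(
            "resampling budget exhausted: rate distributions make k_cat <= delta too likely"
        )
    return [
        TargetParams(alpha[i], delta[i], kon[i], koff[i], kcat[i], id=f"t{i:04d}")
        for i in range(m)
    ]


def draw_cell_mirna_levels(spec: BenchmarkSpec, rng: np.random.Generator | None = None) -> np.ndarray:
    """Per-cell total Ago-miRNA abundances, log2-uniform over the spec range.

    Cells below ``spec.zero_threshold`` molecules are effectively
    miRNA-free; the flag is recomputed from the returned values wherever
    needed (the raw value is retained).
    """
    if rng is None:
        rng = _child_rngs(spec.seed, 4)[1]
    log2a = rng.uniform(spec.log2_a_low, spec.log2_a_high, spec.n_cells)
    return np.exp2(log2a)


def generate_expression_matrix(
    params: Sequence[TargetParams],
    a_cells: np.ndarray,
    spec: BenchmarkSpec,
    rng: np.random.Generator | None = None,
    return_truth: bool = False,
):
    """Steady-state expression of every target in every cell, plus noise.

    For each cell the full competing-target steady state is solved; each
    entry is then multiplied by an independent log-normal factor with
    median 1 and scale ``spec.noise_sigma`` (a shared per-cell factor of
    scale ``spec.cell_factor_sigma`` is applied on top when configured).
    With all noise scales at 0 the analytic surface is returned exactly.
    Cells whose fixed point fails to solve are dropped with a warning.
    """
    if rng is None:
        rng = _child_rngs(spec.seed, 4)[2]
    a_cells = np.asarray(a_cells, dtype=float)
    n = a_cells.size
    m = len(params)

    noiseless = np.empty((n, m))
    a_free = np.empty(n)
    keep = np.ones(n, dtype=bool)
    for j in range(n):
        try:
            state = solve_free_ago(params, float(a_cells[j]))
        except SolverError as exc:  # pragma: no cover - defensive
            logger.warning("dropping cell %d: %s", j, exc)
            keep[j] = False
            continue
        noiseless[j] = state.total
        a_free[j] = state.a_free
    if not keep.all():
        noiseless = noiseless[keep]
        a_free = a_free[keep]
        a_cells = a_cells[keep]
        n = int(keep.sum())

    values = noiseless.copy()
    gene_ids = [p.id or f"t{i:04d}" for i, p in enumerate(params)]
    target_mask = np.ones(m, dtype=bool)
    if spec.n_background > 0:
        bg_rng = _child_rngs(spec.seed, 4)[3]
        bg_levels = _lognormal(
            bg_rng, spec.alpha_median / spec.delta_median, spec.rate_log2_sd, spec.n_background
        )
        values = np.hstack([values, np.tile(bg_levels, (n, 1))])
        gene_ids = gene_ids + [f"bg{i:04d}" for i in range(spec.n_background)]
        target_mask = np.concatenate([target_mask, np.zeros(spec.n_background, dtype=bool)])

    if spec.noise_sigma > 0:
        values = values * np.exp(spec.noise_sigma * rng.standard_normal(values.shape))
    if spec.cell_factor_sigma > 0:
        cell_factor = np.exp(spec.cell_factor_sigma * rng.standard_normal(n))
        values = values * cell_factor[:, None]

    matrix = ExpressionMatrix(
        values=values,
        cell_ids=np.array([f"cell{j:05d}" for j in range(n)]),
        gene_ids=np.array(gene_ids),
        proxy=a_cells,
        target_mask=target_mask,
        zero_proxy=a_cells < spec.zero_threshold,
    )
    if return_truth:
        return matrix, a_free, noiseless
    return matrix


def generate_benchmark(spec: BenchmarkSpec) -> Benchmark:
    """Full benchmark: parameter draw, miRNA draw, expression surface, noise.

    One master seed (``spec.seed``) deterministically derives independent
    sub-streams for the parameter, cell and noise draws.
    """
    rngs = _child_rngs(spec.seed, 4)
    params = draw_target_params(spec, rngs[0])
    a_cells = draw_cell_mirna_levels(spec, rngs[1])
    matrix, a_free, noiseless = generate_expression_matrix(
        params, a_cells, spec, rngs[2], return_truth=True
    )
    return Benchmark(
        spec=spec,
        params=params,
        matrix=matrix,
        a_total=matrix.proxy.copy(),
        a_free=a_free,
        noiseless=noiseless,
    )


def calibrate_noise_sigma(
    spec: BenchmarkSpec,
    fold_spread: float = 2.0,
    quantiles: tuple[float, float] = (0.05, 0.95),
    n_cells: int = 4000,
    tol: float = 1e-4,
) -> float:
    """Noise scale giving the stated spread of total target level.

    Finds the per-entry log-normal sigma at which the ratio of the upper to
    the lower ``quantiles`` of the *total* target level, across a
    population of miRNA-free cells (every target at T0), equals
    ``fold_spread``.  Common random numbers make the spread a strictly
    increasing, deterministic function of sigma, solved by bisection.
    """
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed).spawn(5)[4])
    t0 = params_to_arrays(draw_target_params(spec))["t0"]
    z = rng.standard_normal((n_cells, t0.size))

    def spread(sigma: float) -> float:
        totals = (t0[None, :] * np.exp(sigma * z)).sum(axis=1)
        qlo, qhi = np.quantile(totals, quantiles)
        return qhi / qlo

    lo, hi = 0.0, 0.5
    while spread(hi) < fold_spread:
        hi *= 2.0
        if hi > 64:
            raise InvalidParameterError("requested spread not reachable")
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if spread(mid) < fold_spread:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def example_four_target_params() -> list[TargetParams]:
    """A curated four-target panel spanning expression and sensitivity.

    Two targets (a, b) have low K_M / low critical concentration (respond
    at low miRNA), two (c, d) respond only at high miRNA; expression spans
    30..500 molecules and down-regulation is a moderate 2-4 fold.
    """
    return [
        TargetParams(alpha=50.0, delta=0.1, k_on=1.00, k_off=0.10, k_cat=0.40, id="a"),
        TargetParams(alpha=3.0, delta=0.1, k_on=1.00, k_off=0.20, k_cat=0.30, id="b"),
        TargetParams(alpha=20.0, delta=0.1, k_on=0.02, k_off=0.40, k_cat=0.20, id="c"),
        TargetParams(alpha=8.0, delta=0.1, k_on=0.05, k_off=0.35, k_cat=0.25, id="d"),
    ]


def mirna_gradient(n_cells: int = 50, log2_range: tuple[float, float] = (-2.0, 12.0)) -> np.ndarray:
    """Evenly log2-spaced total miRNA levels for gradient-style in-silico cells."""
    return np.exp2(np.linspace(log2_range[0], log2_range[1], n_cells))


def with_seed(spec: BenchmarkSpec, seed: int) -> BenchmarkSpec:
    """Copy of a spec with a different master seed."""
    return replace(spec, seed=seed)
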