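"""Stochastic simulation of the competing-target reaction network.

Single cells are simulated as a mass-action reaction network with, per
target ``i``, the five reactions

    0 --alpha_i-->  m_i                (production)
    m_i --delta_i m_i--> 0             (free decay)
    m_i + A_F --k_on_i m_i A_F--> Am_i (binding)
    Am_i --k_off_i Am_i--> m_i + A_F   (unbinding)
    Am_i --k_cat_i Am_i--> 0           (catalyzed decay, releases A_F)

The free Ago-miRNA pool ``A_F = A - sum(Am)`` is implicit, so total Ago is
conserved exactly at every event.  Both the exact direct-method SSA and an
approximate tau-leaping scheme (bounded-relative-change step selection,
with exact stepping as an automatic fallback) are provided; inner loops are
JIT-compiled with numba when available.

Each in-silico cell is run as several independent replicates; species are
summarized by their time-averaged post-burn-in means, with standard
deviations taken across replicates (the convention used for reporting
stochastic ensembles alongside deterministic steady states).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .kinetic_core import CellState, InvalidParameterError, TargetParams, params_to_arrays

try:  # pragma: no cover - numba is an ordinary dependency
    from numba import njit
except ImportError:  # pragma: no cover - plain-Python fallback, much slower

    def njit(*args, **kwargs):  # type: ignore[misc]
        if args and callable(args[0]):
            return args[0]

        def wrap(f):
            return f

        return wrap


__all__ = ["SimulationEnsemble", "propensities", "simulate_cell"]


@dataclass
class SimulationEnsemble:
    """Replicate-averaged summary of stochastic trajectories for one cell.

    ``species`` orders the reported quantities as ``m_1..m_M, Am_1..Am_M,
    A_free``.  ``mean``/``sd`` are taken across the replicate time-averages
    (post-burn-in); ``replicate_means`` keeps the per-replicate values so
    standard errors can be formed as ``sd / sqrt(n_replicates)``.
    """

    species: list[str]
    mean: np.ndarray
    sd: np.ndarray
    replicate_means: np.ndarray
    n_replicates: int
    duration: float
    burn_in: float
    seed: int
    method: str
    n_exact_fallbacks: int = 0

    @property
    def se(self) -> np.ndarray:
        """Standard error of the ensemble mean over replicates."""
        return self.sd / math.sqrt(self.n_replicates)

    def total_mean(self, n_targets: int) -> np.ndarray:
        """Per-target mean total mRNA (free + bound)."""
        return self.mean[:n_targets] + self.mean[n_targets : 2 * n_targets]


def propensities(state: CellState, params: Sequence[TargetParams]) -> np.ndarray:
    """Mass-action reaction rates for the current state.

    Returns an array of length ``5 M`` ordered per target as
    (production, free decay, binding, unbinding, catalyzed decay).
    """
    m = np.asarray(state.m)
    am = np.asarray(state.am)
    if np.any(m < 0) or np.any(am < 0) or state.a_free < 0:
        raise InvalidParameterError("copy numbers must be non-negative")
    arr = params_to_arrays(params)
    out = np.empty(5 * len(params))
    out[0::5] = arr["alpha"]
    out[1::5] = arr["delta"] * m
    out[2::5] = arr["k_on"] * m * state.a_free
    out[3::5] = arr["k_off"] * am
    out[4::5] = arr["k_cat"] * am
    return out


@njit(cache=False)
def _fill_propensities(alpha, delta, kon, koff, kcat, m, am, a_free, prop):
    total = 0.0
    for i in range(alpha.size):
        prop[5 * i] = alpha[i]
        prop[5 * i + 1] = delta[i] * m[i]
        prop[5 * i + 2] = kon[i] * m[i] * a_free
        prop[5 * i + 3] = koff[i] * am[i]
        prop[5 * i + 4] = kcat[i] * am[i]
        total += (
            prop[5 * i]
            + prop[5 * i + 1]
            + prop[5 * i + 2]
            + prop[5 * i + 3]
            + prop[5 * i + 4]
        )
    return total


@njit(cache=False)
def _record_until(out, idx, t_new, sample_dt, m, am):
    """Record the current state at every sample time <= t_new; new index."""
    n_targets = m.size
    n_samples = out.shape[0]
    while idx < n_samples and (idx + 1) * sample_dt <= t_new:
        for i in range(n_targets):
            out[idx, i] = m[i]
            out[idx, n_targets + i] = am[i]
        idx += 1
    return idx


@njit(cache=False)
def _pick_and_apply(prop, total, m, am):
    """Select one reaction by its propensity and apply it.

    Returns the change in total bound Ago (+1 binding, -1 release).
    """
    u = np.random.random() * total
    acc = 0.0
    r = prop.size - 1
    for k in range(prop.size):
        acc += prop[k]
        if u < acc:
            r = k
            break
    i = r // 5
    kind = r % 5
    if kind == 0:
        m[i] += 1
        return 0
    if kind == 1:
        m[i] -= 1
        return 0
    if kind == 2:
        m[i] -= 1
        am[i] += 1
        return 1
    if kind == 3:
        m[i] += 1
        am[i] -= 1
        return -1
    am[i] -= 1
    return -1


@njit(cache=False)
def _ssa_run(alpha, delta, kon, koff, kcat, a_total, sample_dt, seed, out):
    """Exact SSA; records the state at uniform sample times into ``out``."""
    np.random.seed(seed)
    n_targets = alpha.size
    n_samples = out.shape[0]
    m = np.zeros(n_targets, np.int64)
    am = np.zeros(n_targets, np.int64)
    a_free = a_total
    prop = np.empty(5 * n_targets)
    t = 0.0
    idx = 0
    while idx < n_samples:
        total = _fill_propensities(alpha, delta, kon, koff, kcat, m, am, a_free, prop)
        t_new = t + np.random.exponential(1.0 / total)
        # the pre-event state holds on (t, t_new]: record it first
        idx = _record_until(out, idx, t_new, sample_dt, m, am)
        a_free -= _pick_and_apply(prop, total, m, am)
        t = t_new
    return 0


@njit(cache=False)
def _tau_run(alpha, delta, kon, koff, kcat, a_total, sample_dt, seed, eps, out):
    """Tau-leaping with exact-SSA fallback; returns the fallback count."""
    np.random.seed(seed)
    n_targets = alpha.size
    n_samples = out.shape[0]
    m = np.zeros(n_targets, np.int64)
    am = np.zeros(n_targets, np.int64)
    a_free = a_total
    prop = np.empty(5 * n_targets)
    dm = np.zeros(n_targets, np.int64)
    dam = np.zeros(n_targets, np.int64)
    t = 0.0
    idx = 0
    n_fallback = 0
    while idx < n_samples:
        total = _fill_propensities(alpha, delta, kon, koff, kcat, m, am, a_free, prop)
        # bounded-relative-change step: per species, the mean and variance
        # of the net change rate limit tau so the expected relative change
        # stays below eps (Cao/Gillespie criterion, g factors omitted)
        tau = 1e300
        mu_f = 0.0
        var_f = 0.0
        for i in range(n_targets):
            mu_m = prop[5 * i] - prop[5 * i + 1] - prop[5 * i + 2] + prop[5 * i + 3]
            var_m = prop[5 * i] + prop[5 * i + 1] + prop[5 * i + 2] + prop[5 * i + 3]
            mu_a = prop[5 * i + 2] - prop[5 * i + 3] - prop[5 * i + 4]
            var_a = prop[5 * i + 2] + prop[5 * i + 3] + prop[5 * i + 4]
            bm = max(eps * m[i], 1.0)
            ba = max(eps * am[i], 1.0)
            if mu_m != 0.0:
                tau = min(tau, bm / abs(mu_m))
            if var_m > 0.0:
                tau = min(tau, bm * bm / var_m)
            if mu_a != 0.0:
                tau = min(tau, ba / abs(mu_a))
            if var_a > 0.0:
                tau = min(tau, ba * ba / var_a)
            mu_f += prop[5 * i + 3] + prop[5 * i + 4] - prop[5 * i + 2]
            var_f += prop[5 * i + 3] + prop[5 * i + 4] + prop[5 * i + 2]
        bf = max(eps * a_free, 1.0)
        if mu_f != 0.0:
            tau = min(tau, bf / abs(mu_f))
        if var_f > 0.0:
            tau = min(tau, bf * bf / var_f)

        if tau < 10.0 / total:
            # leap not worthwhile here; take one exact event instead
            t_new = t + np.random.exponential(1.0 / total)
            idx = _record_until(out, idx, t_new, sample_dt, m, am)
            a_free -= _pick_and_apply(prop, total, m, am)
            t = t_new
            n_fallback += 1
            continue

        # Poisson firing counts over the leap; reject leaps that would
        # drive any population (including the free pool) negative
        accepted = False
        while not accepted:
            dbound = 0
            valid = True
            for i in range(n_targets):
                k_prod = np.random.poisson(prop[5 * i] * tau)
                k_dec = np.random.poisson(prop[5 * i + 1] * tau)
                k_bind = np.random.poisson(prop[5 * i + 2] * tau)
                k_unb = np.random.poisson(prop[5 * i + 3] * tau)
                k_cat = np.random.poisson(prop[5 * i + 4] * tau)
                dm[i] = k_prod - k_dec - k_bind + k_unb
                dam[i] = k_bind - k_unb - k_cat
                dbound += dam[i]
            if a_free - dbound < 0:
                valid = False
            else:
                for i in range(n_targets):
                    if m[i] + dm[i] < 0 or am[i] + dam[i] < 0:
                        valid = False
                        break
            if valid:
                accepted = True
            else:
                tau *= 0.5
                n_fallback += 1
                if tau < 2.0 / total:
                    # give up on leaping for this step; one exact event
                    t_new = t + np.random.exponential(1.0 / total)
                    idx = _record_until(out, idx, t_new, sample_dt, m, am)
                    a_free -= _pick_and_apply(prop, total, m, am)
                    t = t_new
                    dbound = 0
                    for i in range(n_targets):
                        dm[i] = 0
                        dam[i] = 0
                    accepted = True
        t_new = t + tau
        idx = _record_until(out, idx, t_new, sample_dt, m, am)
        for i in range(n_targets):
            m[i] += dm[i]
            am[i] += dam[i]
        a_free -= dbound
        t = t_new
    return n_fallback


def simulate_cell(
    params: Sequence[TargetParams],
    a_total: int,
    duration: float = 100_000.0,
    burn_in: float = 10_000.0,
    n_replicates: int = 6,
    seed: int = 0,
    method: str = "tau_leap",
    sample_dt: float = 1.0,
    eps: float = 0.03,
) -> SimulationEnsemble:
    """Simulate one cell's reaction network and summarize it.

    Runs ``n_replicates`` independent trajectories of length ``duration``
    (time units) from the empty-target state, samples copy numbers on a
    uniform grid of spacing ``sample_dt``, discards samples up to
    ``burn_in`` and reports per-species time-averaged means with
    across-replicate standard deviations.

    ``method`` is ``"ssa"`` (exact) or ``"tau_leap"`` (approximate leaps
    with automatic exact fallback; fallback events are counted in
    ``n_exact_fallbacks``).
    """
    if not duration > burn_in >= 0:
        raise InvalidParameterError("need duration > burn_in >= 0")
    if a_total < 0:
        raise InvalidParameterError("A_total must be >= 0")
    if n_replicates < 1:
        raise InvalidParameterError("n_replicates must be >= 1")
    if method not in ("ssa", "tau_leap"):
        raise InvalidParameterError(f"unknown method {method!r}")

    arr = params_to_arrays(params)
    n_targets = len(params)
    n_samples = int(round(duration / sample_dt))
    n_keep = n_samples - int(round(burn_in / sample_dt))
    if n_keep < 1:
        raise InvalidParameterError("no samples left after burn-in")

    # independent sub-seeds per replicate, derived deterministically
    sub_seeds = np.random.SeedSequence(seed).generate_state(n_replicates)
    rep_means = np.empty((n_replicates, 2 * n_targets + 1))
    n_fallback = 0
    out = np.empty((n_samples, 2 * n_targets), dtype=np.int64)
    for r in range(n_replicates):
        s = int(sub_seeds[r]) % (2**31 - 1)
        if method == "ssa":
            _ssa_run(
                arr["alpha"], arr["delta"], arr["k_on"], arr["k_off"], arr["k_cat"],
                int(a_total), float(sample_dt), s, out,
            )
        else:
            n_fallback += int(
                _tau_run(
                    arr["alpha"], arr["delta"], arr["k_on"], arr["k_off"], arr["k_cat"],
                    int(a_total), float(sample_dt), s, float(eps), out,
                )
            )
        kept = out[n_samples - n_keep :]
        rep_means[r, : 2 * n_targets] = kept.mean(axis=0)
        rep_means[r, 2 * n_targets] = a_total - kept[:, n_targets:].sum(axis=1).mean()

    species = (
        [f"m_{p.id or i}" for i, p in enumerate(params)]
        + [f"Am_{p.id or i}" for i, p in enumerate(params)]
        + ["A_free"]
    )
    return SimulationEnsemble(
        species=species,
        mean=rep_means.mean(axis=0),
        sd=rep_means.std(axis=0, ddof=1) if n_replicates > 1 else np.zeros(rep_means.shape[1]),
        replicate_means=rep_means,
        n_replicates=n_replicates,
        duration=float(duration),
        burn_in=float(burn_in),
        seed=int(seed),
        method=method,
        n_exact_fallbacks=n_fallback,
    )
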