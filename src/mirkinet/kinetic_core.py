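"""Kinetic model of mRNA targets competing for a shared Ago-miRNA pool.

The model considers ``M`` mRNA species ("targets") that are transcribed at
rate ``alpha_i``, decay at rate ``delta_i`` while free, and reversibly bind
a miRNA-loaded Argonaute (Ago-miRNA) complex with rates ``k_on_i`` /
``k_off_i``.  While bound, a target decays at the (typically faster)
catalyzed rate ``k_cat_i``.  The total number ``A`` of Ago-miRNA complexes
in a cell is treated as constant on the time scale of target turnover
(miRNA levels are set externally and are long-lived), so the free pool is
``A_F = A - sum_i Am_i`` with ``Am_i`` the bound copies of target ``i``.

Per free and bound species this gives the 2M-dimensional mass-action system

    dm_i/dt  = alpha_i - delta_i m_i - k_on_i m_i A_F + k_off_i Am_i
    dAm_i/dt = k_on_i m_i A_F - (k_off_i + k_cat_i) Am_i .

At steady state the bound fraction of target ``i`` is the Michaelis-Menten
form ``f_i = 1 / (1 + K_M_i / A_F)`` with ``K_M_i = (k_off_i + k_cat_i) /
k_on_i``, and the total level ``T_i = m_i + Am_i`` interpolates between the
no-miRNA plateau ``T0_i = alpha_i / delta_i`` and the saturated level
``Tinf_i = alpha_i / k_cat_i``:

    T_i* = T0_i / (1 + f_i (T0_i / Tinf_i - 1)) .

The free pool ``A_F`` couples all targets through a single scalar
conservation equation, solved here by bracketed root finding.

Units: abundances are molecules per cell, rates are per hour, and
concentrations are identified with abundances (unit cell volume), so
``K_M`` and ``A_F`` share the molecules-per-cell scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

__all__ = [
    "InvalidParameterError",
    "DegenerateTargetError",
    "SolverError",
    "TargetParams",
    "CellState",
    "km_constant",
    "bound_fraction",
    "target_steady_state",
    "critical_free_ago",
    "solve_free_ago",
    "integrate_ode",
    "params_to_arrays",
    "read_params_tsv",
    "write_params_tsv",
]


class InvalidParameterError(ValueError):
    """A kinetic parameter or model input is outside its admissible range."""


class DegenerateTargetError(ValueError):
    """The target is not down-regulated (Tinf >= T0): no halfway point exists."""


class SolverError(RuntimeError):
    """A numerical solver failed to converge; the residual is reported."""


@dataclass(frozen=True)
class TargetParams:
    """Kinetic rates of one miRNA target.

    Parameters
    ----------
    alpha : float
        Transcription rate (molecules/h), > 0.
    delta : float
        Decay rate of the free mRNA (1/h), > 0.
    k_on : float
        Ago-miRNA binding rate (1/(molecule h)), > 0.
    k_off : float
        Dissociation rate from the complex (1/h), >= 0.
    k_cat : float
        Decay rate of the bound mRNA (1/h), > 0.
    id : str
        Target label.
    """

    alpha: float
    delta: float
    k_on: float
    k_off: float
    k_cat: float
    id: str = ""

    def __post_init__(self) -> None:
        for name in ("alpha", "delta", "k_on", "k_cat"):
            v = getattr(self, name)
            if not (v > 0 and math.isfinite(v)):
                raise InvalidParameterError(f"{name} must be finite and > 0, got {v!r}")
        if not (self.k_off >= 0 and math.isfinite(self.k_off)):
            raise InvalidParameterError(f"k_off must be finite and >= 0, got {self.k_off!r}")

    @property
    def t0(self) -> float:
        """Steady-state total level with no miRNA, alpha/delta."""
        return self.alpha / self.delta

    @property
    def tinf(self) -> float:
        """Steady-state total level at saturating miRNA, alpha/k_cat."""
        return self.alpha / self.k_cat

    @property
    def km(self) -> float:
        """Michaelis-Menten constant (k_off + k_cat)/k_on."""
        return km_constant(self.k_off, self.k_cat, self.k_on)

    @property
    def is_downregulated(self) -> bool:
        """True when k_cat > delta, i.e. Tinf < T0."""
        return self.k_cat > self.delta

    @property
    def a_f_c(self) -> float:
        """Critical free-Ago level (halfway point); requires Tinf < T0."""
        return critical_free_ago(self.km, self.t0, self.tinf)


@dataclass
class CellState:
    """Steady-state (or instantaneous) amounts in one cell.

    ``a_free = a_total - sum(am)`` by conservation; ``f`` holds the bound
    fraction ``am / (m + am)`` per target (0 where the target is absent).
    """

    a_total: float
    a_free: float
    m: np.ndarray
    am: np.ndarray
    f: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.m = np.asarray(self.m, dtype=float)
        self.am = np.asarray(self.am, dtype=float)
        if self.f is None:
            tot = self.m + self.am
            self.f = np.divide(self.am, tot, out=np.zeros_like(tot), where=tot > 0)
        else:
            self.f = np.asarray(self.f, dtype=float)

    @property
    def total(self) -> np.ndarray:
        """Total per-target mRNA, free plus bound."""
        return self.m + self.am


def km_constant(k_off, k_cat, k_on):
    """Michaelis-Menten constant ``(k_off + k_cat) / k_on``.

    Low ``K_M`` means a high-affinity target that retains the miRNA.
    Accepts scalars or arrays.
    """
    k_off = np.asarray(k_off, dtype=float)
    k_cat = np.asarray(k_cat, dtype=float)
    k_on = np.asarray(k_on, dtype=float)
    if np.any(k_on <= 0):
        raise InvalidParameterError("k_on must be > 0")
    if np.any(k_off < 0) or np.any(k_cat < 0):
        raise InvalidParameterError("k_off and k_cat must be >= 0")
    if np.any(k_off + k_cat <= 0):
        raise InvalidParameterError("k_off + k_cat must be > 0")
    out = (k_off + k_cat) / k_on
    return float(out) if out.ndim == 0 else out


def bound_fraction(km, a_free):
    """Fraction of a target bound to Ago-miRNA, ``1 / (1 + K_M / A_F)``.

    Returns 0 at ``a_free = 0``; strictly increasing in ``a_free`` with
    range [0, 1).  Accepts scalars or arrays (broadcasting).
    """
    km = np.asarray(km, dtype=float)
    a_free = np.asarray(a_free, dtype=float)
    if np.any(km <= 0):
        raise InvalidParameterError("K_M must be > 0")
    if np.any(a_free < 0):
        raise InvalidParameterError("A_free must be >= 0")
    # a/(a+K) is the division-safe form of 1/(1+K/a) at a=0.
    out = a_free / (a_free + km)
    return float(out) if out.ndim == 0 else out


def target_steady_state(t0, tinf, f):
    """Total steady-state target level at bound fraction ``f``.

    ``T* = T0 / (1 + f (T0/Tinf - 1))``: equals T0 at f=0 and tends to
    Tinf as f -> 1.  Accepts scalars or arrays.
    """
    t0 = np.asarray(t0, dtype=float)
    tinf = np.asarray(tinf, dtype=float)
    f = np.asarray(f, dtype=float)
    if np.any(t0 <= 0) or np.any(tinf <= 0):
        raise InvalidParameterError("T0 and Tinf must be > 0")
    if np.any(f < 0) or np.any(f >= 1):
        raise InvalidParameterError("f must lie in [0, 1)")
    out = t0 / (1.0 + f * (t0 / tinf - 1.0))
    return float(out) if out.ndim == 0 else out


def critical_free_ago(km, t0, tinf):
    """Free-Ago level at which the target sits halfway between T0 and Tinf.

    Solving ``T*(f(A_F)) = (T0 + Tinf)/2`` for ``A_F`` gives the closed form

        A_F^C = K_M * Tinf / T0 ,

    linear in ``K_M`` and requiring genuine down-regulation (Tinf < T0).
    """
    km = np.asarray(km, dtype=float)
    t0 = np.asarray(t0, dtype=float)
    tinf = np.asarray(tinf, dtype=float)
    if np.any(km <= 0):
        raise InvalidParameterError("K_M must be > 0")
    if np.any(t0 <= 0) or np.any(tinf <= 0):
        raise InvalidParameterError("T0 and Tinf must be > 0")
    if np.any(tinf >= t0):
        raise DegenerateTargetError(
            "Tinf >= T0: target is not down-regulated, halfway point undefined"
        )
    out = km * tinf / t0
    return float(out) if out.ndim == 0 else out


def params_to_arrays(params: Sequence[TargetParams]):
    """Stack a parameter list into per-rate float arrays.

    Returns a dict with keys alpha, delta, k_on, k_off, k_cat, t0, tinf, km.
    """
    alpha = np.array([p.alpha for p in params], dtype=float)
    delta = np.array([p.delta for p in params], dtype=float)
    k_on = np.array([p.k_on for p in params], dtype=float)
    k_off = np.array([p.k_off for p in params], dtype=float)
    k_cat = np.array([p.k_cat for p in params], dtype=float)
    return {
        "alpha": alpha,
        "delta": delta,
        "k_on": k_on,
        "k_off": k_off,
        "k_cat": k_cat,
        "t0": alpha / delta,
        "tinf": alpha / k_cat,
        "km": (k_off + k_cat) / k_on,
    }


def _bound_load(a_free: float, km: np.ndarray, t0: np.ndarray, tinf: np.ndarray) -> float:
    """Total Ago-miRNA sequestered by all targets at free level ``a_free``."""
    f = a_free / (a_free + km)
    t_star = t0 / (1.0 + f * (t0 / tinf - 1.0))
    return float(np.sum(f * t_star))


def solve_free_ago(
    params: Sequence[TargetParams],
    a_total: float,
    rtol: float = 1e-12,
) -> CellState:
    """Steady state of the competing-target system at total Ago-miRNA ``a_total``.

    Solves the scalar conservation fixed point

        A_F + sum_i f_i(A_F) T_i*(A_F) = A_total

    by bracketed root finding on [0, A_total].  The left side is strictly
    increasing in ``A_F`` (each bound amount ``f_i T_i*`` is increasing), so
    the solution is unique and bracketing cannot fail.

    Raises
    ------
    SolverError
        If the root residual exceeds tolerance (pathological inputs).
    """
    if a_total < 0:
        raise InvalidParameterError("A_total must be >= 0")
    arr = params_to_arrays(params)
    km, t0, tinf = arr["km"], arr["t0"], arr["tinf"]

    if a_total == 0:
        m = t0.copy()
        return CellState(0.0, 0.0, m, np.zeros_like(m), np.zeros_like(m))

    def h(a_free: float) -> float:
        return a_free + _bound_load(a_free, km, t0, tinf) - a_total

    if h(a_total) <= 0:  # numerically saturated: everything bound
        a_free = float(a_total)
    else:
        a_free = brentq(h, 0.0, a_total, xtol=1e-30, rtol=4 * np.finfo(float).eps)

    residual = abs(h(a_free))
    if residual > rtol * max(a_total, 1.0) * 1e4:
        raise SolverError(
            f"free-Ago fixed point residual {residual:.3e} exceeds tolerance"
        )
    f = a_free / (a_free + km)
    t_star = t0 / (1.0 + f * (t0 / tinf - 1.0))
    am = f * t_star
    m = t_star - am
    return CellState(float(a_total), float(a_free), m, am, f)


def integrate_ode(
    params: Sequence[TargetParams],
    a_total: float,
    init: CellState | None,
    t_grid: Iterable[float],
    rtol: float = 1e-10,
    atol: float = 1e-10,
) -> list[CellState]:
    """Numerically integrate the 2M-species mass-action system.

    ``A`` is held constant; ``A_F`` is recomputed from conservation at every
    step, so ``a_free + sum(am) == a_total`` holds along the trajectory to
    integration tolerance.  Returns one :class:`CellState` per grid time.
    """
    t_grid = np.asarray(list(t_grid), dtype=float)
    if t_grid.ndim != 1 or np.any(np.diff(t_grid) <= 0):
        raise InvalidParameterError("t_grid must be strictly increasing")
    arr = params_to_arrays(params)
    alpha, delta = arr["alpha"], arr["delta"]
    k_on, k_off, k_cat = arr["k_on"], arr["k_off"], arr["k_cat"]
    n = alpha.size

    if init is None:
        y0 = np.zeros(2 * n)
    else:
        if np.any(init.m < 0) or np.any(init.am < 0):
            raise InvalidParameterError("initial state must be non-negative")
        y0 = np.concatenate([init.m, init.am])

    def rhs(_t: float, y: np.ndarray) -> np.ndarray:
        m, am = y[:n], y[n:]
        a_free = a_total - am.sum()
        bind = k_on * m * a_free
        dm = alpha - delta * m - bind + k_off * am
        dam = bind - (k_off + k_cat) * am
        return np.concatenate([dm, dam])

    sol = solve_ivp(
        rhs,
        (t_grid[0], t_grid[-1]),
        y0,
        t_eval=t_grid,
        method="LSODA",
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        raise SolverError(f"ODE integration failed: {sol.message}")
    out = []
    for k in range(sol.t.size):
        m = sol.y[:n, k]
        am = sol.y[n:, k]
        out.append(CellState(float(a_total), float(a_total - am.sum()), m, am))
    return out


_PARAM_COLUMNS = ["id", "alpha", "delta", "k_on", "k_off", "k_cat"]


def read_params_tsv(path) -> list[TargetParams]:
    """Read target parameters from a TSV with columns id, alpha, delta, k_on, k_off, k_cat."""
    df = pd.read_csv(path, sep="\t")
    missing = set(_PARAM_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"parameter table is missing columns: {sorted(missing)}")
    return [
        TargetParams(
            alpha=row.alpha,
            delta=row.delta,
            k_on=row.k_on,
            k_off=row.k_off,
            k_cat=row.k_cat,
            id=str(row.id),
        )
        for row in df.itertuples()
    ]


def write_params_tsv(params: Sequence[TargetParams], path) -> None:
    """Write target parameters as a TSV (see :func:`read_params_tsv`)."""
    df = pd.DataFrame(
        {
            "id": [p.id for p in params],
            "alpha": [p.alpha for p in params],
            "delta": [p.delta for p in params],
            "k_on": [p.k_on for p in params],
            "k_off": [p.k_off for p in params],
            "k_cat": [p.k_cat for p in params],
        }
    )
    df.to_csv(path, sep="\t", index=False)
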