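"""Equilibrium forward model: free-LuxR partitioning and lux-box occupancy.

At fixed concentrations of the two signals, free LuxR (scaled to the total
intracellular pool, ``r = [LuxR]/[LuxR0]``) partitions into two
homomultimeric complexes,

    rc8 = (c8/k1)^m * r^m        (C8-HSL complex, m copies of LuxR)
    rc6 = (c6/k2)^n * r^n        (3OC6-HSL complex, n copies of LuxR)

subject to conservation of the total pool.  The default closure weights each
complex by its LuxR stoichiometry,

    r + m*rc8 + n*rc6 = 1,

which makes the saturating occupancy depend on the Hill coefficient (the
complex pool tops out at 1/m of total LuxR) — the behaviour needed to
reproduce how the lux-box constant kA reshapes the high-signal plateau.  An
unweighted closure ``r + rc8 + rc6 = 1`` is available via ``closure=``.

Lux-box occupancy follows a two-species competitive binding isotherm,

    P = (PA + PB) / (1 + PA + PB),   PA = rc8/kA,  PB = rc6/kB,

and luminescence is the square of an affine map of P (luciferase acts as a
dimer): L = (a0 + a1*P)^2, floored so L stays positive.

All powers are evaluated in log space; fitted log10 constants span well over
ten decades and a naive ``(c/k)**m`` overflows.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .params import KineticParams, ScaleParams

__all__ = [
    "SolverState",
    "solve_free_luxr",
    "occupancy",
    "occupancy_grid",
    "luminescence",
    "response_surface",
    "suppression_index",
    "EPS_SQRT",
    "CLOSURES",
]

#: floor on a0 + a1*P before squaring, so L > 0 and log-loss is defined
EPS_SQRT = 1e-3

CLOSURES = ("stoichiometric", "unweighted")


@dataclass(frozen=True)
class SolverState:
    """Scaled equilibrium species at one concentration pair."""

    r: float  # free LuxR / total LuxR, in (0, 1]
    rc8: float  # scaled C8 complex concentration
    rc6: float  # scaled 3OC6 complex concentration
    PA: float  # pA/p0 probability ratio, = rc8/kA
    PB: float  # pB/p0 probability ratio, = rc6/kB
    P: float  # lux-box occupancy, (PA+PB)/(1+PA+PB)


def _closure_weights(params: KineticParams, closure: str):
    if closure == "stoichiometric":
        return params.m, params.n
    if closure == "unweighted":
        return 1.0, 1.0
    raise ValueError(f"unknown closure {closure!r}; expected one of {CLOSURES}")


def _solve_r(c8, c6, params: KineticParams, closure: str = "stoichiometric"):
    """Vectorized free-LuxR root solve.

    Returns (r, rc8, rc6) arrays broadcast over c8, c6.  The residual
    g(r) = r + w8*rc8 + w6*rc6 - 1 is strictly increasing in r with
    g(0+) = -1 and g(1) >= 0, so the root in (0, 1] is unique; we bisect on
    t = ln r where every term is overflow-safe.
    """
    c8 = np.asarray(c8, dtype=float)
    c6 = np.asarray(c6, dtype=float)
    if np.any(c8 < 0) or np.any(c6 < 0):
        raise ValueError("HSL concentrations must be non-negative")
    c8, c6 = np.broadcast_arrays(c8, c6)
    m, n = params.m, params.n
    w8, w6 = _closure_weights(params, closure)
    ln10 = math.log(10.0)

    # log of A = (c8/k1)^m and B = (c6/k2)^n; -inf encodes a zero term (0^m = 0)
    with np.errstate(divide="ignore"):
        logA = m * (np.log(c8) - params.log10_k1 * ln10)
        logB = n * (np.log(c6) - params.log10_k2 * ln10)
    logw8A = logA + math.log(w8)
    logw6B = logB + math.log(w6)

    # bracket: at t = 0, g = w8*A + w6*B >= 0; choose t_lo where each of the
    # three increasing terms is below 1/4, hence g(t_lo) <= 3/4 - 1 < 0
    ln4 = math.log(4.0)
    t_lo = np.minimum(-ln4, np.minimum(-(ln4 + logw8A) / m, -(ln4 + logw6B) / n)) - 1.0
    t_lo = np.where(np.isfinite(t_lo), t_lo, -ln4 - 1.0)
    t_hi = np.zeros_like(t_lo)

    width = float(np.max(t_hi - t_lo)) if t_lo.size else 0.0
    n_iter = min(200, max(60, int(math.ceil(math.log2(max(width, 1e-12) / 1e-15)))))
    for _ in range(n_iter):
        t_mid = 0.5 * (t_lo + t_hi)
        g = (
            np.exp(t_mid)
            + np.exp(np.minimum(logw8A + m * t_mid, 700.0))
            + np.exp(np.minimum(logw6B + n * t_mid, 700.0))
            - 1.0
        )
        t_hi = np.where(g >= 0.0, t_mid, t_hi)
        t_lo = np.where(g >= 0.0, t_lo, t_mid)

    t = 0.5 * (t_lo + t_hi)
    both_zero = np.isneginf(logA) & np.isneginf(logB)
    t = np.where(both_zero, 0.0, t)  # no signal: all LuxR free, exactly
    r = np.exp(t)
    rc8 = np.exp(np.minimum(logA + m * t, 700.0))  # exp(-inf) = 0 for zero wells
    rc6 = np.exp(np.minimum(logB + n * t, 700.0))
    return r, rc8, rc6


def solve_free_luxr(
    c8: float,
    c6: float,
    params: KineticParams,
    tol: float = 1e-10,
    closure: str = "stoichiometric",
) -> SolverState:
    """Solve the conservation balance at one (c8, c6) pair, in nM.

    Raises ``ValueError`` on negative concentrations and ``ArithmeticError``
    if the converged root violates the conservation residual tolerance
    (which would indicate a solver defect, not bad input).
    """
    r, rc8, rc6 = (float(x) for x in _solve_r(c8, c6, params, closure))
    w8, w6 = _closure_weights(params, closure)
    resid = r + w8 * rc8 + w6 * rc6 - 1.0
    if not math.isfinite(resid) or abs(resid) > tol:
        raise ArithmeticError(
            f"free-LuxR solve residual {resid:.3e} exceeds tol={tol:.1e} "
            f"at c8={c8}, c6={c6}"
        )
    PA = float(_prob_ratio(rc8, params.kA))
    PB = float(_prob_ratio(rc6, params.kB))
    P = _occ_from_ratios(PA, PB)
    return SolverState(r=r, rc8=rc8, rc6=rc6, PA=PA, PB=PB, P=float(P))


def _prob_ratio(rc, k):
    # rc / k with the 0/0 case (empty complex pool, underflowed k) -> 0:
    # no complex means the lux box cannot be occupied by it at any affinity
    rc = np.asarray(rc, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
        return np.where(rc == 0.0, 0.0, rc / k)


def _occ_from_ratios(PA, PB):
    # stable for huge PA+PB: P = 1 - 1/(1+PA+PB)
    s = PA + PB
    with np.errstate(invalid="ignore"):
        return np.where(s > 1e8, 1.0 - 1.0 / (1.0 + s), s / (1.0 + s))


def occupancy(
    c8: float,
    c6: float,
    params: KineticParams,
    closure: str = "stoichiometric",
) -> float:
    """Lux-box occupancy probability P at one concentration pair."""
    return solve_free_luxr(c8, c6, params, closure=closure).P


def occupancy_grid(
    c8_levels,
    c6_levels,
    params: KineticParams,
    closure: str = "stoichiometric",
) -> np.ndarray:
    """Occupancy matrix over a concentration grid, shape |c8| x |c6|."""
    c8_levels = np.asarray(c8_levels, dtype=float)
    c6_levels = np.asarray(c6_levels, dtype=float)
    if c8_levels.size == 0 or c6_levels.size == 0:
        raise ValueError("concentration axes must be non-empty")
    C8 = c8_levels[:, None]
    C6 = c6_levels[None, :]
    _, rc8, rc6 = _solve_r(C8, C6, params, closure)
    return np.asarray(
        _occ_from_ratios(_prob_ratio(rc8, params.kA), _prob_ratio(rc6, params.kB)),
        dtype=float,
    )


def luminescence(P, scale: ScaleParams):
    """Specific luminescence from occupancy: (a0 + a1*P)^2, floored positive."""
    root = np.maximum(scale.a0 + scale.a1 * np.asarray(P, dtype=float), EPS_SQRT)
    out = root * root
    return float(out) if out.ndim == 0 else out


def response_surface(
    c8_levels,
    c6_levels,
    params: KineticParams,
    scale: ScaleParams,
    closure: str = "stoichiometric",
) -> np.ndarray:
    """Predicted specific-luminescence surface over a concentration grid."""
    return luminescence(occupancy_grid(c8_levels, c6_levels, params, closure), scale)


def suppression_index(surface: np.ndarray, axis: str = "c8") -> float:
    """Largest fractional drop of luminescence past its peak along one axis.

    With ``axis="c8"`` each profile holds the 3OC6 level fixed and sweeps the
    C8 concentration (matrix rows); the index for a profile is
    (peak - minimum at concentrations above the peak) / peak, and the
    surface's index is the maximum over profiles.  Zero means no profile is
    suppressed by further addition of the swept signal.
    """
    S = np.asarray(surface, dtype=float)
    if S.ndim != 2:
        raise ValueError("surface must be a 2-D matrix")
    if np.any(~(S > 0)):
        raise ValueError("surface must be strictly positive")
    if axis in ("c8", "C8"):
        profiles = S.T  # each profile varies along the C8 (row) axis
    elif axis in ("c6", "3OC6", "c6hsl"):
        profiles = S
    else:
        raise ValueError(f"axis must be 'c8' or 'c6', got {axis!r}")
    worst = 0.0
    for prof in profiles:
        i_peak = int(np.argmax(prof))
        peak = prof[i_peak]
        drop = (peak - prof[i_peak:].min()) / peak
        worst = max(worst, float(drop))
    return worst
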