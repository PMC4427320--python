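"""Conversion between scaled and absolute dissociation constants.

The fit determines dissociation constants scaled to the (unmeasured) total
intracellular LuxR concentration [LuxR0].  Given an assumed [LuxR0] they
convert to absolute constants:

    K_A = kA * [LuxR0]             K_B = kB * [LuxR0]
    K1  = (k1^m * [LuxR0]^(m-1))^(1/(2m-1))
    K2  = (k2^n * [LuxR0]^(n-1))^(1/(2n-1))

The default [LuxR0] = 33 nM follows the field's per-cell estimate of the
homologous regulator TraR (~20 protomers per cell).  The K1/K2 exponent
1/(2m-1) is singular at a Hill coefficient of 1/2: there the absolute
constant is undetermined by the scaled one, and values nearby are
numerically fragile (a warning is emitted inside |2m-1| < 0.05).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

from .params import KineticParams

__all__ = ["AbsoluteParams", "scaled_to_absolute", "absolute_to_scaled", "DEFAULT_LUXR0"]

DEFAULT_LUXR0 = 33.0  # nM
_SINGULAR_HALFWIDTH = 0.05  # |2m-1| below this: fragile conversion


class SingularExponentError(ValueError):
    """Hill coefficient exactly 1/2 makes the absolute constant undetermined."""


@dataclass(frozen=True)
class AbsoluteParams:
    """Absolute dissociation constants (nM) at a stated total LuxR."""

    K1: float
    K2: float
    KA: float
    KB: float
    luxr0: float
    fragile: bool = False  # a Hill coefficient sat near the singular value 1/2

    def __post_init__(self) -> None:
        for name in ("K1", "K2", "KA", "KB", "luxr0"):
            v = getattr(self, name)
            if not (v > 0 and math.isfinite(v)):
                raise ValueError(f"{name} must be positive and finite, got {v}")


def _check_exponent(hill: float, label: str) -> bool:
    denom = 2.0 * hill - 1.0
    if denom == 0.0:
        raise SingularExponentError(
            f"{label} = 1/2 makes the 1/(2{label}-1) exponent singular; "
            "the absolute complex dissociation constant is undetermined"
        )
    if abs(denom) < _SINGULAR_HALFWIDTH:
        warnings.warn(
            f"{label} = {hill:g} is within {_SINGULAR_HALFWIDTH} of the singular "
            "value 1/2; the converted constant is numerically fragile",
            RuntimeWarning,
            stacklevel=3,
        )
        return True
    return False


def scaled_to_absolute(params: KineticParams, luxr0: float = DEFAULT_LUXR0) -> AbsoluteParams:
    """Absolute constants from scaled ones at total LuxR ``luxr0`` (nM)."""
    if not luxr0 > 0:
        raise ValueError(f"luxr0 must be positive, got {luxr0}")
    m, n = params.m, params.n
    fragile = _check_exponent(m, "m") | _check_exponent(n, "n")
    log_luxr0 = math.log10(luxr0)
    # log-space: log10 K1 = (m*log10 k1 + (m-1)*log10 luxr0) / (2m-1)
    log_K1 = (m * params.log10_k1 + (m - 1.0) * log_luxr0) / (2.0 * m - 1.0)
    log_K2 = (n * params.log10_k2 + (n - 1.0) * log_luxr0) / (2.0 * n - 1.0)
    return AbsoluteParams(
        K1=10.0**log_K1,
        K2=10.0**log_K2,
        KA=params.kA * luxr0,
        KB=params.kB * luxr0,
        luxr0=luxr0,
        fragile=fragile,
    )


def absolute_to_scaled(abs_params: AbsoluteParams, m: float, n: float) -> KineticParams:
    """Exact inverse of :func:`scaled_to_absolute` at the same Hill exponents."""
    if m <= 0 or n <= 0:
        raise ValueError("Hill coefficients must be positive")
    _check_exponent(m, "m")
    _check_exponent(n, "n")
    log_luxr0 = math.log10(abs_params.luxr0)
    log_k1 = ((2.0 * m - 1.0) * math.log10(abs_params.K1) - (m - 1.0) * log_luxr0) / m
    log_k2 = ((2.0 * n - 1.0) * math.log10(abs_params.K2) - (n - 1.0) * log_luxr0) / n
    return KineticParams(
        log10_k1=log_k1,
        m=m,
        log10_k2=log_k2,
        n=n,
        log10_kA=math.log10(abs_params.KA / abs_params.luxr0),
        log10_kB=math.log10(abs_params.KB / abs_params.luxr0),
    )
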