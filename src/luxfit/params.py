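"""Parameter containers for the two-signal LuxR activation model.

The model describes a LuxR variant that binds either of two acyl-homoserine
lactones (C8-HSL or 3OC6-HSL), forming homomultimeric complexes that occupy
the lux-box operator and drive luminescence.  Six interaction parameters
describe one LuxR variant:

* ``log10_k1``, ``m`` — scaled dissociation constant (nM) and Hill
  coefficient for the LuxR/C8-HSL complex,
* ``log10_k2``, ``n`` — likewise for the LuxR/3OC6-HSL complex,
* ``log10_kA``, ``log10_kB`` — dimensionless scaled lux-box dissociation
  constants of the two complexes (K_A/[LuxR0], K_B/[LuxR0]).

Dissociation constants are carried in log10 because fitted values span many
decades.  Two more parameters map lux-box occupancy P to luminescence via
sqrt(L) = a0 + a1*P (luciferase is a dimer, so light goes as the square of
transcriptional activity).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields

import numpy as np

__all__ = [
    "KineticParams",
    "ScaleParams",
    "SearchBounds",
    "PARAM_NAMES",
    "DEFAULT_BOUNDS",
]

#: canonical coordinate order of the 6-dimensional fit space
PARAM_NAMES = ("log10_k1", "m", "log10_k2", "n", "log10_kA", "log10_kB")


@dataclass(frozen=True)
class KineticParams:
    """Six interaction parameters of one LuxR variant.

    Hill coefficients must be positive; all fields must be finite.
    """

    log10_k1: float
    m: float
    log10_k2: float
    n: float
    log10_kA: float
    log10_kB: float

    def __post_init__(self) -> None:
        vals = self.to_array()
        if not np.all(np.isfinite(vals)):
            raise ValueError(f"non-finite kinetic parameter in {vals}")
        if self.m <= 0 or self.n <= 0:
            raise ValueError(
                f"Hill coefficients must be positive (m={self.m}, n={self.n})"
            )

    # linear-space accessors
    @property
    def k1(self) -> float:
        return 10.0 ** self.log10_k1

    @property
    def k2(self) -> float:
        return 10.0 ** self.log10_k2

    @property
    def kA(self) -> float:
        return 10.0 ** self.log10_kA

    @property
    def kB(self) -> float:
        return 10.0 ** self.log10_kB

    def to_array(self) -> np.ndarray:
        """Coordinates in the canonical order ``PARAM_NAMES``."""
        return np.array([getattr(self, f.name) for f in fields(self)], dtype=float)

    @classmethod
    def from_array(cls, x: np.ndarray) -> "KineticParams":
        x = np.asarray(x, dtype=float)
        if x.shape != (6,):
            raise ValueError(f"expected 6 coordinates, got shape {x.shape}")
        return cls(*x)

    def swapped(self) -> "KineticParams":
        """Exchange the roles of the two signals: (k1,m,kA) <-> (k2,n,kB)."""
        return KineticParams(
            log10_k1=self.log10_k2,
            m=self.n,
            log10_k2=self.log10_k1,
            n=self.m,
            log10_kA=self.log10_kB,
            log10_kB=self.log10_kA,
        )


@dataclass(frozen=True)
class ScaleParams:
    """Affine map from occupancy to sqrt-luminescence: sqrt(L) = a0 + a1*P."""

    a0: float
    a1: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.a0) and math.isfinite(self.a1)):
            raise ValueError(f"non-finite scale parameters ({self.a0}, {self.a1})")


@dataclass(frozen=True)
class SearchBounds:
    """Per-coordinate box for the global random seed search.

    Coordinates follow ``PARAM_NAMES``: log10 for the four dissociation
    constants, linear for the Hill coefficients m and n.
    """

    low: tuple = field(default=(-6.0, 0.05, -6.0, 0.05, -6.0, -6.0))
    high: tuple = field(default=(8.0, 4.0, 8.0, 4.0, 16.0, 16.0))

    def __post_init__(self) -> None:
        lo, hi = np.asarray(self.low, float), np.asarray(self.high, float)
        if lo.shape != (6,) or hi.shape != (6,):
            raise ValueError("bounds must have six coordinates each")
        if not np.all(lo < hi):
            raise ValueError("every low bound must be below its high bound")
        if lo[1] <= 0 or lo[3] <= 0:
            raise ValueError("Hill-coefficient bounds must be strictly positive")

    def as_arrays(self) -> tuple:
        return np.asarray(self.low, float), np.asarray(self.high, float)


#: default search box: envelope of published fit ranges with margin
DEFAULT_BOUNDS = SearchBounds()
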