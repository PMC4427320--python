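"""Synthetic well-plate generator and parameter-recovery harness.

Simulated plates have the statistical structure the fitting assumes: a
deterministic luminescence surface from the equilibrium model on the
standard two-fold-style dilution design (0, 12.5, 25, 100, 400, 800, 1600,
3200 nM on both axes), corrupted by multiplicative lognormal noise with
mean one.  The noise is proportional by construction, matching the use of a
log-scale loss; it does not emulate plate-reader detector floors, carryover
between wells, or growth (OD) variation — specific luminescence is drawn
directly.

Four presets carry published median parameter estimates for the LuxR
variants studied with this assay (wild-type MJ1 and ES114, and the
engineered variants A and B), with the typical scale a0=10, a1=550.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .equilibrium import response_surface
from .fitting import (
    FitOptions,
    ensemble_fit,
    global_seed_search,
    summarize,
)
from .params import DEFAULT_BOUNDS, PARAM_NAMES, KineticParams, ScaleParams, SearchBounds
from .plateio import PlateGrid

__all__ = [
    "DEFAULT_SCALE",
    "STRAIN_PRESETS",
    "StrainPreset",
    "NoiseModel",
    "default_grid",
    "simulate_plate",
    "recovery_experiment",
]

DEFAULT_SCALE = ScaleParams(a0=10.0, a1=550.0)


@dataclass(frozen=True)
class StrainPreset:
    """A named LuxR variant: median kinetic parameters plus default scale."""

    name: str
    params: KineticParams
    scale: ScaleParams = DEFAULT_SCALE


# median ensemble-fit estimates per variant, order (log10k1, m, log10k2, n,
# log10kA, log10kB); kA/kB for MJ1 and ES114 reflect weak C8-HSL activation
STRAIN_PRESETS = {
    "MJ1": StrainPreset("MJ1", KineticParams(0.46, 0.27, 5.3, 1.51, 3.2, -4.5)),
    "ES114": StrainPreset("ES114", KineticParams(1.3, 0.61, 2.7, 1.3, 2.4, -1.7)),
    "A": StrainPreset("A", KineticParams(2.6, 1.23, 2.63, 1.15, 0.27, 0.41)),
    "B": StrainPreset("B", KineticParams(3.5, 1.6, 2.2, 0.34, -1.8, 5.3)),
}


@dataclass(frozen=True)
class NoiseModel:
    """Mean-one multiplicative lognormal well noise.

    ``cv`` is the coefficient of variation of the multiplier; cv=0
    reproduces the deterministic surface exactly.  With
    sigma^2 = ln(1 + cv^2) and mu = -sigma^2/2 the multiplier has mean
    exactly 1, so noise does not bias the surface.
    """

    cv: float = 0.15
    rng_seed: int | None = None

    def __post_init__(self) -> None:
        if self.cv < 0:
            raise ValueError("coefficient of variation must be >= 0")

    def multipliers(self, shape, rng=None) -> np.ndarray:
        if self.cv == 0:
            return np.ones(shape)
        rng = np.random.default_rng(self.rng_seed if rng is None else rng)
        sigma2 = np.log1p(self.cv**2)
        return rng.lognormal(mean=-sigma2 / 2, sigma=np.sqrt(sigma2), size=shape)


def default_grid():
    """The standard 8x8 concentration design (nM), identical on both axes."""
    levels = np.array([0.0, 12.5, 25.0, 100.0, 400.0, 800.0, 1600.0, 3200.0])
    return levels.copy(), levels.copy()


def simulate_plate(
    params: KineticParams,
    scale: ScaleParams = DEFAULT_SCALE,
    grid=None,
    noise: NoiseModel = NoiseModel(cv=0.0),
    rng=None,
    closure: str = "stoichiometric",
    meta: dict | None = None,
) -> PlateGrid:
    """One synthetic plate: model surface times iid lognormal multipliers."""
    c8, c6 = default_grid() if grid is None else (np.asarray(g, float) for g in grid)
    surface = response_surface(c8, c6, params, scale, closure=closure)
    L = surface * noise.multipliers(surface.shape, rng=rng)
    return PlateGrid(c8, c6, L, meta=dict(meta or {}))


@dataclass(frozen=True)
class RecoveryReport:
    """Truth vs ensemble estimate, per parameter, for one simulated strain."""

    preset: StrainPreset
    table: pd.DataFrame  # rows: parameters; truth, median, p20..p80, error, covered
    n_fits: int
    results: list = field(repr=False, default_factory=list)


def recovery_experiment(
    truth: StrainPreset,
    n_replicates: int = 3,
    noise: NoiseModel = NoiseModel(cv=0.10),
    n_points: int = 3_000,
    n_keep: int = 10,
    bounds: SearchBounds = DEFAULT_BOUNDS,
    options: FitOptions | None = None,
    include_truth_seed: bool = False,
    rng=None,
) -> RecoveryReport:
    """Simulate replicate plates from a preset and re-infer its parameters.

    Runs the full pipeline — global seed search on the first replicate,
    ensemble of local fits over every (seed, replicate) pair, percentile
    summary — and reports, per parameter, the truth, the median estimate,
    the 20-80 percentile interval, the absolute error of the median, and
    whether the truth falls inside the interval.
    """
    if n_replicates < 1:
        raise ValueError("need at least one replicate plate")
    rng = np.random.default_rng(rng)
    plates = [
        simulate_plate(
            truth.params,
            truth.scale,
            noise=noise,
            rng=rng,
            meta={"dataset_id": f"{truth.name}-rep{i + 1}"},
        )
        for i in range(n_replicates)
    ]
    seeds = []
    if n_points > 0:
        seeds = global_seed_search(
            plates[0], n_points=n_points, n_keep=n_keep, bounds=bounds, rng=rng
        )
    if include_truth_seed or not seeds:
        seeds = [truth.params] + seeds
    results = ensemble_fit(plates, seeds, options)
    summary = summarize(results)
    rows = {}
    for name in PARAM_NAMES:
        true_val = getattr(truth.params, name)
        est = summary.table.loc[name]
        rows[name] = {
            "truth": true_val,
            "median": est["median"],
            "p20": est["p20"],
            "p25": est["p25"],
            "p75": est["p75"],
            "p80": est["p80"],
            "abs_error": abs(est["median"] - true_val),
            "covered": bool(est["p20"] <= true_val <= est["p80"]),
        }
    return RecoveryReport(
        preset=truth,
        table=pd.DataFrame.from_dict(rows, orient="index"),
        n_fits=len(results),
        results=results,
    )
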