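"""Ensemble nonlinear least-squares fitting of the activation model.

The loss for one candidate parameter set is computed in three steps that
mirror how plate data are actually compared to the model:

1. evaluate lux-box occupancy P over the plate's concentration grid;
2. find the scale (a0, a1) by *linear* least squares of sqrt(L_data) on P
   (the scale is never a free coordinate of the nonlinear search);
3. score the model on a log scale, sum((log10 L_data - log10 L_model)^2),
   because luminescence spans decades and errors are roughly proportional.

Inference is an ensemble: a broad uniform random search over the six
coordinates [log10 k1, m, log10 k2, n, log10 kA, log10 kB] keeps the
best-scoring points, each of which seeds a Nelder-Mead refinement against
each replicate plate separately.  Percentiles over the resulting fits are
the uncertainty statement; no curvature-based intervals are computed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .equilibrium import luminescence, occupancy_grid
from .params import DEFAULT_BOUNDS, PARAM_NAMES, KineticParams, ScaleParams, SearchBounds
from .plateio import PlateGrid

__all__ = [
    "DegenerateFitError",
    "FitOptions",
    "FitResult",
    "EnsembleSummary",
    "fit_scale",
    "log_sse",
    "objective",
    "local_fit",
    "global_seed_search",
    "ensemble_fit",
    "summarize",
    "results_to_frame",
    "save_results",
    "load_results",
]

#: Hill coefficients at or below this are rejected inside the objective
MIN_HILL = 0.01


class DegenerateFitError(ValueError):
    """The scale fit is singular: occupancy does not vary across wells."""


@dataclass(frozen=True)
class FitOptions:
    """Nelder-Mead settings; defaults follow standard simplex practice."""

    xatol: float = 1e-6  # simplex spread tolerance
    fatol: float = 1e-6  # loss spread tolerance
    max_iter: int = 2000
    closure: str = "stoichiometric"


@dataclass(frozen=True)
class FitResult:
    """Outcome of one local optimization from one seed on one dataset."""

    params: KineticParams
    scale: ScaleParams
    loss: float
    converged: bool
    iterations: int
    seed_index: int = 0
    dataset_id: str = ""

    def to_dict(self) -> dict:
        d = {name: getattr(self.params, name) for name in PARAM_NAMES}
        d.update(
            a0=self.scale.a0,
            a1=self.scale.a1,
            loss=self.loss,
            converged=self.converged,
            iterations=self.iterations,
            seed_index=self.seed_index,
            dataset_id=self.dataset_id,
        )
        return d


@dataclass(frozen=True)
class EnsembleSummary:
    """Percentile digest (median, 20/25/75/80) of an ensemble of fits."""

    table: pd.DataFrame  # rows: parameters; columns: median, p20, p25, p75, p80
    n_fits: int

    @property
    def median_params(self) -> KineticParams:
        return KineticParams(*(self.table.loc[name, "median"] for name in PARAM_NAMES))

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index_label="parameter")


def _data_parts(data):
    """Accept a PlateGrid or a bare matrix; return (L, present-mask)."""
    if isinstance(data, PlateGrid):
        return data.L, data.mask
    L = np.asarray(data, dtype=float)
    return L, np.isfinite(L)


def fit_scale(P_matrix: np.ndarray, L_data) -> ScaleParams:
    """Linear least-squares alignment of a0 + a1*P to sqrt(L_data).

    Unconstrained ordinary least squares over the non-missing wells.  Raises
    :class:`DegenerateFitError` when P is constant across wells (singular
    normal equations) or fewer than two wells are available.
    """
    P = np.asarray(P_matrix, dtype=float)
    L, present = _data_parts(L_data)
    if P.shape != L.shape:
        raise ValueError(f"shape mismatch: P {P.shape} vs data {L.shape}")
    p = P[present]
    y = np.sqrt(L[present])
    if p.size < 2 or np.ptp(p) < 1e-12:
        raise DegenerateFitError("occupancy constant across wells; scale fit singular")
    X = np.column_stack([np.ones_like(p), p])
    (a0, a1), *_ = np.linalg.lstsq(X, y, rcond=None)
    return ScaleParams(a0=float(a0), a1=float(a1))


def log_sse(L_model, L_data) -> float:
    """Sum of squared log10 differences over non-missing wells.

    Both matrices are floored at 1e-6 of the data maximum before logging so
    zero-luminescence wells stay in the fit without producing -inf.
    """
    Lm = np.asarray(L_model, dtype=float)
    Ld, present = _data_parts(L_data)
    if Lm.shape != Ld.shape:
        raise ValueError(f"shape mismatch: model {Lm.shape} vs data {Ld.shape}")
    floor = 1e-6 * np.max(Ld[present])
    lm = np.log10(np.maximum(Lm[present], floor))
    ld = np.log10(np.maximum(Ld[present], floor))
    return float(np.sum((ld - lm) ** 2))


def objective(params, data: PlateGrid, closure: str = "stoichiometric"):
    """Loss of one kinetic parameter set on one plate, with its best scale.

    Returns ``(loss, ScaleParams)``; a degenerate scale fit or out-of-domain
    Hill coefficient yields ``(inf, None)`` so simplex searches simply move
    away from it.
    """
    if isinstance(params, KineticParams):
        kp = params
    else:
        x = np.asarray(params, dtype=float)
        if not np.all(np.isfinite(x)) or x[1] <= MIN_HILL or x[3] <= MIN_HILL:
            return np.inf, None
        kp = KineticParams.from_array(x)
    try:
        P = occupancy_grid(data.c8_levels, data.c6_levels, kp, closure=closure)
        if not np.all(np.isfinite(P)):
            return np.inf, None
        scale = fit_scale(P, data)
    except DegenerateFitError:
        return np.inf, None
    return log_sse(luminescence(P, scale), data), scale


def local_fit(
    seed: KineticParams,
    data: PlateGrid,
    options: FitOptions | None = None,
    seed_index: int = 0,
    dataset_id: str = "",
) -> FitResult:
    """Nelder-Mead refinement of the six coordinates from one seed.

    The returned loss never exceeds the seed's own objective (the simplex
    only ever replaces points with better ones and the best vertex is
    returned).  Hitting the iteration cap is reported via ``converged``.
    """
    opts = options or FitOptions()
    seed_loss, _ = objective(seed, data, closure=opts.closure)
    if not np.isfinite(seed_loss):
        raise ValueError("objective is not finite at the seed")
    res = minimize(
        lambda x: objective(x, data, closure=opts.closure)[0],
        seed.to_array(),
        method="Nelder-Mead",
        options={
            "xatol": opts.xatol,
            "fatol": opts.fatol,
            "maxiter": opts.max_iter,
            "maxfev": 4 * opts.max_iter,
        },
    )
    best = KineticParams.from_array(res.x)
    loss, scale = objective(best, data, closure=opts.closure)
    if not np.isfinite(loss) or loss > seed_loss:  # descent guarantee
        best, loss = seed, seed_loss
        _, scale = objective(seed, data, closure=opts.closure)
    return FitResult(
        params=best,
        scale=scale,
        loss=loss,
        converged=bool(res.success),
        iterations=int(res.nit),
        seed_index=seed_index,
        dataset_id=dataset_id,
    )


def global_seed_search(
    data: PlateGrid,
    n_points: int = 30_000,
    n_keep: int = 50,
    bounds: SearchBounds = DEFAULT_BOUNDS,
    rng=None,
    closure: str = "stoichiometric",
) -> list:
    """Uniform random search of the six-coordinate box; keep the best points.

    Sampling is uniform in the listed coordinates (log10 for the four
    dissociation constants, linear for m and n).  Returns ``n_keep``
    :class:`KineticParams` sorted by ascending objective on ``data``.
    """
    if n_keep > n_points:
        raise ValueError(f"n_keep={n_keep} exceeds n_points={n_points}")
    rng = np.random.default_rng(rng)
    lo, hi = bounds.as_arrays()
    draws = rng.uniform(lo, hi, size=(n_points, 6))
    losses = np.array([objective(x, data, closure=closure)[0] for x in draws])
    order = np.argsort(losses, kind="stable")[:n_keep]
    return [KineticParams.from_array(draws[i]) for i in order]


def ensemble_fit(
    datasets,
    seeds,
    options: FitOptions | None = None,
) -> list:
    """Run a local fit for every (seed, replicate dataset) pair.

    Replicate plates are always fit separately, never averaged; each result
    carries its seed index and dataset label.
    """
    datasets = list(datasets)
    seeds = list(seeds)
    if not datasets or not seeds:
        raise ValueError("need at least one dataset and one seed")
    results = []
    for d_idx, data in enumerate(datasets):
        ds_id = str(data.meta.get("dataset_id", d_idx))
        for s_idx, seed in enumerate(seeds):
            results.append(
                local_fit(seed, data, options, seed_index=s_idx, dataset_id=ds_id)
            )
    return results


_SUMMARY_COLS = ("median", "p20", "p25", "p75", "p80")
_SUMMARY_Q = (0.50, 0.20, 0.25, 0.75, 0.80)


def summarize(results) -> EnsembleSummary:
    """Median and 20/25/75/80 percentiles of every parameter over the fits.

    Quantiles use linear interpolation between order statistics.
    """
    results = list(results)
    if not results:
        raise ValueError("cannot summarize an empty ensemble")
    frame = results_to_frame(results)
    rows = {}
    for name in list(PARAM_NAMES) + ["a0", "a1", "loss"]:
        q = np.quantile(frame[name].to_numpy(), _SUMMARY_Q, method="linear")
        rows[name] = dict(zip(_SUMMARY_COLS, q))
    table = pd.DataFrame.from_dict(rows, orient="index")[list(_SUMMARY_COLS)]
    return EnsembleSummary(table=table, n_fits=len(results))


def results_to_frame(results) -> pd.DataFrame:
    """Flat table of fit results, one row per optimization."""
    return pd.DataFrame([r.to_dict() for r in results])


def save_results(results, path) -> None:
    """Write an ensemble as CSV (.csv) or JSON (anything else)."""
    path = Path(path)
    if path.suffix == ".csv":
        results_to_frame(results).to_csv(path, index=False)
    else:
        path.write_text(json.dumps([r.to_dict() for r in results], indent=1))


def load_results(path) -> list:
    """Inverse of :func:`save_results`."""
    path = Path(path)
    if path.suffix == ".csv":
        records = pd.read_csv(path).to_dict("records")
    else:
        records = json.loads(path.read_text())
    out = []
    for rec in records:
        out.append(
            FitResult(
                params=KineticParams(*(float(rec[n]) for n in PARAM_NAMES)),
                scale=ScaleParams(a0=float(rec["a0"]), a1=float(rec["a1"])),
                loss=float(rec["loss"]),
                converged=bool(rec["converged"]),
                iterations=int(rec["iterations"]),
                seed_index=int(rec["seed_index"]),
                dataset_id=str(rec["dataset_id"]),
            )
        )
    return out
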