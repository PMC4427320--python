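"""Model/Results front end for ensemble fitting of plate data.

:class:`LuxRActivationModel` is constructed from one or more replicate
plates of a single LuxR variant; ``fit()`` runs the full two-stage
procedure (global random seed search, then a Nelder-Mead refinement of
every retained seed against every replicate) and returns
:class:`EnsembleFitResults` holding the individual fits, their percentile
summary, predictions and unit conversions.

    >>> model = LuxRActivationModel(plates, strain="A")
    >>> res = model.fit(n_points=3000, n_keep=10, seed=1)
    >>> print(res.summary())
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from . import fitting
from .equilibrium import response_surface
from .fitting import FitOptions, FitResult
from .params import DEFAULT_BOUNDS, PARAM_NAMES, KineticParams, ScaleParams, SearchBounds
from .plateio import PlateGrid, read_plate
from .units import DEFAULT_LUXR0, scaled_to_absolute

__all__ = ["LuxRActivationModel", "EnsembleFitResults"]


class LuxRActivationModel:
    """Competitive two-signal activation model bound to replicate plates.

    Parameters
    ----------
    plates : PlateGrid or sequence of PlateGrid
        Replicate luminescence plates of one strain; each replicate is fit
        separately, never averaged.
    bounds : SearchBounds
        Box for the global random seed search.
    closure : {"stoichiometric", "unweighted"}
        LuxR conservation closure (complexes weighted by their Hill
        stoichiometry, or counted once each).
    strain : str
        Label carried into results and summaries.
    """

    def __init__(
        self,
        plates,
        bounds: SearchBounds = DEFAULT_BOUNDS,
        closure: str = "stoichiometric",
        strain: str = "",
    ) -> None:
        if isinstance(plates, PlateGrid):
            plates = [plates]
        self.plates = list(plates)
        if not self.plates:
            raise ValueError("need at least one plate")
        for i, p in enumerate(self.plates):
            p.meta.setdefault("dataset_id", str(i))
        self.bounds = bounds
        self.closure = closure
        self.strain = strain

    @classmethod
    def from_csv(cls, paths, **kwargs) -> "LuxRActivationModel":
        """Build a model from plate CSV files (matrix or long dialect)."""
        if isinstance(paths, (str, bytes)) or hasattr(paths, "__fspath__"):
            paths = [paths]
        return cls([read_plate(p) for p in paths], **kwargs)

    def loss(self, params: KineticParams, dataset: int = 0) -> float:
        """Objective (log-scale SSE, scale profiled out) on one replicate."""
        return fitting.objective(params, self.plates[dataset], closure=self.closure)[0]

    def fit(
        self,
        n_points: int = 30_000,
        n_keep: int = 50,
        seed=None,
        options: FitOptions | None = None,
        search_dataset: int = 0,
        seeds=None,
    ) -> "EnsembleFitResults":
        """Run the ensemble fit.

        The random search is run once, on ``plates[search_dataset]``; its
        ``n_keep`` best points seed local fits against every replicate
        (``n_keep * len(plates)`` optimizations in total).  Pass ``seeds``
        to skip the search and refine explicit starting points instead.
        ``seed`` controls all randomness.
        """
        opts = options or FitOptions(closure=self.closure)
        if seeds is None:
            seeds = fitting.global_seed_search(
                self.plates[search_dataset],
                n_points=n_points,
                n_keep=n_keep,
                bounds=self.bounds,
                rng=seed,
                closure=self.closure,
            )
        results = fitting.ensemble_fit(self.plates, seeds, opts)
        return EnsembleFitResults(self, results)


class EnsembleFitResults:
    """Ensemble of local fits with percentile-based uncertainty.

    Attributes
    ----------
    results : list of FitResult
        Every (seed, replicate) optimization outcome.
    median_params : KineticParams
        Per-parameter medians over the ensemble (the headline estimate).
    percentiles : pandas.DataFrame
        median/p20/p25/p75/p80 per parameter, plus the scale and the loss.
    """

    def __init__(self, model: LuxRActivationModel, results) -> None:
        self.model = model
        self.results = list(results)
        self._summary = fitting.summarize(self.results)

    # -- estimates ---------------------------------------------------------
    @property
    def percentiles(self) -> pd.DataFrame:
        return self._summary.table

    @property
    def median_params(self) -> KineticParams:
        return self._summary.median_params

    @property
    def median_scale(self) -> ScaleParams:
        t = self._summary.table
        return ScaleParams(a0=t.loc["a0", "median"], a1=t.loc["a1", "median"])

    @property
    def best(self) -> FitResult:
        return min(self.results, key=lambda r: r.loss)

    @property
    def n_fits(self) -> int:
        return len(self.results)

    # -- diagnostics and output -------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        return fitting.results_to_frame(self.results)

    def save(self, path) -> None:
        fitting.save_results(self.results, path)

    def predict(self, c8_levels=None, c6_levels=None, params=None, scale=None) -> np.ndarray:
        """Model luminescence surface, by default at the median estimate
        on the first plate's concentration grid."""
        plate = self.model.plates[0]
        return response_surface(
            plate.c8_levels if c8_levels is None else c8_levels,
            plate.c6_levels if c6_levels is None else c6_levels,
            params or self.median_params,
            scale or self.median_scale,
            closure=self.model.closure,
        )

    def to_absolute(self, luxr0: float = DEFAULT_LUXR0) -> pd.DataFrame:
        """Absolute dissociation constants (nM) at an assumed total LuxR.

        Each fit in the ensemble is converted separately and the table
        reports median and 20-80 percentile of the absolute constants;
        fits whose Hill coefficient sits near the singular value 1/2 (where
        the complex constant is undetermined) are dropped from K1/K2.
        """
        rows = {k: [] for k in ("K1", "K2", "KA", "KB")}
        for r in self.results:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                try:
                    ap = scaled_to_absolute(r.params, luxr0)
                except ValueError:
                    continue
            for k in rows:
                v = getattr(ap, k)
                if np.isfinite(v) and not (ap.fragile and k in ("K1", "K2")):
                    rows[k].append(v)
        out = {}
        for k, vals in rows.items():
            q = np.quantile(vals, [0.5, 0.2, 0.8]) if vals else [np.nan] * 3
            out[k] = dict(zip(("median", "p20", "p80"), q))
        df = pd.DataFrame.from_dict(out, orient="index")
        df.attrs["luxr0_nM"] = luxr0
        return df

    def summary(self) -> str:
        """Human-readable report of the ensemble estimates."""
        t = self.percentiles
        n_conv = sum(r.converged for r in self.results)
        lines = [
            "Competitive two-HSL LuxR activation model — ensemble fit",
            "=" * 60,
            f"strain: {self.model.strain or '(unlabeled)'}    closure: {self.model.closure}",
            f"replicate plates: {len(self.model.plates)}    fits: {self.n_fits}"
            f"    converged: {n_conv}",
            f"median loss (log10-SSE): {t.loc['loss', 'median']:.4g}"
            f"    best: {self.best.loss:.4g}",
            "-" * 60,
            f"{'parameter':<12}{'median':>10}{'p20':>10}{'p80':>10}",
        ]
        for name in list(PARAM_NAMES) + ["a0", "a1"]:
            row = t.loc[name]
            lines.append(
                f"{name:<12}{row['median']:>10.3g}{row['p20']:>10.3g}{row['p80']:>10.3g}"
            )
        lines.append("-" * 60)
        lines.append(
            "k1, k2 in nM; kA, kB scaled to total LuxR; uncertainty is the "
            "20-80 percentile\nspan of the fit ensemble, not a confidence interval."
        )
        return "\n".join(lines)

    def plot_surfaces(self, plate_index: int = 0):
        """Side-by-side log-scale data and model surfaces (matplotlib)."""
        import matplotlib.pyplot as plt

        plate = self.model.plates[plate_index]
        pred = self.predict(plate.c8_levels, plate.c6_levels)
        fig, axes = plt.subplots(1, 2, figsize=(9, 4), sharey=True)
        for ax, Z, title in ((axes[0], plate.L, "data"), (axes[1], pred, "model")):
            im = ax.imshow(np.log10(np.maximum(Z, 1e-6)), origin="lower", aspect="auto")
            ax.set_title(f"{title} (log10 L)")
            ax.set_xlabel("3OC6-HSL level index")
            fig.colorbar(im, ax=ax)
        axes[0].set_ylabel("C8-HSL level index")
        fig.tight_layout()
        return fig
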