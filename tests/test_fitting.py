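"""Scale fit, log-scale loss, objective composition, local/ensemble fits."""

import dataclasses

import numpy as np
import pytest

import luxfit as lf
from luxfit.fitting import (
    DegenerateFitError,
    FitOptions,
    load_results,
    results_to_frame,
    save_results,
)


class TestFitScale:
    def test_noiseless_recovery(self):
        P = np.array([[0.0, 0.1], [0.3, 0.8]])
        L = (10 + 550 * P) ** 2
        sc = lf.fit_scale(P, L)
        assert sc.a0 == pytest.approx(10.0, rel=1e-9)
        assert sc.a1 == pytest.approx(550.0, rel=1e-9)

    def test_two_point_interpolation(self):
        # exact line through (P, sqrt L) = (0, 10) and (1, 20)
        sc = lf.fit_scale(np.array([[0.0, 1.0]]), np.array([[100.0, 400.0]]))
        assert sc.a0 == pytest.approx(10.0)
        assert sc.a1 == pytest.approx(10.0)

    def test_constant_occupancy_is_degenerate(self):
        with pytest.raises(DegenerateFitError):
            lf.fit_scale(np.full((2, 2), 0.3), np.ones((2, 2)))

    def test_missing_wells_excluded(self):
        P = np.array([[0.0, 0.5], [1.0, 0.25]])
        L = (10 + 550 * P) ** 2
        L[1, 1] = np.nan  # corrupt a masked well; fit must ignore it
        sc = lf.fit_scale(P, L)
        assert (sc.a0, sc.a1) == (pytest.approx(10.0), pytest.approx(550.0))


class TestLogSse:
    def test_equal_is_zero(self):
        L = np.array([[10.0, 100.0]])
        assert lf.log_sse(L, L) == 0.0

    def test_single_decade(self):
        assert lf.log_sse(np.array([[100.0]]), np.array([[1000.0]])) == pytest.approx(1.0)

    def test_log_ratio_symmetry(self):
        # ratios 10 and 0.1 contribute one squared decade each
        Ld = np.array([[1000.0, 100.0]])
        Lm = np.array([[100.0, 1000.0]])
        assert lf.log_sse(Lm, Ld) == pytest.approx(2.0)

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            lf.log_sse(np.ones((2, 2)), np.ones((2, 3)))


def _ols_line(x, y):
    # independent two-parameter OLS: slope = cov/var, intercept from means
    b = np.cov(x, y, bias=True)[0, 1] / np.var(x)
    return y.mean() - b * x.mean(), b


class TestObjective:
    def test_zero_at_generating_parameters(self, preset_a, noiseless_plate_a):
        loss, scale = lf.objective(preset_a.params, noiseless_plate_a)
        assert loss <= 1e-12
        assert scale.a0 == pytest.approx(10.0, rel=1e-6)
        assert scale.a1 == pytest.approx(550.0, rel=1e-6)

    def test_perturbation_increases_loss(self, preset_a, noiseless_plate_a):
        for field, delta in [("m", 0.2), ("log10_k1", 0.5), ("log10_kA", 0.5)]:
            shifted = dataclasses.replace(
                preset_a.params, **{field: getattr(preset_a.params, field) + delta}
            )
            assert lf.objective(shifted, noiseless_plate_a)[0] > 0

    def test_hand_composed_pipeline(self):
        """Objective equals scale-fit + log-SSE composed with independent
        closed forms on a 2x2 grid built from worked occupancy values."""
        p = lf.KineticParams(2, 1, 2, 1, 1, 1)  # k1=k2=100, kA=kB=10
        levels = np.array([0.0, 100.0])
        # closed-form occupancies: P(0,0)=0, single-signal 0.05/1.05,
        # mixed well r=1/3 so PA=PB=1/30 and P=2/32
        P = np.array([[0.0, 0.05 / 1.05], [0.05 / 1.05, 2.0 / 32.0]])
        L_data = np.array([[100.0, 900.0], [1600.0, 2500.0]])
        a0, a1 = _ols_line(P.ravel(), np.sqrt(L_data).ravel())
        L_model = (a0 + a1 * P) ** 2
        expected = float(np.sum((np.log10(L_data) - np.log10(L_model)) ** 2))
        grid = lf.PlateGrid(levels, levels, L_data)
        loss, scale = lf.objective(p, grid)
        assert loss == pytest.approx(expected, rel=1e-9)
        assert (scale.a0, scale.a1) == (pytest.approx(a0), pytest.approx(a1))

    def test_invariant_under_signal_swap_and_transpose(self, preset_a, rng):
        plate = lf.simulate_plate(
            preset_a.params, noise=lf.NoiseModel(cv=0.1), rng=rng
        )
        loss, _ = lf.objective(preset_a.params, plate)
        loss_sw, _ = lf.objective(preset_a.params.swapped(), plate.transposed())
        assert loss_sw == pytest.approx(loss, rel=1e-10)


class TestLocalFit:
    def test_seed_at_truth_stays(self, preset_a, noiseless_plate_a):
        fr = lf.local_fit(preset_a.params, noiseless_plate_a)
        assert fr.loss <= 1e-12

    def test_recovers_shifted_k1_noiseless(self, preset_a, noiseless_plate_a):
        seed = dataclasses.replace(
            preset_a.params, log10_k1=preset_a.params.log10_k1 + 0.5
        )
        fr = lf.local_fit(seed, noiseless_plate_a)
        assert fr.params.log10_k1 == pytest.approx(preset_a.params.log10_k1, abs=0.05)
        assert fr.loss < 1e-4

    def test_iteration_cap_flags_nonconvergence(self, preset_a, noiseless_plate_a):
        seed = dataclasses.replace(
            preset_a.params, log10_k1=preset_a.params.log10_k1 + 1.0
        )
        fr = lf.local_fit(seed, noiseless_plate_a, FitOptions(max_iter=1))
        assert not fr.converged
        assert fr.iterations <= 1

    def test_descent_from_random_seeds(self, preset_a, rng):
        plate = lf.simulate_plate(
            preset_a.params, noise=lf.NoiseModel(cv=0.1), rng=rng
        )
        seeds = lf.global_seed_search(plate, n_points=200, n_keep=2, rng=rng)
        for seed in seeds:
            seed_loss, _ = lf.objective(seed, plate)
            fr = lf.local_fit(seed, plate, FitOptions(max_iter=300))
            assert fr.loss <= seed_loss


class TestGlobalSeedSearch:
    def test_deterministic_given_seed(self, noiseless_plate_a):
        a = lf.global_seed_search(noiseless_plate_a, n_points=100, n_keep=5, rng=7)
        b = lf.global_seed_search(noiseless_plate_a, n_points=100, n_keep=5, rng=7)
        assert a == b

    def test_keep_all_returns_sorted(self, noiseless_plate_a):
        seeds = lf.global_seed_search(noiseless_plate_a, n_points=40, n_keep=40, rng=3)
        losses = [lf.objective(s, noiseless_plate_a)[0] for s in seeds]
        finite = [l for l in losses if np.isfinite(l)]
        assert len(seeds) == 40
        assert finite == sorted(finite)

    def test_keep_one_is_argmin(self, noiseless_plate_a):
        rng_seed = 11
        best = lf.global_seed_search(
            noiseless_plate_a, n_points=60, n_keep=1, rng=rng_seed
        )[0]
        everything = lf.global_seed_search(
            noiseless_plate_a, n_points=60, n_keep=60, rng=rng_seed
        )
        assert best == everything[0]

    def test_keep_more_than_points_rejected(self, noiseless_plate_a):
        with pytest.raises(ValueError):
            lf.global_seed_search(noiseless_plate_a, n_points=5, n_keep=6)

    def test_samples_respect_bounds(self, noiseless_plate_a):
        lo, hi = lf.DEFAULT_BOUNDS.as_arrays()
        for s in lf.global_seed_search(noiseless_plate_a, n_points=50, n_keep=50, rng=5):
            x = s.to_array()
            assert np.all(x >= lo) and np.all(x <= hi)


class TestEnsemble:
    def test_label_bookkeeping_2x2(self, preset_a, noiseless_plate_a):
        plates = [noiseless_plate_a, noiseless_plate_a.transposed().transposed()]
        for i, p in enumerate(plates):
            p.meta["dataset_id"] = f"d{i}"
        seeds = [preset_a.params, dataclasses.replace(preset_a.params, m=1.3)]
        res = lf.ensemble_fit(plates, seeds, FitOptions(max_iter=1))
        assert len(res) == 4
        assert len({(r.seed_index, r.dataset_id) for r in res}) == 4

    def test_empty_inputs_rejected(self, preset_a, noiseless_plate_a):
        with pytest.raises(ValueError):
            lf.ensemble_fit([], [preset_a.params])
        with pytest.raises(ValueError):
            lf.ensemble_fit([noiseless_plate_a], [])


def _fake_results(values):
    return [
        lf.FitResult(
            params=lf.KineticParams(v, v, v, v, v, v),
            scale=lf.ScaleParams(v, v),
            loss=float(v),
            converged=True,
            iterations=1,
            seed_index=i,
            dataset_id="d",
        )
        for i, v in enumerate(values)
    ]


class TestSummarize:
    def test_identical_results_collapse(self):
        s = lf.summarize(_fake_results([2.0] * 7))
        assert np.allclose(s.table.loc["m"], 2.0)
        assert s.n_fits == 7

    def test_median_of_five(self):
        s = lf.summarize(_fake_results([1, 2, 3, 4, 5]))
        assert s.table.loc["m", "median"] == 3

    def test_linear_interpolation_quantiles(self):
        s = lf.summarize(_fake_results(np.arange(1, 101, dtype=float)))
        assert s.table.loc["m", "p20"] == pytest.approx(20.8)
        assert s.table.loc["m", "p80"] == pytest.approx(80.2)

    def test_quantile_ordering(self, rng):
        s = lf.summarize(_fake_results(rng.uniform(0.1, 5, size=31)))
        for name in ("log10_k1", "m", "log10_kA"):
            row = s.table.loc[name]
            assert row["p20"] <= row["p25"] <= row["median"] <= row["p75"] <= row["p80"]

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            lf.summarize([])


def test_results_roundtrip_csv_and_json(tmp_path, rng):
    results = _fake_results(rng.uniform(0.2, 3, size=4))
    for name in ("fits.csv", "fits.json"):
        path = tmp_path / name
        save_results(results, path)
        back = load_results(path)
        assert len(back) == 4
        for a, b in zip(results, back):
            np.testing.assert_allclose(a.params.to_array(), b.params.to_array())
            assert a.dataset_id == b.dataset_id and a.seed_index == b.seed_index
    frame = results_to_frame(results)
    assert list(frame.columns[:6]) == list(lf.params.PARAM_NAMES)
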