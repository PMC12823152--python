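"""Spectrum fitting: NNLS recovery, noise decomposition, refinement, MC."""

import numpy as np
import pytest

from sedgrid import (
    CustomGridModel,
    FitError,
    GridAxisSpec,
    Scan,
    ScanSet,
    build_subgrid,
    simulate_mixture,
)

TRUTH_IDX = [7, 25, 43]
TRUTH_AMP = np.array([0.3, 0.4, 0.2])


@pytest.fixture(scope="module")
def small_grid(water):
    return build_subgrid(GridAxisSpec("s", 5, 50, 10),
                         GridAxisSpec("vbar", 0.96, 0.995, 6), 1.1, water)


@pytest.fixture(scope="module")
def clean_data(small_grid, geometry, omega, scan_times, water_spec):
    sols = [small_grid.solutes[i] for i in TRUTH_IDX]
    return simulate_mixture(sols, TRUTH_AMP, geometry, omega, scan_times,
                            buffer=water_spec, n_radial=220)


def _with_noise(data, sigma=0.0, ti=None, ri=None, seed=0):
    rng = np.random.default_rng(seed)
    Y = data.signal_matrix().copy()
    if sigma:
        Y += rng.normal(0, sigma, Y.shape)
    if ti is not None:
        Y += ti[None, :]
    if ri is not None:
        Y += ri[:, None]
    scans = [Scan(t=s.t, omega=s.omega, T=s.T, signal=y)
             for s, y in zip(data.scans, Y)]
    return ScanSet(geometry=data.geometry, buffer=data.buffer,
                   radius=data.radius, scans=scans)


@pytest.fixture(scope="module")
def noisy_data(clean_data):
    return _with_noise(clean_data, sigma=0.005, seed=1)


@pytest.fixture(scope="module")
def noisy_fit(noisy_data, small_grid):
    return CustomGridModel(noisy_data, small_grid).fit()


class TestExactRecovery:
    def test_grid_point_mixture_recovered_to_machine_precision(
            self, clean_data, small_grid):
        res = CustomGridModel(clean_data, small_grid).fit()
        assert res.rmsd < 1e-8
        amps = res.amplitudes
        for i, a in zip(TRUTH_IDX, TRUTH_AMP):
            assert amps[i] == pytest.approx(a, rel=1e-6)
        off = np.delete(amps, TRUTH_IDX)
        assert np.abs(off).max() < 1e-9

    def test_total_signal_matches_loading(self, clean_data, small_grid):
        res = CustomGridModel(clean_data, small_grid).fit()
        assert res.total_signal == pytest.approx(TRUTH_AMP.sum(), rel=0.02)


class TestNoisyFit:
    def test_rmsd_estimates_noise_sigma(self, noisy_fit):
        assert noisy_fit.rmsd == pytest.approx(0.005, rel=0.05)

    def test_residuals_pass_runs_randomness_check(self, noisy_fit):
        z = noisy_fit.runs_zscores()
        assert abs(z.mean()) < 1.0
        assert np.mean(np.abs(z) < 3) >= 0.9

    def test_grid_superset_never_increases_rmsd(
            self, noisy_data, small_grid, water):
        base = CustomGridModel(noisy_data, small_grid).fit().rmsd
        from sedgrid import combine_grids
        extra = build_subgrid(GridAxisSpec("s", 55, 80, 3),
                              GridAxisSpec("vbar", 0.96, 0.995, 4),
                              1.1, water)
        superset = combine_grids(small_grid, extra)
        assert CustomGridModel(noisy_data, superset).fit().rmsd <= base + 1e-12

    def test_summary_mentions_fit_quality(self, noisy_fit):
        s = noisy_fit.summary()
        assert "rmsd" in s and "vbar" in s


class TestIterativeRefinement:
    def test_single_partition_equals_direct_fit(self, noisy_data, small_grid):
        direct = CustomGridModel(noisy_data, small_grid).fit()
        it = CustomGridModel(noisy_data, small_grid).fit(
            method="iterative", n_partitions=1)
        assert it.rmsd == pytest.approx(direct.rmsd, rel=1e-9)

    def test_matches_full_grid_oracle_support(
            self, small_grid, geometry, omega, scan_times, water_spec):
        """With 4 partitions the refined support contains the grid points
        nearest both true solutes, as a direct full-grid fit does."""
        sols = [small_grid.solutes[i] for i in (13, 40)]
        data = simulate_mixture(sols, [0.5, 0.4], geometry, omega,
                                scan_times, buffer=water_spec, n_radial=220)
        full = CustomGridModel(data, small_grid).fit()
        it = CustomGridModel(data, small_grid).fit(method="iterative",
                                                   n_partitions=4)
        assert it.rmsd == pytest.approx(full.rmsd, abs=1e-10)
        support = set(it.fitted_indices[it.fitted_amplitudes > 1e-9])
        assert {13, 40} <= support

    def test_rmsd_monotone_across_refinement_steps(
            self, noisy_data, small_grid):
        res = CustomGridModel(noisy_data, small_grid).fit(
            method="iterative", n_partitions=4)
        hist = np.array(res.provenance["rmsd_history"])
        assert np.all(np.diff(hist) <= 1e-9)
        assert res.rmsd <= hist[0]


class TestNoiseDecomposition:
    def test_injected_ti_bump_recovered(self, clean_data, small_grid):
        r = clean_data.radius
        ti = 0.05 * np.exp(-0.5 * ((r - 6.5) / 0.05) ** 2)
        data = _with_noise(clean_data, sigma=0.003, ti=ti, seed=2)
        res = CustomGridModel(data, small_grid, fit_ti=True).fit()
        rms = np.sqrt(np.mean((res.ti_noise - ti) ** 2))
        assert rms / 0.05 < 0.02

    def test_injected_ri_offsets_recovered(self, clean_data, small_grid):
        rng = np.random.default_rng(3)
        ri = rng.normal(0, 0.02, len(clean_data.scans))
        ri -= ri.mean()
        data = _with_noise(clean_data, sigma=0.003, ri=ri, seed=4)
        res = CustomGridModel(data, small_grid, fit_ti=True,
                              fit_ri=True).fit()
        rms = np.sqrt(np.mean((res.ri_noise - ri) ** 2))
        assert rms / np.sqrt(np.mean(ri**2)) < 0.10
        assert res.ri_noise.mean() == pytest.approx(0.0, abs=1e-12)

    def test_noise_free_input_gives_null_noise_vectors(
            self, clean_data, small_grid):
        plain = CustomGridModel(clean_data, small_grid).fit()
        res = CustomGridModel(clean_data, small_grid, fit_ti=True,
                              fit_ri=True).fit()
        assert np.abs(res.ti_noise).max() < 1e-8
        assert np.abs(res.ri_noise).max() < 1e-8
        assert res.rmsd == pytest.approx(plain.rmsd, abs=1e-8)

    def test_ri_requires_three_scans(self, clean_data, small_grid):
        short = ScanSet(geometry=clean_data.geometry,
                        buffer=clean_data.buffer, radius=clean_data.radius,
                        scans=clean_data.scans[:2])
        with pytest.raises(FitError, match="scans"):
            CustomGridModel(short, small_grid, fit_ri=True)


class TestBoundaryRefinement:
    def test_meniscus_recovered_within_candidate_spacing(
            self, noisy_data, small_grid):
        res = CustomGridModel(noisy_data, small_grid).fit_boundary(
            meniscus_range=(5.87, 5.93), n_candidates=5)
        spacing = (5.93 - 5.87) / 4
        assert abs(res.meniscus - 5.9) <= spacing
        assert res.provenance["meniscus_bracketed"]

    def test_rmsd_minimized_at_true_position(self, clean_data, small_grid):
        res = CustomGridModel(clean_data, small_grid).fit_boundary(
            meniscus_range=(5.88, 5.92), n_candidates=5)
        rmsds = np.array(res.provenance["meniscus_rmsds"])
        cand = np.array(res.provenance["meniscus_candidates"])
        k = int(np.argmin(np.abs(cand - 5.9)))
        assert int(np.argmin(rmsds)) == k
        # unimodal: rmsd increases moving away from the optimum
        assert np.all(np.diff(rmsds[: k + 1]) <= 0)
        assert np.all(np.diff(rmsds[k:]) >= 0)


class TestMonteCarlo:
    def test_same_seed_is_bit_identical(self, noisy_fit):
        a = noisy_fit.monte_carlo(5, seed=42)
        b = noisy_fit.monte_carlo(5, seed=42)
        assert np.array_equal(a.amplitude_matrix(), b.amplitude_matrix())

    def test_weighted_s_unbiased_on_simulated_data(self, noisy_fit,
                                                   small_grid):
        ens = noisy_fit.monte_carlo(12, seed=7)
        mean_s, sd_s = ens.weighted_mean("s_sv")
        truth = float(
            TRUTH_AMP @ [small_grid.solutes[i].s_sv for i in TRUTH_IDX]
        ) / TRUTH_AMP.sum()
        assert abs(mean_s - truth) < max(2 * sd_s, 0.05 * abs(truth))

    def test_ensemble_spread_scales_with_noise(self, clean_data, small_grid):
        """Quadrupling the injected noise quadruples the ensemble sd of the
        signal-weighted mean s.  (Individual amplitudes of nearly collinear
        neighbouring grid solutes are not separately identifiable, so the
        scaling is asserted on this identifiable aggregate.)"""
        sds = []
        for sigma in (0.002, 0.008):
            data = _with_noise(clean_data, sigma=sigma, seed=5)
            res = CustomGridModel(data, small_grid).fit()
            ens = res.monte_carlo(8, seed=9)
            sds.append(ens.weighted_mean("s_sv")[1])
        assert sds[1] / sds[0] == pytest.approx(4.0, rel=0.5)

    def test_too_few_iterations_rejected(self, noisy_fit):
        with pytest.raises(FitError):
            noisy_fit.monte_carlo(1, seed=0)

    def test_model_roundtrips_to_dict(self, noisy_fit, tmp_path):
        import json

        p = tmp_path / "model.json"
        noisy_fit.save(p)
        d = json.loads(p.read_text())
        assert d["rmsd"] == pytest.approx(noisy_fit.rmsd)
        assert len(d["solutes"]) == int(
            (noisy_fit.fitted_amplitudes > 0).sum())
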