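"""Concentration-series route: no-intercept regression, mixture correction, peaks."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from glycospec.errors import CompositionError, GridAlignmentError
from glycospec.experimental import (
    ConcentrationSeries,
    SolutionComposition,
    correct_for_nonglycated,
    epsilon_solution_by_averaging,
    epsilon_solution_from_series,
    find_q_band_peaks,
    hba1c_fraction,
    level_fraction,
    run_experimental_pipeline,
)
from glycospec.spectra import Spectrum, SpectrumKind, WavelengthGrid, restrict_band
from glycospec.synthetic import (
    GaussianBand,
    BandModel,
    NoiseModel,
    gaussian_band_spectrum,
    simulate_level_dataset,
)


def abs_spec(values, lam=None):
    values = np.asarray(values, float)
    if lam is None:
        lam = 500.0 + 10.0 * np.arange(values.size)
    return Spectrum(np.asarray(lam, float), values, SpectrumKind.ABSORBANCE)


def eps_spec(values, lam=None):
    values = np.asarray(values, float)
    if lam is None:
        lam = 500.0 + 10.0 * np.arange(values.size)
    return Spectrum(np.asarray(lam, float), values, SpectrumKind.MOLAR_ABSORPTION)


def make_series(concentrations, spectra, f=0.5, d=1.0):
    return ConcentrationSeries(
        tuple(
            (SolutionComposition(c_total_mol_l=c, glycated_fraction=f, path_cm=d), s)
            for c, s in zip(concentrations, spectra)
        )
    )


class TestFractions:
    def test_fraction_is_simple_quotient(self):
        assert hba1c_fraction(0.5, 1.0) == 0.5
        assert hba1c_fraction(1.0, 1.0) == 1.0

    def test_level_fractions_computed_from_certified_concentrations(self):
        assert level_fraction("level1") == pytest.approx(0.228 / 9.43, rel=1e-15)
        assert level_fraction("level2") == pytest.approx(0.488 / 7.44, rel=1e-15)

    def test_excess_hba1c_rejected(self):
        with pytest.raises(CompositionError):
            hba1c_fraction(2.0, 1.0)

    def test_unknown_level(self):
        with pytest.raises(KeyError):
            level_fraction("level9")


class TestEpsilonFromSeries:
    def test_single_member_degenerates_to_a_over_cd(self):
        series = make_series([5e-5], [abs_spec([0.5, 0.5])])
        eps = epsilon_solution_from_series(series)
        np.testing.assert_allclose(eps.values, 10_000.0, rtol=1e-12)
        assert eps.kind is SpectrumKind.MOLAR_ABSORPTION

    def test_exact_series_recovers_slope_with_zero_residual(self):
        truth = np.array([30_000.0, 12_000.0])
        concs = [3e-5, 4e-5, 5e-5, 6e-5, 7e-5]
        series = make_series(concs, [abs_spec(truth * c) for c in concs])
        eps = epsilon_solution_from_series(series)
        np.testing.assert_allclose(eps.values, truth, rtol=1e-12)
        np.testing.assert_allclose(eps.dispersion, 0.0, atol=1e-12)

    def test_noisy_series_within_three_standard_errors(self):
        rng = np.random.default_rng(2024)
        truth = np.full(8, 20_000.0)
        concs = np.array([3e-5, 4e-5, 5e-5, 6e-5, 7e-5])
        sd = 0.005
        errs = []
        for _ in range(200):
            series = make_series(
                concs, [abs_spec(truth * c + rng.normal(0, sd, truth.size)) for c in concs]
            )
            errs.append(epsilon_solution_from_series(series).values - truth)
        rmse = np.sqrt(np.mean(np.square(errs), axis=0))
        analytic_se = sd / np.sqrt(np.sum(concs**2))
        assert np.all(rmse < 1.2 * analytic_se)  # rmse concentrates on the analytic se
        assert np.all(rmse > 0.8 * analytic_se)

    def test_averaging_estimator_agrees_on_exact_data(self):
        truth = np.array([30_000.0, 12_000.0])
        concs = [3e-5, 5e-5, 7e-5]
        series = make_series(concs, [abs_spec(truth * c) for c in concs])
        np.testing.assert_allclose(
            epsilon_solution_by_averaging(series).values, truth, rtol=1e-12
        )

    def test_repeated_concentrations_rejected(self):
        with pytest.raises(CompositionError):
            make_series([5e-5, 5e-5], [abs_spec([0.5, 0.5])] * 2)


class TestMixtureCorrection:
    def test_pure_hba1c_limit(self):
        eps_sol = eps_spec([100.0, 200.0])
        out = correct_for_nonglycated(eps_sol, eps_spec([50.0, 60.0]), f=1.0)
        np.testing.assert_array_equal(out.values, eps_sol.values)

    def test_zero_nonglycated_reference(self):
        out = correct_for_nonglycated(eps_spec([100.0, 200.0]), eps_spec([0.0, 0.0]), f=0.25)
        np.testing.assert_allclose(out.values, [400.0, 800.0], rtol=1e-15)

    @pytest.mark.parametrize("f", [0.228 / 9.43, 0.488 / 7.44, 0.5, 1.0])
    def test_algebraic_inverse_of_forward_mixture(self, f):
        eps_a = eps_spec([800_000.0, 500_000.0, 120_000.0])
        eps_n = eps_spec([13_000.0, 12_500.0, 4_000.0])
        eps_sol = eps_spec(f * eps_a.values + (1 - f) * eps_n.values)
        rec = correct_for_nonglycated(eps_sol, eps_n, f)
        np.testing.assert_allclose(rec.values, eps_a.values, rtol=1e-12)

    def test_fraction_bounds(self):
        with pytest.raises(CompositionError):
            correct_for_nonglycated(eps_spec([1.0, 1.0]), eps_spec([1.0, 1.0]), f=0.0)

    def test_grid_mismatch(self):
        with pytest.raises(GridAlignmentError):
            correct_for_nonglycated(
                eps_spec([1.0, 1.0]), eps_spec([1.0, 1.0], lam=[1.0, 2.0]), f=0.5
            )

    @settings(derandomize=True, max_examples=50)
    @given(
        lo=st.floats(min_value=0.01, max_value=0.9),
        step=st.floats(min_value=0.01, max_value=0.09),
    )
    def test_monotone_decreasing_in_f_when_solution_below_reference(self, lo, step):
        # d eps/df = -(eps_sol - eps_non)/f^2 > 0 iff eps_sol < eps_non
        eps_sol = eps_spec([100.0, 100.0])
        eps_non = eps_spec([300.0, 300.0])
        hi = lo + step
        out_lo = correct_for_nonglycated(eps_sol, eps_non, lo).values[0]
        out_hi = correct_for_nonglycated(eps_sol, eps_non, hi).values[0]
        assert out_hi > out_lo


class TestPeakFinding:
    def make_two_band_spectrum(self, scale=1.0):
        grid = WavelengthGrid(450.0, 700.0, 1.0)
        model = BandModel(
            bands=(GaussianBand(545.0, 10.0, 7.9e5 * scale),
                   GaussianBand(579.0, 11.0, 6.9e5 * scale))
        )
        return gaussian_band_spectrum(model, grid)

    def test_two_gaussians_found_at_centers(self):
        report = find_q_band_peaks(self.make_two_band_spectrum())
        assert report.wavelengths_nm == (545.0, 579.0)

    def test_scale_invariance(self):
        r1 = find_q_band_peaks(self.make_two_band_spectrum(1.0))
        r2 = find_q_band_peaks(self.make_two_band_spectrum(123.0))
        assert r1.wavelengths_nm == r2.wavelengths_nm

    def test_monotone_spectrum_reports_empty_with_warning(self):
        lam = np.arange(500.0, 601.0, 1.0)
        s = eps_spec(np.linspace(1.0, 2.0, lam.size), lam=lam)
        with pytest.warns(UserWarning, match="fewer"):
            report = find_q_band_peaks(s)
        assert len(report) == 0

    def test_single_gaussian_yields_one_peak(self):
        grid = WavelengthGrid(450.0, 700.0, 1.0)
        s = gaussian_band_spectrum(
            BandModel(bands=(GaussianBand(550.0, 12.0, 1e5),)), grid
        )
        with pytest.warns(UserWarning, match="fewer"):
            report = find_q_band_peaks(s, n_peaks=2)
        assert report.wavelengths_nm == (550.0,)

    def test_min_separation_suppresses_near_duplicates(self):
        lam = np.arange(500.0, 601.0, 1.0)
        v = np.exp(-((lam - 545.0) ** 2) / 50.0) + 0.9 * np.exp(-((lam - 549.0) ** 2) / 50.0)
        s = eps_spec(v, lam=lam)
        with pytest.warns(UserWarning, match="fewer"):
            report = find_q_band_peaks(s, n_peaks=2)
        # the 549 shoulder is within 10 nm of the 545 maximum: only one peak survives
        assert all(
            abs(a - b) >= 10.0
            for i, a in enumerate(report.wavelengths_nm)
            for b in report.wavelengths_nm[i + 1:]
        )


class TestExperimentalPipeline:
    @pytest.mark.parametrize("level, centers", [("level1", (545.0, 579.0)),
                                                ("level2", (544.0, 577.0))])
    def test_noiseless_recovery_and_peak_centers(self, level, centers):
        sim = simulate_level_dataset(level, noise=NoiseModel(0.0, 0), replicates=3)
        eps, peaks = run_experimental_pipeline(sim.replicate_series, sim.eps_non)
        truth = restrict_band(sim.eps_a1c, 450.0, 700.0)
        np.testing.assert_allclose(eps.values, truth.values, rtol=1e-9)
        assert peaks.wavelengths_nm == centers

    def test_unit_fraction_override_returns_solution_epsilon(self):
        sim = simulate_level_dataset("level1", noise=NoiseModel(0.0, 0), replicates=1)
        eps_f1, _ = run_experimental_pipeline(sim.replicate_series, sim.eps_non, f=1.0)
        f = sim.glycated_fraction
        eps_mix = f * sim.eps_a1c.values + (1 - f) * sim.eps_non.values
        truth = restrict_band(sim.eps_a1c.with_values(eps_mix), 450.0, 700.0)
        np.testing.assert_allclose(eps_f1.values, truth.values, rtol=1e-9)

    def test_noisy_recovery_peaks_within_two_nm(self):
        hits = 0
        for seed in range(20):
            sim = simulate_level_dataset(
                "level1", noise=NoiseModel(0.002, seed), replicates=3
            )
            _, peaks = run_experimental_pipeline(sim.replicate_series, sim.eps_non)
            if len(peaks) == 2 and abs(peaks.wavelengths_nm[0] - 545.0) <= 2.0 \
                    and abs(peaks.wavelengths_nm[1] - 579.0) <= 2.0:
                hits += 1
        assert hits >= 19
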