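"""Preprocessing chain: crop, despike, smooth, baseline, normalize, average."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ramanscreen.preprocess import (
    BaselineFit,
    PreprocessConfig,
    PreprocessError,
    area_normalize,
    average_replicates,
    crop,
    despike,
    preprocess_cohort,
    preprocess_scan,
    smooth,
    subtract_baseline,
    vancouver_baseline,
)
from ramanscreen.spectrum import CLASS_LABELS, RamanSpectrum, SpectrumSet
from ramanscreen.synth import (
    CohortConfig,
    ClassProfile,
    PeakSpec,
    default_class_profiles,
    simulate_scan,
)

AXIS = np.arange(200.0, 2001.0)
CROPPED = np.arange(600.0, 1801.0)


def _order7_polynomial(x, scale=1000.0):
    t = (x - x[0]) / (x[-1] - x[0]) * 2 - 1
    return scale * (
        1 + 0.5 * t - 0.3 * t**2 + 0.2 * t**3 - 0.1 * t**4
        + 0.05 * t**5 - 0.02 * t**6 + 0.01 * t**7
    )


class TestCrop:
    def test_closed_interval_channel_count(self):
        spec = RamanSpectrum(AXIS, np.ones_like(AXIS))
        out = crop(spec, 600.0, 1800.0)
        assert len(out) == 1201
        assert out.wavenumber[0] == 600.0 and out.wavenumber[-1] == 1800.0

    def test_identity_when_already_inside(self):
        spec = RamanSpectrum(CROPPED, np.ones_like(CROPPED))
        assert crop(spec, 600.0, 1800.0) is spec

    def test_empty_window_raises(self):
        spec = RamanSpectrum(AXIS, np.ones_like(AXIS))
        with pytest.raises(PreprocessError):
            crop(spec, 2100.0, 2200.0)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        lo=st.floats(min_value=200, max_value=1500),
        width=st.floats(min_value=10, max_value=500),
    )
    def test_all_channels_inside_window(self, lo, width):
        spec = RamanSpectrum(AXIS, np.ones_like(AXIS))
        out = crop(spec, lo, lo + width)
        assert np.all((out.wavenumber >= lo) & (out.wavenumber <= lo + width))


class TestDespike:
    def test_single_spike_restored_others_untouched(self):
        rng = np.random.default_rng(0)
        noise_sd = 2.0
        y = 100.0 + rng.normal(0, noise_sd, AXIS.size)
        spiked = y.copy()
        spiked[700] += 100 * noise_sd
        out = despike(RamanSpectrum(AXIS, spiked), window=7, z=8.0)
        assert abs(out.intensity[700] - 100.0) <= 2 * noise_sd
        mask = np.ones(AXIS.size, bool)
        mask[700] = False
        assert np.array_equal(out.intensity[mask], spiked[mask])

    def test_low_false_positive_rate_on_smooth_spectrum(self):
        y = _order7_polynomial(AXIS) + 50 * np.exp(-((AXIS - 1000) / 30) ** 2)
        out = despike(RamanSpectrum(AXIS, y), window=7, z=8.0)
        modified = np.sum(out.intensity != y)
        assert modified <= 0.01 * AXIS.size

    def test_constant_spectrum_unchanged(self):
        y = np.full(AXIS.size, 7.0)
        out = despike(RamanSpectrum(AXIS, y))
        assert np.array_equal(out.intensity, y)

    def test_even_window_rejected(self):
        with pytest.raises(PreprocessError):
            despike(RamanSpectrum(AXIS, np.ones_like(AXIS)), window=6)


class TestSmooth:
    def test_low_degree_polynomial_reproduced_exactly(self):
        y = 1.0 + 2.0 * AXIS + 0.003 * AXIS**2 - 1e-6 * AXIS**3
        out = smooth(RamanSpectrum(AXIS, y), window=9, polyorder=3)
        interior = slice(4, -4)
        assert np.max(np.abs(out.intensity[interior] - y[interior])) <= 1e-9 * np.max(np.abs(y))

    def test_variance_reduction_on_white_noise(self):
        rng = np.random.default_rng(1)
        reduced = 0
        for _ in range(100):
            y = rng.normal(size=300)
            out = smooth(RamanSpectrum(np.arange(300.0), y), window=9, polyorder=3)
            reduced += np.var(out.intensity) < np.var(y)
        assert reduced == 100

    def test_invalid_window_is_config_error(self):
        with pytest.raises(PreprocessError):
            smooth(RamanSpectrum(AXIS, np.ones_like(AXIS)), window=5, polyorder=7)


class TestVancouverBaseline:
    def test_polynomial_input_is_fixed_point(self):
        y = _order7_polynomial(CROPPED)
        fit = vancouver_baseline(RamanSpectrum(CROPPED, y), PreprocessConfig())
        assert fit.converged
        assert fit.n_iterations <= 2
        assert np.max(np.abs(fit.baseline - y)) <= 1e-6 * np.max(np.abs(y))

    def test_matches_direct_polyfit_on_polynomial_input(self):
        """On peak-free polynomial input the iteration reduces to one
        least-squares fit."""
        y = _order7_polynomial(CROPPED, scale=500.0)
        fit = vancouver_baseline(RamanSpectrum(CROPPED, y), PreprocessConfig())
        direct = np.polynomial.Polynomial.fit(CROPPED, y, deg=7)(CROPPED)
        assert np.allclose(fit.baseline, direct, atol=1e-6 * np.max(np.abs(y)))

    @staticmethod
    def _peaks_plus_background(noise_sd, seed=0):
        # Gaussian bands: compactly supported, so channels beyond 3 HWHM
        # carry pure background and the oracle comparison is well defined
        profiles = default_class_profiles(lineshape="gaussian")
        profile = profiles["normal"]
        rng = np.random.default_rng(seed)
        background = _order7_polynomial(CROPPED, scale=1500.0)
        peaks = np.zeros_like(CROPPED)
        for p, a in zip(profile.peaks, profile.amplitudes()):
            peaks += a * p.profile(CROPPED)
        y = background + peaks + rng.normal(0, noise_sd, CROPPED.size)
        return background, peaks, y, profile

    def test_recovers_background_away_from_peaks(self):
        noise_sd = 5.0
        background, _, y, profile = self._peaks_plus_background(noise_sd)
        fit = vancouver_baseline(RamanSpectrum(CROPPED, y), PreprocessConfig())
        far = np.ones(CROPPED.size, bool)
        for p in profile.peaks:
            far &= np.abs(CROPPED - p.center) >= 3 * p.width
        rms = np.sqrt(np.mean((fit.baseline[far] - background[far]) ** 2))
        assert rms <= 2 * noise_sd

    def test_peak_area_recovered_within_10_percent(self):
        """Integrated 1002 cm^-1 band area after subtraction vs simulated truth."""
        noise_sd = 5.0
        _, peaks, y, profile = self._peaks_plus_background(noise_sd, seed=4)
        fit = vancouver_baseline(RamanSpectrum(CROPPED, y), PreprocessConfig())
        residual = y - fit.baseline
        band = next(p for p in profile.peaks if p.center == 1002.0)
        window = np.abs(CROPPED - band.center) <= 3 * band.width
        est = np.trapezoid(residual[window], CROPPED[window])
        true = np.trapezoid(peaks[window], CROPPED[window])
        assert abs(est - true) <= 0.10 * true

    def test_too_few_channels_rejected(self):
        with pytest.raises(PreprocessError):
            vancouver_baseline(
                RamanSpectrum(np.arange(5.0), np.ones(5)), PreprocessConfig()
            )


class TestSubtractNormalizeAverage:
    def test_subtract_self_gives_zero_and_inverts(self):
        rng = np.random.default_rng(2)
        y = rng.normal(100, 10, CROPPED.size)
        spec = RamanSpectrum(CROPPED, y)
        fit = BaselineFit(baseline=y.copy(), n_iterations=1, converged=True, noise_estimate=0.0)
        zero = subtract_baseline(spec, fit)
        assert np.all(zero.intensity == 0.0)
        back = zero.intensity + fit.baseline
        assert np.max(np.abs(back - y)) <= 1e-12

    def test_subtract_axis_mismatch_raises(self):
        spec = RamanSpectrum(CROPPED, np.ones_like(CROPPED))
        fit = BaselineFit(np.ones(10), 1, True, 0.0)
        with pytest.raises(PreprocessError):
            subtract_baseline(spec, fit)

    def test_constant_normalizes_to_inverse_range(self):
        spec = RamanSpectrum(CROPPED, np.full(CROPPED.size, 17.0))
        out = area_normalize(spec)
        assert np.allclose(out.intensity, 1.0 / 1200.0)

    def test_output_integral_is_one(self):
        rng = np.random.default_rng(3)
        y = np.abs(rng.normal(50, 20, CROPPED.size))
        out = area_normalize(RamanSpectrum(CROPPED, y))
        assert np.trapezoid(out.intensity, CROPPED) == pytest.approx(1.0, abs=1e-9)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(scale=st.floats(min_value=1e-3, max_value=1e3))
    def test_scale_invariance(self, scale):
        rng = np.random.default_rng(4)
        y = np.abs(rng.normal(50, 20, 200)) + 1.0
        axis = 600.0 + np.arange(200.0)
        a = area_normalize(RamanSpectrum(axis, y))
        b = area_normalize(RamanSpectrum(axis, scale * y))
        assert np.allclose(a.intensity, b.intensity, rtol=1e-9)

    def test_nonpositive_area_raises(self):
        spec = RamanSpectrum(CROPPED, np.full(CROPPED.size, -1.0))
        with pytest.raises(PreprocessError):
            area_normalize(spec)

    def test_average_idempotent_on_identical_scans(self):
        y = np.linspace(1, 2, CROPPED.size)
        scans = [RamanSpectrum(CROPPED, y, sample_id="s", scan_index=k) for k in range(10)]
        mean = average_replicates(scans)
        assert np.allclose(mean.intensity, y, rtol=1e-12, atol=0)
        assert mean.scan_index is None
        assert mean.sample_id == "s"

    def test_average_arithmetic_and_symmetry(self):
        a = RamanSpectrum(CROPPED, np.zeros(CROPPED.size))
        b = RamanSpectrum(CROPPED, np.full(CROPPED.size, 2.0))
        assert np.all(average_replicates([a, b]).intensity == 1.0)
        assert np.array_equal(
            average_replicates([a, b]).intensity,
            average_replicates([b, a]).intensity,
        )

    def test_average_mixed_axes_raises(self):
        a = RamanSpectrum(CROPPED, np.ones(CROPPED.size))
        b = RamanSpectrum(CROPPED + 1.0, np.ones(CROPPED.size))
        with pytest.raises(Exception):
            average_replicates([a, b])


class TestPreprocessCohort:
    def test_feature_matrix_shape(self, small_cohort, small_features):
        config, cohort, _ = small_cohort
        X, y, wn, ids = small_features
        assert X.shape == (cohort.n_samples, 1201)
        assert list(ids) == cohort.sample_ids
        assert set(y) == set(CLASS_LABELS)
        assert wn[0] == 600.0 and wn[-1] == 1800.0

    def test_single_sample_single_scan(self):
        config = CohortConfig(
            n_cancer=1, n_benign=1, n_normal=1, scans_per_sample=1, seed=0
        )
        from ramanscreen.synth import simulate_cohort

        cohort, _ = simulate_cohort(config)
        one = SpectrumSet()
        sid = cohort.sample_ids[0]
        label, scans = cohort.samples[sid]
        one.add_sample(sid, label, scans)
        X, y, wn, ids = preprocess_cohort(one)
        assert X.shape == (1, 1201)

    def test_sample_reordering_permutes_rows(self, small_cohort, small_features):
        _, cohort, _ = small_cohort
        X, _, _, ids = small_features
        order = list(reversed(cohort.sample_ids))
        X2, _, _, ids2 = preprocess_cohort(cohort.reordered(order))
        assert ids2 == order
        lookup = {sid: i for i, sid in enumerate(ids)}
        assert np.array_equal(X2, X[[lookup[sid] for sid in order]])

    def test_end_to_end_scale_invariance(self, small_cohort, small_features):
        """Multiplying every raw scan of a sample by a constant leaves its
        final feature row unchanged: area normalization absorbs laser power."""
        _, cohort, _ = small_cohort
        X, _, _, ids = small_features
        sid = ids[0]
        label, scans = cohort.samples[sid]
        scaled = SpectrumSet()
        scaled.add_sample(sid, label, [s.with_intensity(5.0 * s.intensity) for s in scans])
        X2, _, _, _ = preprocess_cohort(scaled)
        assert np.allclose(X2[0], X[0], atol=1e-6 * np.max(np.abs(X[0])))

    def test_deterministic(self, small_cohort):
        _, cohort, _ = small_cohort
        X1, _, _, _ = preprocess_cohort(cohort)
        X2, _, _, _ = preprocess_cohort(cohort)
        assert np.array_equal(X1, X2)

    def test_despike_recovers_spike_free_truth(self, small_cohort):
        """Processed spikes leave no visible residue: compare a spiked scan
        against the same scan with its recorded spikes removed."""
        config, cohort, truth = small_cohort
        spiked = [t for t in truth.scans if t.spike_channels.size > 0]
        assert spiked, "expected at least one cosmic-ray spike in the cohort"
        t = spiked[0]
        label, scans = cohort.samples[t.sample_id]
        scan = scans[t.scan_index]
        clean_int = scan.intensity.copy()
        for ch, amp in zip(t.spike_channels, t.spike_amplitudes):
            clean_int[ch] -= amp
        p_spiked = preprocess_scan(scan, PreprocessConfig())
        p_clean = preprocess_scan(scan.with_intensity(clean_int), PreprocessConfig())
        scale = np.max(np.abs(p_clean.intensity))
        assert np.allclose(p_spiked.intensity, p_clean.intensity, atol=0.02 * scale)
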