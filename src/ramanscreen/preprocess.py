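"""Spectral preprocessing chain for serum Raman screening.

Per scan: crop to the 600-1800 cm^-1 fingerprint window, remove cosmic-ray
spikes (rolling median + MAD z-score), Savitzky-Golay denoise, subtract the
autofluorescence background with the iterative modified-polyfit ("Vancouver")
algorithm at polynomial order 7, and normalize to unit integrated area.
Replicate scans of each serum are averaged last, yielding one feature row
per sample. The whole chain is deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import median_filter
from scipy.signal import savgol_filter

from .spectrum import RamanSpectrum, SpectrumSet, SpectrumError, common_grid


class PreprocessError(ValueError):
    """Raised for invalid preprocessing configuration or degenerate input."""


@dataclass(frozen=True)
class PreprocessConfig:
    """Parameters of the preprocessing chain.

    crop_lo/crop_hi
        Fingerprint window bounds in cm^-1 (closed interval).
    despike_window / despike_z
        Rolling-median window (channels, odd) and MAD z-score threshold for
        cosmic-ray removal.
    smooth_window / smooth_polyorder
        Savitzky-Golay parameters.
    poly_order / max_iter / rel_tol
        Baseline polynomial order, iteration cap, and relative convergence
        tolerance on the residual-noise estimate.
    """

    crop_lo: float = 600.0
    crop_hi: float = 1800.0
    despike_window: int = 7
    despike_z: float = 8.0
    smooth_window: int = 9
    smooth_polyorder: int = 3
    poly_order: int = 7
    max_iter: int = 100
    rel_tol: float = 0.005

    def __post_init__(self) -> None:
        if self.crop_lo >= self.crop_hi:
            raise PreprocessError("crop_lo must be < crop_hi")
        if self.poly_order < 1:
            raise PreprocessError("poly_order must be >= 1")
        if self.despike_window < 3 or self.despike_window % 2 == 0:
            raise PreprocessError("despike_window must be odd and >= 3")
        if self.smooth_window % 2 == 0 or self.smooth_window <= self.smooth_polyorder:
            raise PreprocessError("smooth_window must be odd and > smooth_polyorder")
        if self.max_iter < 1 or self.rel_tol <= 0:
            raise PreprocessError("max_iter >= 1 and rel_tol > 0 required")


@dataclass
class BaselineFit:
    """Result of the iterative baseline fit on one (cropped) spectrum."""

    baseline: np.ndarray
    n_iterations: int
    converged: bool
    noise_estimate: float


def crop(spectrum: RamanSpectrum, lo: float, hi: float) -> RamanSpectrum:
    """Keep exactly the channels with lo <= wavenumber <= hi."""
    mask = (spectrum.wavenumber >= lo) & (spectrum.wavenumber <= hi)
    if not mask.any():
        raise PreprocessError(
            f"crop window [{lo}, {hi}] contains no channels of the spectrum"
        )
    if mask.all():
        return spectrum
    return RamanSpectrum(
        spectrum.wavenumber[mask], spectrum.intensity[mask],
        sample_id=spectrum.sample_id, scan_index=spectrum.scan_index,
        label=spectrum.label,
    )


def despike(spectrum: RamanSpectrum, window: int = 7, z: float = 8.0) -> RamanSpectrum:
    """Replace cosmic-ray outliers by the local rolling median.

    A channel is flagged when its deviation from the rolling median exceeds
    ``z`` times a MAD-based robust scale of those local-median deviations;
    only flagged channels are modified.
    """
    if window < 3 or window % 2 == 0:
        raise PreprocessError("despike window must be odd and >= 3")
    y = spectrum.intensity
    med = median_filter(y, size=window, mode="nearest")
    resid = y - med
    # MAD of the rolling-median residuals as a Gaussian-comparable sigma;
    # a whole-spectrum MAD is stable where a windowed one would have a fat
    # lower tail and flag noise. Floored for (near-)constant signal.
    scale = 1.4826 * float(np.median(np.abs(resid)))
    floor = 1e-12 * max(1.0, float(np.max(np.abs(y))))
    scale = max(scale, floor)
    spikes = np.abs(resid) > z * scale
    if not spikes.any():
        return spectrum
    out = y.copy()
    out[spikes] = med[spikes]
    return spectrum.with_intensity(out)


def smooth(spectrum: RamanSpectrum, window: int = 9, polyorder: int = 3) -> RamanSpectrum:
    """Savitzky-Golay smoothing; preserves band shape better than a boxcar."""
    if window % 2 == 0 or window <= polyorder:
        raise PreprocessError("smooth window must be odd and > polyorder")
    if window > len(spectrum):
        raise PreprocessError("smooth window exceeds spectrum length")
    return spectrum.with_intensity(
        savgol_filter(spectrum.intensity, window_length=window, polyorder=polyorder)
    )


def vancouver_baseline(
    spectrum: RamanSpectrum, config: PreprocessConfig | None = None
) -> BaselineFit:
    """Iterative modified-polyfit estimate of the autofluorescence baseline.

    Each round fits an order-``poly_order`` polynomial P to the working
    spectrum (axis rescaled to [-1, 1] for conditioning), estimates the
    residual noise level DEV = std(working - P), and clips the working
    spectrum at P + DEV so that Raman bands are progressively excluded from
    the next fit while baseline and noise survive. Iteration stops when the
    relative change in DEV falls below ``rel_tol`` or ``max_iter`` rounds
    have run; non-convergence is reported, not raised.
    """
    config = config or PreprocessConfig()
    y = spectrum.intensity.astype(float)
    if y.size < config.poly_order + 2:
        raise PreprocessError(
            f"need >= {config.poly_order + 2} channels for an order-"
            f"{config.poly_order} baseline fit"
        )
    x = spectrum.wavenumber
    working = y.copy()
    prev_dev = None
    converged = False
    n_iter = 0
    fitted = np.zeros_like(y)
    for n_iter in range(1, config.max_iter + 1):
        poly = np.polynomial.Polynomial.fit(x, working, deg=config.poly_order)
        fitted = poly(x)
        dev = float(np.std(working - fitted))
        if dev == 0.0:
            converged = True
            break
        working = np.minimum(working, fitted + dev)
        if prev_dev is not None and abs(dev - prev_dev) / dev < config.rel_tol:
            converged = True
            break
        prev_dev = dev
    return BaselineFit(
        baseline=fitted, n_iterations=n_iter, converged=converged,
        noise_estimate=float(np.std(working - fitted)),
    )


def subtract_baseline(spectrum: RamanSpectrum, fit: BaselineFit) -> RamanSpectrum:
    """Channelwise subtraction; negative residual noise is retained."""
    if fit.baseline.shape != spectrum.intensity.shape:
        raise PreprocessError("baseline/spectrum length mismatch")
    return spectrum.with_intensity(spectrum.intensity - fit.baseline)


def area_normalize(spectrum: RamanSpectrum) -> RamanSpectrum:
    """Divide by the trapezoidal integral so total signal mass is 1.

    The integral is computed on the intensity floored at zero so that the
    normalizer is a positive measure of signal mass even when subtraction
    left negative noise excursions; those excursions are preserved in the
    output.
    """
    floored = np.maximum(spectrum.intensity, 0.0)
    area = float(np.trapezoid(floored, spectrum.wavenumber))
    if area <= 0.0:
        raise PreprocessError(
            f"nonpositive integrated area ({area}); degenerate spectrum"
        )
    return spectrum.with_intensity(spectrum.intensity / area)


def average_replicates(scans: list[RamanSpectrum]) -> RamanSpectrum:
    """Channelwise mean of replicate scans of one sample."""
    if not scans:
        raise PreprocessError("average_replicates needs at least one scan")
    grid = common_grid(scans)
    mean = np.mean([s.intensity for s in scans], axis=0)
    first = scans[0]
    return RamanSpectrum(
        grid, mean, sample_id=first.sample_id, scan_index=None, label=first.label
    )


def preprocess_scan(
    scan: RamanSpectrum, config: PreprocessConfig
) -> RamanSpectrum:
    """Full single-scan chain: crop, despike, smooth, baseline-subtract, normalize."""
    s = crop(scan, config.crop_lo, config.crop_hi)
    s = despike(s, config.despike_window, config.despike_z)
    s = smooth(s, config.smooth_window, config.smooth_polyorder)
    fit = vancouver_baseline(s, config)
    s = subtract_baseline(s, fit)
    return area_normalize(s)


def preprocess_cohort(
    cohort: SpectrumSet, config: PreprocessConfig | None = None
) -> tuple[np.ndarray, np.ndarray, np.ndarray, list[str]]:
    """Run the chain on every scan and average replicates per sample.

    Returns ``(features, labels, wavenumbers, sample_ids)`` where
    ``features`` has one row per sample on the cropped grid, in cohort
    order. Scans on a different grid than the first sample's cropped grid
    are linearly interpolated onto it.
    """
    config = config or PreprocessConfig()
    rows: list[np.ndarray] = []
    labels: list[str] = []
    sample_ids: list[str] = []
    ref_grid: np.ndarray | None = None
    for sid, (label, scans) in cohort.samples.items():
        processed: list[RamanSpectrum] = []
        for scan in scans:
            try:
                p = preprocess_scan(scan, config)
            except (PreprocessError, SpectrumError) as exc:
                raise PreprocessError(
                    f"sample {sid!r} scan {scan.scan_index}: {exc}"
                ) from exc
            if ref_grid is None:
                ref_grid = p.wavenumber
            elif not (
                p.wavenumber.shape == ref_grid.shape
                and np.allclose(p.wavenumber, ref_grid, atol=1e-9, rtol=0.0)
            ):
                p = RamanSpectrum(
                    ref_grid,
                    np.interp(ref_grid, p.wavenumber, p.intensity),
                    sample_id=p.sample_id, scan_index=p.scan_index, label=p.label,
                )
            processed.append(p)
        mean = average_replicates(processed)
        rows.append(mean.intensity)
        labels.append(label)
        sample_ids.append(sid)
    assert ref_grid is not None
    return np.vstack(rows), np.array(labels), ref_grid, sample_ids


__all__ = [
    "PreprocessConfig",
    "BaselineFit",
    "PreprocessError",
    "crop",
    "despike",
    "smooth",
    "vancouver_baseline",
    "subtract_baseline",
    "area_normalize",
    "average_replicates",
    "preprocess_scan",
    "preprocess_cohort",
]
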