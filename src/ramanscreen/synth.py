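"""Synthetic serum Raman cohort generator.

Raw serum spectra are dominated by a broad autofluorescence background with
Raman bands of biomolecules (amino acids, lipids, nucleic-acid bases,
carotenoids, protein amide modes) riding on top, contaminated by shot-like
detector noise and occasional single-channel cosmic-ray spikes. The
generator emulates a three-class clinical cohort (breast cancer / benign
lesion / healthy control) in which the class signal lives entirely in the
relative intensities of 18 known marker bands, while everything else —
background shape, laser-power scale, replicate scatter — is nuisance
structure the preprocessing chain must remove.

Every nuisance component is recorded as ground truth so that downstream
stages (despiking, baseline subtraction) can be tested against the exact
signal they are supposed to recover.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from .spectrum import CLASS_LABELS, RamanSpectrum, SpectrumSet


class ConfigError(ValueError):
    """Raised for invalid simulation configuration."""


Lineshape = Literal["lorentzian", "gaussian"]

# The 18 marker bands: position (cm^-1) -> (band assignment, tentative
# contribution). Positions span 784-1650 cm^-1, inside the analysis window.
PEAK_TABLE: dict[float, tuple[str, str]] = {
    784.0: ("Phosphate backbone of DNA δ(C3CO) deformation", "Cytosine; L-Histidine; Citric acid"),
    835.0: ("para-substituted benzene ring", "Tyrosine"),
    925.0: ("C(6)-OH", "D-Mannose; L-Glutamate; D-(-)-Fructose"),
    986.0: ("", "Proline"),
    989.0: ("", "Tryptophan"),
    1002.0: ("trigonal ring breathing of the benzene ring; N(C-O) stretch",
             "Phenylalanine; beta-D-glucose; N-Acetylglucosamine"),
    1020.0: ("indole ring ν(C-O) and ν(C-C) stretches",
             "Tryptophan; N-Acetyl-D-glucosamine; glucose; Glucuronic acid; Lactose; D-(+)-Galactosamine"),
    1056.0: ("", "L-Glutamate"),
    1114.0: ("C-C stretch", "breast lipid"),
    1127.0: ("", "Amino acids; Fatty acids; Saccharides; D-fructose-6-phosphate"),
    1139.0: ("stretching vibrational ν(C-N)", "D-Mannose; Amide III"),
    1285.0: ("alpha-helix", "Amide III; phosphatide"),
    1295.0: ("δ(CH2) twist vibrations", "Fatty acids"),
    1346.0: ("", "Glycine; alpha-D-glucose"),
    1367.0: ("CH3 indole rings", "Tryptophan"),
    1437.0: ("CH2 scissoring, δ(CH2, CH3) bending vibrations", "Lipids"),
    1531.0: ("ν(C=C) stretching", "beta-carotene"),
    1650.0: ("alpha-helix", "Protein Amide I"),
}

# Bands with a reported cancer-vs-control direction: +1 means elevated in
# the cancer group (nucleic acids, glutamate/tryptophan, lipid C-C stretch),
# -1 means depleted (free amino acids, amide alpha-helix, beta-carotene).
CANCER_DIRECTION: dict[float, int] = {
    784.0: +1, 1020.0: +1, 1056.0: +1, 1114.0: +1, 1367.0: +1,
    835.0: -1, 986.0: -1, 989.0: -1, 1002.0: -1, 1285.0: -1,
    1531.0: -1, 1650.0: -1,
}

# Bands that differ between groups without a stated direction; given small
# alternating-direction offsets so that no marker band is exactly null.
_UNDIRECTED = (925.0, 1127.0, 1139.0, 1295.0, 1346.0, 1437.0)

# Base (healthy-control) band amplitudes in detector counts, chosen so that
# major serum features (phenylalanine 1002, amide I 1650, CH2 1437) dominate.
_BASE_AMPLITUDE: dict[float, float] = {
    784.0: 70.0, 835.0: 65.0, 925.0: 60.0, 986.0: 75.0, 989.0: 75.0,
    1002.0: 140.0, 1020.0: 80.0, 1056.0: 70.0, 1114.0: 65.0, 1127.0: 70.0,
    1139.0: 65.0, 1285.0: 85.0, 1295.0: 80.0, 1346.0: 75.0, 1367.0: 70.0,
    1437.0: 110.0, 1531.0: 90.0, 1650.0: 130.0,
}

# Fractional class effect at directed / undirected bands (at effect_scale 1).
_DIRECTED_DELTA = 0.25
_UNDIRECTED_DELTA = 0.06

# Autofluorescence background: order-5 polynomial in t = (wn-200)/1800,
# positive and slowly decaying toward high wavenumber, as raw serum
# autofluorescence does. Scaled by CohortConfig-independent baseline_scale.
DEFAULT_BASELINE_COEFFS: tuple[float, ...] = (3.0, -4.0, 2.0, -0.6, 0.12, -0.02)
DEFAULT_BASELINE_SCALE = 1500.0


@dataclass(frozen=True)
class PeakSpec:
    """One Raman band shared by all classes, with class-specific amplitudes."""

    center: float
    width: float  # half-width at half-maximum, cm^-1
    lineshape: Lineshape = "lorentzian"
    amplitude_by_class: dict[str, float] = field(default_factory=dict)
    assignment: str = ""
    contribution: str = ""

    def __post_init__(self) -> None:
        if not 200.0 <= self.center <= 2000.0:
            raise ConfigError(f"peak center {self.center} outside [200, 2000]")
        if self.width <= 0:
            raise ConfigError("peak width must be > 0")
        if self.lineshape not in ("lorentzian", "gaussian"):
            raise ConfigError(f"unknown lineshape {self.lineshape!r}")
        if any(a < 0 for a in self.amplitude_by_class.values()):
            raise ConfigError("peak amplitudes must be >= 0")

    def profile(self, wavenumber: np.ndarray, shift: float = 0.0) -> np.ndarray:
        """Unit-amplitude lineshape on ``wavenumber``, center shifted by ``shift``."""
        x = (wavenumber - (self.center + shift)) / self.width
        if self.lineshape == "lorentzian":
            return 1.0 / (1.0 + x * x)
        return np.exp(-np.log(2.0) * x * x)


@dataclass(frozen=True)
class ClassProfile:
    """Noiseless spectral model of one clinical class."""

    label: str
    peaks: tuple[PeakSpec, ...]
    baseline_coeffs: tuple[float, ...] = DEFAULT_BASELINE_COEFFS
    baseline_scale: float = DEFAULT_BASELINE_SCALE

    def __post_init__(self) -> None:
        if len(self.baseline_coeffs) > 8:
            raise ConfigError("baseline polynomial order must be <= 7")
        t = np.linspace(0.0, 1.0, 512)
        if np.any(np.polynomial.polynomial.polyval(t, self.baseline_coeffs) < 0):
            raise ConfigError("baseline polynomial must be nonnegative over [200, 2000]")

    def baseline(self, wavenumber: np.ndarray) -> np.ndarray:
        t = (np.asarray(wavenumber, float) - 200.0) / 1800.0
        return self.baseline_scale * np.polynomial.polynomial.polyval(
            t, self.baseline_coeffs
        )

    def amplitudes(self) -> np.ndarray:
        return np.array([p.amplitude_by_class[self.label] for p in self.peaks])


@dataclass(frozen=True)
class CohortConfig:
    """Study-design parameters of a simulated cohort.

    Defaults reproduce the clinical study design: 129 cancer, 91 benign and
    113 control sera, 10 replicate scans per serum, acquisition over
    200-2000 cm^-1 at 1 cm^-1 steps.
    """

    n_cancer: int = 129
    n_benign: int = 91
    n_normal: int = 113
    scans_per_sample: int = 10
    grid_start: float = 200.0
    grid_stop: float = 2000.0
    grid_step: float = 1.0
    noise_sd: float = 5.0
    spike_rate: float = 0.5
    spike_amplitude_range: tuple[float, float] = (50.0, 250.0)
    between_sample_sd: float = 0.08
    within_sample_sd: float = 0.03
    axis_jitter_sd: float = 0.3
    baseline_scale_jitter_sd: float = 0.10
    effect_scale: float = 1.0
    lineshape: Lineshape = "lorentzian"
    peak_width: float = 8.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_cancer, self.n_benign, self.n_normal) <= 0:
            raise ConfigError("group sizes must be > 0")
        if self.scans_per_sample <= 0:
            raise ConfigError("scans_per_sample must be > 0")
        if self.grid_start >= self.grid_stop:
            raise ConfigError("grid_start must be < grid_stop")
        if self.grid_step <= 0:
            raise ConfigError("grid_step must be > 0")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be >= 0")
        if self.spike_rate < 0:
            raise ConfigError("spike_rate must be >= 0")
        if self.effect_scale < 0:
            raise ConfigError("effect_scale must be >= 0")

    @property
    def grid(self) -> np.ndarray:
        n = int(round((self.grid_stop - self.grid_start) / self.grid_step)) + 1
        return self.grid_start + self.grid_step * np.arange(n)

    @property
    def n_samples(self) -> int:
        return self.n_cancer + self.n_benign + self.n_normal


@dataclass
class ScanTruth:
    """Ground truth for one generated scan (never read by the pipeline)."""

    sample_id: str
    scan_index: int
    label: str
    baseline: np.ndarray          # noiseless background incl. scale jitter
    peak_signal: np.ndarray       # noiseless sum of band lineshapes
    spike_channels: np.ndarray    # integer channel indices
    spike_amplitudes: np.ndarray
    peak_amplitudes: np.ndarray   # per-band amplitudes used for this scan


@dataclass
class GroundTruth:
    """Per-scan and per-sample ground truth for a simulated cohort."""

    scans: list[ScanTruth] = field(default_factory=list)
    sample_labels: dict[str, str] = field(default_factory=dict)
    sample_amplitudes: dict[str, np.ndarray] = field(default_factory=dict)


def default_class_profiles(
    effect_scale: float = 1.0,
    lineshape: Lineshape = "lorentzian",
    peak_width: float = 8.0,
) -> dict[str, ClassProfile]:
    """Build the three class profiles over the 18 marker bands.

    The cancer-vs-control direction of each directed band follows the
    serum biochemistry summarized in :data:`CANCER_DIRECTION`; the benign
    profile sits at the midpoint of cancer and control, reflecting the
    close spectral resemblance of malignant and benign sera. Bands without
    a reported direction receive small alternating offsets. ``effect_scale``
    multiplies every class difference; at 0 the three classes coincide.
    """
    if effect_scale < 0:
        raise ConfigError("effect_scale must be >= 0")
    peaks: list[PeakSpec] = []
    for i, (center, (assignment, contribution)) in enumerate(sorted(PEAK_TABLE.items())):
        base = _BASE_AMPLITUDE[center]
        if center in CANCER_DIRECTION:
            delta = CANCER_DIRECTION[center] * _DIRECTED_DELTA
        else:
            sign = 1 if _UNDIRECTED.index(center) % 2 == 0 else -1
            delta = sign * _UNDIRECTED_DELTA
        cancer = base * (1.0 + effect_scale * delta)
        normal = base
        benign = 0.5 * (cancer + normal)
        peaks.append(
            PeakSpec(
                center=center,
                width=peak_width,
                lineshape=lineshape,
                amplitude_by_class={
                    "cancer": cancer, "benign": benign, "normal": normal
                },
                assignment=assignment,
                contribution=contribution,
            )
        )
    shared = tuple(peaks)
    return {label: ClassProfile(label=label, peaks=shared) for label in CLASS_LABELS}


def simulate_scan(
    profile: ClassProfile,
    sample_amplitudes: np.ndarray,
    config: CohortConfig,
    rng: np.random.Generator,
    sample_id: str = "",
    scan_index: int = 0,
) -> tuple[RamanSpectrum, ScanTruth]:
    """Generate one scan: baseline + bands + Gaussian noise + cosmic spikes.

    ``sample_amplitudes`` are the per-band amplitudes of the serum being
    scanned (between-sample biology already applied); this function adds
    the per-scan nuisances: within-sample amplitude jitter, laser-power
    scale jitter on the background, a small wavenumber calibration shift,
    detector noise and Poisson-count cosmic-ray spikes.
    """
    grid = config.grid
    sample_amplitudes = np.asarray(sample_amplitudes, float)
    if sample_amplitudes.shape != (len(profile.peaks),):
        raise ConfigError("sample_amplitudes must have one entry per peak")

    scan_amps = sample_amplitudes * np.exp(
        rng.normal(0.0, config.within_sample_sd, size=sample_amplitudes.size)
    )
    shift = rng.normal(0.0, config.axis_jitter_sd) if config.axis_jitter_sd > 0 else 0.0
    baseline = profile.baseline(grid) * np.exp(
        rng.normal(0.0, config.baseline_scale_jitter_sd)
        if config.baseline_scale_jitter_sd > 0
        else 0.0
    )
    peak_signal = np.zeros_like(grid)
    for amp, peak in zip(scan_amps, profile.peaks):
        peak_signal += amp * peak.profile(grid, shift=shift)

    intensity = baseline + peak_signal
    if config.noise_sd > 0:
        intensity = intensity + rng.normal(0.0, config.noise_sd, size=grid.size)

    n_spikes = rng.poisson(config.spike_rate)
    spike_channels = rng.integers(0, grid.size, size=n_spikes)
    lo, hi = config.spike_amplitude_range
    spike_amplitudes = rng.uniform(lo, hi, size=n_spikes)
    for ch, amp in zip(spike_channels, spike_amplitudes):
        intensity[ch] += amp

    spectrum = RamanSpectrum(
        grid, intensity, sample_id=sample_id, scan_index=scan_index,
        label=profile.label,
    )
    truth = ScanTruth(
        sample_id=sample_id, scan_index=scan_index, label=profile.label,
        baseline=baseline, peak_signal=peak_signal,
        spike_channels=spike_channels, spike_amplitudes=spike_amplitudes,
        peak_amplitudes=scan_amps,
    )
    return spectrum, truth


def simulate_cohort(config: CohortConfig) -> tuple[SpectrumSet, GroundTruth]:
    """Generate a full cohort, deterministic for a fixed ``config.seed``.

    Per sample, band amplitudes are drawn once with lognormal between-sample
    jitter around the class profile, then perturbed per scan by
    :func:`simulate_scan`.
    """
    rng = np.random.default_rng(config.seed)
    profiles = default_class_profiles(
        effect_scale=config.effect_scale,
        lineshape=config.lineshape,
        peak_width=config.peak_width,
    )
    counts = {
        "cancer": config.n_cancer, "benign": config.n_benign,
        "normal": config.n_normal,
    }
    cohort = SpectrumSet(provenance=f"synthetic cohort, seed={config.seed}")
    truth = GroundTruth()
    for label in CLASS_LABELS:
        profile = profiles[label]
        class_amps = profile.amplitudes()
        for i in range(counts[label]):
            sid = f"{label}_{i + 1:03d}"
            sample_amps = class_amps * np.exp(
                rng.normal(0.0, config.between_sample_sd, size=class_amps.size)
            )
            scans = []
            for k in range(config.scans_per_sample):
                spec, scan_truth = simulate_scan(
                    profile, sample_amps, config, rng,
                    sample_id=sid, scan_index=k,
                )
                scans.append(spec)
                truth.scans.append(scan_truth)
            cohort.add_sample(sid, label, scans)
            truth.sample_labels[sid] = label
            truth.sample_amplitudes[sid] = sample_amps
    return cohort, truth


__all__ = [
    "PEAK_TABLE",
    "CANCER_DIRECTION",
    "PeakSpec",
    "ClassProfile",
    "CohortConfig",
    "ScanTruth",
    "GroundTruth",
    "ConfigError",
    "default_class_profiles",
    "simulate_scan",
    "simulate_cohort",
]
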