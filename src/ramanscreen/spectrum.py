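"""Core in-memory containers for Raman spectra.

A :class:`RamanSpectrum` holds one acquisition (scan): a strictly increasing
wavenumber axis in cm^-1 and an intensity vector in detector counts, plus
lightweight metadata identifying the sample, the scan index within the
sample, and (when known) the clinical class label.

A :class:`SpectrumSet` groups the scans of a cohort by sample, enforcing a
shared wavenumber grid within each sample.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator, Sequence

import numpy as np

#: Fixed class-label vocabulary, in the canonical reporting order.
CLASS_LABELS: tuple[str, ...] = ("cancer", "benign", "normal")

#: Accepted label tokens for samples whose class is not (yet) known.
UNLABELED = "unlabeled"


class SpectrumError(ValueError):
    """Raised for malformed spectra or incompatible spectrum operations."""


@dataclass(frozen=True)
class RamanSpectrum:
    """One Raman scan: wavenumber axis (cm^-1) plus intensity (counts).

    Parameters
    ----------
    wavenumber
        Strictly increasing axis in cm^-1.
    intensity
        Intensity vector, same length as ``wavenumber``. Finite values;
        negative values are permitted (baseline-subtracted spectra carry
        negative noise excursions).
    sample_id, scan_index, label
        Metadata. ``scan_index`` is ``None`` for per-sample mean spectra.
    """

    wavenumber: np.ndarray
    intensity: np.ndarray
    sample_id: str = ""
    scan_index: int | None = None
    label: str | None = None

    def __post_init__(self) -> None:
        wn = np.asarray(self.wavenumber, dtype=float)
        it = np.asarray(self.intensity, dtype=float)
        object.__setattr__(self, "wavenumber", wn)
        object.__setattr__(self, "intensity", it)
        if wn.ndim != 1 or it.ndim != 1 or wn.shape != it.shape:
            raise SpectrumError(
                f"axis/intensity shape mismatch: {wn.shape} vs {it.shape}"
            )
        if wn.size < 2:
            raise SpectrumError("spectrum needs at least 2 channels")
        if not np.all(np.diff(wn) > 0):
            raise SpectrumError("wavenumber axis must be strictly increasing")
        if not np.all(np.isfinite(it)):
            raise SpectrumError("intensities must be finite")
        if self.label is not None and self.label not in CLASS_LABELS + (UNLABELED,):
            raise SpectrumError(f"unknown class label: {self.label!r}")

    def __len__(self) -> int:
        return int(self.wavenumber.size)

    def with_intensity(self, intensity: np.ndarray, **meta) -> "RamanSpectrum":
        """Return a copy with a new intensity vector (same axis)."""
        kwargs = dict(
            sample_id=self.sample_id, scan_index=self.scan_index, label=self.label
        )
        kwargs.update(meta)
        return RamanSpectrum(self.wavenumber, np.asarray(intensity, float), **kwargs)

    def same_axis(self, other: "RamanSpectrum", atol: float = 1e-9) -> bool:
        return self.wavenumber.shape == other.wavenumber.shape and np.allclose(
            self.wavenumber, other.wavenumber, atol=atol, rtol=0.0
        )


@dataclass
class SpectrumSet:
    """A cohort of samples, each carrying one or more replicate scans.

    ``samples`` maps a unique ``sample_id`` to ``(label, [scans])``; insertion
    order is the cohort order and is preserved by every downstream stage.
    """

    samples: dict[str, tuple[str, list[RamanSpectrum]]] = field(default_factory=dict)
    provenance: str = ""

    def add_sample(self, sample_id: str, label: str, scans: Sequence[RamanSpectrum]) -> None:
        if sample_id in self.samples:
            raise SpectrumError(f"duplicate sample_id: {sample_id!r}")
        if label not in CLASS_LABELS + (UNLABELED,):
            raise SpectrumError(f"unknown class label: {label!r}")
        scans = list(scans)
        if not scans:
            raise SpectrumError(f"sample {sample_id!r} has no scans")
        first = scans[0]
        for s in scans[1:]:
            if not first.same_axis(s):
                raise SpectrumError(f"sample {sample_id!r}: scans on different grids")
        self.samples[sample_id] = (label, scans)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.samples.keys())

    @property
    def labels(self) -> list[str]:
        return [lab for lab, _ in self.samples.values()]

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_scans(self) -> int:
        return sum(len(scans) for _, scans in self.samples.values())

    def iter_scans(self) -> Iterator[RamanSpectrum]:
        for _, scans in self.samples.values():
            yield from scans

    def reordered(self, sample_ids: Sequence[str]) -> "SpectrumSet":
        """Return a new set with samples in the given order."""
        if set(sample_ids) != set(self.samples):
            raise SpectrumError("reorder must use exactly the existing sample_ids")
        out = SpectrumSet(provenance=self.provenance)
        for sid in sample_ids:
            lab, scans = self.samples[sid]
            out.add_sample(sid, lab, scans)
        return out


def common_grid(spectra: Sequence[RamanSpectrum]) -> np.ndarray:
    """Return the shared axis of ``spectra``, raising if grids differ."""
    first = spectra[0]
    for s in spectra[1:]:
        if not first.same_axis(s):
            raise SpectrumError("spectra are not on a common wavenumber grid")
    return first.wavenumber


__all__ = [
    "CLASS_LABELS",
    "UNLABELED",
    "RamanSpectrum",
    "SpectrumSet",
    "SpectrumError",
    "common_grid",
    "replace",
]
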