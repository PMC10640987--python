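"""Text-format persistence: spectra, manifests, configs, result tables.

Spectra are plain two-column CSV (``wavenumber_cm-1,intensity``); a cohort
manifest is a CSV mapping sample ids to class labels and their replicate
scan files; configs are YAML with keys mirroring the config dataclasses;
metric tables are tidy CSV. All writers are deterministic byte-for-byte
for identical inputs (no timestamps inside data files) and numeric values
round-trip at full double precision.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from .evaluate import CVConfig, CVResult
from .preprocess import PreprocessConfig
from .spectrum import CLASS_LABELS, UNLABELED, RamanSpectrum, SpectrumSet
from .synth import CohortConfig, GroundTruth


class ManifestError(ValueError):
    """Raised for malformed manifests or unknown label vocabulary."""


class SpectrumParseError(ValueError):
    """Raised when a spectrum file cannot be parsed."""


_VOCAB = set(CLASS_LABELS) | {UNLABELED}
MIN_POINTS = 10


@dataclass(frozen=True)
class ManifestRow:
    sample_id: str
    label: str
    scan_paths: tuple[str, ...]


@dataclass
class Manifest:
    rows: list[ManifestRow]
    path: Path | None = None

    def __len__(self) -> int:
        return len(self.rows)


def read_spectrum(path: str | Path) -> RamanSpectrum:
    """Read a two-column (wavenumber, intensity) text/CSV spectrum.

    A single header line is tolerated; the axis is sorted ascending and
    exact-duplicate wavenumbers are dropped (first occurrence kept).
    """
    path = Path(path)
    wn: list[float] = []
    it: list[float] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            parts = [p for p in line.replace("\t", ",").split(",") if p != ""]
            if len(parts) < 2:
                raise SpectrumParseError(f"{path}:{lineno}: expected two columns")
            try:
                w, v = float(parts[0]), float(parts[1])
            except ValueError:
                if lineno == 1:  # header row
                    continue
                raise SpectrumParseError(
                    f"{path}:{lineno}: non-numeric row {line!r}"
                ) from None
            wn.append(w)
            it.append(v)
    if len(wn) < MIN_POINTS:
        raise SpectrumParseError(
            f"{path}: malformed spectrum ({len(wn)} points, need >= {MIN_POINTS})"
        )
    w = np.array(wn)
    v = np.array(it)
    order = np.argsort(w, kind="stable")
    w, v = w[order], v[order]
    keep = np.concatenate([[True], np.diff(w) > 0])
    return RamanSpectrum(w[keep], v[keep])


def write_spectrum(spectrum: RamanSpectrum, path: str | Path) -> None:
    """Write a spectrum as CSV with full double precision (lossless)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write("wavenumber_cm-1,intensity\n")
        for w, v in zip(spectrum.wavenumber, spectrum.intensity):
            fh.write(f"{w:.12g},{v:.17g}\n")


def read_manifest(path: str | Path) -> Manifest:
    """Read a cohort manifest CSV: sample_id,label,scan_paths(;-separated)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"manifest not found: {path}")
    df = pd.read_csv(path, dtype=str)
    required = {"sample_id", "label", "scan_paths"}
    if not required <= set(df.columns):
        raise ManifestError(f"{path}: manifest needs columns {sorted(required)}")
    rows: list[ManifestRow] = []
    seen: set[str] = set()
    for _, rec in df.iterrows():
        sid, label = rec["sample_id"], rec["label"]
        if label not in _VOCAB:
            raise ManifestError(
                f"{path}: unknown label {label!r} for sample {sid!r}; "
                f"expected one of {sorted(_VOCAB)}"
            )
        if sid in seen:
            raise ManifestError(f"{path}: duplicate sample_id {sid!r}")
        seen.add(sid)
        paths = tuple(p for p in str(rec["scan_paths"]).split(";") if p)
        for p in paths:
            if not (path.parent / p).exists():
                raise FileNotFoundError(f"scan file missing: {path.parent / p}")
        rows.append(ManifestRow(sample_id=sid, label=label, scan_paths=paths))
    return Manifest(rows=rows, path=path)


def write_manifest(manifest: Manifest, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write("sample_id,label,scan_paths\n")
        for row in manifest.rows:
            fh.write(f"{row.sample_id},{row.label},{';'.join(row.scan_paths)}\n")


def write_cohort(cohort: SpectrumSet, out_dir: str | Path) -> Path:
    """Write every scan as CSV plus a manifest; returns the manifest path."""
    out_dir = Path(out_dir)
    spectra_dir = out_dir / "spectra"
    rows: list[ManifestRow] = []
    for sid, (label, scans) in cohort.samples.items():
        paths = []
        for scan in scans:
            rel = f"spectra/{sid}_scan{scan.scan_index:02d}.csv"
            write_spectrum(scan, out_dir / rel)
            paths.append(rel)
        rows.append(ManifestRow(sample_id=sid, label=label, scan_paths=tuple(paths)))
    manifest_path = out_dir / "manifest.csv"
    write_manifest(Manifest(rows=rows), manifest_path)
    return manifest_path


def read_cohort(manifest_path: str | Path) -> SpectrumSet:
    """Load a cohort from its manifest, resolving scan paths relative to it."""
    manifest = read_manifest(manifest_path)
    base = Path(manifest_path).parent
    cohort = SpectrumSet(provenance=f"loaded from {Path(manifest_path).name}")
    for row in manifest.rows:
        scans = []
        for k, rel in enumerate(row.scan_paths):
            raw = read_spectrum(base / rel)
            scans.append(
                RamanSpectrum(
                    raw.wavenumber, raw.intensity,
                    sample_id=row.sample_id, scan_index=k, label=row.label,
                )
            )
        cohort.add_sample(row.sample_id, row.label, scans)
    return cohort


def write_ground_truth(truth: GroundTruth, path: str | Path) -> None:
    """Sidecar JSON of simulation ground truth; never read by the pipeline."""
    payload = {
        "sample_labels": truth.sample_labels,
        "sample_amplitudes": {
            sid: list(map(float, a)) for sid, a in truth.sample_amplitudes.items()
        },
        "scans": [
            {
                "sample_id": s.sample_id,
                "scan_index": s.scan_index,
                "spike_channels": [int(c) for c in s.spike_channels],
                "spike_amplitudes": [float(a) for a in s.spike_amplitudes],
            }
            for s in truth.scans
        ],
    }
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)


_CONFIG_TYPES = {
    "cohort": CohortConfig,
    "preprocess": PreprocessConfig,
    "cv": CVConfig,
}


def load_config(path: str | Path) -> dict[str, Any]:
    """Load a YAML config; recognized sections become config dataclasses.

    Top-level keys ``cohort``, ``preprocess`` and ``cv`` are instantiated
    as :class:`CohortConfig`, :class:`PreprocessConfig` and
    :class:`CVConfig`; unknown sections pass through as dicts.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"config not found: {path}")
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    out: dict[str, Any] = {}
    for key, value in raw.items():
        cls = _CONFIG_TYPES.get(key)
        if cls is not None and isinstance(value, dict):
            fields = {f.name for f in dataclasses.fields(cls)}
            unknown = set(value) - fields
            if unknown:
                raise ManifestError(f"{path}: unknown {key} keys {sorted(unknown)}")
            value = {
                k: tuple(v) if isinstance(v, list) else v for k, v in value.items()
            }
            out[key] = cls(**value)
        else:
            out[key] = value
    return out


def write_config(configs: dict[str, Any], path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    payload = {
        key: dataclasses.asdict(val) if dataclasses.is_dataclass(val) else val
        for key, val in configs.items()
    }
    payload = json.loads(json.dumps(payload))  # tuples -> lists, np -> native
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=True)


def write_metrics_table(result: CVResult | pd.DataFrame, path: str | Path) -> None:
    """Write the class x metric table (mean, std, 95% CI) as CSV."""
    table = result.metrics_table() if isinstance(result, CVResult) else result
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, index=False, float_format="%.6g")


def read_features(path: str | Path) -> tuple[np.ndarray, np.ndarray, np.ndarray, list[str]]:
    """Read a feature table written by :func:`write_features`."""
    df = pd.read_csv(path)
    labels = df["label"].to_numpy()
    sample_ids = df["sample_id"].tolist()
    chan_cols = [c for c in df.columns if c not in ("sample_id", "label")]
    wavenumbers = np.array([float(c) for c in chan_cols])
    return df[chan_cols].to_numpy(float), labels, wavenumbers, sample_ids


def write_features(
    features: np.ndarray,
    labels: np.ndarray,
    wavenumbers: np.ndarray,
    sample_ids: list[str],
    path: str | Path,
) -> None:
    """Write the sample x channel matrix with wavenumber header columns."""
    df = pd.DataFrame(features, columns=[f"{w:.6g}" for w in wavenumbers])
    df.insert(0, "label", labels)
    df.insert(0, "sample_id", sample_ids)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format="%.10g")


__all__ = [
    "Manifest",
    "ManifestRow",
    "ManifestError",
    "SpectrumParseError",
    "read_spectrum",
    "write_spectrum",
    "read_manifest",
    "write_manifest",
    "write_cohort",
    "read_cohort",
    "write_ground_truth",
    "load_config",
    "write_config",
    "write_metrics_table",
    "read_features",
    "write_features",
]
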