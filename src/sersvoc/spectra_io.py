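"""Spectral data model and plain-text I/O.

A SERS spectrum is a pair of equal-length arrays: Raman shift (cm^-1,
strictly increasing) and intensity (arbitrary counts), with optional
metadata (aldehyde class, analyte concentration as a v/v volume
fraction, replicate id).  Spectra are exchanged as two-column CSV and
collections are described by a manifest CSV; both dialects are fixed
(comma delimiter, decimal point, mandatory header) so files diff
cleanly across tools.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

#: Canonical class order used throughout: six gaseous aldehydes.
ALDEHYDE_CLASSES: tuple[str, ...] = (
    "formaldehyde",
    "benzaldehyde",
    "oxalaldehyde",
    "glutaraldehyde",
    "salicylaldehyde",
    "4-nitrobenzaldehyde",
)

#: Concentration helpers (dimensionless volume fractions).
PPM = 1e-6
PPB = 1e-9
PPT = 1e-12

#: Default acquisition axis: 1000-2300 cm^-1 sampled at 648 points.
AXIS_START = 1000.0
AXIS_STOP = 2300.0
AXIS_POINTS = 648

SPECTRUM_HEADER = ("raman_shift_cm1", "intensity")
MANIFEST_HEADER = ("path", "label", "concentration_vv", "replicate")


def default_axis() -> np.ndarray:
    """The default 648-point shift axis spanning 1000-2300 cm^-1."""
    return np.linspace(AXIS_START, AXIS_STOP, AXIS_POINTS)


@dataclass
class RamanSpectrum:
    """One spectrum: shift axis + intensities + optional metadata."""

    shift_axis: np.ndarray
    intensity: np.ndarray
    label: str | None = None
    concentration: float | None = None
    replicate_id: int | None = None

    def __post_init__(self) -> None:
        self.shift_axis = np.asarray(self.shift_axis, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.shift_axis.ndim != 1 or self.intensity.ndim != 1:
            raise ValueError("shift_axis and intensity must be 1-D")
        if self.shift_axis.size == 0:
            raise ValueError("zero-length spectrum forbidden")
        if self.shift_axis.shape != self.intensity.shape:
            raise ValueError(
                f"axis length {self.shift_axis.size} != intensity length "
                f"{self.intensity.size}"
            )
        if not np.all(np.isfinite(self.shift_axis)):
            raise ValueError("non-finite value in shift axis")
        if not np.all(np.isfinite(self.intensity)):
            raise ValueError("non-finite value in intensity")
        diffs = np.diff(self.shift_axis)
        if np.any(diffs <= 0):
            row = int(np.argmax(diffs <= 0)) + 1
            raise ValueError(
                f"axis not strictly increasing at row {row} "
                f"(shift {self.shift_axis[row]!r})"
            )

    def __len__(self) -> int:
        return int(self.shift_axis.size)


@dataclass
class SpectrumDataset:
    """Spectra on a shared axis; the unit of training and evaluation."""

    spectra: list[RamanSpectrum]
    class_set: tuple[str, ...] = ALDEHYDE_CLASSES

    def __post_init__(self) -> None:
        self.class_set = tuple(self.class_set)
        if self.spectra:
            axis = self.spectra[0].shift_axis
            for i, sp in enumerate(self.spectra):
                if not np.array_equal(sp.shift_axis, axis):
                    raise ValueError(f"spectrum {i} axis differs from spectrum 0")
        for i, sp in enumerate(self.spectra):
            if sp.label is not None and sp.label not in self.class_set:
                raise ValueError(f"unknown class {sp.label!r} in spectrum {i}")

    def __len__(self) -> int:
        return len(self.spectra)

    @property
    def axis(self) -> np.ndarray:
        if not self.spectra:
            return default_axis()
        return self.spectra[0].shift_axis

    def intensity_matrix(self) -> np.ndarray:
        """n_spectra x n_points intensity matrix (row order preserved)."""
        if not self.spectra:
            return np.empty((0, AXIS_POINTS))
        return np.vstack([sp.intensity for sp in self.spectra])

    def labels(self) -> list[str | None]:
        return [sp.label for sp in self.spectra]

    def concentrations(self) -> list[float | None]:
        return [sp.concentration for sp in self.spectra]


# ---------------------------------------------------------------------------
# File I/O


def read_spectrum(path: str | Path) -> RamanSpectrum:
    """Read a two-column spectrum CSV (``raman_shift_cm1,intensity``).

    Metadata is absent on the returned spectrum; it lives in the
    manifest, not the spectrum file.
    """
    path = Path(path)
    if not path.is_file():
        raise FileNotFoundError(f"spectrum file not found: {path}")
    df = pd.read_csv(path, dtype=str)
    if tuple(df.columns) != SPECTRUM_HEADER:
        raise ValueError(
            f"{path}: expected header {','.join(SPECTRUM_HEADER)}, "
            f"got {','.join(map(str, df.columns))}"
        )
    try:
        shift = df[SPECTRUM_HEADER[0]].astype(float).to_numpy()
        inten = df[SPECTRUM_HEADER[1]].astype(float).to_numpy()
    except ValueError:
        # locate the first bad row for the diagnostic
        for i, row in df.iterrows():
            for cell in row:
                try:
                    float(cell)
                except (TypeError, ValueError):
                    raise ValueError(
                        f"{path}: non-numeric value {cell!r} at data row {i + 1}"
                    ) from None
        raise
    try:
        return RamanSpectrum(shift, inten)
    except ValueError as exc:
        raise ValueError(f"{path}: {exc}") from None


def write_spectrum(spectrum: RamanSpectrum, path: str | Path) -> None:
    """Write the exact CSV dialect :func:`read_spectrum` accepts.

    Values are serialized with 17 significant digits so a round trip
    is exact on the axis and well below 1e-8 absolute on intensities.
    """
    path = Path(path)
    lines = [",".join(SPECTRUM_HEADER)]
    for s, y in zip(spectrum.shift_axis, spectrum.intensity):
        lines.append(f"{s:.17g},{y:.17g}")
    path.write_text("\n".join(lines) + "\n")


def _parse_optional_float(cell: object) -> float | None:
    if cell is None or (isinstance(cell, float) and math.isnan(cell)):
        return None
    text = str(cell).strip()
    if not text:
        return None
    return float(text)


def read_manifest(
    path: str | Path,
    class_set: tuple[str, ...] = ALDEHYDE_CLASSES,
) -> SpectrumDataset:
    """Load every spectrum listed in a manifest CSV, manifest order kept.

    Columns: ``path,label,concentration_vv,replicate``; empty fields
    mean absent metadata.  Relative spectrum paths resolve against the
    manifest's directory.
    """
    path = Path(path)
    if not path.is_file():
        raise FileNotFoundError(f"manifest not found: {path}")
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if tuple(df.columns) != MANIFEST_HEADER:
        raise ValueError(
            f"{path}: expected header {','.join(MANIFEST_HEADER)}, "
            f"got {','.join(map(str, df.columns))}"
        )
    spectra: list[RamanSpectrum] = []
    for i, row in df.iterrows():
        sp_path = Path(row["path"])
        if not sp_path.is_absolute():
            sp_path = path.parent / sp_path
        sp = read_spectrum(sp_path)
        label = row["label"].strip() or None
        if label is not None and label not in class_set:
            raise ValueError(f"{path} row {i + 1}: unknown class {label!r}")
        sp.label = label
        sp.concentration = _parse_optional_float(row["concentration_vv"])
        rep = row["replicate"].strip()
        sp.replicate_id = int(rep) if rep else None
        spectra.append(sp)
    return SpectrumDataset(spectra, class_set=class_set)


def write_manifest(rows: list[dict], path: str | Path) -> None:
    """Write a manifest CSV from dicts with the manifest columns."""
    path = Path(path)
    df = pd.DataFrame(rows, columns=list(MANIFEST_HEADER))
    df = df.fillna("")
    df.to_csv(path, index=False)


def save_dataset(dataset: SpectrumDataset, out_dir: str | Path) -> Path:
    """Write one CSV per spectrum plus ``manifest.csv``; returns its path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, sp in enumerate(dataset.spectra):
        name = f"spectrum_{i:04d}.csv"
        write_spectrum(sp, out_dir / name)
        rows.append(
            {
                "path": name,
                "label": sp.label or "",
                "concentration_vv": "" if sp.concentration is None else repr(sp.concentration),
                "replicate": "" if sp.replicate_id is None else sp.replicate_id,
            }
        )
    manifest = out_dir / "manifest.csv"
    write_manifest(rows, manifest)
    return manifest
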