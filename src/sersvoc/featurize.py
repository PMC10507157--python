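"""Band-wise peak-position features.

Each spectrum is partitioned into 12 Raman-shift bands — interior
edges 1030, 1152, 1174, 1195, 1280, 1350, 1410, 1450, 1522, 1545 and
1800 cm^-1 between the outer limits 1000 and 2300 — and the shift of
the highest intensity within each band is the feature.  Positions are
invariant to global intensity scaling and additive offsets, which is
what makes them robust classifier inputs for SERS data whose absolute
counts drift between acquisitions.

Bands are half-open [e_i, e_{i+1}) except the last, which is closed at
2300; within a band, ties break toward the lowest shift.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .spectra_io import RamanSpectrum, SpectrumDataset, default_axis

DEFAULT_BAND_EDGES: tuple[float, ...] = (
    1000.0, 1030.0, 1152.0, 1174.0, 1195.0, 1280.0, 1350.0,
    1410.0, 1450.0, 1522.0, 1545.0, 1800.0, 2300.0,
)


@dataclass(frozen=True)
class BandScheme:
    """12-band partition of the 1000-2300 cm^-1 axis (13 edges)."""

    edges: tuple[float, ...] = DEFAULT_BAND_EDGES

    def __post_init__(self) -> None:
        if len(self.edges) < 2:
            raise ValueError("need at least 2 edges")
        if any(b <= a for a, b in zip(self.edges, self.edges[1:])):
            raise ValueError("edges must be strictly increasing")

    @property
    def n_bands(self) -> int:
        return len(self.edges) - 1

    def band_index(self, shift: float) -> int:
        """Index of the band containing a shift; last band closed."""
        if shift < self.edges[0] or shift > self.edges[-1]:
            raise ValueError(f"shift {shift} outside scheme range")
        if shift == self.edges[-1]:
            return self.n_bands - 1
        return int(np.searchsorted(np.asarray(self.edges), shift, side="right")) - 1

    def band_masks(self, axis: np.ndarray) -> list[np.ndarray]:
        """Boolean membership of each axis point, per band."""
        masks = []
        for i in range(self.n_bands):
            lo, hi = self.edges[i], self.edges[i + 1]
            if i == self.n_bands - 1:
                m = (axis >= lo) & (axis <= hi)
            else:
                m = (axis >= lo) & (axis < hi)
            masks.append(m)
        return masks


@dataclass
class FeatureVector:
    """Per-band highest-peak positions (cm^-1) for one spectrum."""

    positions: np.ndarray
    label: str | None = None

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)


def build_band_scheme() -> BandScheme:
    """The canonical 13-edge / 12-band scheme."""
    return BandScheme()


def extract_features(spectrum: RamanSpectrum, scheme: BandScheme | None = None) -> FeatureVector:
    """Shift of the intensity maximum in each band; ties to lowest shift."""
    scheme = scheme or BandScheme()
    axis = spectrum.shift_axis
    positions = np.empty(scheme.n_bands)
    for i, mask in enumerate(scheme.band_masks(axis)):
        idx = np.flatnonzero(mask)
        if idx.size == 0:
            raise ValueError(f"empty band {i}: axis has no point in "
                             f"[{scheme.edges[i]}, {scheme.edges[i + 1]})")
        # np.argmax returns the first maximum -> lowest-shift tie-break
        positions[i] = axis[idx[np.argmax(spectrum.intensity[idx])]]
    return FeatureVector(positions, label=spectrum.label)


def normalize_features(fv: FeatureVector, scheme: BandScheme | None = None) -> FeatureVector:
    """Min-max scale each position to [0, 1] within its band."""
    scheme = scheme or BandScheme()
    edges = np.asarray(scheme.edges)
    scaled = (fv.positions - edges[:-1]) / (edges[1:] - edges[:-1])
    return FeatureVector(scaled, label=fv.label)


def featurize_dataset(
    dataset: SpectrumDataset,
    scheme: BandScheme | None = None,
    normalize: bool = False,
) -> pd.DataFrame:
    """n x 12 feature table (columns f01..f12) plus a label column."""
    scheme = scheme or BandScheme()
    cols = [f"f{i + 1:02d}" for i in range(scheme.n_bands)]
    rows, labels = [], []
    for sp in dataset.spectra:
        fv = extract_features(sp, scheme)
        if normalize:
            fv = normalize_features(fv, scheme)
        rows.append(fv.positions)
        labels.append(sp.label)
    df = pd.DataFrame(rows if rows else np.empty((0, scheme.n_bands)), columns=cols)
    df["label"] = labels if labels else pd.Series(dtype=object)
    return df


class BandPeakFeaturizer(TransformerMixin, BaseEstimator):
    """Transformer from intensity matrices to band peak positions.

    Parameters
    ----------
    edges : tuple of float
        Band edges (13 values for the canonical 12-band scheme).
    normalize : bool
        Min-max scale each position to [0, 1] within its band.
    axis : array-like or None
        Shared shift axis of the input rows; the default 648-point
        1000-2300 cm^-1 axis when None.
    """

    def __init__(self, edges: tuple[float, ...] = DEFAULT_BAND_EDGES,
                 normalize: bool = True, axis=None):
        self.edges = edges
        self.normalize = normalize
        self.axis = axis

    def fit(self, X, y=None):
        axis = np.asarray(self.axis, dtype=float) if self.axis is not None else default_axis()
        scheme = BandScheme(tuple(self.edges))
        masks = scheme.band_masks(axis)
        for i, m in enumerate(masks):
            if not m.any():
                raise ValueError(f"empty band {i}")
        self.axis_ = axis
        self.scheme_ = scheme
        self.band_indices_ = [np.flatnonzero(m) for m in masks]
        self.n_features_in_ = axis.size
        return self

    def transform(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        if X.shape[1] != self.axis_.size:
            raise ValueError("column count does not match the axis")
        out = np.empty((X.shape[0], self.scheme_.n_bands))
        for j, idx in enumerate(self.band_indices_):
            out[:, j] = self.axis_[idx[np.argmax(X[:, idx], axis=1)]]
        if self.normalize:
            edges = np.asarray(self.scheme_.edges)
            out = (out - edges[:-1]) / (edges[1:] - edges[:-1])
        return out
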