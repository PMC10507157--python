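"""Internal-standard ratiometric quantification.

The capture chemistry converts an aldehyde into an imine (Schiff base)
whose C=N stretch appears near 1625 cm^-1; an internal-standard (IS)
alkyne band at 1985 cm^-1 sits in the Raman-silent region and is
insensitive to the analyte.  The ratio I_1625/I_1985 cancels common
multiplicative fluctuations (laser power, focus, substrate-to-substrate
enhancement) and follows a log-linear law in concentration:

    I_1625 / I_1985 = k * log10(c) + b

Fitting that line by ordinary least squares gives the calibration; the
limit of detection (LOD) back-projects the blank ratio mean + 3 sd
through the line (signal-to-noise 3:1 convention).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin

from .spectra_io import RamanSpectrum, SpectrumDataset

ANALYTE_CENTER = 1625.0
IS_CENTER = 1985.0
#: Half-width of the peak-reading window, cm^-1: wider than typical
#: peak-center jitter, narrower than the spacing between bands.
HALF_WINDOW = 10.0


@dataclass
class CalibrationResult:
    slope: float
    intercept: float
    r_squared: float
    residual_sd: float
    n_points: int

    def __post_init__(self) -> None:
        if self.n_points < 3:
            raise ValueError("calibration needs at least 3 points")
        if not -1e-9 <= self.r_squared <= 1 + 1e-9:
            raise ValueError("r_squared outside [0, 1]")


@dataclass
class LodEstimate:
    lod: float
    snr_multiplier: float
    blank_mean: float
    blank_sd: float

    def __post_init__(self) -> None:
        if self.lod <= 0:
            raise ValueError("lod must be positive")
        if self.snr_multiplier <= 0:
            raise ValueError("snr_multiplier must be positive")

    @property
    def above_calibration_range(self) -> bool:
        """LOD at/above 1 v/v means the line never reaches the blank level."""
        return self.lod >= 1.0


def peak_intensity(
    spectrum: RamanSpectrum, center: float, half_window: float = HALF_WINDOW
) -> float:
    """Baseline-corrected peak height inside ``center +- half_window``.

    The local baseline is the straight line between the window's two
    edge samples; the reading is the maximum of (intensity - line)
    within the window, floored at zero.
    """
    axis = spectrum.shift_axis
    lo, hi = center - half_window, center + half_window
    if hi < axis[0] or lo > axis[-1]:
        raise ValueError(
            f"window [{lo}, {hi}] lies outside axis "
            f"[{axis[0]}, {axis[-1]}]"
        )
    mask = (axis >= lo) & (axis <= hi)
    idx = np.flatnonzero(mask)
    x = axis[idx]
    y = spectrum.intensity[idx]
    if x.size == 1:
        return max(float(y[0]), 0.0)
    # local edge-line baseline
    slope = (y[-1] - y[0]) / (x[-1] - x[0])
    baseline = y[0] + slope * (x - x[0])
    return max(float(np.max(y - baseline)), 0.0)


def ratiometric_signal(
    spectrum: RamanSpectrum,
    analyte_center: float = ANALYTE_CENTER,
    is_center: float = IS_CENTER,
    half_window: float = HALF_WINDOW,
) -> float:
    """I(analyte)/I(internal standard), both baseline-corrected."""
    denom = peak_intensity(spectrum, is_center, half_window)
    if denom <= 0:
        raise ValueError("internal standard absent (zero 1985 cm^-1 intensity)")
    num = peak_intensity(spectrum, analyte_center, half_window)
    return num / denom


class RatiometricCalibrator(RegressorMixin, BaseEstimator):
    """OLS fit of ratiometric signal against log10(concentration).

    Parameters
    ----------
    analyte_center, is_center, half_window : float
        Windows used when reading ratios straight from spectra.

    Attributes
    ----------
    slope_ : float
        Ratio units per decade of concentration.
    intercept_ : float
        Ratio at concentration 1 v/v.
    r_squared_ : float
        Coefficient of determination of the line.
    residual_sd_ : float
        Residual standard deviation (n - 2 degrees of freedom).
    n_points_ : int
    """

    def __init__(
        self,
        analyte_center: float = ANALYTE_CENTER,
        is_center: float = IS_CENTER,
        half_window: float = HALF_WINDOW,
    ):
        self.analyte_center = analyte_center
        self.is_center = is_center
        self.half_window = half_window

    def fit(self, X, y):
        """Fit on concentrations ``X`` (v/v, shape (n,) or (n,1)) and ratios ``y``."""
        conc = np.asarray(X, dtype=float).reshape(-1)
        ratios = np.asarray(y, dtype=float).reshape(-1)
        if conc.shape != ratios.shape:
            raise ValueError("X and y length mismatch")
        if np.any(conc <= 0):
            raise ValueError("concentrations must be positive (log undefined)")
        logc = np.log10(conc)
        if np.unique(np.round(logc, 12)).size < 3:
            raise ValueError("need at least 3 distinct concentrations")
        n = logc.size
        xm, ym = logc.mean(), ratios.mean()
        sxx = float(np.sum((logc - xm) ** 2))
        if sxx == 0:
            raise ValueError("zero variance in log-concentration")
        slope = float(np.sum((logc - xm) * (ratios - ym)) / sxx)
        intercept = ym - slope * xm
        resid = ratios - (slope * logc + intercept)
        ss_res = float(np.sum(resid**2))
        ss_tot = float(np.sum((ratios - ym) ** 2))
        self.slope_ = slope
        self.intercept_ = float(intercept)
        self.r_squared_ = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
        self.residual_sd_ = float(np.sqrt(ss_res / (n - 2)))
        self.n_points_ = n
        return self

    def fit_spectra(self, series: SpectrumDataset):
        """Fit from a calibration series of labeled spectra."""
        conc, ratios = [], []
        for sp in series.spectra:
            if sp.concentration is None:
                raise ValueError("calibration spectrum lacks a concentration")
            conc.append(sp.concentration)
            ratios.append(
                ratiometric_signal(
                    sp, self.analyte_center, self.is_center, self.half_window
                )
            )
        return self.fit(conc, ratios)

    def predict(self, X):
        conc = np.asarray(X, dtype=float).reshape(-1)
        return self.slope_ * np.log10(conc) + self.intercept_

    def result_(self) -> CalibrationResult:
        return CalibrationResult(
            slope=self.slope_,
            intercept=self.intercept_,
            r_squared=self.r_squared_,
            residual_sd=self.residual_sd_,
            n_points=self.n_points_,
        )


def fit_calibration(series: SpectrumDataset) -> CalibrationResult:
    """OLS of ratiometric signal on log10(concentration) over a series."""
    return RatiometricCalibrator().fit_spectra(series).result_()


def estimate_lod(
    calibration: CalibrationResult,
    blank_mean: float,
    blank_sd: float,
    multiplier: float = 3.0,
) -> LodEstimate:
    """LOD from the blank ratio distribution at signal-to-noise ``multiplier``.

    lod = 10 ** ((blank_mean + multiplier*blank_sd - intercept) / slope)
    """
    if calibration.slope <= 0:
        raise ValueError("calibration not invertible (non-positive slope)")
    if blank_sd < 0:
        raise ValueError("blank_sd must be non-negative")
    exponent = (blank_mean + multiplier * blank_sd - calibration.intercept) / calibration.slope
    return LodEstimate(
        lod=float(10.0**exponent),
        snr_multiplier=multiplier,
        blank_mean=blank_mean,
        blank_sd=blank_sd,
    )
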