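"""Synthetic SERS spectra of six gaseous aldehydes.

The generator emulates the statistical structure of aldehyde SERS
spectra captured on a 4-ATP / phenylacetylene-functionalized substrate:

* shared 4-ATP reporter bands at 1141, 1179 and 1593 cm^-1, identical
  across classes;
* an internal-standard (phenylacetylene alkyne) band at 1985 cm^-1 in
  the Raman-silent region;
* class-specific C=N (Schiff-base imine) bands — oxalaldehyde 1632,
  glutaraldehyde 1627, salicylaldehyde 1610, 4-nitrobenzaldehyde 1652,
  benzaldehyde 1625 cm^-1 — and class-specific C-C bands in
  1558–1589 cm^-1; formaldehyde carries no C=N band and its C-C band
  at 1585 cm^-1 is its analyte-responsive line;
* two synthetic "fingerprint" bands per class in the 1100–1500 cm^-1
  deformation/stretching region, where real aldehyde spectra differ
  most (positions here are package conventions, not literature values);
* erratic miscellaneous peaks placed uniformly in 1100–1500 cm^-1,
  Poisson-many per spectrum;
* Gaussian peak-center jitter, a polynomial baseline (degree <= 2) and
  additive white noise.

The analyte-responsive band's amplitude is solved so that the package's
own ratiometric reading I(C=N analog)/I(1985) equals the configured
log-linear law k*log10(c) + b (clipped at zero): the generator is
calibrated against the measurement operator, so a noise-free series
reproduces the law exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from functools import lru_cache

import numpy as np
from scipy.optimize import brentq

from . import quantify
from .spectra_io import (
    ALDEHYDE_CLASSES,
    AXIS_POINTS,
    AXIS_START,
    AXIS_STOP,
    RamanSpectrum,
    SpectrumDataset,
)

# ---------------------------------------------------------------------------
# Peak primitives


@dataclass(frozen=True)
class PeakSpec:
    """One spectral line: center (cm^-1), amplitude (>=0), FWHM, shape."""

    center: float
    amplitude: float
    fwhm: float = 12.0
    shape: str = "lorentzian"

    def __post_init__(self) -> None:
        if not AXIS_START <= self.center <= AXIS_STOP:
            raise ValueError(f"center {self.center} outside {AXIS_START}-{AXIS_STOP}")
        if self.fwhm <= 0:
            raise ValueError("fwhm must be positive")
        if self.amplitude < 0:
            raise ValueError("amplitude must be non-negative")
        if self.shape not in ("lorentzian", "gaussian"):
            raise ValueError(f"unknown shape {self.shape!r}")


def peak_profile(axis: np.ndarray, peak: PeakSpec) -> np.ndarray:
    """Evaluate one peak on the axis; unit height at its center."""
    d = axis - peak.center
    if peak.shape == "lorentzian":
        hwhm = peak.fwhm / 2.0
        return peak.amplitude / (1.0 + (d / hwhm) ** 2)
    return peak.amplitude * np.exp(-4.0 * math.log(2.0) * (d / peak.fwhm) ** 2)


def render_peaks(axis: np.ndarray, peaks: list[PeakSpec] | tuple[PeakSpec, ...]) -> np.ndarray:
    """Sum of peak profiles on the axis."""
    y = np.zeros_like(axis, dtype=float)
    for p in peaks:
        y += peak_profile(axis, p)
    return y


# ---------------------------------------------------------------------------
# Aldehyde signatures

#: Shared 4-ATP reporter bands (cm^-1 -> amplitude).  The 1593 band is
#: kept weak relative to the analyte C-C/C=N bands so the 1545-1800
#: region stays class-diagnostic.
REPORTER_PEAKS: tuple[PeakSpec, ...] = (
    PeakSpec(1141.0, 3.0),
    PeakSpec(1179.0, 2.5),
    PeakSpec(1593.0, 0.5),
)

#: Internal standard: phenylacetylene alkyne band, Raman-silent region.
#: Its amplitude sets the scale of the analyte C=N line (ratio law times
#: this); 3.0 keeps the C=N line clearly above the C-C / 1593-reporter
#: pileup at the discrimination concentration of 100 ppb.
IS_PEAK = PeakSpec(1985.0, 3.0)

_CC_AMPLITUDE = 0.7
_FINGERPRINT_AMPLITUDE = 1.2

# class -> (C=N center or None, C-C centers, fingerprint centers)
# C=N / C-C positions are the published assignments; fingerprint
# positions in 1100-1500 cm^-1 are synthetic conventions.
_SIGNATURE_TABLE: dict[str, tuple[float | None, tuple[float, ...], tuple[float, ...]]] = {
    "formaldehyde": (None, (1585.0,), (1245.0, 1465.0)),
    "benzaldehyde": (1625.0, (1574.0,), (1205.0, 1311.0)),
    "oxalaldehyde": (1632.0, (1575.0,), (1260.0, 1372.0)),
    "glutaraldehyde": (1627.0, (1588.0,), (1228.0, 1430.0)),
    "salicylaldehyde": (1610.0, (1587.0, 1571.0), (1212.0, 1480.0)),
    "4-nitrobenzaldehyde": (1652.0, (1558.0, 1588.0), (1268.0, 1341.0)),
}


@dataclass(frozen=True)
class AldehydeSignature:
    """Peak recipe for one aldehyde class.

    ``quant_center`` is the analyte-responsive line whose amplitude
    follows the concentration law: the C=N band where one exists, the
    C-C band for formaldehyde.
    """

    class_name: str
    characteristic_peaks: tuple[PeakSpec, ...]
    quant_center: float
    reporter_peaks: tuple[PeakSpec, ...] = REPORTER_PEAKS
    is_peak: PeakSpec = IS_PEAK

    def __post_init__(self) -> None:
        if not self.characteristic_peaks and self.quant_center is None:
            raise ValueError("signature needs at least one characteristic peak")

    def fixed_peaks(self) -> tuple[PeakSpec, ...]:
        """All concentration-independent peaks."""
        return self.reporter_peaks + (self.is_peak,) + self.characteristic_peaks

    def characteristic_centers(self) -> tuple[float, ...]:
        """Centers of class-specific peaks including the analyte line."""
        return tuple(p.center for p in self.characteristic_peaks) + (self.quant_center,)

    def strongest_characteristic_center(self, concentration: float, config: "GeneratorConfig") -> float:
        """Center of the strongest class-specific line in 1545-1800 cm^-1."""
        amp = quant_amplitude(self.class_name, concentration, config)
        best_c, best_a = self.quant_center, amp
        for p in self.characteristic_peaks:
            if 1545.0 <= p.center < 1800.0 and p.amplitude > best_a:
                best_c, best_a = p.center, p.amplitude
        return best_c


def build_aldehyde_library() -> dict[str, AldehydeSignature]:
    """Signatures for the six aldehyde classes, canonical order."""
    lib: dict[str, AldehydeSignature] = {}
    for name in ALDEHYDE_CLASSES:
        cn, cc, fp = _SIGNATURE_TABLE[name]
        peaks = []
        for i, center in enumerate(cc):
            # secondary split peak (salicylaldehyde, 4-nitrobenzaldehyde)
            # is weaker than the main C-C line
            amp = _CC_AMPLITUDE if i == 0 else 0.5
            # formaldehyde's C-C line is the analyte line, not fixed
            if cn is None and center == 1585.0:
                continue
            peaks.append(PeakSpec(center, amp))
        for center in fp:
            peaks.append(PeakSpec(center, _FINGERPRINT_AMPLITUDE))
        quant_center = cn if cn is not None else 1585.0
        lib[name] = AldehydeSignature(
            class_name=name,
            characteristic_peaks=tuple(peaks),
            quant_center=quant_center,
        )
    return lib


# ---------------------------------------------------------------------------
# Generator configuration

#: Largest nominal peak amplitude in the library (1141 reporter);
#: preset noise levels are expressed relative to it.
MAX_NOMINAL_AMPLITUDE = 3.0


@dataclass(frozen=True)
class GeneratorConfig:
    """Knobs of the synthetic-spectrum process.

    ``baseline_coeffs`` are polynomial coefficients (c0, c1, c2) in the
    reduced coordinate u = (shift - 1000)/1300, so the baseline stays
    O(c) across the axis regardless of units.
    """

    axis_start: float = AXIS_START
    axis_stop: float = AXIS_STOP
    n_points: int = AXIS_POINTS
    noise_sd: float = 0.03
    baseline_coeffs: tuple[float, ...] = (0.3, 0.4, -0.2)
    center_jitter_sd: float = 1.0
    misc_peak_rate: float = 1.0
    misc_amplitude_range: tuple[float, float] = (0.2, 0.8)
    misc_fwhm: float = 12.0
    response_slope: float = 0.5
    response_intercept: float = 4.0
    peak_shape: str = "lorentzian"
    n_batches: int = 4

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.misc_peak_rate < 0:
            raise ValueError("misc_peak_rate must be >= 0")
        if self.n_points < 13:
            raise ValueError("need at least 13 points (one per band)")
        if len(self.baseline_coeffs) > 3:
            raise ValueError("baseline degree must be <= 2")
        if self.misc_amplitude_range[0] > self.misc_amplitude_range[1]:
            raise ValueError("misc_amplitude_range must be (lo, hi)")

    def axis(self) -> np.ndarray:
        return np.linspace(self.axis_start, self.axis_stop, self.n_points)

    def baseline(self, axis: np.ndarray) -> np.ndarray:
        u = (axis - AXIS_START) / (AXIS_STOP - AXIS_START)
        y = np.zeros_like(axis, dtype=float)
        for k, c in enumerate(self.baseline_coeffs):
            y += c * u**k
        return y


def easy_config(**overrides) -> GeneratorConfig:
    """ppb-level spectral quality: mild jitter, 1% noise, sparse misc peaks."""
    cfg = GeneratorConfig(
        noise_sd=0.01 * MAX_NOMINAL_AMPLITUDE,
        center_jitter_sd=1.0,
        misc_peak_rate=1.0,
        misc_amplitude_range=(0.2, 0.8),
    )
    return replace(cfg, **overrides) if overrides else cfg


def hard_config(**overrides) -> GeneratorConfig:
    """ppt-level spectral quality: strong jitter, 10% noise, dense misc peaks."""
    cfg = GeneratorConfig(
        noise_sd=0.10 * MAX_NOMINAL_AMPLITUDE,
        center_jitter_sd=4.0,
        misc_peak_rate=5.0,
        misc_amplitude_range=(0.4, 1.5),
    )
    return replace(cfg, **overrides) if overrides else cfg


PRESETS = {"easy": easy_config, "hard": hard_config}


def expected_ratio(concentration: float, config: GeneratorConfig) -> float:
    """Target ratiometric signal: max(0, k*log10(c) + b); 0 for a blank."""
    if concentration < 0:
        raise ValueError("concentration must be >= 0")
    if concentration == 0:
        return 0.0
    return max(0.0, config.response_slope * math.log10(concentration) + config.response_intercept)


# ---------------------------------------------------------------------------
# Analyte amplitude calibrated against the measurement operator


@lru_cache(maxsize=4096)
def _quant_amplitude_cached(
    class_name: str, concentration: float, config: GeneratorConfig
) -> float:
    target = expected_ratio(concentration, config)
    if target == 0.0:
        return 0.0
    lib = build_aldehyde_library()
    sig = lib[class_name]
    axis = config.axis()
    fixed = render_peaks(axis, sig.fixed_peaks()) + config.baseline(axis)
    unit = peak_profile(axis, PeakSpec(sig.quant_center, 1.0, shape=config.peak_shape))

    def measured_minus_target(a: float) -> float:
        sp = RamanSpectrum(axis, fixed + a * unit)
        return (
            quantify.ratiometric_signal(sp, analyte_center=sig.quant_center)
            - target
        )

    lo, hi = 0.0, 1.0
    while measured_minus_target(hi) < 0 and hi < 1e6:
        hi *= 2.0
    if measured_minus_target(lo) >= 0:
        return 0.0  # contamination alone already reaches the target
    return float(brentq(measured_minus_target, lo, hi, xtol=1e-12, rtol=1e-14))


def quant_amplitude(class_name: str, concentration: float, config: GeneratorConfig) -> float:
    """Amplitude of the analyte line so the measured ratio hits the law."""
    return _quant_amplitude_cached(class_name, float(concentration), config)


# ---------------------------------------------------------------------------
# Spectrum and dataset generation


def generate_spectrum(
    class_name: str,
    concentration: float,
    config: GeneratorConfig,
    rng: np.random.Generator,
    library: dict[str, AldehydeSignature] | None = None,
    replicate_id: int | None = None,
) -> RamanSpectrum:
    """Draw one synthetic spectrum for a class at a concentration (v/v)."""
    lib = library if library is not None else build_aldehyde_library()
    if class_name not in lib:
        raise ValueError(f"unknown class {class_name!r}")
    if concentration < 0:
        raise ValueError("concentration must be >= 0")
    sig = lib[class_name]
    axis = config.axis()

    amp = quant_amplitude(class_name, concentration, config) if library is None else (
        expected_ratio(concentration, config) * sig.is_peak.amplitude
    )
    peaks = list(sig.fixed_peaks())
    if amp > 0:
        peaks.append(PeakSpec(sig.quant_center, amp, shape=config.peak_shape))

    y = np.zeros_like(axis)
    for p in peaks:
        jitter = rng.normal(0.0, config.center_jitter_sd) if config.center_jitter_sd > 0 else 0.0
        center = min(max(p.center + jitter, config.axis_start), config.axis_stop)
        y += peak_profile(axis, replace(p, center=center))

    n_misc = rng.poisson(config.misc_peak_rate) if config.misc_peak_rate > 0 else 0
    lo, hi = config.misc_amplitude_range
    for _ in range(n_misc):
        center = rng.uniform(1100.0, 1500.0)
        a = rng.uniform(lo, hi)
        y += peak_profile(axis, PeakSpec(center, a, fwhm=config.misc_fwhm))

    y += config.baseline(axis)
    if config.noise_sd > 0:
        y += rng.normal(0.0, config.noise_sd, size=axis.size)

    return RamanSpectrum(
        axis, y, label=class_name, concentration=concentration, replicate_id=replicate_id
    )


def _spectrum_rng(seed: int, class_index: int, sample_index: int) -> np.random.Generator:
    # one independent stream per (class, sample): adding spectra to one
    # class never perturbs another class's draws
    ss = np.random.SeedSequence(entropy=seed, spawn_key=(class_index, sample_index))
    return np.random.default_rng(ss)


def generate_dataset(
    n_per_class: int = 108,
    classes: tuple[str, ...] = ALDEHYDE_CLASSES,
    concentration: float = 1e-7,
    config: GeneratorConfig | None = None,
    seed: int = 0,
) -> SpectrumDataset:
    """Labeled dataset with exact per-class counts, reproducible by seed.

    Defaults mirror the discrimination experiment: 108 spectra per
    class at 100 ppb (1e-7 v/v), six classes, 648 spectra in total,
    replicate ids cycling over 4 independent measurement batches.
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    if not classes:
        raise ValueError("empty class list")
    cfg = config if config is not None else easy_config()
    spectra = []
    for ci, cls in enumerate(classes):
        for i in range(n_per_class):
            rng = _spectrum_rng(seed, ci, i)
            spectra.append(
                generate_spectrum(
                    cls,
                    concentration,
                    cfg,
                    rng,
                    replicate_id=i % cfg.n_batches,
                )
            )
    return SpectrumDataset(spectra, class_set=tuple(classes))


DEFAULT_CALIBRATION_SERIES = (1e-8, 1e-7, 1e-6, 1e-5, 1e-4)


def generate_calibration_series(
    concentrations: tuple[float, ...] = DEFAULT_CALIBRATION_SERIES,
    config: GeneratorConfig | None = None,
    seed: int = 0,
    n_replicates: int = 3,
    class_name: str = "benzaldehyde",
) -> SpectrumDataset:
    """Benzaldehyde dilution series spanning the calibration range."""
    if any(c <= 0 for c in concentrations):
        raise ValueError("calibration concentrations must be positive")
    cfg = config if config is not None else easy_config()
    spectra = []
    for li, conc in enumerate(concentrations):
        for r in range(n_replicates):
            rng = _spectrum_rng(seed, li, r)
            spectra.append(
                generate_spectrum(class_name, conc, cfg, rng, replicate_id=r)
            )
    return SpectrumDataset(spectra)
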