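"""Generator: signatures, peak math, determinism, calibration law."""

import numpy as np
import pytest

from sersvoc import quantify as q
from sersvoc import synthetic_data as sd
from sersvoc.spectra_io import ALDEHYDE_CLASSES, default_axis


class TestLibrary:
    def test_six_classes_with_reporters_and_is(self):
        lib = sd.build_aldehyde_library()
        assert tuple(lib) == ALDEHYDE_CLASSES
        for sig in lib.values():
            centers = {p.center for p in sig.fixed_peaks()}
            assert {1141.0, 1179.0, 1593.0, 1985.0} <= centers
            assert len(sig.characteristic_centers()) >= 1

    def test_characteristic_centers_pairwise_distinct(self):
        """No two classes share an identical multiset of class peaks."""
        lib = sd.build_aldehyde_library()
        multisets = {c: sorted(lib[c].characteristic_centers()) for c in lib}
        names = list(multisets)
        for i, a in enumerate(names):
            for b in names[i + 1:]:
                assert multisets[a] != multisets[b], (a, b)

    def test_published_cn_centers(self):
        lib = sd.build_aldehyde_library()
        assert lib["oxalaldehyde"].quant_center == 1632.0
        assert lib["glutaraldehyde"].quant_center == 1627.0
        assert lib["salicylaldehyde"].quant_center == 1610.0
        assert lib["4-nitrobenzaldehyde"].quant_center == 1652.0
        assert lib["benzaldehyde"].quant_center == 1625.0
        assert lib["formaldehyde"].quant_center == 1585.0  # C-C analog


class TestPeakMath:
    def test_on_grid_lorentzian_height_exact(self):
        axis = default_axis()
        center = axis[300]
        y = sd.render_peaks(axis, [sd.PeakSpec(center, 5.0, fwhm=10.0)])
        assert y[300] == 5.0

    def test_gaussian_height_and_fwhm(self):
        axis = np.linspace(1000, 2300, 2601)  # 0.5 cm-1 grid
        y = sd.render_peaks(axis, [sd.PeakSpec(1600.0, 2.0, fwhm=20.0, shape="gaussian")])
        i = np.argmin(np.abs(axis - 1600))
        assert y[i] == pytest.approx(2.0)
        at_half = np.argmin(np.abs(axis - 1610))
        assert y[at_half] == pytest.approx(1.0, rel=1e-6)

    def test_peakspec_validation(self):
        with pytest.raises(ValueError):
            sd.PeakSpec(900.0, 1.0)
        with pytest.raises(ValueError):
            sd.PeakSpec(1500.0, 1.0, fwhm=0.0)
        with pytest.raises(ValueError):
            sd.PeakSpec(1500.0, -1.0)


class TestGenerateSpectrum:
    def test_all_zero_amplitudes_yield_flat_spectrum(self, rng):
        zero_lib = {
            "benzaldehyde": sd.AldehydeSignature(
                class_name="benzaldehyde",
                characteristic_peaks=(sd.PeakSpec(1574.0, 0.0),),
                quant_center=1625.0,
                reporter_peaks=(),
                is_peak=sd.PeakSpec(1985.0, 0.0),
            )
        }
        cfg = sd.GeneratorConfig(noise_sd=0.0, baseline_coeffs=(),
                                 center_jitter_sd=0.0, misc_peak_rate=0.0)
        sp = sd.generate_spectrum("benzaldehyde", 1e-6, cfg, rng, library=zero_lib)
        assert np.all(sp.intensity == 0.0)

    def test_oxalaldehyde_local_max_at_1632(self, rng):
        cfg = sd.GeneratorConfig(noise_sd=0.0, center_jitter_sd=0.0, misc_peak_rate=0.0)
        sp = sd.generate_spectrum("oxalaldehyde", 1e-7, cfg, rng)
        i = int(np.argmin(np.abs(sp.shift_axis - 1632.0)))
        assert sp.intensity[i] > sp.intensity[i - 1]
        assert sp.intensity[i] > sp.intensity[i + 1]

    def test_rejects_unknown_class_and_negative_concentration(self, rng):
        cfg = sd.easy_config()
        with pytest.raises(ValueError, match="unknown class"):
            sd.generate_spectrum("acetone", 1e-7, cfg, rng)
        with pytest.raises(ValueError, match=">= 0"):
            sd.generate_spectrum("benzaldehyde", -1e-7, cfg, rng)

    def test_blank_has_no_analyte_line(self, rng):
        cfg = sd.GeneratorConfig(noise_sd=0.0, center_jitter_sd=0.0, misc_peak_rate=0.0)
        blank = sd.generate_spectrum("benzaldehyde", 0.0, cfg, rng)
        # ratio of a blank is the residual overlap contamination, far below 1
        assert q.ratiometric_signal(blank) < 0.05


class TestGenerateDataset:
    def test_default_counts_108_per_class(self, easy_dataset):
        assert len(easy_dataset) == 648
        labels = easy_dataset.labels()
        for cls in ALDEHYDE_CLASSES:
            assert sum(l == cls for l in labels) == 108

    def test_single_spectrum_dataset(self):
        ds = sd.generate_dataset(n_per_class=1, classes=("benzaldehyde",), seed=0)
        assert len(ds) == 1
        assert ds.spectra[0].label == "benzaldehyde"

    def test_determinism_same_seed(self):
        a = sd.generate_dataset(n_per_class=4, seed=11)
        b = sd.generate_dataset(n_per_class=4, seed=11)
        np.testing.assert_array_equal(a.intensity_matrix(), b.intensity_matrix())
        assert a.labels() == b.labels()
        assert [s.replicate_id for s in a.spectra] == [s.replicate_id for s in b.spectra]

    def test_different_seed_differs(self):
        a = sd.generate_dataset(n_per_class=2, seed=1)
        b = sd.generate_dataset(n_per_class=2, seed=2)
        assert not np.array_equal(a.intensity_matrix(), b.intensity_matrix())

    def test_class_streams_independent(self):
        """Adding spectra to one class leaves other classes' draws unchanged."""
        small = sd.generate_dataset(n_per_class=2, classes=("benzaldehyde", "oxalaldehyde"), seed=5)
        big = sd.generate_dataset(n_per_class=4, classes=("benzaldehyde", "oxalaldehyde"), seed=5)
        np.testing.assert_array_equal(
            small.spectra[2].intensity, big.spectra[4].intensity
        )

    def test_replicates_cycle_over_batches(self):
        ds = sd.generate_dataset(n_per_class=8, classes=("benzaldehyde",), seed=0)
        assert [s.replicate_id for s in ds.spectra] == [0, 1, 2, 3, 0, 1, 2, 3]

    def test_empty_class_list_rejected(self):
        with pytest.raises(ValueError, match="empty class list"):
            sd.generate_dataset(n_per_class=1, classes=(), seed=0)


class TestCalibrationSeries:
    def test_default_five_decades(self):
        ds = sd.generate_calibration_series(seed=0, n_replicates=1)
        assert sorted({s.concentration for s in ds.spectra}) == [1e-8, 1e-7, 1e-6, 1e-5, 1e-4]

    def test_zero_concentration_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            sd.generate_calibration_series(concentrations=(0.0, 1e-6, 1e-5))

    def test_noiseless_ratio_matches_law_exactly(self):
        cfg = sd.GeneratorConfig(noise_sd=0.0, center_jitter_sd=0.0, misc_peak_rate=0.0)
        ds = sd.generate_calibration_series(concentrations=(1e-6,), config=cfg,
                                            seed=0, n_replicates=1)
        # k*log10(1e-6) + b = 0.5*(-6) + 4 = 1.0
        assert q.ratiometric_signal(ds.spectra[0]) == pytest.approx(1.0, abs=1e-9)

    def test_mean_ratio_converges_to_law(self):
        """Mean measured ratio over 200 noisy replicates hits the law within 3 SE."""
        cfg = sd.easy_config(misc_peak_rate=0.0)
        ds = sd.generate_calibration_series(concentrations=(1e-6,), config=cfg,
                                            seed=7, n_replicates=200)
        ratios = np.array([q.ratiometric_signal(s) for s in ds.spectra])
        se = ratios.std(ddof=1) / np.sqrt(ratios.size)
        assert abs(ratios.mean() - 1.0) < 3 * se


class TestClassIdentifiability:
    def test_band_argmax_recovers_strongest_characteristic_peak(self):
        """With jitter <= 2 and no misc peaks, the 1545-1800 argmax locks
        onto each class's strongest class-specific line — the analyte
        C=N analog — for 100/100 spectra per class.  The expected
        position is the line's jittered center (replayed from the same
        random stream), matched to within the ~2 cm^-1 grid step."""
        cfg = sd.easy_config(center_jitter_sd=2.0, misc_peak_rate=0.0)
        lib = sd.build_aldehyde_library()
        grid_step = (2300.0 - 1000.0) / 647
        from sersvoc.featurize import extract_features

        for ci, cls in enumerate(ALDEHYDE_CLASSES):
            sig = lib[cls]
            assert sig.strongest_characteristic_center(1e-7, cfg) == sig.quant_center
            n_peaks = len(sig.fixed_peaks()) + 1  # analyte line drawn last
            for i in range(100):
                seed = [17, ci, i]
                sp = sd.generate_spectrum(
                    cls, 1e-7, cfg, np.random.default_rng(seed)
                )
                jitters = np.random.default_rng(seed).normal(0.0, 2.0, size=n_peaks)
                expected = sig.quant_center + jitters[-1]
                pos = extract_features(sp).positions[10]
                assert abs(pos - expected) <= 1.5 * grid_step, (cls, pos, expected)
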