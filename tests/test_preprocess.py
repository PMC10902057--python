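"""Preprocessing chain: alignment, TIC normalization, average spectrum,
peak picking, cube reduction."""

from dataclasses import replace

import numpy as np
import pytest

from lipidseg.cube import SpectraCube
from lipidseg.preprocess import (AverageSpectrum, align_spectra,
                                 average_spectrum, pick_peaks,
                                 preprocess_cube, reduce_cube, tic_normalize,
                                 tissue_mask)
from lipidseg.simulate import NOISELESS, simulate_cube


def _mini_cube(rows, mz=None):
    rows = np.atleast_2d(np.asarray(rows, float))
    mz = np.arange(rows.shape[1], dtype=float) + 550.0 if mz is None else mz
    coords = np.column_stack([np.zeros(len(rows), int), np.arange(len(rows))])
    return SpectraCube(mz=mz, intensities=rows, coords=coords,
                       shape=(1, len(rows)))


class TestTicNormalize:
    def test_arithmetic(self):
        out, tics, zero = tic_normalize(_mini_cube([[2, 3, 5]]))
        np.testing.assert_allclose(out.intensities[0], [0.2, 0.3, 0.5])
        assert tics[0] == 10 and not zero[0]

    def test_idempotent(self):
        once, _, _ = tic_normalize(_mini_cube([[2, 3, 5]]))
        twice, _, _ = tic_normalize(once)
        np.testing.assert_allclose(once.intensities, twice.intensities)

    def test_zero_pixel_flagged_not_raised(self):
        out, tics, zero = tic_normalize(_mini_cube([[0, 0, 0], [1, 1, 2]]))
        assert zero[0] and not zero[1]
        np.testing.assert_array_equal(out.intensities[0], 0)

    def test_rows_sum_to_one(self, noisy_cube):
        cube, _ = noisy_cube
        out, _, zero = tic_normalize(cube)
        sums = out.intensities[~zero].sum(axis=1)
        np.testing.assert_allclose(sums, 1.0, atol=1e-9)


class TestAlign:
    def test_zero_drift_estimates_zero(self, noiseless_cube):
        cube, _ = noiseless_cube
        _, res = align_spectra(cube, max_shift_ppm=10)
        assert np.abs(res.shifts_ppm).max() < 0.5  # within grid resolution

    def test_two_pixel_pm6ppm_recovered(self, noiseless_cube):
        """Two copies of a spectrum drifted by +6 and -6 ppm align to
        within +/-1 ppm of the injected shifts."""
        cube, truth = noiseless_cube
        lab = truth.pixel_labels(cube.coords)
        base = cube.intensities[np.flatnonzero(lab == 2)[0]]
        mz = cube.mz
        rows = np.vstack([
            np.interp(mz * (1 - 6e-6), mz, base),
            np.interp(mz * (1 + 6e-6), mz, base),
        ])
        two = _mini_cube(rows, mz=mz)
        _, res = align_spectra(two, max_shift_ppm=10)
        assert abs(res.shifts_ppm[0] - 6.0) < 1.0
        assert abs(res.shifts_ppm[1] + 6.0) < 1.0

    def test_drift_beyond_bound_saturates_and_flags(self, noiseless_cube):
        cube, truth = noiseless_cube
        lab = truth.pixel_labels(cube.coords)
        base = cube.intensities[np.flatnonzero(lab == 2)[0]]
        mz = cube.mz
        rows = np.vstack([base] * 4 + [np.interp(mz * (1 - 20e-6), mz, base)])
        c = _mini_cube(rows, mz=mz)
        _, res = align_spectra(c, max_shift_ppm=10)
        assert res.saturated[4]
        assert abs(res.shifts_ppm[4]) == pytest.approx(10.0, abs=0.5)

    def test_all_zero_pixel_flagged(self):
        c = _mini_cube([[1, 5, 1], [0, 0, 0]])
        _, res = align_spectra(c, max_shift_ppm=10)
        assert res.zero_pixels[1] and res.shifts_ppm[1] == 0.0


class TestAverage:
    def test_single_pixel_identity(self):
        c = _mini_cube([[1, 4, 2]])
        avg = average_spectrum(c)
        np.testing.assert_allclose(avg.intensity, [1, 4, 2])

    def test_linearity(self):
        x = np.array([1.0, 4.0, 2.0])
        avg = average_spectrum(_mini_cube([x, 3 * x]))
        np.testing.assert_allclose(avg.intensity, 2 * x)

    def test_empty_raises(self):
        c = _mini_cube([[1, 2, 3]])
        with pytest.raises(ValueError):
            average_spectrum(c, mask=np.array([False]))

    def test_noiseless_apexes_at_library_mz(self, noiseless_cube):
        cube, truth = noiseless_cube
        out, _, _ = tic_normalize(cube)
        avg = average_spectrum(out)
        for name, mu in truth.species_mz.items():
            sel = np.abs(avg.mz - mu) < 0.02   # inside this species' own peak
            apex = avg.mz[sel][np.argmax(avg.intensity[sel])]
            step = mu * 4e-6
            assert abs(apex - mu) <= step / 2 + 1e-9, name


class TestPickPeaks:
    def _spiky(self, heights, gap=20):
        n = gap * (len(heights) + 1)
        y = np.zeros(n)
        mz = 550 + np.arange(n) * 0.01
        for i, h in enumerate(heights):
            y[gap * (i + 1)] = h
        return AverageSpectrum(mz=mz, intensity=y)

    def test_threshold_arithmetic(self):
        peaks = pick_peaks(self._spiky([1000, 6, 4]), threshold_fraction=0.005,
                           smooth_window=1)
        assert len(peaks) == 2                      # cutoff = 5 keeps 1000 and 6
        np.testing.assert_allclose(peaks.intensity, [1000, 6])

    def test_zero_threshold_keeps_all_maxima(self):
        peaks = pick_peaks(self._spiky([1000, 6, 4]), threshold_fraction=0.0,
                           smooth_window=1)
        assert len(peaks) == 3

    def test_lower_threshold_gives_superset(self, noiseless_cube):
        cube, _ = noiseless_cube
        avg = average_spectrum(cube)
        tight = set(pick_peaks(avg, 0.01).mz)
        loose = set(pick_peaks(avg, 0.005).mz)
        assert tight <= loose

    def test_flat_spectrum_empty(self):
        flat = AverageSpectrum(mz=np.arange(10.0) + 550, intensity=np.ones(10))
        assert len(pick_peaks(flat)) == 0

    def test_finds_every_simulated_species(self, noiseless_cube):
        cube, truth = noiseless_cube
        out, _, _ = tic_normalize(cube)
        mask = tissue_mask(cube.tic())
        peaks = pick_peaks(average_spectrum(out, mask))
        assert len(peaks) == len(truth.species_mz)


class TestReduce:
    def test_no_signal_gives_zero(self):
        c = _mini_cube([[5, 0, 0]])
        from lipidseg.preprocess import PeakList
        pl = PeakList(mz=np.array([550.0, 552.0]), intensity=np.array([5.0, 1.0]))
        fm = reduce_cube(c, pl, tol_ppm=100)
        assert fm.values[0, 0] == 5 and fm.values[0, 1] == 0

    def test_tolerance_monotonicity(self, noisy_cube):
        cube, _ = noisy_cube
        from lipidseg.preprocess import PeakList
        mus = np.sort(cube.mz[np.argsort(cube.intensities.sum(0))[-200:]])[::5]
        pl = PeakList(mz=mus, intensity=np.ones(len(mus)))
        small = reduce_cube(cube, pl, tol_ppm=3).values
        large = reduce_cube(cube, pl, tol_ppm=6).values
        assert (large >= small - 1e-12).all()

    def test_feature_rows_capture_at_most_unit_tic(self, noisy_cube):
        """After TIC normalization every feature row sums to at most the
        captured fraction of total signal (<= 1)."""
        cube, _ = noisy_cube
        pp = preprocess_cube(cube)
        sums = pp["features"].values.sum(axis=1)
        assert (sums <= 1.0 + 1e-9).all()
        assert sums.max() > 0.1


def test_pipeline_order_normalize_average_commute_for_equal_tics():
    """When all pixels share the same TIC, normalizing before or after
    averaging changes the average only by that scalar."""
    x = np.array([4.0, 3.0, 3.0])
    y = np.array([1.0, 7.0, 2.0])          # same TIC = 10
    c = _mini_cube([x, y])
    avg_then = average_spectrum(c).intensity / 10.0
    norm, _, _ = tic_normalize(c)
    then_avg = average_spectrum(norm).intensity
    np.testing.assert_allclose(avg_then, then_avg, atol=1e-12)


def test_end_to_end_noiseless_recovery(noiseless_cube):
    """Cosine similarity between each region's mean feature row and its
    template exceeds 0.999 on the noiseless phantom."""
    cube, truth = noiseless_cube
    pp = preprocess_cube(cube)
    fm = pp["features"]
    lab = truth.labels[fm.coords[:, 0], fm.coords[:, 1]]
    names = sorted(truth.species_mz, key=truth.species_mz.get)
    for region, tmpl in truth.templates.items():
        rows = fm.values[lab == region]
        if len(rows) == 0:
            continue
        mean = rows.mean(axis=0)
        expected = tmpl.vector(names)
        cos = mean @ expected / np.linalg.norm(mean) / np.linalg.norm(expected)
        assert cos > 0.999
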