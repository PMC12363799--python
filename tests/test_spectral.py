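import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from alffkit import (
    BandSpec,
    FrequencyIndex,
    am_alff,
    am_falff,
    amplitude_spectrum,
    band_indices,
    demean,
    qm_alff_freq,
    qm_falff_freq,
)

from conftest import cosines, series_from
from _oracles import (
    am_alff_ref,
    am_falff_ref,
    naive_dft_amplitude,
    nearest_bin_ref,
    qm_alff_ref,
    qm_falff_ref,
)


def _metrics(data, tr, band=None):
    band = band or BandSpec()
    dm = demean(series_from(data, tr=tr))
    spec = amplitude_spectrum(dm)
    idx = band_indices(band, dm.n_timepoints, dm.tr)
    return {
        "amALFF": am_alff(spec, idx).values,
        "qmALFF": qm_alff_freq(spec, idx).values,
        "amfALFF": am_falff(spec, idx).values,
        "qmfALFF": qm_falff_freq(spec, idx).values,
    }, idx


class TestDemean:
    def test_removes_mean_and_stores_it(self):
        out = demean(series_from([[3.0, 5.0, 7.0] * 4]))
        assert np.allclose(out.data[0][:3], [-2.0, 0.0, 2.0])
        assert out.voxel_means[0] == 5.0
        assert out.demeaned

    def test_idempotent(self):
        rng = np.random.default_rng(0)
        once = demean(series_from(rng.normal(size=(5, 32))))
        twice = demean(once)
        assert twice is once

    def test_mbi_survives_demeaning(self):
        rng = np.random.default_rng(1)
        raw = series_from(rng.normal(size=(5, 32)) + 100.0)
        assert np.array_equal(demean(raw).temporal_means(), raw.temporal_means())


class TestBandIndices:
    def test_exact_grid_alignment(self):
        idx = band_indices(BandSpec(), n=100, tr=1.0)
        assert (idx.k_fl, idx.k_fh) == (1, 8)
        assert idx.delta_f == 0.01

    @pytest.mark.parametrize("n,tr", [(230, 2.5), (1200, 0.72), (97, 1.3)])
    def test_matches_exhaustive_argmin(self, n, tr):
        band = BandSpec()
        idx = band_indices(band, n=n, tr=tr)
        assert idx.k_fl == max(nearest_bin_ref(band.fl, n, tr), 1)
        assert idx.k_fh == nearest_bin_ref(band.fh, n, tr)
        assert idx.k_fc == nearest_bin_ref(band.fc, n, tr)

    def test_dc_bin_never_enters_band(self):
        # fl far below the resolution still maps to bin 1
        idx = band_indices(BandSpec(fl=1e-5, fh=0.08), n=64, tr=2.0)
        assert idx.k_fl == 1

    def test_tie_rounds_toward_larger_k(self):
        # n*tr = 100 s; f = 0.015 sits exactly between bins 1 and 2
        idx = band_indices(BandSpec(fl=0.015, fh=0.08), n=50, tr=2.0)
        assert idx.k_fl == 2

    def test_band_above_nyquist_rejected(self):
        with pytest.raises(ValueError, match="Nyquist"):
            band_indices(BandSpec(fc=0.3), n=100, tr=2.0)  # Nyquist 0.25

    def test_invalid_band_ordering_rejected(self):
        with pytest.raises(ValueError, match="fl < fh"):
            BandSpec(fl=0.08, fh=0.01)


class TestAmplitudeSpectrum:
    def test_zero_row_gives_zero_spectrum(self):
        spec = amplitude_spectrum(series_from(np.zeros((1, 64)), demeaned=True))
        assert np.all(spec.amplitudes == 0)

    def test_bin_aligned_cosine_closed_form(self):
        # amplitude A=2 at bin k0: |FFT| = A*n/2 there, ~0 elsewhere
        n, tr, k0 = 100, 1.0, 4
        data = cosines([(k0 / (n * tr), 2.0, 0.0)], n=n, tr=tr)
        spec = amplitude_spectrum(demean(series_from(data, tr=tr)))
        assert spec.amplitudes[0, k0] == pytest.approx(100.0, rel=1e-12)
        others = np.delete(spec.amplitudes[0], k0)
        assert np.all(others < 1e-9 * spec.amplitudes[0, k0])

    @pytest.mark.parametrize("n", [64, 63])  # even and odd lengths
    def test_matches_naive_dft(self, n):
        rng = np.random.default_rng(2)
        dm = demean(series_from(rng.normal(size=(3, n))))
        spec = amplitude_spectrum(dm)
        for row, amp in zip(dm.data, spec.amplitudes):
            ref = naive_dft_amplitude(row)
            np.testing.assert_allclose(amp, ref, rtol=1e-9, atol=1e-9)

    def test_requires_demeaned_input(self, random_series):
        with pytest.raises(ValueError, match="demeaned"):
            amplitude_spectrum(random_series)

    def test_dc_bin_vanishes_after_demeaning(self, random_series):
        spec = amplitude_spectrum(demean(random_series))
        assert np.all(
            spec.amplitudes[:, 0] <= 1e-8 * spec.amplitudes.max(axis=1)
        )


class TestClosedFormMetrics:
    """Noiseless bin-aligned cosines against hand-derived values."""

    def test_single_cosine_in_eight_bin_band(self):
        # A=2 at 0.04 Hz; n=100, tr=1 -> band bins 1..8
        vals, _ = _metrics(cosines([(0.04, 2.0, 0.0)], n=100, tr=1.0), tr=1.0)
        assert vals["amALFF"][0] == pytest.approx(0.25, rel=1e-9)
        assert vals["qmALFF"][0] == pytest.approx(2 / np.sqrt(8), rel=1e-9)
        assert vals["amfALFF"][0] == pytest.approx(1.0, rel=1e-9)
        assert vals["qmfALFF"][0] == pytest.approx(1.0, rel=1e-9)

    def test_two_equal_cosines_split_fractional_metrics(self):
        # one in band (0.0375 Hz = bin 18), one outside it but below fc
        # (0.15 Hz = bin 72); both bin-aligned at n=240, tr=2
        data = cosines([(0.0375, 1.0, 0.0), (0.15, 1.0, 0.0)], n=240, tr=2.0)
        vals, _ = _metrics(data, tr=2.0)
        assert vals["amfALFF"][0] == pytest.approx(0.5, rel=1e-9)
        assert vals["qmfALFF"][0] == pytest.approx(1 / np.sqrt(2), rel=1e-9)

    def test_zero_signal_maps_to_zero_alff(self):
        dm = series_from(np.zeros((1, 64)), demeaned=True)
        spec = amplitude_spectrum(dm)
        idx = band_indices(BandSpec(), 64, 2.0)
        assert am_alff(spec, idx).values[0] == 0.0
        assert qm_alff_freq(spec, idx).values[0] == 0.0

    def test_flat_spectrum_guard_yields_nan_with_warning(self):
        dm = series_from(np.zeros((1, 64)), demeaned=True)
        spec = amplitude_spectrum(dm)
        idx = band_indices(BandSpec(), 64, 2.0)
        with pytest.warns(UserWarning, match="zero spectral energy"):
            out = am_falff(spec, idx)
        assert np.isnan(out.values[0])


class TestOracleEquivalence:
    @pytest.mark.parametrize("n,tr", [(128, 2.0), (96, 2.0), (101, 2.0)])
    def test_fast_path_matches_naive_dft_metrics(self, n, tr):
        rng = np.random.default_rng(3)
        dm = demean(series_from(rng.normal(size=(10, n)), tr=tr))
        vals, idx = _metrics(dm.data, tr=tr)
        for row, am, qm, amf, qmf in zip(
            dm.data, vals["amALFF"], vals["qmALFF"],
            vals["amfALFF"], vals["qmfALFF"],
        ):
            amp = naive_dft_amplitude(row)
            assert am == pytest.approx(
                am_alff_ref(amp, n, idx.k_fl, idx.k_fh), rel=1e-9)
            assert qm == pytest.approx(
                qm_alff_ref(amp, n, idx.k_fl, idx.k_fh), rel=1e-9)
            assert amf == pytest.approx(
                am_falff_ref(amp, idx.k_fl, idx.k_fh, idx.k_fc), rel=1e-9)
            assert qmf == pytest.approx(
                qm_falff_ref(amp, idx.k_fl, idx.k_fh, idx.k_fc), rel=1e-9)


class TestScaleCovariance:
    @given(c=st.floats(0.01, 100.0))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_alff_scales_falff_does_not(self, c):
        rng = np.random.default_rng(4)
        data = rng.normal(size=(5, 96))
        base, _ = _metrics(data, tr=2.0)
        scaled, _ = _metrics(c * data, tr=2.0)
        np.testing.assert_allclose(scaled["amALFF"], c * base["amALFF"], rtol=1e-10)
        np.testing.assert_allclose(scaled["qmALFF"], c * base["qmALFF"], rtol=1e-10)
        np.testing.assert_allclose(scaled["amfALFF"], base["amfALFF"], rtol=1e-10)
        np.testing.assert_allclose(scaled["qmfALFF"], base["qmfALFF"], rtol=1e-10)


class TestOrderingAndBounds:
    def test_qm_at_least_am_with_equality_only_for_flat_band(self, random_series):
        vals, _ = _metrics(random_series.data, tr=2.0)
        assert np.all(vals["qmALFF"] >= vals["amALFF"] * (1 - 1e-12))
        # random spectra are never exactly flat across the band
        assert np.all(vals["qmALFF"] > vals["amALFF"])

    def test_single_bin_spectrum_gives_equality_times_band_width(self):
        # all in-band energy at one bin: qm = am * sqrt(n_band)
        data = cosines([(0.04, 1.0, 0.0)], n=100, tr=1.0)
        vals, idx = _metrics(data, tr=1.0)
        assert vals["qmALFF"][0] == pytest.approx(
            vals["amALFF"][0] * np.sqrt(idx.n_band), rel=1e-9)

    def test_fractional_metrics_bounded(self, random_series):
        vals, _ = _metrics(random_series.data, tr=2.0)
        for key in ("amfALFF", "qmfALFF"):
            assert np.all(vals[key] >= 0)
            assert np.all(vals[key] <= 1 + 1e-12)


class TestParseval:
    @pytest.mark.parametrize("n", [64, 65])
    def test_total_one_sided_power_equals_time_energy(self, n):
        rng = np.random.default_rng(5)
        dm = demean(series_from(rng.normal(size=(8, n))))
        spec = amplitude_spectrum(dm)
        # sum over ALL bins of S^2/n, rebuilding the two-sided sum
        s2 = spec.amplitudes**2
        weights = np.full(spec.n_bins, 2.0)
        weights[0] = 1.0
        if n % 2 == 0:
            weights[-1] = 1.0
        freq_energy = (s2 * weights).sum(axis=1) / n
        time_energy = (dm.data**2).sum(axis=1)
        np.testing.assert_allclose(freq_energy, time_energy, rtol=1e-9)


class TestFrequencyIndexContract:
    def test_inconsistent_n_rejected(self, random_series):
        spec = amplitude_spectrum(demean(random_series))
        idx = band_indices(BandSpec(), n=128, tr=2.0)
        with pytest.raises(ValueError, match="n="):
            am_alff(spec, idx)

    def test_invariant_violations_rejected(self):
        with pytest.raises(ValueError, match="k_fl"):
            FrequencyIndex(k_fl=0, k_fh=8, k_fc=20, n=100, delta_f=0.01)
        with pytest.raises(ValueError, match="k_fl"):
            FrequencyIndex(k_fl=9, k_fh=8, k_fc=20, n=100, delta_f=0.01)
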