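"""Spectral quantification: Welch epochs, band integration, IQR outlier
masking, median normalization, state summaries, theta peak."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import somnospec as sp
from somnospec.bands import DEFAULT_BANDS, BandDefinition
from somnospec.recording import Recording
from somnospec.spectral import (
    BandPowerTable,
    CapabilityError,
    EpochSpectra,
    _parabolic_peak,
)


def make_recording(data, fs=1000.0, n_accel=0):
    data = np.atleast_2d(data)
    names = [f"EEG Front{i}" for i in range(data.shape[0])]
    roles = ["frontal"] * data.shape[0]
    for i in range(n_accel):
        names.append(f"ACC {i}")
        roles.append("accelerometer")
    if n_accel:
        data = np.vstack([data, np.zeros((n_accel, data.shape[1]))])
    return Recording(data=data, sample_rate=fs, channel_names=names,
                     channel_roles=roles)


def make_spectra(power, freqs=None, roles=None):
    power = np.asarray(power, dtype=float)
    n_ep, n_ch, n_f = power.shape
    freqs = np.arange(n_f, dtype=float) if freqs is None else np.asarray(freqs)
    roles = roles or ["frontal"] * n_ch
    return EpochSpectra(
        times=np.arange(n_ep, dtype=float), freqs=freqs, power=power,
        channel_names=[f"ch{i}" for i in range(n_ch)], channel_roles=roles,
    )


class TestComputeEpochSpectra:
    def test_sinusoid_peak_at_seven_hz(self):
        fs = 1000.0
        t = np.arange(10 * int(fs)) / fs
        rec = make_recording(np.sin(2 * np.pi * 7.0 * t))
        spectra = sp.compute_epoch_spectra(rec)
        assert spectra.n_epochs == 10
        res = spectra.freqs[1] - spectra.freqs[0]
        for ep in range(10):
            peak = spectra.freqs[np.argmax(spectra.power[ep, 0])]
            assert abs(peak - 7.0) <= res

    def test_zero_signal_zero_power(self):
        rec = make_recording(np.zeros(3 * 1000))
        spectra = sp.compute_epoch_spectra(rec)
        assert np.all(spectra.power == 0)

    def test_low_sample_rate_names_missing_bands(self):
        rec = make_recording(np.zeros(1000), fs=200.0)
        with pytest.raises(CapabilityError, match="ripple"):
            sp.compute_epoch_spectra(rec)

    def test_trailing_partial_epoch_dropped(self):
        rec = make_recording(np.zeros(2500), fs=1000.0)
        assert sp.compute_epoch_spectra(rec).n_epochs == 2

    def test_white_noise_spectrum_is_flat_across_bands(self):
        rng = np.random.default_rng(0)
        rec = make_recording(rng.standard_normal(120 * 400), fs=400.0)
        table = sp.integrate_bands(sp.compute_epoch_spectra(rec))
        means = table.raw.mean(axis=(0, 1))
        assert means.max() / means.min() < 1.2


class TestIntegrateBands:
    def test_flat_psd_gives_constant_band_power(self):
        freqs = np.arange(0, 200.0, 2.0)
        power = np.full((3, 2, len(freqs)), 1.7)
        table = sp.integrate_bands(make_spectra(power, freqs))
        assert np.allclose(table.raw, 1.7)

    def test_single_bin_hits_only_beta(self):
        freqs = np.arange(0, 200.0, 1.0)
        power = np.zeros((2, 1, len(freqs)))
        power[:, :, 25] = 5.0
        table = sp.integrate_bands(make_spectra(power, freqs))
        by_name = dict(zip(table.band_names, table.raw[0, 0]))
        assert by_name["beta"] > 0
        for name in ("delta", "theta", "spindle", "gamma", "ripple"):
            assert by_name[name] == 0

    def test_toy_table_matches_hand_averages(self):
        freqs = np.array([1.0, 2.0, 3.0, 5.0, 7.0])
        bands = (BandDefinition("lo", 0.5, 3.0), BandDefinition("hi", 4.0, 8.0))
        power = np.arange(3 * 1 * 5, dtype=float).reshape(3, 1, 5)
        table = sp.integrate_bands(make_spectra(power, freqs), bands)
        # hand: lo = mean of bins 0-2, hi = mean of bins 3-4
        for ep in range(3):
            assert table.raw[ep, 0, 0] == pytest.approx(power[ep, 0, :3].mean())
            assert table.raw[ep, 0, 1] == pytest.approx(power[ep, 0, 3:].mean())

    def test_band_without_bins_is_an_error(self):
        freqs = np.array([0.0, 50.0, 100.0, 150.0, 200.0])
        power = np.ones((2, 1, 5))
        with pytest.raises(ValueError, match="delta"):
            sp.integrate_bands(make_spectra(power, freqs))

    def test_band_integration_is_linear(self):
        rng = np.random.default_rng(1)
        freqs = np.arange(0, 200.0, 2.0)
        p1 = rng.random((4, 2, len(freqs)))
        p2 = rng.random((4, 2, len(freqs)))
        a, b = 2.5, -0.5
        t1 = sp.integrate_bands(make_spectra(p1, freqs)).raw
        t2 = sp.integrate_bands(make_spectra(p2, freqs)).raw
        t3 = sp.integrate_bands(make_spectra(a * p1 + b * p2, freqs)).raw
        assert np.allclose(t3, a * t1 + b * t2)


def brute_quantile(values, q):
    """Independent linear-interpolation quantile (sort + interpolate)."""
    v = sorted(values)
    h = (len(v) - 1) * q
    lo = int(np.floor(h))
    hi = min(lo + 1, len(v) - 1)
    return v[lo] + (h - lo) * (v[hi] - v[lo])


def brute_outlier_mask(raw, k):
    """Reference implementation of the per-channel any-band IQR rule."""
    n_ep, n_ch, n_b = raw.shape
    mask = np.zeros((n_ep, n_ch), dtype=bool)
    for ci in range(n_ch):
        for bi in range(n_b):
            col = raw[:, ci, bi]
            q1 = brute_quantile(col, 0.25)
            q3 = brute_quantile(col, 0.75)
            iqr = q3 - q1
            for ep in range(n_ep):
                if col[ep] > q3 + k * iqr or col[ep] < q1 - k * iqr:
                    mask[ep, ci] = True
    return mask


def table_from_raw(raw):
    raw = np.asarray(raw, dtype=float)
    n_ep, n_ch, n_b = raw.shape
    return BandPowerTable(
        times=np.arange(n_ep, dtype=float), bands=DEFAULT_BANDS[:n_b], raw=raw,
        channel_names=[f"ch{i}" for i in range(n_ch)],
        channel_roles=["frontal"] * n_ch,
    )


class TestFlagOutliers:
    def test_constant_series_masks_nothing(self):
        table = sp.flag_outliers(table_from_raw(np.ones((50, 2, 3))))
        assert not table.outlier.any()

    def test_single_spike_is_masked_exactly(self):
        """Place one epoch above Q3 + 15*IQR computed by the independent
        brute-force quantile routine; exactly that epoch must be masked."""
        rng = np.random.default_rng(2)
        raw = 1.0 + 0.01 * rng.random((1000, 1, 1))
        q1 = brute_quantile(raw[:, 0, 0], 0.25)
        q3 = brute_quantile(raw[:, 0, 0], 0.75)
        spike_value = q3 + 16 * (q3 - q1)
        raw[123, 0, 0] = spike_value
        table = sp.flag_outliers(table_from_raw(raw))
        expected = brute_outlier_mask(raw, 15.0)
        assert np.array_equal(table.outlier, expected)
        assert table.outlier[123, 0] and table.outlier.sum() == expected.sum()

    def test_normal_tail_fraction_matches_closed_form(self):
        """k=0.5 on a standard-normal sample: the masked fraction matches
        2 * P(Z > Q3 + 0.5*IQR) with the normal quartiles."""
        from scipy.stats import norm

        rng = np.random.default_rng(3)
        raw = rng.standard_normal((10_000, 1, 1))
        table = sp.flag_outliers(table_from_raw(raw), k=0.5)
        q3 = norm.ppf(0.75)
        expected = 2 * norm.sf(q3 + 0.5 * (2 * q3))
        assert table.outlier.mean() == pytest.approx(expected, rel=0.15)

    def test_masking_is_idempotent(self, normalized_table):
        before = normalized_table.outlier.copy()
        again = sp.flag_outliers(normalized_table)
        assert np.array_equal(before, again.outlier)

    def test_nonpositive_k_rejected(self):
        with pytest.raises(ValueError, match="k"):
            sp.flag_outliers(table_from_raw(np.ones((10, 1, 1))), k=0)

    def test_too_few_epochs_rejected(self):
        with pytest.raises(ValueError, match="4 epochs"):
            sp.flag_outliers(table_from_raw(np.ones((3, 1, 1))))

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_matches_brute_force_on_random_tables(self, seed):
        rng = np.random.default_rng(seed)
        raw = rng.lognormal(0.0, 2.0, size=(50, 2, 3))
        table = sp.flag_outliers(table_from_raw(raw), k=1.0)
        assert np.array_equal(table.outlier, brute_outlier_mask(raw, 1.0))


class TestNormalizePower:
    def test_known_median(self):
        raw = np.array([1.0, 2, 3, 4, 5]).reshape(5, 1, 1)
        table = sp.normalize_power(sp.flag_outliers(table_from_raw(raw)))
        assert np.allclose(table.normalized[:, 0, 0],
                           [1 / 3, 2 / 3, 1.0, 4 / 3, 5 / 3])

    def test_median_of_normalized_is_one(self, normalized_table):
        t = normalized_table
        for ci in range(t.raw.shape[1]):
            ok = ~t.outlier[:, ci]
            med = np.median(t.normalized[ok, ci, :], axis=0)
            assert np.allclose(med, 1.0, atol=1e-9)

    def test_scale_invariance(self):
        rng = np.random.default_rng(4)
        raw = rng.lognormal(size=(60, 2, 3))
        t1 = sp.normalize_power(sp.flag_outliers(table_from_raw(raw)))
        t2 = sp.normalize_power(sp.flag_outliers(table_from_raw(10 * raw)))
        assert np.allclose(t1.normalized, t2.normalized)

    def test_requires_outlier_mask(self):
        with pytest.raises(ValueError, match="flag_outliers"):
            sp.normalize_power(table_from_raw(np.ones((10, 1, 1))))

    def test_zero_median_names_the_band(self):
        raw = np.ones((10, 1, 2))
        raw[:, 0, 1] = 0.0
        with pytest.raises(ValueError, match="theta"):
            sp.normalize_power(sp.flag_outliers(table_from_raw(raw)))


class TestStateBandSummary:
    def test_all_wake_leaves_sleep_states_missing(self):
        raw = np.ones((10, 1, 6))
        table = sp.normalize_power(sp.flag_outliers(table_from_raw(raw)))
        labels = np.full(10, "WAKE")
        out = sp.state_band_summary(table, labels)
        wake_beta = out.query("state == 'WAKE' and band == 'beta'")
        assert wake_beta["mean_norm_power"].iloc[0] == pytest.approx(1.0)
        assert out.query("state == 'REM'")["mean_norm_power"].isna().all()

    def test_two_state_toy_matches_hand_means(self):
        rng = np.random.default_rng(5)
        raw = rng.lognormal(size=(6, 1, 6))
        table = sp.normalize_power(sp.flag_outliers(table_from_raw(raw)))
        labels = np.array(["WAKE", "WAKE", "NREM", "NREM", "NREM", "WAKE"])
        out = sp.state_band_summary(table, labels)
        bi = table.band_names.index("delta")
        wake_hand = table.normalized[[0, 1, 5], 0, bi].mean()
        nrem_hand = table.normalized[[2, 3, 4], 0, bi].mean()
        got = out.set_index(["state", "band"])["mean_norm_power"]
        assert got[("WAKE", "delta")] == pytest.approx(wake_hand)
        assert got[("NREM", "delta")] == pytest.approx(nrem_hand)

    def test_grid_mismatch_reports_both_lengths(self):
        raw = np.ones((10, 1, 6))
        table = sp.normalize_power(sp.flag_outliers(table_from_raw(raw)))
        with pytest.raises(ValueError, match="12"):
            sp.state_band_summary(table, np.full(12, "WAKE"))


class TestThetaPeak:
    def test_tie_breaks_to_lower_frequency(self):
        freqs = np.arange(0, 20.0, 1.0)
        power = np.zeros(len(freqs))
        power[6] = power[9] = 1.0
        assert _parabolic_peak(freqs, power, 5.0, 10.0) == 6.0

    def test_seven_hz_component_recovered(self, short_recording, short_spectra):
        rec, truth = short_recording
        peaks = sp.theta_peak_frequency(short_spectra, truth.hypnogram)
        for role in ("frontal", "parietal"):
            assert peaks[role] == pytest.approx(7.0, abs=0.5)

    def test_missing_state_yields_nan(self, short_spectra):
        labels = np.full(short_spectra.n_epochs, "WAKE")
        with pytest.warns(UserWarning, match="no REM"):
            peaks = sp.theta_peak_frequency(short_spectra, labels)
        assert all(np.isnan(v) for v in peaks.values())
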