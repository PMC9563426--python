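"""Per-second spectral quantification.

Pipeline: Welch PSD per 1-s epoch per EEG channel -> band integration over
the six canonical bands -> 15x interquartile-range outlier exclusion per
channel -> normalization by the per-(channel, band) median over the
lights-on period -> per-state, per-role band means and REM theta peak.

Numerical conventions
---------------------
* Welch uses 0.5-s Hann segments with 50% overlap, giving a 2-Hz frequency
  grid at any sample rate. The delta band's nominal 0.5-Hz lower edge thus
  starts at the first usable bin (2 Hz); the DC bin is never included.
* Band membership is by bin center with inclusive bounds; band power is the
  arithmetic mean of PSD over member bins (scale-free after normalization).
* Quantiles use the linear-interpolation convention (numpy default); the
  15xIQR mask is sensitive to this, so it is fixed and stated.
* "Any second with elements" beyond the fences is interpreted at the band
  level: an epoch is masked for a channel when any of that channel's band
  values for that second is an outlier.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .bands import DEFAULT_BANDS, BandDefinition
from .recording import EEG_ROLES, Recording

#: minimum sample rate able to resolve the ripple band (130-180 Hz)
MIN_SAMPLE_RATE = 360.0


@dataclass
class EpochSpectra:
    """Per-epoch, per-channel power spectral density on a fixed grid."""

    times: np.ndarray  # (n_epochs,) epoch start seconds
    freqs: np.ndarray  # (n_freqs,) Hz, strictly increasing
    power: np.ndarray  # (n_epochs, n_channels, n_freqs), >= 0
    channel_names: list[str]
    channel_roles: list[str]
    #: fundamental Welch resolution in Hz; the grid itself may be finer
    #: (zero-padded). None when constructed from an arbitrary grid.
    resolution_hz: float | None = None

    @property
    def n_epochs(self) -> int:
        return self.power.shape[0]

    def role_indices(self, role: str) -> list[int]:
        return [i for i, r in enumerate(self.channel_roles) if r == role]


@dataclass
class BandPowerTable:
    """Per-epoch, per-channel, per-band power with outlier mask and
    median-normalized values."""

    times: np.ndarray
    bands: tuple[BandDefinition, ...]
    raw: np.ndarray  # (n_epochs, n_channels, n_bands)
    channel_names: list[str]
    channel_roles: list[str]
    outlier: np.ndarray | None = None  # (n_epochs, n_channels) bool
    normalized: np.ndarray | None = None  # same shape as raw
    meta: dict = field(default_factory=dict)

    @property
    def band_names(self) -> list[str]:
        return [b.name for b in self.bands]


class CapabilityError(ValueError):
    """Sample rate cannot resolve the requested bands."""


def compute_epoch_spectra(recording: Recording, epoch_s: float = 1.0) -> EpochSpectra:
    """Welch PSD within each epoch for every EEG channel.

    0.5-s Hann segments, 50% overlap; trailing partial epoch dropped. The
    spectrum is evaluated on a 4x zero-padded grid (bin spacing 2 Hz / 4),
    which leaves the fundamental 2-Hz resolution untouched but interpolates
    the estimate so band edges (the 0.5-Hz delta lower bound) and spectral
    peak positions are better localized.
    """
    fs = recording.sample_rate
    if fs < MIN_SAMPLE_RATE:
        bad = [b.name for b in DEFAULT_BANDS if b.hi > fs / 2]
        raise CapabilityError(
            f"sample rate {fs} Hz < {MIN_SAMPLE_RATE} Hz; cannot resolve "
            f"bands: {', '.join(bad)}"
        )
    spe = int(round(epoch_s * fs))  # samples per epoch
    n_epochs = recording.n_samples // spe
    if n_epochs < 1:
        raise ValueError("recording shorter than one epoch")
    nperseg = int(round(0.5 * fs))
    eeg = recording.eeg_indices
    psd = None
    for j, ci in enumerate(eeg):
        x = recording.data[ci, : n_epochs * spe].reshape(n_epochs, spe)
        freqs, p = signal.welch(
            x, fs=fs, window="hann", nperseg=nperseg, noverlap=nperseg // 2,
            nfft=4 * nperseg, detrend="constant", axis=-1,
        )
        if psd is None:
            psd = np.empty((n_epochs, len(eeg), len(freqs)))
        psd[:, j, :] = p
    times = np.arange(n_epochs, dtype=float) * epoch_s
    return EpochSpectra(
        times=times,
        freqs=freqs,
        power=psd,
        channel_names=[recording.channel_names[i] for i in eeg],
        channel_roles=[recording.channel_roles[i] for i in eeg],
        resolution_hz=fs / nperseg,
    )


def integrate_bands(
    spectra: EpochSpectra, bands: tuple[BandDefinition, ...] = DEFAULT_BANDS
) -> BandPowerTable:
    """Mean PSD over the bins whose centers fall inside each band
    (inclusive bounds).

    A band's lower edge is raised to the estimator's fundamental resolution
    when that is known (first-usable-bin rule): grid points below it sit in
    the detrended DC main lobe and systematically underestimate power, so
    the delta band effectively starts at 2 Hz with the default estimator.
    """
    freqs = spectra.freqs
    df = np.median(np.diff(freqs))
    first_usable = spectra.resolution_hz or 0.0
    raw = np.empty((spectra.n_epochs, spectra.power.shape[1], len(bands)))
    for bi, b in enumerate(bands):
        mask = (freqs >= max(b.lo, first_usable)) & (freqs <= b.hi)
        if not mask.any():
            raise ValueError(
                f"band {b.name!r} [{b.lo}, {b.hi}] Hz contains no frequency "
                f"bins at resolution {df:g} Hz"
            )
        raw[:, :, bi] = spectra.power[:, :, mask].mean(axis=-1)
    return BandPowerTable(
        times=spectra.times,
        bands=tuple(bands),
        raw=raw,
        channel_names=list(spectra.channel_names),
        channel_roles=list(spectra.channel_roles),
    )


def flag_outliers(table: BandPowerTable, k: float = 15.0) -> BandPowerTable:
    """Mask any second whose band values stray beyond ``k`` interquartile
    ranges outside the quartiles, per channel.

    Fences are computed per (channel, band) over all epochs of the
    recording; an epoch is masked for a channel when ANY band value for
    that channel exceeds Q3 + k*IQR or falls below Q1 - k*IQR. Idempotent:
    fences are always computed from the raw values, not the masked subset.
    """
    if k <= 0:
        raise ValueError(f"outlier multiplier k must be > 0, got {k}")
    if table.raw.shape[0] < 4:
        raise ValueError("need at least 4 epochs to estimate quartiles")
    q1 = np.quantile(table.raw, 0.25, axis=0)  # (channels, bands)
    q3 = np.quantile(table.raw, 0.75, axis=0)
    iqr = q3 - q1
    lo, hi = q1 - k * iqr, q3 + k * iqr
    bad = (table.raw < lo) | (table.raw > hi)  # epochs x channels x bands
    table.outlier = bad.any(axis=2)
    table.meta["outlier_fences"] = {"lo": lo, "hi": hi, "k": k}
    return table


def normalize_power(table: BandPowerTable) -> BandPowerTable:
    """Divide each (channel, band) series by its median over non-outlier
    epochs of the lights-on period."""
    if table.outlier is None:
        raise ValueError("run flag_outliers before normalize_power")
    n_ep, n_ch, n_b = table.raw.shape
    med = np.empty((n_ch, n_b))
    for ci in range(n_ch):
        ok = ~table.outlier[:, ci]
        if not ok.any():
            raise ValueError(f"channel {table.channel_names[ci]!r}: all epochs masked")
        med[ci] = np.median(table.raw[ok, ci, :], axis=0)
    degenerate = np.argwhere(med <= 0)
    if degenerate.size:
        ci, bi = degenerate[0]
        raise ValueError(
            f"non-positive median for channel {table.channel_names[ci]!r}, "
            f"band {table.band_names[bi]!r}; cannot normalize"
        )
    table.normalized = table.raw / med[None, :, :]
    table.meta["band_medians"] = med
    return table


MISSING = float("nan")


def state_band_summary(table: BandPowerTable, hypnogram) -> "pd.DataFrame":
    """Mean normalized band power per (state, channel-role, band).

    Averages unmasked epochs of each state per channel, then averages the
    left/right channels of a role. States with zero epochs yield NaN.
    Returns a tidy DataFrame with columns state, role, band, mean_norm_power.
    """
    import pandas as pd

    from .staging import Hypnogram  # local import to avoid a cycle

    labels = hypnogram.labels if isinstance(hypnogram, Hypnogram) else np.asarray(hypnogram)
    if len(labels) != table.raw.shape[0]:
        raise ValueError(
            f"epoch grid mismatch: hypnogram has {len(labels)} epochs, "
            f"band table has {table.raw.shape[0]}"
        )
    if table.normalized is None:
        raise ValueError("normalize_power must run before state_band_summary")
    rows = []
    for state in ("WAKE", "NREM", "REM"):
        in_state = labels == state
        for role in EEG_ROLES:
            chans = [i for i, r in enumerate(table.channel_roles) if r == role]
            if not chans:
                continue
            for bi, bname in enumerate(table.band_names):
                per_chan = []
                for ci in chans:
                    ok = in_state & ~table.outlier[:, ci]
                    if ok.any():
                        per_chan.append(table.normalized[ok, ci, bi].mean())
                val = float(np.mean(per_chan)) if per_chan else MISSING
                rows.append(
                    {"state": state, "role": role, "band": bname,
                     "mean_norm_power": val}
                )
    return pd.DataFrame(rows)


def _parabolic_peak(freqs: np.ndarray, power: np.ndarray, lo: float, hi: float) -> float:
    """Peak frequency of ``power`` restricted to [lo, hi], refined by fitting
    a parabola through the argmax bin and its grid neighbours (which may lie
    just outside the band). Ties break to the lower frequency."""
    band = np.where((freqs >= lo) & (freqs <= hi))[0]
    if band.size == 0:
        return MISSING
    sub = power[band]
    i = band[int(np.argmax(sub))]  # argmax returns first (lowest-f) maximum
    if i == 0 or i == len(freqs) - 1:
        return float(freqs[i])
    y0, y1, y2 = power[i - 1], power[i], power[i + 1]
    denom = y0 - 2 * y1 + y2
    if denom >= 0:  # flat or non-concave neighbourhood: keep the bin center
        return float(freqs[i])
    delta = 0.5 * (y0 - y2) / denom
    delta = float(np.clip(delta, -0.5, 0.5))
    df = freqs[i + 1] - freqs[i]
    return float(freqs[i] + delta * df)


def theta_peak_frequency(
    spectra: EpochSpectra,
    hypnogram,
    state: str = "REM",
    lo: float = 5.0,
    hi: float = 10.0,
    outlier: np.ndarray | None = None,
) -> dict[str, float]:
    """Peak frequency (Hz) of the state-averaged PSD in the theta range,
    per channel role.

    Each channel's PSD is averaged over the state's epochs and normalized
    by a per-channel scalar (its integral) so left/right channels contribute
    comparably to the role average; a scalar leaves the spectral shape — and
    hence the peak location — untouched, unlike per-frequency median
    normalization, which tilts the spectrum and biases the peak upward.
    The peak is located with parabolic interpolation for sub-bin resolution.
    Returns NaN per role when the state has no epochs.
    """
    from .staging import Hypnogram

    labels = hypnogram.labels if isinstance(hypnogram, Hypnogram) else np.asarray(hypnogram)
    if len(labels) != spectra.n_epochs:
        raise ValueError(
            f"epoch grid mismatch: {len(labels)} labels vs {spectra.n_epochs} epochs"
        )
    in_state = labels == state
    out: dict[str, float] = {}
    for role in EEG_ROLES:
        chans = spectra.role_indices(role)
        if not chans:
            continue
        if not in_state.any():
            warnings.warn(f"no {state} epochs; theta peak undefined")
            out[role] = MISSING
            continue
        role_psd = np.zeros(len(spectra.freqs))
        for ci in chans:
            keep = in_state
            if outlier is not None:
                keep = in_state & ~outlier[:, ci]
            if not keep.any():
                continue
            psd = spectra.power[keep, ci, :].mean(axis=0)
            total = psd.sum()
            role_psd += psd / total if total > 0 else psd
        out[role] = _parabolic_peak(spectra.freqs, role_psd, lo, hi)
    return out


def band_table_to_frame(table: BandPowerTable) -> "pd.DataFrame":
    """Tidy export: epoch_s, channel, band, raw, normalized, outlier."""
    import pandas as pd

    n_ep, n_ch, n_b = table.raw.shape
    ep = np.repeat(table.times, n_ch * n_b)
    ch = np.tile(np.repeat(table.channel_names, n_b), n_ep)
    bd = np.tile(table.band_names, n_ep * n_ch)
    raw = table.raw.reshape(-1)
    norm = table.normalized.reshape(-1) if table.normalized is not None else np.nan
    outl = (
        np.repeat(table.outlier, n_b).reshape(-1)
        if table.outlier is not None
        else False
    )
    return pd.DataFrame(
        {"epoch_s": ep, "channel": ch, "band": bd, "raw": raw,
         "normalized": norm, "outlier": outl}
    )
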