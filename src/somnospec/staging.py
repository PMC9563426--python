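"""Automated 1-s-epoch vigilance-state scoring.

Each second is assigned WAKE, NREM or REM from three features:

* slow-wave activity (SWA): normalized delta-band power, frontal channels;
* theta ratio: theta / (delta + theta) power from parietal channels —
  parietal sites carry volume-conducted hippocampal theta in mice; the
  ratio form bounds the feature in [0, 1];
* movement: per-epoch accelerometer variance summed over the three axes.

The decision cascade thresholds each feature with Otsu's criterion (a
deterministic two-class split): high movement -> WAKE; among the rest, high
SWA -> NREM; among low-movement low-SWA epochs, high theta ratio -> REM,
else quiet WAKE. Runs shorter than ``min_bout_s`` are absorbed into the
longer flanking state, and REM bouts not preceded by NREM within 10 s are
relabelled WAKE (rodents do not enter REM from wake).

All computed thresholds are logged and attached to the hypnogram for audit.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import median_filter
from skimage.filters import threshold_otsu

from .bands import band_by_name
from .recording import Recording
from .spectral import EpochSpectra

logger = logging.getLogger(__name__)

STATE_TOKENS = ("WAKE", "NREM", "REM")


@dataclass
class Hypnogram:
    """Per-1-s-epoch state labels aligned to the recording clock."""

    labels: np.ndarray  # (n_epochs,) of "WAKE"|"NREM"|"REM"
    epoch_s: float = 1.0
    provenance: str = "automatic"  # automatic | ground-truth | edited
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype="U4")
        bad = set(np.unique(self.labels)) - set(STATE_TOKENS)
        if bad:
            raise ValueError(f"unknown state tokens: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.labels)

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, Hypnogram)
            and self.epoch_s == other.epoch_s
            and np.array_equal(self.labels, other.labels)
        )


@dataclass
class EpochFeatures:
    """Per-epoch scoring features; one row per epoch of the recording."""

    swa: np.ndarray          # normalized frontal delta power, >= 0
    theta_ratio: np.ndarray  # parietal theta/(delta+theta), in [0, 1]
    movement: np.ndarray     # summed accelerometer variance, >= 0

    def __len__(self) -> int:
        return len(self.swa)


def extract_features(spectra: EpochSpectra, recording: Recording) -> EpochFeatures:
    """Compute SWA, theta ratio and movement per epoch.

    All three are smoothed with a centred 5-epoch median filter to suppress
    single-second glitches before thresholding.
    """
    accel = recording.accel_indices
    if not accel:
        raise ValueError(
            "recording has no accelerometer channels; movement is required "
            "to separate wake"
        )
    delta = band_by_name("delta")
    theta = band_by_name("theta")
    freqs = spectra.freqs
    d_mask = (freqs >= delta.lo) & (freqs <= delta.hi)
    t_mask = (freqs >= theta.lo) & (freqs <= theta.hi)

    frontal = spectra.role_indices("frontal")
    parietal = spectra.role_indices("parietal")
    if not frontal or not parietal:
        raise ValueError("need at least one frontal and one parietal channel")

    # SWA: frontal delta, normalized per channel by its median over epochs
    d_front = spectra.power[:, frontal, :][:, :, d_mask].mean(axis=-1)
    med = np.median(d_front, axis=0)
    med[med <= 0] = np.finfo(float).tiny
    swa = (d_front / med).mean(axis=1)

    d_par = spectra.power[:, parietal, :][:, :, d_mask].mean(axis=-1).mean(axis=1)
    t_par = spectra.power[:, parietal, :][:, :, t_mask].mean(axis=-1).mean(axis=1)
    denom = d_par + t_par
    with np.errstate(invalid="ignore", divide="ignore"):
        theta_ratio = np.where(denom > 0, t_par / denom, 0.0)

    n_epochs = spectra.n_epochs
    spe = int(round(spectra.times[1] - spectra.times[0]) * recording.sample_rate) \
        if n_epochs > 1 else int(recording.sample_rate)
    acc = recording.data[accel, : n_epochs * spe].reshape(len(accel), n_epochs, spe)
    movement = acc.var(axis=-1).sum(axis=0)

    k = 5
    swa = median_filter(swa, size=k, mode="nearest")
    theta_ratio = median_filter(theta_ratio, size=k, mode="nearest")
    movement = median_filter(movement, size=k, mode="nearest")
    return EpochFeatures(swa=swa, theta_ratio=theta_ratio, movement=movement)


def _otsu_or_none(values: np.ndarray) -> float | None:
    """Otsu threshold, or None when the sample is degenerate (unimodal to
    machine precision)."""
    v = values[np.isfinite(values)]
    if v.size < 2 or np.ptp(v) < 1e-12:
        return None
    return float(threshold_otsu(v, nbins=256))


def _runs(labels: np.ndarray) -> list[tuple[str, int, int]]:
    """Run-length encoding: (label, start, length)."""
    out = []
    start = 0
    for i in range(1, len(labels) + 1):
        if i == len(labels) or labels[i] != labels[start]:
            out.append((str(labels[start]), start, i - start))
            start = i
    return out


def _absorb_short_runs(labels: np.ndarray, min_bout: int) -> np.ndarray:
    """Merge interior runs shorter than ``min_bout`` into the longer flank
    (tie -> preceding state). The first and last runs keep their length."""
    labels = labels.copy()
    changed = True
    while changed:
        changed = False
        runs = _runs(labels)
        for ri in range(1, len(runs) - 1):
            state, start, length = runs[ri]
            if length >= min_bout:
                continue
            prev_state, _, prev_len = runs[ri - 1]
            next_state, _, next_len = runs[ri + 1]
            winner = next_state if next_len > prev_len else prev_state
            labels[start : start + length] = winner
            changed = True
            break  # recompute runs after each merge
    return labels


def _forbid_wake_to_rem(labels: np.ndarray, lookback_s: int = 10) -> np.ndarray:
    """Relabel REM bouts entered from prolonged wake as WAKE.

    A REM bout is kept only when sleep (NREM, or REM — a fragment of an
    interrupted REM bout counts as continuation) occurs within
    ``lookback_s`` seconds before its onset.
    """
    labels = labels.copy()
    for state, start, length in _runs(labels):
        if state != "REM":
            continue
        lo = max(0, start - lookback_s)
        before = labels[lo:start]
        if start == 0 or not np.any((before == "NREM") | (before == "REM")):
            labels[start : start + length] = "WAKE"
    return labels


def score_states(features: EpochFeatures, min_bout_s: int = 3,
                 forbid_wake_to_rem: bool = True) -> Hypnogram:
    """Threshold cascade -> minimum-bout smoothing -> transition rules.

    ``forbid_wake_to_rem`` applies the rodent convention that REM is only
    entered from NREM; disable it to score without transition constraints.
    """
    n = len(features)
    if n < 60:
        raise ValueError(f"need at least 60 epochs to score, got {n}")
    eps = np.finfo(float).tiny
    log_mov = np.log(features.movement + eps)
    thresholds: dict[str, float | None] = {}

    t_mov = _otsu_or_none(log_mov)
    thresholds["log_movement"] = t_mov
    if t_mov is None:
        warnings.warn("degenerate movement feature; scoring all epochs as one state")
        labels = np.full(n, "WAKE", dtype="U4")
        return Hypnogram(labels, provenance="automatic",
                         meta={"thresholds": thresholds, "degenerate": True})
    wake = log_mov > t_mov

    labels = np.full(n, "WAKE", dtype="U4")
    still = ~wake
    log_swa = np.log(features.swa + eps)
    t_swa = _otsu_or_none(log_swa[still])
    thresholds["log_swa"] = t_swa
    if t_swa is not None:
        nrem = still & (log_swa > t_swa)
    else:
        nrem = np.zeros(n, dtype=bool)
    labels[nrem] = "NREM"

    # the theta threshold is learned on all still epochs — the NREM cluster
    # anchors the low-theta mode — and applied to the remaining epochs only;
    # log scale keeps Otsu honest when the class masses are unbalanced
    rest = still & ~nrem
    log_theta = np.log(features.theta_ratio + eps)
    t_theta = _otsu_or_none(log_theta[still]) if rest.any() else None
    thresholds["theta_ratio"] = None if t_theta is None else float(np.exp(t_theta))
    if t_theta is not None:
        labels[rest & (log_theta > t_theta)] = "REM"

    logger.info("scoring thresholds: %s", thresholds)
    labels = _absorb_short_runs(labels, min_bout_s)
    if forbid_wake_to_rem:
        labels = _forbid_wake_to_rem(labels)
    return Hypnogram(labels, provenance="automatic", meta={"thresholds": thresholds})


def save_hypnogram(h: Hypnogram, path) -> None:
    """Write the `epoch_start_s,state` CSV dialect."""
    with open(path, "w") as f:
        f.write("epoch_start_s,state\n")
        for i, s in enumerate(h.labels):
            f.write(f"{i * h.epoch_s:g},{s}\n")


def load_hypnogram(path, provenance: str = "automatic") -> Hypnogram:
    """Read the `epoch_start_s,state` CSV dialect with strict validation."""
    starts: list[float] = []
    labels: list[str] = []
    with open(path) as f:
        header = f.readline().strip()
        if header != "epoch_start_s,state":
            raise ValueError(f"{path}: line 1: expected header 'epoch_start_s,state'")
        for ln, line in enumerate(f, start=2):
            line = line.strip()
            if not line:
                continue
            try:
                t_str, state = line.split(",")
                t = float(t_str)
            except ValueError:
                raise ValueError(f"{path}: line {ln}: malformed row {line!r}") from None
            if state not in STATE_TOKENS:
                raise ValueError(f"{path}: line {ln}: unknown state token {state!r}")
            starts.append(t)
            labels.append(state)
    if not labels:
        raise ValueError(f"{path}: no epochs")
    starts_arr = np.asarray(starts)
    if len(starts_arr) > 1:
        steps = np.diff(starts_arr)
        if not np.allclose(steps, steps[0]) or steps[0] <= 0:
            bad = int(np.argmax(~np.isclose(steps, steps[0]))) + 3
            raise ValueError(f"{path}: line {bad}: non-contiguous epochs")
        epoch_s = float(steps[0])
    else:
        epoch_s = 1.0
    return Hypnogram(np.asarray(labels, dtype="U4"), epoch_s=epoch_s,
                     provenance=provenance)
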