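"""Ground-truthed synthetic polysomnography.

Generates cohorts of mouse-like 12-h lights-on recordings with a known
per-second hypnogram, so every downstream stage (staging, band-power
quantification, architecture metrics, group statistics) can be validated
against ground truth.

The generative model has two layers:

1. A semi-Markov vigilance-state process: alternating WAKE/NREM/REM bouts
   with log-normal dwell times per state and a zero-diagonal row-stochastic
   transition matrix. WAKE->REM transitions are disallowed by default, as
   in healthy rodents.
2. A state-conditioned signal model per EEG channel: 1/f background noise
   plus band-limited oscillatory components (band-pass-filtered Gaussian
   noise) whose amplitudes switch at state boundaries with a 0.5-s
   cross-fade. NREM carries strong delta and a spindle bump, REM is
   theta-dominant, wake is mixed with high broadband/gamma content.
   Accelerometer channels are white noise with state-dependent variance
   (high in wake, minimal in REM).

Genotype effects — the mutant phenotype — are expressed as multiplicative
band-power modifiers per (state, role, band), a REM theta-peak shift in Hz,
a global bout-duration scale, and a REM-share increase. Between-animal
variability is modelled as a mild log-normal jitter on component amplitudes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal
from scipy.ndimage import uniform_filter1d

from .bands import band_of_frequency
from .recording import STATES, Recording


class ConfigurationError(ValueError):
    """Raised for an internally inconsistent simulation configuration."""


@dataclass(frozen=True)
class SpectralComponent:
    """One oscillatory bump: band-pass-filtered noise at ``center_hz`` with
    ~``bandwidth_hz`` width and RMS amplitude ``amplitude`` (arbitrary units,
    same scale as the 1/f background)."""

    center_hz: float
    bandwidth_hz: float
    amplitude: float


@dataclass(frozen=True)
class DwellParams:
    """Log-normal bout-duration law for one state: mean and coefficient of
    variation, both on the seconds scale."""

    mean_s: float
    cv: float = 1.0


@dataclass(frozen=True)
class GenotypeEffects:
    """Multiplicative phenotype of the mutant genotype.

    band_power_scale maps (state, role, band name) -> band-power multiplier;
    amplitudes are scaled by its square root so the multiplier acts on power.
    """

    band_power_scale: dict[tuple[str, str, str], float] = field(default_factory=dict)
    rem_theta_shift_hz: float = 0.0
    bout_scale: float = 1.0
    rem_dwell_factor: float = 1.0
    rem_entry_factor: float = 1.0

    def scale_for(self, state: str, role: str, center_hz: float) -> float:
        band = band_of_frequency(center_hz)
        if band is None:
            return 1.0
        return self.band_power_scale.get((state, role, band), 1.0)


def default_mutant_effects() -> GenotypeEffects:
    """Default mutant phenotype: higher REM beta (both sites), higher NREM
    parietal beta, slower REM theta peak, higher wake parietal delta and
    lower wake parietal gamma, plus shorter/more numerous bouts with a
    larger REM share."""
    return GenotypeEffects(
        band_power_scale={
            ("REM", "frontal", "beta"): 2.0,
            ("REM", "parietal", "beta"): 2.0,
            ("NREM", "parietal", "beta"): 1.5,
            ("WAKE", "parietal", "delta"): 1.5,
            ("WAKE", "parietal", "gamma"): 0.67,
        },
        rem_theta_shift_hz=-1.0,
        bout_scale=0.5,
        rem_dwell_factor=1.25,
        rem_entry_factor=1.25,
    )


def _default_components() -> dict[str, dict[str, list[SpectralComponent]]]:
    # Amplitudes are RMS in units of the 1/f background scale. Between-state
    # contrasts within each band are kept at the few-fold ratios seen in
    # real rodent EEG (NREM/wake delta ~3.5x, wake/NREM beta ~2x, wake/NREM
    # gamma ~2.5x) rather than order-of-magnitude separations: per-second
    # band power across states then forms a smoothly overlapping mixture,
    # so the recording-wide medians used for normalization are stable
    # against the animal-to-animal drift in state composition. Every band
    # that can carry a genotype effect keeps its oscillatory component well
    # above the background floor in all states, so a multiplicative effect
    # on the component is not washed out by the floor.
    nrem = {
        "frontal": [
            SpectralComponent(2.0, 2.0, 2.09),   # slow-wave activity
            SpectralComponent(14.0, 4.0, 0.30),  # spindle bump
            SpectralComponent(25.0, 6.0, 0.46),
            SpectralComponent(70.0, 40.0, 0.63),
            SpectralComponent(155.0, 30.0, 0.30),
        ],
        "parietal": [
            SpectralComponent(2.0, 2.0, 2.09),
            SpectralComponent(14.0, 4.0, 0.30),
            SpectralComponent(25.0, 6.0, 0.46),
            SpectralComponent(70.0, 40.0, 0.63),
            SpectralComponent(155.0, 30.0, 0.30),
        ],
    }
    rem = {
        "frontal": [
            SpectralComponent(7.0, 2.0, 0.78),   # volume-conducted theta
            SpectralComponent(2.0, 2.0, 1.05),
            SpectralComponent(25.0, 6.0, 0.78),
            SpectralComponent(70.0, 40.0, 0.89),
            SpectralComponent(155.0, 30.0, 0.30),
        ],
        "parietal": [
            SpectralComponent(7.0, 2.0, 1.00),   # hippocampal theta
            SpectralComponent(2.0, 2.0, 1.05),
            SpectralComponent(25.0, 6.0, 0.78),
            SpectralComponent(70.0, 40.0, 0.89),
            SpectralComponent(155.0, 30.0, 0.30),
        ],
    }
    wake = {
        "frontal": [
            SpectralComponent(2.0, 2.0, 0.85),
            SpectralComponent(7.0, 2.0, 0.41),
            SpectralComponent(25.0, 6.0, 0.69),
            SpectralComponent(70.0, 40.0, 1.07),
            SpectralComponent(155.0, 30.0, 0.30),
        ],
        "parietal": [
            SpectralComponent(2.0, 2.0, 0.85),
            SpectralComponent(7.0, 2.0, 0.41),
            SpectralComponent(25.0, 6.0, 0.69),
            SpectralComponent(70.0, 40.0, 1.07),
            SpectralComponent(155.0, 30.0, 0.30),
        ],
    }
    return {"WAKE": wake, "NREM": nrem, "REM": rem}


def _default_transition_matrix() -> np.ndarray:
    # order WAKE, NREM, REM; wake never enters REM directly
    return np.array(
        [
            [0.0, 1.0, 0.0],
            [0.55, 0.0, 0.45],
            [0.6, 0.4, 0.0],
        ]
    )


@dataclass
class SimConfig:
    """Full description of one synthetic animal/recording.

    Defaults model a 12-h lights-on session. ``states`` may be restricted to
    a subset (e.g. a single state) for degenerate test configurations; the
    transition matrix rows/columns follow the order of ``states``.
    """

    duration_s: int = 43_200
    sample_rate: float = 1_000.0
    states: tuple[str, ...] = STATES
    dwell: dict[str, DwellParams] = field(
        default_factory=lambda: {
            "WAKE": DwellParams(120.0, 1.0),
            "NREM": DwellParams(95.0, 1.0),
            "REM": DwellParams(72.0, 0.8),
        }
    )
    transition_matrix: np.ndarray = field(default_factory=_default_transition_matrix)
    spectral_components: dict[str, dict[str, list[SpectralComponent]]] = field(
        default_factory=_default_components
    )
    background_slope: float = 1.0  # PSD ~ 1/f^slope
    background_scale: float = 1.0  # RMS of the background process
    # slow log-normal amplitude modulation: within-state band power in real
    # EEG fluctuates second to second with heavy right tails; without it the
    # per-second band-power mixture is a stack of near-disjoint state modes
    # and recording-wide medians become knife-edge functions of composition
    component_am_sigma: float = 0.15  # log-amplitude SD of the modulation
    background_am_sigma: float = 0.2
    am_smooth_s: float = 10.0  # correlation time of the modulation
    movement_variance: dict[str, float] = field(
        default_factory=lambda: {"WAKE": 1.0, "NREM": 0.01, "REM": 0.003}
    )
    amplitude_jitter_cv: float = 0.02  # between-animal component-amplitude CV
    crossfade_s: float = 0.5
    genotype_effects: GenotypeEffects | None = None
    eeg_channels: tuple[tuple[str, str], ...] = (
        ("EEG FrontL", "frontal"),
        ("EEG FrontR", "frontal"),
        ("EEG ParL", "parietal"),
        ("EEG ParR", "parietal"),
    )
    n_accel_axes: int = 3

    def validate(self) -> None:
        tm = np.asarray(self.transition_matrix, dtype=float)
        k = len(self.states)
        if k == 0:
            raise ConfigurationError("states must be non-empty")
        if k > 1:
            if tm.shape != (k, k):
                raise ConfigurationError(
                    f"transition matrix shape {tm.shape} != ({k}, {k})"
                )
            if np.any(np.diag(tm) != 0):
                raise ConfigurationError("transition matrix diagonal must be zero")
            if not np.allclose(tm.sum(axis=1), 1.0):
                raise ConfigurationError("transition matrix rows must sum to 1")
            if np.any(tm < 0):
                raise ConfigurationError("transition probabilities must be >= 0")
        for s in self.states:
            if self.dwell[s].mean_s <= 1.0:
                raise ConfigurationError(f"dwell mean for {s} must exceed 1 s")
        nyq = self.sample_rate / 2.0
        for state, roles in self.spectral_components.items():
            for role, comps in roles.items():
                for c in comps:
                    if c.amplitude < 0:
                        raise ConfigurationError(
                            f"negative amplitude in {state}/{role}"
                        )
                    if c.center_hz + c.bandwidth_hz / 2 >= nyq:
                        raise ConfigurationError(
                            f"component at {c.center_hz} Hz ({state}/{role}) "
                            f"exceeds Nyquist {nyq} Hz"
                        )
        if self.duration_s < 1:
            raise ConfigurationError("duration_s must be >= 1 s")

    def with_effects(self, effects: GenotypeEffects | None) -> "SimConfig":
        return replace(self, genotype_effects=effects)


@dataclass
class GroundTruth:
    """Oracle output of the generator: the true per-second hypnogram, the
    bout list that tiles it, and the realized per-(state, role, band)
    amplitude targets after genotype effects and animal jitter."""

    hypnogram: np.ndarray  # (duration_s,) of state labels
    bouts: list[tuple[str, int, int]]  # (state, start_s, length_s)
    band_targets: dict[tuple[str, str, str], float] = field(default_factory=dict)


def _lognormal_params(mean: float, cv: float) -> tuple[float, float]:
    sigma2 = math.log1p(cv * cv)
    mu = math.log(mean) - sigma2 / 2.0
    return mu, math.sqrt(sigma2)


def _effective_dwell(config: SimConfig) -> dict[str, DwellParams]:
    eff = config.genotype_effects
    out = {}
    for s in config.states:
        d = config.dwell[s]
        mean = d.mean_s
        if eff is not None:
            mean *= eff.bout_scale
            if s == "REM":
                mean *= eff.rem_dwell_factor
        out[s] = DwellParams(max(mean, 1.000001), d.cv)
    return out


def _effective_transitions(config: SimConfig) -> np.ndarray:
    tm = np.array(config.transition_matrix, dtype=float)
    eff = config.genotype_effects
    if eff is not None and eff.rem_entry_factor != 1.0 and "NREM" in config.states and "REM" in config.states:
        i = config.states.index("NREM")
        j = config.states.index("REM")
        tm[i, j] = min(tm[i, j] * eff.rem_entry_factor, 1.0)
        row = tm[i]
        row[i] = 0.0
        tm[i] = row / row.sum()
    return tm


def sample_hypnogram(config: SimConfig, seed: int) -> GroundTruth:
    """Draw a bout sequence that exactly tiles ``[0, duration_s)``.

    Dwell times are log-normal per state, truncated to >= 1 s and rounded to
    whole seconds; the final bout is clipped to the recording end.
    """
    config.validate()
    rng = np.random.default_rng(seed)
    states = config.states
    dwell = _effective_dwell(config)
    tm = _effective_transitions(config)

    if len(states) == 1:
        only = states[0]
        hyp = np.full(config.duration_s, only, dtype="U4")
        return GroundTruth(hyp, [(only, 0, config.duration_s)])

    # start from the stationary distribution of the embedded chain
    evals, evecs = np.linalg.eig(tm.T)
    pi = np.real(evecs[:, np.argmax(np.real(evals))])
    pi = np.abs(pi) / np.abs(pi).sum()
    state_i = rng.choice(len(states), p=pi)

    bouts: list[tuple[str, int, int]] = []
    t = 0
    while t < config.duration_s:
        s = states[state_i]
        mu, sig = _lognormal_params(dwell[s].mean_s, dwell[s].cv)
        length = int(round(rng.lognormal(mu, sig)))
        length = max(length, 1)
        length = min(length, config.duration_s - t)
        bouts.append((s, t, length))
        t += length
        state_i = rng.choice(len(states), p=tm[state_i])

    hyp = np.empty(config.duration_s, dtype="U4")
    for s, start, length in bouts:
        hyp[start : start + length] = s
    return GroundTruth(hyp, bouts)


def _state_weights(hypnogram: np.ndarray, states: tuple[str, ...],
                   sample_rate: float, crossfade_s: float) -> np.ndarray:
    """Per-sample soft state indicators, cross-faded at bout boundaries.

    Smoothing a partition of unity preserves it, so the weights sum to 1 at
    every sample.
    """
    fs = int(round(sample_rate))
    n = len(hypnogram) * fs
    w = np.zeros((len(states), n), dtype=np.float32)
    for i, s in enumerate(states):
        w[i] = np.repeat((hypnogram == s).astype(np.float32), fs)
    width = int(round(crossfade_s * sample_rate))
    if width > 1:
        w = uniform_filter1d(w, size=width, axis=1, mode="nearest")
    return w


def _colored_noise(rng: np.random.Generator, n: int, slope: float,
                   scale: float, sample_rate: float) -> np.ndarray:
    """1/f^slope (power) Gaussian background with RMS ``scale``."""
    if scale == 0:
        return np.zeros(n, dtype=np.float32)
    white = rng.standard_normal(n, dtype=np.float32)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0 / sample_rate)
    shaping = np.zeros_like(freqs)
    nz = freqs > 0
    shaping[nz] = freqs[nz] ** (-slope / 2.0)
    x = np.fft.irfft(spec * shaping, n=n).astype(np.float32)
    sd = x.std()
    if sd > 0:
        x *= np.float32(scale / sd)
    return x


def _bandlimited_noise(rng: np.random.Generator, n: int, center: float,
                       bandwidth: float, sample_rate: float) -> np.ndarray:
    """Unit-RMS band-pass-filtered Gaussian noise."""
    nyq = sample_rate / 2.0
    lo = max(center - bandwidth / 2.0, 0.1)
    hi = min(center + bandwidth / 2.0, nyq * 0.999)
    sos = signal.butter(4, [lo / nyq, hi / nyq], btype="bandpass", output="sos")
    x = signal.sosfilt(sos.astype(np.float32),
                       rng.standard_normal(n, dtype=np.float32))
    sd = x.std()
    if sd > 0:
        x /= sd
    return x


def _am_envelope(rng: np.random.Generator, duration_s: int, fs: int,
                 sigma: float, smooth_s: float) -> np.ndarray | float:
    """Slow log-normal amplitude envelope, piecewise-constant per second."""
    if sigma <= 0:
        return 1.0
    g = rng.standard_normal(duration_s)
    width = max(int(round(smooth_s)), 1)
    if width > 1:
        g = uniform_filter1d(g, size=width, mode="wrap")
        sd = g.std()
        if sd > 0:
            g /= sd
    env = np.exp(sigma * g - sigma * sigma / 2.0).astype(np.float32)
    return np.repeat(env, fs)


def _component_multipliers(config: SimConfig,
                           rng: np.random.Generator) -> dict[tuple[str, str, int], float]:
    """Animal-level log-normal amplitude jitter, shared across the left/right
    channels of a role so it survives role averaging."""
    cv = config.amplitude_jitter_cv
    mult: dict[tuple[str, str, int], float] = {}
    for state in sorted(config.spectral_components):
        for role in sorted(config.spectral_components[state]):
            for k, _ in enumerate(config.spectral_components[state][role]):
                if cv > 0:
                    mu, sig = _lognormal_params(1.0, cv)
                    mult[(state, role, k)] = rng.lognormal(mu, sig)
                else:
                    mult[(state, role, k)] = 1.0
    return mult


def synthesize_signals(truth: GroundTruth, config: SimConfig, seed: int) -> Recording:
    """Render EEG + accelerometer signals for a hypnogram.

    Each EEG channel is 1/f background noise plus the state's oscillatory
    components (band-limited noise), gated by cross-faded state envelopes.
    Each component's band-limited carrier and its slow amplitude modulation
    are shared across the channels of the recording — screw electrodes over
    a mouse skull see largely volume-conducted common sources — while the
    1/f background is independent per channel. Accelerometer channels are
    variance-switched white noise. Also fills ``truth.band_targets`` with
    the realized per-(state, role, band) amplitude targets.
    """
    config.validate()
    if len(truth.hypnogram) != config.duration_s:
        raise ValueError(
            f"hypnogram length {len(truth.hypnogram)} != duration {config.duration_s}"
        )
    fs = int(round(config.sample_rate))
    n = config.duration_s * fs
    eff = config.genotype_effects

    ss = np.random.SeedSequence(seed)
    n_eeg = len(config.eeg_channels)
    child = ss.spawn(2 + 2 * n_eeg + config.n_accel_axes)
    jitter = _component_multipliers(config, np.random.default_rng(child[0]))
    comp_rng = np.random.default_rng(child[1])
    # dedicated per-channel streams for electrode-local gain fluctuations
    am_rngs = [np.random.default_rng(child[2 + n_eeg + ci])
               for ci in range(n_eeg)]

    weights = _state_weights(
        truth.hypnogram, config.states, config.sample_rate, config.crossfade_s
    )

    targets: dict[tuple[str, str, str], float] = {}
    data = np.zeros((n_eeg + config.n_accel_axes, n), dtype=np.float32)
    names = [name for name, _ in config.eeg_channels]
    roles = [role for _, role in config.eeg_channels]

    for ci, (name, role) in enumerate(config.eeg_channels):
        rng = np.random.default_rng(child[2 + ci])
        chan = _colored_noise(rng, n, config.background_slope,
                              config.background_scale, config.sample_rate)
        chan *= _am_envelope(rng, config.duration_s, fs,
                             config.background_am_sigma, config.am_smooth_s)
        data[ci] = chan

    # shared carriers: iterate (state, component) once, add to every channel
    for si, state in enumerate(config.states):
        by_role = config.spectral_components.get(state, {})
        n_comps = max((len(c) for c in by_role.values()), default=0)
        for k in range(n_comps):
            # carrier frequency may be genotype-shifted; assume roles agree
            # on the component grid (same centers/bandwidths per index)
            any_role = next(r for r in by_role if len(by_role[r]) > k)
            proto = by_role[any_role][k]
            center = proto.center_hz
            if eff is not None and state == "REM" \
                    and band_of_frequency(center) == "theta":
                center = center + eff.rem_theta_shift_hz
            carrier = _bandlimited_noise(comp_rng, n, center,
                                         proto.bandwidth_hz,
                                         config.sample_rate)
            carrier *= weights[si]
            for ci, (name, role) in enumerate(config.eeg_channels):
                # local modulation drawn unconditionally to keep the
                # per-channel stream aligned across configurations
                local_am = _am_envelope(am_rngs[ci], config.duration_s, fs,
                                        config.component_am_sigma,
                                        config.am_smooth_s)
                comps = by_role.get(role, [])
                if k >= len(comps):
                    continue
                comp = comps[k]
                amp = comp.amplitude
                if eff is not None:
                    amp *= math.sqrt(eff.scale_for(state, role, comp.center_hz))
                amp *= jitter[(state, role, k)]
                band = band_of_frequency(comp.center_hz)
                if band is not None:
                    key = (state, role, band)
                    targets[key] = targets.get(key, 0.0) + amp / 2.0  # L+R avg
                if amp != 0:
                    data[ci] += (amp * carrier) * local_am

    # movement: white noise with state-switched variance
    var = np.zeros(n, dtype=np.float32)
    for si, state in enumerate(config.states):
        var += config.movement_variance.get(state, 0.0) * weights[si]
    sd = np.sqrt(var)
    for ax in range(config.n_accel_axes):
        rng = np.random.default_rng(child[2 + 2 * n_eeg + ax])
        data[n_eeg + ax] = sd * rng.standard_normal(n, dtype=np.float32)
        names.append(f"ACC {'XYZ'[ax]}")
        roles.append("accelerometer")

    truth.band_targets = targets
    return Recording(
        data=data,
        sample_rate=float(fs),
        channel_names=names,
        channel_roles=roles,
        lights_on=(0.0, float(config.duration_s)),
        meta={"seed": seed},
    )


@dataclass
class CohortAnimal:
    animal_id: str
    genotype: str  # "WT" | "MUT"
    recording: Recording
    truth: GroundTruth


def simulate_cohort(
    n_wt: int,
    n_mut: int,
    config: SimConfig,
    seed: int,
    mutant_effects: GenotypeEffects | None = None,
    signals: bool = True,
) -> list[CohortAnimal]:
    """Simulate ``n_wt`` wild-type and ``n_mut`` mutant animals.

    Per-animal seeds are spawned deterministically from the master seed;
    genotype effects apply only to mutants. With ``signals=False`` only
    hypnograms are generated (recording is empty), which is much cheaper
    when only architecture metrics are needed.
    """
    if n_wt < 0 or n_mut < 0 or n_wt + n_mut < 1:
        raise ValueError("need at least one animal")
    if mutant_effects is None:
        mutant_effects = default_mutant_effects()
    animals: list[CohortAnimal] = []
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(n_wt + n_mut)
    labels = ["WT"] * n_wt + ["MUT"] * n_mut
    for i, (genotype, child) in enumerate(zip(labels, children)):
        cfg = config.with_effects(mutant_effects if genotype == "MUT" else None)
        sub = child.generate_state(2)  # two 32-bit seeds: hypnogram, signals
        truth = sample_hypnogram(cfg, int(sub[0]))
        if signals:
            rec = synthesize_signals(truth, cfg, int(sub[1]))
        else:
            rec = Recording(
                data=np.zeros((1, 1), dtype=np.float32),
                sample_rate=cfg.sample_rate,
                channel_names=["EEG FrontL"],
                channel_roles=["frontal"],
            )
        animals.append(CohortAnimal(f"{genotype.lower()}{i:02d}", genotype, rec, truth))
    return animals
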