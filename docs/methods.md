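# Methods

`somnospec` analyses rodent polysomnography the way a mouse sleep-EEG study
does: score every second of a 12-h lights-on session as WAKE, NREM or REM;
quantify spectral band power per second, exclude extreme outliers, normalize
by recording-wide medians; summarise sleep architecture; and compare two
genotype groups metric by metric. Because no public recordings accompany the
phenotype this pipeline models, the package ships a ground-truthed synthetic
generator that plays the role of the animal cohort, and every claim the
pipeline makes is validated as *recovery* of effects the generator put in.

## Synthetic polysomnography

**Vigilance-state process.** A semi-Markov chain over {WAKE, NREM, REM}
emits alternating bouts. Dwell times are log-normal per state — rodent bout
durations are heavy-tailed — parameterized by mean and coefficient of
variation, truncated to ≥ 1 s and rounded to whole seconds; the final bout
is clipped so the bout list exactly tiles the recording. Defaults (mean
dwell: wake 120 s, NREM 95 s, REM 72 s; CV 1.0/1.0/0.8; wake never enters
REM directly, NREM→REM probability 0.45) give a stationary composition of
roughly 44% wake, 42% NREM and 13% REM of recording time — a plausible
lights-on mouse. These are generator choices, not literature estimates.

**Signal model.** Each EEG channel (frontal L/R, parietal L/R) is 1/f
Gaussian background noise plus state-conditioned oscillatory components:
band-pass-filtered Gaussian noise at a centre frequency and bandwidth, so
band *power* — not a line spectrum — is the recovered quantity. NREM
carries strong delta (2 Hz) and a spindle bump (14 Hz); REM is
theta-dominant (7 Hz, strongest parietally); wake is mixed with the highest
gamma. Component amplitudes switch at state boundaries with a 0.5-s
cross-fade (the true label of a transition second is the state occupying
most of it). Three accelerometer channels are white noise with
state-switched variance (wake 1.0, NREM 0.01, REM 0.003 in arbitrary
units²) — movement is modelled only as variance, with no gait or twitch
structure.

Three design choices matter for realism and are worth stating explicitly:

* **Few-fold, not order-of-magnitude, state contrasts.** Within each band
  the between-state power ratios are kept at the few-fold values seen in
  real rodent EEG (NREM/wake delta ≈ 5, wake/NREM beta ≈ 2, wake/NREM
  gamma ≈ 2.5). Extreme separations would make the per-second band-power
  mixture a stack of disjoint state modes, and the recording-wide medians
  used for normalization would then jump discontinuously with small
  animal-to-animal differences in state composition.
* **Slow amplitude modulation.** Every component (and the background)
  carries a slow log-normal amplitude envelope (component log-SD 0.15,
  background 0.2, per channel, ~10-s correlation time). Real within-state band power fluctuates strongly
  second to second; this is what makes recording-wide quantiles smooth
  functionals of the state mixture.
* **Shared carriers, local gains.** The band-limited carrier of each
  component is shared across channels — skull screw electrodes in a mouse
  see largely volume-conducted common sources — while each channel applies
  its own slow gain envelope and the 1/f background is channel-independent.

**Between-animal variability** is a per-animal log-normal jitter on every
component amplitude (CV 0.02, i.e. ~4% in power). This is deliberately
modest: the cohorts model littermates of an inbred transgenic line.

**Genotype effects** are the mutant phenotype, all expressed relative to
wild type: band-power multipliers per (state, role, band) — by default REM
beta ×2.0 in both roles, NREM parietal beta ×1.5, wake parietal delta ×1.5,
wake parietal gamma ×0.67 — a −1 Hz shift of the REM theta component, a
0.5× scale on all bout durations, and a REM-share increase (REM dwell
×1.25, NREM→REM entry ×1.25). The multiplicative magnitudes are free
parameters of the generator (the modelled study reports directions, not
effect sizes); they were fixed once at values that make each contrast
comfortably detectable at the study's group sizes (5 vs 9), which is the
regime the original statistics operated in.

## Epoch spectra and band power

Per 1-s epoch and EEG channel, power spectral density is estimated by Welch
with 0.5-s Hann segments and 50% overlap, evaluated on a 4× zero-padded
grid. The fundamental resolution is therefore 2 Hz (the grid is 0.5 Hz);
any trailing partial epoch is dropped. Bands are delta 0.5–4, theta 5–10,
spindle 11–19, beta 20–30, gamma 40–100, ripple 130–180 Hz — non-contiguous
as defined, with power in the gaps deliberately unassigned. Band power is
the arithmetic mean of PSD over bins whose centres fall inside the band
(inclusive bounds); the mean rather than the integral is scale-free after
normalization. **First-usable-bin rule:** a band's lower edge is raised to
the fundamental resolution, because padded grid points below it sit inside
the detrended DC main lobe; with the default estimator the delta band
effectively starts at 2 Hz. A sample rate of at least 360 Hz is required to
cover the ripple band.

**Outlier exclusion.** Per channel, a second is masked when *any* of its
band values lies above Q3 + 15·IQR or below Q1 − 15·IQR, with quartiles
taken over all epochs of the lights-on period. Two conventions are fixed
and matter: "elements" are interpreted at the band level (the quantity
subsequently analysed), not raw spectrogram bins; and quantiles use linear
interpolation. Masking is idempotent because fences are always computed
from the full raw series.

**Normalization.** Each (channel, band) series is divided by its median
over non-outlier epochs; by construction the median of unmasked normalized
values is 1. Note a structural consequence the analysis inherits from this
convention: a genotype effect confined to a state that dominates the
recording partially cancels, because it drags the median with it. The
generator's level orderings (wake lowest in delta, NREM lowest in beta)
keep each effect-carrying state away from its band's median, which is also
the physiologically natural ordering.

**State summaries.** Mean normalized power per (state, role, band) averages
non-outlier epochs per channel and then the left/right channels of a role;
a state absent from the hypnogram yields NaN, never zero. The REM theta
peak is the maximum of the REM-averaged PSD in 5–10 Hz, per role, with each
channel normalized by a scalar (its spectral integral) so channels weigh
equally — a scalar leaves the peak location untouched, whereas
per-frequency median normalization tilts the spectrum and biases the peak
upward by most of a bin. Sub-bin resolution comes from a parabola through
the argmax bin and its grid neighbours; ties break to the lower frequency.

## Automated staging

Three features per second, each smoothed by a centred 5-epoch median
filter: slow-wave activity (frontal delta power, median-normalized per
channel), theta ratio = theta/(delta+theta) from parietal channels (bounded
in [0, 1]; parietal sites carry volume-conducted hippocampal theta), and
movement (accelerometer variance summed over axes). The classifier is a
deterministic Otsu-threshold cascade — chosen over a mixture-model fit for
determinism and explainability, with every threshold logged: (1) high
log-movement → WAKE; (2) among still epochs, high log-SWA → NREM; (3) the
theta threshold is learned on *all* still epochs (the NREM cluster anchors
the low-theta mode — learning it only on the leftovers fails when they
contain a single cluster) on the log scale, where Otsu is not biased by the
unbalanced class masses; remaining still, low-SWA epochs above it → REM,
the rest → quiet WAKE. Runs shorter than `min_bout_s` (default 3 s; the
1-s scoring grain implies some smoothing since bouts are reported) are
absorbed into the longer flank, ties to the preceding state; first and last
runs are left as scored. Finally, REM bouts entered from prolonged wake are
relabelled WAKE: a REM bout survives only if NREM — or REM, since a
fragment of an interrupted REM bout is a continuation, not a wake→REM
transition — occurs within the preceding 10 s. Degenerate inputs (e.g.
constant movement) produce a warning and a single-state hypnogram rather
than an error. Which electrodes fed the original scorer this pipeline
models is unknown; the frontal-SWA/parietal-theta split is an assumption.

## Architecture metrics

A bout is a maximal run of identical labels; edge runs count, and no
minimum bout length is imposed here (smoothing belongs to the scorer), so
1-s singletons are counted. Per state: total seconds, bout count, mean bout
duration (NaN for absent states), and — for REM and NREM only — percentage
of total sleep time, TST = REM + NREM seconds (NaN when TST = 0).
Invariants: totals sum to the recording duration and
n_bouts × mean_bout_s = total_s exactly in integer seconds.

## Group statistics

Each metric is compared between genotypes two-sided at α = 0.05. A gate —
Shapiro–Wilk normality per group and median-centred Levene variance
equality, instruments unnamed in the design this models and therefore
logged per comparison — selects the pooled-variance t-test when all three
p-values exceed 0.05, otherwise the Mann–Whitney U test (exact null
distribution when the combined sample is ≤ 20 and tie-free; mid-rank ties
and the asymptotic method otherwise). Groups below n = 3 are an error, or
skipped on request (`on_insufficient="skip"`), which short recordings need
when a state is absent in some animals. A Kruskal–Wallis variant is
available behind a flag. Sex ratios use Pearson's chi-square without
continuity correction on the 2×2 genotype-by-sex table. Bonferroni families
follow figure panels: one family per architecture metric across states, one
per state across bands × roles for spectral power, one for the REM theta
peaks — family definitions are a declared convention, not derivable from
the modelled design.

## Validation experiments and problem sizes

The experiments in `somnospec.experiments` (run by `analysis/` scripts, the
acceptance tests and `scripts/acceptance.py`) simulate cohorts of 9
wild-type vs 5 mutant animals, the modelled study's group sizes.

* Architecture experiments need only hypnograms and use full 12-h
  durations.
* Signal-bearing experiments use time-compressed sessions at 400 Hz
  (Nyquist-safe for the ripple band): 60 min with dwell means scaled ×0.15
  for spectral recovery, 10 min for the null calibration. Compressing time
  without compressing bouts would leave a handful of sleep-wake cycles per
  recording and make the normalization medians wildly variable between
  animals; scaling both keeps the cycle count close to a full session.
  Staging recovery uses 1-h sessions with *unscaled* bouts, since scoring
  accuracy depends on bout structure, not on cycle count.

What passing these experiments shows — and what it does not: the generator
contains no electrode artifacts, no circadian drift, no EMG-distinct
movement structure, and its within-state spectra are stationary up to slow
log-normal gain. Staging accuracy near 0.94 here therefore states that the
cascade recovers states whose features match its model assumptions; real
recordings, with artifacts and manual-score ambiguity, will be harder.
Likewise the spectral-recovery rates certify the pipeline's sensitivity at
the configured effect sizes under this noise model, not the effect sizes of
any real colony.

## Numerical conventions and degenerate inputs

Quantiles: linear interpolation throughout. Otsu thresholds: 256-bin
histogram on finite values; a feature with range < 1e-12 is treated as
degenerate. Theta-peak parabola: skipped (bin centre returned) at grid
edges or when the three points are not concave. Empty states: NaN
propagated, dropped from tidy tables. EDF output quantizes each channel to
16 bits of its own physical range; a round trip is exact only to that
quantization. All randomness flows from one master seed through named
`SeedSequence` substreams per animal and stage, so cohorts are byte-stable
across runs and platforms with the same NumPy generation scheme.

## Known limitations

* The staging cascade is a transparent re-implementation of the
  feature-threshold approach, not a port of any published scorer's
  internals; agreement with a human-checked hypnogram on real data is
  unmeasured.
* Median normalization makes majority-state effects partially
  self-cancelling (see above); the pipeline reports what the convention
  measures.
* The generator's genotype effects are multiplicative and stationary; no
  state-transition dynamics beyond dwell scaling, no age or sex structure.
* Manual score editing is out of scope; `score --override` accepts an
  externally edited hypnogram instead.
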