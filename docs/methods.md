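# Methods

This note documents the models, numerical choices and open design decisions
behind the package, and what the synthetic-data tests do and do not show
about real recordings.

## Synthetic signals

**SSVEP EEG.** A trial attending target $t$ is, per channel,
$x(t) = g \sum_{h=1}^{H} a_h \sin(2\pi h f_t\, \tau + \phi_h) + n(\tau)$
with $H = 2$ harmonics, second-to-first harmonic amplitude ratio
$a_2/a_1 = 0.5$ (configurable; response morphology is not standardized),
channel-specific gains $g \sim U(0.7, 1.3)$ and uniform random phases.
The background $n$ is per-channel independent pink noise: white Gaussian
noise whose spectral amplitude is shaped by $f^{-1/2}$ (a $1/f$ power
spectrum, the conventional EEG background model), with the DC bin zeroed.
`snr` is defined as RMS(signal)/RMS(noise) per channel before summation;
the noise RMS is fixed at 5 µV so `snr=0` yields pure noise and
`snr=inf` a noise-free trial. Sampling is 256 Hz on three occipital
channels (O1, Oz, O2).

The generator spans failure-to-success regimes rather than imitating any
particular cohort: no published quantitative SNR distribution exists for
the target population. The levels used in tests are 0 (signal-free), 0.1
(near the decoding threshold for 2-s queries) and 1.0 (reliably decodable).
What passing tests show is that the *decoding machinery* behaves correctly
across those regimes — not that any human user would attain a given
accuracy. Real EEG adds non-stationarity, alpha activity overlapping the
stimulation band, eye-blink/EMG artifacts with structure richer than the
Poisson burst injector, and electrode drift; none of these are modeled.

**Gaze.** Trial gaze points are i.i.d. isotropic bivariate normal around
the target center with i.i.d. Bernoulli dropouts (60 Hz, 3-s trials).
The *continuous* gaze stream for the dwell simulator instead uses a
stationary AR(1) error process (per-sample correlation 0.95, i.e. a time
constant of roughly 0.3 s at 60 Hz) with the same marginal scatter:
independent 60-Hz jitter would make continuous dwell essentially
impossible at any realistic scatter, whereas fixational error is smooth.
Real gaze data additionally show saccadic structure, calibration bias
(systematic offset, not just scatter) and asymmetric dropout, which are
not modeled.

**Artifacts.** Bursts arrive as a Poisson process (events/minute), each a
Hann-windowed transient on one random channel with peak amplitude
`amplitude_factor` times the channel's pre-injection peak, sign-aligned so
the contaminated peak provably reaches that factor. Affected channels get
a quality flag. This reproduces the *failure mode* of intermittent
high-amplitude non-EEG contamination, not its physiology.

## Features

The per-frequency feature is the first canonical correlation between the
channel set and a bank of sin/cos references at the fundamental and second
harmonic. Channels are mean-centered per segment; each auto-covariance
block receives a ridge of $10^{-12} \times \mathrm{trace}$ before the
generalized eigensolve, which keeps duplicated or collinear channels
harmless while leaving noise-free in-subspace scores equal to 1 within
$10^{-9}$. A constant (flat-lined) segment returns all-zero scores with a
degenerate flag and a warning rather than an error, so upstream loops can
skip bad trials. Only the largest canonical correlation is used — standard
SSVEP practice, and it keeps each density one-dimensional. Scores from a
truncated window are computed by one shared path (truncate, rebuild bank,
rescore); no sliding-window averaging is applied.

## Likelihood models and the confusion channel

Densities are Gaussian-kernel KDEs with Silverman's rule bandwidth
$h = 0.9 \min(\hat\sigma, \mathrm{IQR}/1.34)\, n^{-1/5}$, floored at
$10^{-3}$ so repeated-datum calibration sets degrade to narrow peaks
instead of singular fits. Evaluated densities are floored at $10^{-12}$:
no class ever receives exactly zero mass, and log-space products over
frequencies cannot underflow. Frequencies are treated as independent in
the joint likelihood — an approximation; CCA scores share broadband noise.

The confusion matrix is estimated by leave-one-out classification (the
20-trials-per-target calibration is too small for a held-out split), with
Laplace smoothing (default pseudo-count 0.5) so no row is degenerate for
the capacity computation.

Gaze trials are summarized by the 20%-trimmed mean of valid samples;
trials with under 25% valid samples are "unrecognized" rather than forced
to a target. Whether the original eye-tracking decoder used positions,
velocities or dwell statistics is unknown; trial-mean position is an
assumption.

**Operating length.** Score distributions shift with trial duration, so
the decoder used online must be fitted on calibration scores truncated to
the operating trial length (`CalibrationResult.refit_at_length`). Fitting
at 6 s and decoding 2-s queries mis-calibrates the likelihoods badly
enough to destroy low-SNR performance.

## Capacity and trial length

Nykopp's information transfer rate is the capacity of the confusion
channel, computed by Blahut–Arimoto (tolerance $10^{-9}$ on the
upper-lower bound gap, 10,000 iteration cap, $0\log 0 \equiv 0$
throughout). Trial length maximizes capacity/(length + overhead) in
bits/s over a 1.0–6.0 s grid (0.5-s steps), ties toward the shortest
length. The overhead defaults to the 2-s inter-query pause; whether the
original system maximized bits/selection or bits/second is not stated, so
bits/second with configurable overhead is implemented. A plan whose best
rate falls below 0.12 bits/s is flagged degenerate; that threshold was set
~25% above the largest spurious rate observed in a 30-seed null simulation
(signal-free calibrations), whose small-sample leave-one-out rates reach
about 0.10 bits/s.

## Partition optimization

Exact search over $4^{28}$ assignments is infeasible. Because the
objective $I(\text{intended box}; \text{decoded box})$ depends on the
assignment only through per-box posterior mass, and mutual information is
concave in the input distribution, the search seeds by dealing characters
(largest posterior first) toward the channel's capacity-achieving input
distribution, with information-greedy and mass-balancing seedings as
further starts. Each start is hill-climbed by steepest ascent over a
vectorized candidate batch: single-character moves, pairwise exchanges,
whole-box relabelings (asymmetric channels make box identity matter), and
— for alphabets of at most 12 characters, where lumpy masses create
packing-type local optima — simultaneous two-character relocations. The
procedure is deterministic (ties break by alphabet order and lowest box
index) and achieved the exhaustive optimum to within 1% on 600 random
small instances during development, at about 2 ms per 28-character call.

## Selection loop and protocol

The posterior starts uniform at each character selection; conditioning on
previously typed text is exposed as a prior hook but off by default (how
the original system used "previous user inputs" is unspecified, and
guessing a language model would change behavior unverifiably). Updates run
in log space. Selection requires the maximum posterior to *strictly*
exceed the 0.85 threshold. Evidence is "recognized" when the largest
normalized box likelihood is at least 0.3 and the largest-to-second
ratio at least 1.05 — the protocol acknowledges unrecognized input
without defining it, so these are package defaults, as are the limits of
30 queries per selection and 10 consecutive unrecognized trials.
Simulated timing: 5 s initial alphabet display, the trial duration per
query, 2 s pause before each re-shuffle.

Copy-spelling sessions type five 5-letter words with backspace
error-correction semantics (backspace on an empty string counts as
incorrect; word advancement clears the typed string). Stop rules, in
precedence order: 20-min session cap; 5-min early stop with zero correct
selections; word advance after 4 consecutive incorrect selections or an
unrecognized-input run. The 65-word pool is a bundled list of common
five-letter words; word identity affects no computation. The dwell
baseline implements the fixed three-step hierarchy (alphabetical blocks of
≤7 assigned top→right→bottom→left, pairs within, then single characters)
with reset-on-exit dwell accumulation and a small central go-back target;
only the first-level "A–G in the top box" arrangement is documented for
the original interface, the rest is a config default.

## Metrics

Accuracy is reported two ways — crediting appropriate backspaces as
correct, and counting correct letters only — and typing speed three ways
(total selections, correct selections, correct letters per active typing
minute). Active typing time excludes between-word breaks but includes
query pauses within a selection, since they occur inside words; exports
round accuracies to one decimal while internal values keep full precision.
Sessions terminated by the early-stop rule still produce metrics (0%
accuracy), matching how failed baseline sessions are reported.

## Problem sizes used in tests

The shipped test-suite and acceptance-script sizes — 100 simulated
selections per SNR regime, 50 random partition instances against
exhaustive enumeration, 20 random channels against the simplex grid
(step 0.01), 200 random logs for the metric identity, 30–200 seed null
simulations behind frozen thresholds — were chosen so the full suite
exercises every regime in about a minute of compute while keeping binomial
confidence bands meaningful.

## Known limitations

- The EEG generator's phase-random harmonics and pink noise omit
  non-stationarity, alpha rhythms and real artifact morphology; absolute
  accuracies in simulation do not transfer to humans.
- Independence of CCA scores across frequencies is an approximation.
- The gaze decoder's trial-mean-position feature and the dwell AR(1) gaze
  model are plausible but unvalidated against real eye-tracking data.
- The language-model prior hook is unimplemented by design (unspecified in
  the source protocol).
- Wall-clock time is simulated throughout; the package is not a real-time
  presentation system and contains no stimulus rendering or device I/O.
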