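# Methods

`corrcode` implements a correlation-based analysis of sounds and of neural
ensemble activity, together with the Bayesian decoders that read sound
identity and sound category out of correlation statistics. This note
documents the models, the estimators, the numerical choices, and what the
synthetic data generator does and does not emulate.

## Cochlear front-end

Sounds are decomposed by a bank of gammatone filters,

    h_k(t) = a_k t^(n-1) exp(-2π b_k t) cos(2π f_k t + φ),   n = 3, φ = 0,

with center frequencies on a geometric ladder `f_k = f_min · 2^((k-1)·step)`
(defaults: 100 Hz, 1/8-octave steps, capped at 58 channels) and bandwidths
following human critical bands, `b(F) = 25 + 75 (1 + 1.4 F²)^0.69` Hz with
`F` in kHz (≈162 Hz at 1 kHz). Note the 1/8-octave ladder from 100 Hz to
16 kHz contains 59 points; we keep the first 58 (top ≈13.96 kHz) and expose
`f_max` and `max_channels` so either reading is available.

Filters are realized as FIRs by sampling `h_k(t)` and truncating where the
remaining envelope-energy tail falls below 10⁻⁴ of the total (via the
incomplete gamma function); `a_k` is set so the frequency-response
magnitude at `f_k` is exactly 1. Envelopes are the magnitude of the
analytic signal (Hilbert transform of the filter output), low-pass filtered
at 500 Hz by a linear-phase Kaiser-designed FIR (125 Hz transition, ≥60 dB
stopband) standing in for the hair-cell synapse, and decimated to a 1 kHz
envelope rate — the 500 Hz low-pass doubles as the anti-alias filter, since
500 Hz is the Nyquist frequency of the decimated rate. Each channel is
advanced by its gammatone envelope-peak delay `(n-1)/(2π b_k)` plus the FIR
group delay, so an impulse produces envelope peaks aligned within ±2 ms
across channels.

## Short-term correlation statistics of sounds

The running short-term correlation between cochleogram channels k and l is

    Φ_kl(t, τ) = Σ_γ S_k(γ) S_l(γ−τ) W²(t−γ),

where `W²` is a Kaiser window (β = 3.4) whose *resolution* τ_W is defined
as two temporal standard deviations of the normalized window; the window
length is solved numerically from that definition. Envelopes are **not**
mean-removed: cochlear envelopes are nonnegative and the un-centered
statistic is the one the indices and decoders consume. A consequence worth
knowing: two *independent* log-normal channels have zero-lag correlation
`exp(−s²)` (s the log-std), not 0.

Normalization divides by windowed *second moments*

    σ_k²(t) = Σ_γ S_k²(γ) W²(t−γ),   σ_l²(t, τ) = Σ_γ S_l²(γ−τ) W²(t−γ),

which by Cauchy–Schwarz bounds `c_kl = Φ/√(σ_k² σ_l²)` in [−1, 1] exactly
and gives `c_kk(t, 0) = 1` wherever the channel has power. (A first-moment
normalization would guarantee neither identity.) Time points where any
channel has zero windowed power are flagged invalid and excluded from
averages, as are points whose window or lag support overhangs the record.

The lag grid is symmetric and strictly inside ±τ_W/2: at τ_W = 100 ms and
1 kHz this is −49…+49 samples, i.e. M = 99 lags, the dimension used in the
stationarity-index vectorization (an inclusive grid would give 101).

The windowed estimator attaches the window to the first channel's time
axis, so the exact symmetry is `Φ_kl(t, τ) = Φ_lk(t−τ, −τ)`; the common
statement `c_kl(t, τ) ≈ c_lk(t, −τ)` holds only up to that τ-sized window
shift and is treated as approximate in the tests.

Decompositions: *spectral* features are the zero-lag matrix's upper
triangle (L(L+1)/2 values per time point); *temporal* features are the
same-channel lag profiles with (time, channel) pairs as observations, so
temporal structure is not tied to a channel; *spectro-temporal* features
vectorize the full M·L² tensor. Time-averaged correlations also report the
full widths of the channel-averaged autocorrelation at 50% and 10% of its
peak-to-floor range — range-normalized because un-centered envelope
correlations decay to a positive floor.

## Stationarity and diversity indices

With `c̄(t)` the M·L²-dimensional correlation vector at time t (τ_W =
100 ms by convention),

    SI  = 1 − ⟨‖c̄(t) − ⟨c̄⟩‖⟩ / ‖⟨c̄⟩‖      (clipped to [0, 1]),
    CDI = E_n[‖c̄_n − E[c̄_n]‖] / ‖E[c̄_n]‖,

where `c̄_n` is the time-averaged vector of ensemble member n. The CDI
numerator averages the deviation *norms* across members (the
"variance-across-the-ensemble" reading); the alternative — norm of the mean
deviation — is identically zero and therefore cannot be the intended
estimator. Both indices are invariant to common scaling because the
underlying correlations are normalized. Correlation-similarity comparisons
use the Pearson coefficient over corresponding entries, optionally
excluding the k = l diagonal (spectral) or the τ = 0 entries (temporal).

## Trial-shuffled neural correlations

Neural responses are channel × trial × time aMUA envelopes at 2 kHz, with
per-channel per-trial global means removed. The stimulus-driven (signal)
correlogram averages windowed cross-correlations over *different* trial
pairs; it is computed with the fast PSTH-based form

    Φ_stim = [N² Φ_PSTH − Σ_m φ_kl,mm] / (N(N−1)),

which costs N+1 windowed correlations per channel pair instead of N(N−1)
and is verified against the literal double sum to 10⁻¹⁰ relative error in
the tests. The unshuffled correlogram averages same-trial correlations;
the noise correlogram is unshuffled minus shuffled. The analysis window is
a unit-amplitude rectangle (62.5–1000 ms on a half-octave ladder), so
W² = W and the first/second-moment distinction does not arise.

Normalization uses the trial-averaged windowed second moment of the
mean-removed response, `σ_k²(t) = (1/N) Σ_m Σ_γ r²_km(γ) W²(t−γ)` (and its
τ-shifted analog with the same global means — re-centering inside each
shifted window would break the identities below). This makes

    c_total = c_stim + c_noise  (exactly, by construction), and
    c_total,kk(t, 0) = 1        (exactly, wherever power > 0),

while the diagonal zero-lag entries of `c_stim` and `c_noise` individually
stay below 1 whenever trial-to-trial variability is present. Cauchy–Schwarz
bounds `c_stim` and `c_total` in [−1, 1]; `c_noise`, being their
difference, is bounded by construction only through them.

Population summaries collapse spectral matrices along diagonals to a
channel-offset profile and temporal correlations across channels to a lag
profile, enabling averaging across ensembles with different frequency
ranges.

## Decoders

All decoders share one scheme: PCA on training observations only,
per-class likelihood models on the retained scores, equiprobable priors,
and MAP decisions by summed log-likelihood over conditionally independent
observations.

**Neural (naive Bayes).** Per-class axis-aligned Gaussians. PCA retention
is either a fixed count, a variance fraction, or a sweep over 1…min(40,
n−1) components choosing the count that maximizes accuracy on a nested
stratified 70/30 split of the training data. Class variances are floored
at 10⁻⁶ of the mean score variance. The *noiseless* decoder draws
trial-shuffled correlations about randomly selected time points (500 ms
model windows); the *single-trial* decoder draws same-trial correlograms
with the trial index randomized jointly with the time point (1000 ms model
windows), normalized per trial. Validation windows vary over the
half-octave duration ladder; each classification uses one window, and
accuracy is averaged over random (time, trial) draws — the
repeated-single-window reading of duration. The joint spectro-temporal
decoder model-averages the spectral and temporal log-posteriors,
`L = α·log P_spec + (1−α)·log P_temp`, with α grid-searched (step 0.05,
ties to the smaller α) to maximize the training-data true-class
log-posterior. The tonotopy-shuffle control permutes the channel blocks of
*validation* temporal features per observation, leaving training intact;
the spectrum (rate-code) control replaces correlations with windowed
per-channel mean responses.

**Sound categories (GMM).** PCA retains the components explaining 90% of
training variance; each category's likelihood is a diagonal-covariance
Gaussian mixture fit by EM (k-means initialization, 5 restarts, covariance
floor 10⁻⁶ of the mean score variance, tolerance 10⁻⁶, up to 500
iterations), with the component count selected from a grid (1–20 in the
full configuration) by 5-fold cross-validated held-out log-likelihood.
Model observations come from successive *non-overlapping* analysis
windows; a duration of N segments uses the first N windows from sound
onset, and the N ladder advances in half-octave steps. Cross-validation
over sounds is leave-one-out: each held-out sound scores 0 or 100%, and
accuracy averages the iterations.

**Performance curves.** The asymptote is the accuracy at the longest
duration; the integration rise time τ_c is the first duration reaching 90%
of the asymptote, log-linearly interpolated between grid points (first
crossing, with a warning, if the curve is non-monotone).

## Preprocessing

aMUA extraction: band-pass 325–3000 Hz, full-wave rectify, low-pass
475 Hz, resample to 2 kHz; all filters are linear-phase Kaiser FIRs with
125 Hz transitions and ≥60 dB stopbands, group-delay compensated, so the
envelope is α-homogeneous in the input gain and DC is rejected.

1/f equalization: a zero-phase inversion filter with amplitude response
`H(f) = C / (S(f) √f)` is applied by frequency-domain multiplication,
where `S(f)` is the sound's Welch *magnitude* spectrum (Kaiser window,
≥40 dB sidelobes, 10 Hz resolution). The √f — rather than f — in the
denominator is what makes the output *power* spectrum proportional to 1/f
(equal power per octave); an f⁻¹ amplitude response would produce a 1/f²
power spectrum instead. The equalized band defaults to 50 Hz–0.45·fs with
cosine roll-offs outside; spectral bins below max(S)/10⁵ are floored with
a warning; C is set so the output RMS equals the input RMS exactly.

## Synthetic data: what it emulates, and what it does not

`gen_correlated_envelopes` draws stationary latent Gaussian processes by
circulant spectral synthesis (covariance exact at all lags up to the
record length, up to clipping of tiny negative spectral values), mixes
them across channels by an eigenvalue square root of the target
correlation matrix (non-PSD targets raise, naming the offending
eigenvalue), and exponentiates: log-normal envelopes. The transform is
monotone and sign-preserving, and the achieved envelope correlation has
the closed form `(e^{ρs²}−1)/(e^{s²}−1)`, so targeting is verifiable
against a Monte-Carlo oracle. Temporal kernels are exponential (fast/slow)
or exponentially damped cosines (periodic, e.g. ~20 Hz). Nonstationary
"speech-like" textures alternate deterministically between regimes every
`switch_period` seconds — reproducible nonstationarity for the SI tests.

Category datasets plant the contrasts the analysis is meant to detect:
broad + fast (fire-like), near-diagonal + fast (water-like), broad + slow
+ switching (speech-like), with exemplar parameters jittered
multiplicatively by `exp(jitter·N(0,1))`. Default exemplar duration is
10 s, matching the length of the natural-sound recordings such category
databases typically provide.

`gen_ensemble_raster` adds trial-independent noise with controlled
structure: channel mixing by a sliding boxcar of width reach+1 gives a
triangular spatial correlation `(reach+1−d)/(reach+1)` that is *exactly*
zero beyond the reach; Gaussian temporal smoothing gives a Gaussian noise
autocorrelation whose FWHM equals `temporal_width`. Noise SD is
`noise_gain` times each channel's signal SD (unit scale on silent
channels, so pure-noise rasters are well-defined). Ground truth is
attached to the raster for oracle tests.

What passing tests on these data do **not** show: the generator produces
second-order (correlation) structure only — no sparse acoustic events, no
modulation-depth or higher-order texture statistics, no adaptation or
nonlinear gain control in the "neural" responses, and noise that is
Gaussian and stationary rather than state-dependent. Conclusions about
real recordings inherit those caveats.

## Numerical and design notes

* The windowed-correlation engine evaluates all lags and channel pairs at
  a window center with one BLAS matrix product over a strided view of the
  lagged record; brute-force triple-loop oracles in the test suite pin it
  to 10⁻¹²–10⁻¹⁰ relative error.
* Window centers for running estimates default to a quarter-window hop;
  classifiers use non-overlapping windows (sounds) or random draws
  (neural), with train/validation splits expressed as fractions of the
  record.
* Ties in MAP decisions break toward the lowest class index; ties in the
  α grid toward the smaller α.
* Problem sizes in the test and acceptance suites (8–16 channels, 10–40
  trials, 4–60 s records) are chosen so every check runs comfortably on a
  single CPU while keeping estimator errors well inside the asserted
  tolerances.
* The noiseless-vs-single-trial accuracy ordering is a statement about
  trial noise; it is exercised on ensembles whose sounds share envelope
  timescales. When class timescales differ strongly and the validation
  window is much shorter than the model window, short-window feature
  overdispersion can favor the widest class under a naive-Bayes variance
  model — a train/validation mismatch effect, not a property of the
  shuffling estimator.

## Known limitations

* Single-trial features are normalized per trial; alternative
  normalizations (ensemble variance) would change feature scale but not
  the decision structure.
* The equalizer estimates spectra at 10 Hz resolution; sounds shorter than
  ~0.2 s cannot be equalized.
* `classify_loo` truncates requested durations to the shortest sound with
  a warning rather than failing.
* The cochlear model is linear up to envelope extraction: no compression,
  adaptation, or efferent effects.
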