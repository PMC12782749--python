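# Methods

## Overview

`epinet` implements a low-dimensional, interpretable pipeline for locating
epileptogenic networks (EpiNets) from interictal intracranial EEG. The
premise is that although many biomarkers of epileptogenicity exist —
aberrant critical dynamics of local oscillations, pathological bistability,
shifted excitation/inhibition balance, abnormally strong phase synchrony,
interictal spikes — their diagnostic content is largely shared and can be
compressed into very few latent dimensions. The pipeline therefore:

1. extracts a large bank of per-channel narrowband features,
2. learns an orthonormal *eigenfeature* basis by SVD of the pooled,
   within-subject-normalized feature matrix,
3. ranks eigenfeature coefficients by the effect size of the clinical
   label contrast against label-shuffled surrogates and retains the top
   r = 10,
4. converts the two leading coefficients (Phi1, Phi2) into a probabilistic
   EpiNet-saliency lookup surface via consensus soft clustering, and
5. applies that two-input model time-resolved to long sleep recordings,
   validating the output against spike-density dynamics and a canonical
   polyadic (CP) tensor decomposition of the raw feature tensor.

Because clinical SEEG cannot be redistributed, the package ships a
first-class synthetic-data module that generates multichannel recordings
with planted ground truth, and the entire test suite runs against it.

## Feature bank

Broadband signals are low-pass filtered (equiripple FIR, passband edge
440 Hz, stopband 500 Hz, passband ripple <= 2%) and line noise (50 Hz base
and harmonics, configurable) is removed with narrow FIR band-stops
(~53 dB). Filters are applied by centred convolution, i.e. zero phase.

Narrowband analytic signals come from complex Morlet wavelets at
log10-spaced centre frequencies: 20 bands from 2-225 Hz with m = 5 cycles
for criticality features, and 50 bands from 2-450 Hz with m = 7.5 for
synchrony. One wavelet support (m/f seconds) is discarded at each edge.

Per channel and band, three criticality features:

* **DFA exponent** — slope of log10 RMS detrended fluctuation vs log10
  window size of the cumulative demeaned amplitude envelope; 16 log-spaced
  window sizes from 1 s to a tenth of the segment, non-overlapping windows,
  linear detrending. Values > 0.6 mark significant long-range temporal
  correlations (the extended critical / Griffiths-phase regime).
* **Bistability index (BiS)** — per-sample BIC difference between a two-
  and a one-component Gaussian mixture fitted to the log-envelope
  (deterministic subsample, default 2000 points). Positive values support
  a two-state amplitude distribution and grow with mode separation; a
  log-normal (unimodal) envelope gives BiS <= 0.
* **Functional E/I (fE/I)** — the envelope is cut into 5 s windows; per
  window the mean amplitude and the detrended fluctuation of the
  amplitude-normalized profile are computed; fE/I = 1 - r, their
  correlation across windows. fE/I > 1 (negative r, fluctuations shrink at
  high amplitude) marks excitation-dominant dynamics, < 1
  inhibition-dominant. The estimator is only defined inside the critical
  regime and returns NaN when the envelope's DFA exponent is <= 0.6.

Per band, the phase-locking value (PLV) matrix — modulus of the
time-averaged unit phasor of pairwise phase differences — yields four node
features on the weighted graph: eigenvector centrality (EVC, leading
eigenvector, unit max), effective weight (We, mean weight of a node's
suprathreshold edges, threshold = graph-median edge weight; configurable
to plain node strength), clustering coefficient (Cc, Onnela geometric-mean
triangle intensity on the suprathreshold graph) and local efficiency (LE,
mean inverse shortest-path length within each node's neighborhood,
distances 1/weight). We is not uniquely pinned down by published
descriptions; the graph-median construction was chosen as the simplest
first-order hub measure and is exposed as a parameter.

The default configuration yields k = 3 x 20 + 4 x 50 = 260 features per
channel. For the supervised baseline only, normalized narrowband features
are averaged into 4 criticality clusters (delta 2-4, theta-alpha 5.4-11,
beta 15-30, gamma 45-225 Hz) and 6 synchrony clusters (delta-theta 2-5.4,
alpha 6.1-13, beta 15-30, gamma1 40-96, gamma2 110-250, gamma3
270-450 Hz), giving 36 band-collapsed features.

## Latent space and saliency model

Per feature and subject, values are normalized across channels as
x_hat = (x - median) / max(x - median), so the median channel maps to 0
and the most deviant channel to 1. NaN features (degenerate channels,
gated fE/I) are median-imputed with a logged warning. The normalization is
applied before the SVD: pooling raw features across subjects would
otherwise let between-subject offsets dominate the leading eigenfeatures.

The pooled matrix X (k x q) is decomposed X = U S V'; only U is kept.
Each column of U is oriented so its largest-|loading| element is positive
(removes sign ambiguity). Coefficients Phi = U'X are ranked by pooled
Cohen's d (n-1 pooled SD, ties broken by index) of the positive/negative
label contrast; significance uses label-shuffled surrogates (default
10^4). Three null summaries are kept: per-coefficient 2.5/97.5
percentiles and the rank-sorted null |d| curve (both for ranking
diagnostics and plots), and the 95th percentile of the per-shuffle
maximum |d| — the single-step max-statistic (Westfall-Young), which is
what "a coefficient exceeds the surrogate bounds" refers to. Only the
max-statistic gives a family-wise guarantee: with pointwise 95%
intervals, a null cohort with k coefficients would show ~0.05k spurious
exceedances by construction. A
within-subject validation (median across subjects of per-subject d) is
provided. The retained top-10 rows form the reduced basis; each retained
row is additionally flipped so the positive class has the higher
coefficient, making "high Phi1" mean "more pathological" at test time
when labels do not exist.

Channels pooled across training subjects are then soft-clustered in the
retained coordinates with Gaussian mixtures and Fuzzy C-means (fuzzifier
m = 2), each with 2 clusters, on the top-n coefficients for n = 2..10.
The cluster with the higher mean Phi1 is the EpiNet cluster; at training
time the orientation is checked against labels and a warning is raised if
it is not positive-class enriched. Memberships are averaged across n
within each classifier and the two classifier means are averaged into the
consensus membership M_hat.

The saliency surface bins the training (Phi1, Phi2) plane into 30 x 30
linear bins, takes per-bin mean M_hat, triangulates the populated bin
centres, and interpolates linearly inside the convex hull. Outside the
hull the nearest populated bin's value is used rather than planar
extrapolation: membership is bounded in [0, 1], so any unbounded linear
extension would immediately saturate at the clip and make far-field
values depend on triangulation details; the nearest-value rule is
deterministic and bounded. All outputs are clipped to [0, 1].

Applied to a new recording, features are extracted in sliding windows
(default 10 min window, 1 min step), normalized within subject per
window, projected through the reduced basis, and the (Phi1, Phi2) pair
per channel and window is looked up: lambda_hat(q, t). The channel mean
Lambda_hat(t) is the momentary global saliency; the per-window AUC of
lambda_hat against labels (Mann-Whitney with midranks) summarizes
classification performance over time.

## Spike machinery

A 0.5 s window of a broadband channel is "spiky" when >= 3 consecutive
samples exceed the session mean + 7 SD (one-sided positive; configurable
to bipolar); spike density is the percentage of spiky windows. The global
density trace is demeaned, smoothed (10 min moving average) and
Hilbert-transformed to give the phase of its slow fluctuation; effects of
label on saliency can be resolved into four 90-degree phase bins with
label-shuffled surrogate bounds.

## Tensor validation

The raw sleep feature tensor X (k x q x t) is z-scored per feature over
(channels x time) — feature scales are otherwise wildly heterogeneous —
and factorized by unconstrained CP-ALS with R components (default 20;
desk-scale preset 5), three random restarts, best fit kept; the relative
reconstruction error is non-increasing per iteration. Per-component time
loadings are rank-correlated with Lambda_hat(t) and with the global spike
density; significance uses circular-shift surrogates, which preserve
autocorrelation where plain shuffles would not.

A caveat on component selectivity: on synthetic sleep subjects the
planted ultradian modulation contaminates many channels' features (graph
features are global, so modulating the pathological channels' coupling
moves every node's centrality), and with only tens of analysis windows
CP spreads that shared temporal pattern across several components — more
than one time loading then exceeds the shift null. The selectivity of
the surrogate machinery (exactly the pathological component flagged) is
therefore assessed on directly planted tensors at a clinically realistic
temporal size (400 windows, 90 min ultradian period), where it holds in
>= 90% of runs. Inter-contact similarity
matrices (Pearson correlations between contact loading vectors, between
lambda_hat time courses, and between spike-density time courses) are
compared with Mantel-style row/column permutation nulls, and the
saliency-linked component (largest rho^2 against Lambda_hat) gets a
label contrast on its contact loadings (t-test, Cohen's d, surrogate z).

## Synthetic cohorts

Each channel is an amplitude-modulated narrowband oscillation (carrier
10 Hz) on a pink-noise background, with spikes added at Poisson times:

* The slow envelope is exp(0.35 * fGn(H)), with fractional Gaussian noise
  sampled exactly by Davies-Harte circulant embedding, so the planted DFA
  target is analytic and the unimodal log-envelope is Gaussian by
  construction (BiS <= 0).
* Bistability multiplies the envelope by a smoothed two-state telegraph
  process (mean dwell 10 s; level ratio 1 + bistability_level).
* The E/I regime couples the gain of fast (sub-5 s) multiplicative
  envelope fluctuations to the local mean amplitude with exponent -3
  (excitation: relative fluctuations shrink at high amplitude, the
  saturation signature) or +3 (inhibition). The additive form
  m * (1 + 0.3 * fast * gain) keeps window means unbiased by the gain; a
  floor at 0.05 m guards positivity.
* Channels in a coupling group mix a shared phase-diffusing 10 Hz driver
  into their carrier at coupling_strength c: (1-c) cos(own) + c cos(driver).
  Within-group PLV rises monotonically with c.
* Default planted contrast: EpiNet channels H = 0.85, level ratio 4,
  inhibition-dominant, coupling 0.8 (one shared group), 3 spikes/min;
  background channels H = 0.6, unimodal, balanced, coupling 0.1 in groups
  of four, 0.2 spikes/min. Background dynamics are not quantitatively
  constrained by clinical data; these defaults are chosen for contrast,
  not fidelity. The E/I gain coupling scales with a per-channel
  ``ei_strength`` so that graded-pathology channels can be generated
  (`graded_channel_spec` interpolates every parameter between background
  and EpiNet defaults).
* Cohort assembly perturbs every channel's parameters
  (`perturb_channel_spec`: Hurst SD 0.08, coupling SD 0.12, multiplicative
  jitter on bistability and spike rate). Real contacts are heterogeneous;
  without channel-level jitter every channel estimates its nominal
  parameters almost exactly, and ensemble classifiers can aggregate even
  minute systematic offsets into perfect channel classification, which
  abolishes the graded relationship between planted contrast and
  classification accuracy that the coupling analyses rely on. Jitter is
  drawn once per channel, so it is correlated across that channel's
  features, as biological variability would be.
* Sleep mode synthesizes a background twin and an EpiNet twin of each
  pathological channel and crossfades them under an ultradian envelope
  s(t) in [0, 1] (sinusoid + slow noise; default period 90 min, desk
  scale 15 min), which is stored as the ground-truth saliency. The
  crossfade weight is s^2: amplitude mixing is strongly convex in the
  downstream feature response (the pathological component dominates
  synchrony and LRTC estimates well below equal weight), and squaring
  makes planted saliency map roughly linearly onto feature contrast
  instead of saturating early in the cycle. Spike trains are thinned by
  the same envelope.
* One master seed; per-subject and per-channel substreams via
  `numpy.random.SeedSequence` spawning. Identical (spec, seed) pairs are
  bit-reproducible.

What the generator does *not* emulate: volume conduction and referencing
artifacts, realistic 1/f spectra with oscillatory peaks at several
frequencies, non-stationary artifacts, seizures, and medication effects.
Passing tests therefore demonstrate that the pipeline recovers the
specific statistical structure it models — not clinical performance.

## Desk-scale configuration

The `PipelineConfig.reduced()` preset keeps every structural choice of
the default configuration but shrinks the problem: 128 Hz sampling,
8 criticality bands 2-32 Hz, 10 synchrony bands 2-40 Hz (k = 64),
2000 ranking shuffles, CP rank 5. Test cohorts use 6 training subjects x
20 channels x 10 min, a 40 min sleep subject with a 15 min ultradian
cycle assessed with a 2 min window and 1 min step (>= 2 full cycles,
39 windows), and a 20-subject graded-contrast cohort (16 channels x
5 min) for the saliency-accuracy coupling. Sizes were chosen so that
k <= q everywhere (the SVD requires pooling at least as many channels as
features) and each analysis stays within interactive runtimes.

## Numerical choices and degenerate inputs

* DFA window sizes are clamped to >= 8 samples; constant envelopes yield
  NaN with a warning.
* BiS subsampling is deterministic (evenly strided), so identical
  envelopes give identical scores; GMM fits use a fixed seed.
* fE/I returns exactly 1 when either windowed quantity is constant.
* The spike detector returns all-false with a warning on zero-variance
  channels; a run of suprathreshold samples split across a window
  boundary is not counted by either window (the printed rule is applied
  per window).
* PLV matrices are clipped to [0, 1] and the diagonal forced to 1.
* CP-ALS normalizes factors to unit column norm with weights sorted
  descending; non-convergence within max_iter returns the best fit with
  a warning flag.
* GMM clustering failures are retried with incremented seeds (<= 6) before
  erroring.

## Known limitations

* Orienting the retained eigenfeature axes so the positive class scores
  higher is a label-dependent choice: on a cohort with no real contrast
  it aligns the axes with label noise, which biases the *in-sample*
  membership AUC above 0.5 (~0.6-0.7 in practice). Out-of-sample
  assessments (projecting held-out channels through the frozen basis and
  surface) do not inherit this bias and are the appropriate null check.

* BiS measures evidence for *any* second mixture component, so strongly
  skewed or heavy-tailed unimodal envelopes can score mildly positive;
  the unimodal null used in tests is the appropriate reference.
* fE/I is undefined outside the critical regime by construction; on
  cohorts where background channels sit near DFA 0.6 roughly half the
  fE/I entries are NaN and are median-imputed before the SVD.
* The saliency surface is only as good as the training support; queries
  far outside it return the nearest populated bin's value, which is
  deliberate but means extrapolated saliency carries no gradient
  information.
* CP components are identifiable only up to scale/sign and component
  order; congruence-based matching is used in all recovery checks.
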