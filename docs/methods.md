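# Methods

`microstatekit` implements a complete resting-state EEG microstate
analysis — preprocessing, group-level polarity-invariant segmentation,
backfitting, temporal-parameter extraction and group statistics — together
with a synthetic two-group cohort generator whose every output has a
recorded ground truth.  This note documents the model, the conventions and
defaults, the numerical choices, and what the synthetic cohorts do and do
not establish about real data.

## The microstate model

Multichannel EEG is treated as a sequence of quasi-stable scalp potential
topographies ("microstates"), each lasting on the order of 50–125 ms,
conventionally clustered into four classes labelled A–D.  Only the *shape*
of the map carries information: a topography and its polarity inversion
are the same state (spontaneous alpha-band activity reverses sign twice
per cycle).  Everything in the analysis path is therefore polarity
invariant: spatial similarity is the absolute Pearson correlation across
channels of the two zero-meaned maps, clustering assigns by squared
projection, and global map dissimilarity (GMD) is minimized over sign.

Conventions the literature leaves open, fixed here:

* **GFP** is the *population* standard deviation across channels
  (divide by the channel count, not count − 1).
* **Spatial correlation** is Pearson across channels of zero-meaned maps;
  polarity ignored by taking absolute values.
* **GMD** between GFP-normalized maps x̂, â is
  `min_± sqrt(mean_c (x̂_c ∓ â_c)^2) = sqrt(2(1 − |corr|))`.
* **GEV** = `Σ_t (GFP_t · |corr(x_t, a_{L_t})|)^2 / Σ_t GFP_t^2`.

## Analysis chain and defaults

1. **Preprocessing** (deterministic, fixed order): average reference →
   1–20 Hz band-pass → downsample to 250 Hz → 2 s epochs → rejection of
   any epoch whose absolute amplitude strictly exceeds 80 µV at any
   electrode → exclusion of subjects with fewer than 100 clean epochs.
   The filter is a 4th-order Butterworth applied forward–backward (SOS
   realization, zero phase); resampling is polyphase with anti-aliasing.
   An optional time-window crop (e.g. minutes 2–7 of a longer recording)
   can precede all stages.  The original toolchain's ICA artifact
   correction is a documented no-op hook: synthetic cohorts contain no
   artifacts, and real-data users can plug a corrector callable in.
   The amplitude rule is applied per epoch to the filtered, re-referenced
   signal, with a strict `>` bound ("exceeding").
2. **GFP peaks**: strict local maxima within epochs, kept greedily in
   descending height with a 10 ms minimum separation (ties go to the
   earlier sample).  Per subject, peaks higher than mean + 2 SD of that
   subject's peak heights are eliminated (one-sided — the aim is removing
   abnormally strong fields), and 1,000 of the survivors are sampled
   uniformly without replacement under a fixed seed.
3. **Clustering**: all subjects' selected peak maps are concatenated into
   one pool (a single joint group-level clustering across both groups) and
   clustered by the modified K-means algorithm with K = 4, 50 random
   restarts, at most 1,000 iterations each, and a relative-GEV convergence
   tolerance of 1e-6 (the tolerance is our choice; restarts and the
   iteration cap are the study's).  Each restart initializes from K
   distinct pool maps; assignment is `argmax_k (x_t·a_k)^2`; the update
   replaces `a_k` with the principal eigenvector of `Σ_{t∈k} x_t x_tᵀ`
   (computed by warm-started power iteration, which preserves the ascent
   property at every step — GEV is asserted non-decreasing within each
   restart).  An emptied cluster is re-seeded from the pool map currently
   worst fitted.  The restart with the highest GEV wins.
4. **Canonical ordering**: prototypes are assigned to the A–D archetypes
   by exact search over all 4! permutations maximizing total |corr|
   (ties broken lexicographically).  For K ≠ 4 the classes are labelled
   1..K and no canonical mapping is attempted.
5. **Backfitting**: every frame is labelled with the prototype of highest
   absolute spatial correlation; zero-GFP frames inherit the nearest
   labelled frame within the epoch.
6. **Smoothing**: segments shorter than 30 ms are dissolved, shortest
   first, within epochs.  Each frame of a rejected segment moves to its
   *next most likely* class by GMD — rejections are cumulative per frame
   (a dissolved class cannot return to the same frame), which is what
   makes the walk down each frame's similarity ranking terminate; a frame
   that exhausts all classes is merged into the neighbouring segment with
   the smaller mean GMD.  Epochs are treated as independent; segments
   truncated at epoch edges are retained and counted (flagged in output
   metadata), because excluding them would bias duration differently per
   class.
7. **Parameters** per subject and class: mean segment duration (ms),
   occurrence (segments/s), coverage (time fraction), and conditional
   transition probabilities between consecutive within-epoch segments
   (row-normalized by outgoing count; rows without outgoing transitions
   are zero and flagged).  Because boundary segments enter all three
   statistics, `occurrence × duration/1000 = coverage` holds exactly.
8. **Statistics**: pooled-variance Student t-tests (df = n1+n2−2; Welch
   by flag) on all 24 parameters, raw p-values by default with an
   optional Benjamini–Hochberg column; Spearman correlations (mid-rank
   ties, t-approximation) between smokers' microstate features and FTND,
   cigarettes/day and pack-years.  An exact permutation p is available
   for n ≤ 8 (8! permutations; beyond that enumeration is impractical and
   the t-approximation is accurate).

## The synthetic cohort generator

The generator emulates a 25 + 25 two-group study (smokers vs non-smoking
controls), eyes closed, 64 channels in a standard 10-20 layout, 5 min of
usable signal per subject at 250 Hz.  It synthesizes directly at the
analysis rate — generating at a higher hardware rate and decimating would
add cost without adding information; the resampler is exercised by its
own unit tests on constructed signals.

* **State sequence**: semi-Markov.  The next class is drawn among the
  other three classes proportionally to per-class *entry weights*
  (uniform by default); run lengths are discretized gamma draws
  (shape 4, minimum one sample) with the subject's per-class mean.  A
  gamma with shape 4 puts the mode near the mean, as observed segment
  distributions do; a geometric law would make sub-30 ms segments
  dominate.
* **Forward model**: `x_t = s · a_t · map_{L_t} + noise`, where `a_t` is
  a band-limited Gaussian carrier (8–12 Hz) of unit RMS and `s` a random
  ±1 per segment.  The carrier's own sign alternation plus the segment
  flips make polarity completely uninformative, |a_t| is the momentary
  field-strength envelope, and GFP peaks fall at envelope maxima (twice
  per alpha cycle, as in real eyes-closed EEG).  Keeping the amplitude
  signed keeps the signal spectrum inside the carrier band, so the 1–20 Hz
  analysis filter passes the topography intact; a rectified (always
  positive) amplitude would concentrate power at DC, which the 1 Hz
  high-pass removes — an early design iteration confirmed that variant
  loses ~20 percentage points of frame-label accuracy purely to the
  filter.  Noise is Gaussian and spatially white by default (a uniform
  channel-correlation option exists, off by default), scaled so
  state-signal RMS / noise RMS equals the requested SNR (default 4); the
  global amplitude scale is 15 µV, giving realistic ±25 µV traces that
  stay below the 80 µV rejection bound in clean data.
* **Templates**: the four archetypes are smooth dipolar Gaussian fields
  on the sensor sheet — A and B mirror-image diagonals (right-frontal /
  left-posterior and left-frontal / right-posterior), C an
  anterior–posterior dipole, D a fronto-central peak — zero-meaned,
  unit-normed, with every pairwise |corr| < 0.7 (measured maximum ≈ 0.55).
* **Planted effects** (directions as reported for nicotine dependence):
  smokers' class-C entry weight is 0.7 (longer gaps between C visits →
  ~21 % lower C occurrence with durations untouched); smokers' class-D
  mean duration is 100 ms vs 85 ms in controls; within smokers the class-D
  mean moves by −4 ms per FTND point about the FTND midpoint, so the
  group difference and the within-group correlation are controlled
  independently.  FTND scores are uniform integers on [3, 10] (the
  study's inclusion bound).  Between-subject variability is a 10 %
  lognormal jitter on each class mean.  These magnitudes were fixed once,
  by an a-priori power calculation (stationary distribution of the
  switch chain plus a two-sample power formula), to be comfortably
  detectable at n = 25 per group — they are generator properties, not
  fitted values.
* **Determinism**: all randomness flows from one master seed; subject
  *i* draws from an independent substream keyed `(seed, i)`, and cohort
  demographics from `(seed, 10000)`.  Re-running a spec reproduces every
  artifact bit for bit.
* **Truth tables** are computed from the generated label sequences with
  the same `features` code used by the analysis, so the truth and the
  recovered parameters share one measurement definition.

### What the synthetic cohorts do not show

No ocular/muscle artifacts (hence the ICA no-op), no volume-conduction
forward model, no 1/f background or non-alpha rhythms, no electrode
drift, no missing channels.  Passing recovery tests therefore shows the
*algorithm chain* is correct and unbiased under the stated generative
model; it does not certify performance on recordings whose noise violates
those assumptions.

## Study-scale evaluation sizes

The recovery evaluation runs the complete chain on the default cohort
(50 subjects × 300 s × 64 channels, SNR 4, seed 0; ≈50,000 pooled peak
maps) in about a minute.  Power, type-I-error and correlation-recovery
rates use 100 replicate cohorts with 120 s records; these replicate
studies evaluate the statistics layer on parameters measured from the
generator's label sequences directly — the rendering/clustering path is
already validated by the recovery tests, and re-clustering 100 cohorts
would add hours of compute without changing what is being tested.

On the default cohort the chain recovers all four templates at
|corr| > 0.99, labels ~92 % of frames correctly, and recovers cohort-mean
durations within ~6 % (a small upward bias from the 30 ms smoothing is
partly offset by epoch-edge truncation).

## Known limitations

* Durations inherit a small positive bias from minimum-duration
  smoothing; at the default generative means this is ≈ 3–6 %.
* The 2-SD peak-height exclusion uses a one-sided bound; with Gaussian
  envelopes almost nothing is removed (it matters for artifacted data).
* `df` for the pooled test is n1 + n2 − 2 (= 48 at 25 + 25); reports that
  print df = 50 for this design are not reproducible from the data shape.
* Transition probabilities are conditional (row-normalized); total-count
  normalization would need a one-line change.
* K is fixed at 4; no cluster-count selection criterion, AAHC or PCA
  segmentation variants are provided.
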