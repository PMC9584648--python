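# Methods

This note documents what the package computes, the assumptions behind each
step, the defaults and why they were chosen, and what the synthetic-data
validation does and does not establish.

## Signal conditioning

Raw recordings are processed in a fixed order: bad-channel removal (an
explicit drop list; no automatic detection) → average referencing over the
retained channels → polyphase downsampling to 250 Hz with anti-alias
filtering (skipped with a logged notice when the input rate is already
below 500 Hz) → zero-phase high-pass 0.1 Hz, low-pass 45 Hz and 60 Hz
notch.  Dropping precedes referencing so that a noisy channel cannot leak
into the common reference.

Filters are 4th-order Butterworth sections applied forward–backward
(`sosfiltfilt`); the notch is a 2nd-order IIR at 60 Hz with Q = 30.
Zero-phase filtering is not optional: any phase distortion introduced by
conditioning would bias the directed phase-lag estimate, which counts
per-sample phase leads.  A test verifies the band-center phase shift is
below 1°.

Analysis operates on non-overlapping 10-s windows; the trailing remainder
is discarded.  The alpha band-pass (8–13 Hz, same filter family) is
applied per window, zero-phase; with 2500-sample windows the filtfilt edge
transients are negligible, and windowed filtering keeps the window an
independent unit of estimation.  An optional amplitude-threshold window
rejector (default 150 µV when enabled) stands in for manual artifact
inspection, which is not reproducible; rejected windows are logged.

## Connectivity

Per window, analytic signals come from the FFT-based Hilbert transform and
the cross-spectrum is the per-sample product `C_ij = a_i · conj(a_j)`, with
expectations taken as within-window sample means (the recordings here are
a few minutes long; no multitaper averaging is layered on top).  wPLI and
dPLI both reduce to functionals of `Im C_ij`: the sign of the wrapped
phase difference equals the sign of the imaginary cross-spectrum, so the
Heaviside tie convention H(0) = ½ falls out naturally from samples with
exactly zero imaginary part.  This makes dPLI antisymmetry
(`dpli_ij + dpli_ji = 1`) exact by construction, which the property suite
asserts without tolerance.

**Degenerate pairs.**  When the mean |Im C| of a pair falls below 1e-9 of
the mean |C|, the pair carries no phase-lag information (for exact
zero-lag scalar mixtures the imaginary part is analytically zero and the
computed values are pure rounding noise); such pairs are assigned wPLI 0
and dPLI 0.5 directly rather than a ratio of rounding errors.  The
threshold sits ~6 orders of magnitude above double-precision rounding and
~7 below any physiologically plausible lag signal.

**Surrogate correction.**  For each pair and window, 20 surrogates are
built by circularly shifting the second channel by a uniform random offset
of at least 1 s (spectrum and autocorrelation preserved, phase relation
destroyed); sample shuffling is available as an alternative scrambling.
Because the DFT-based Hilbert transform commutes exactly with circular
shifts, surrogates are computed by rolling the analytic signal — identical
to re-analyzing the shifted series, at a fraction of the cost.  The
observed value is bias-corrected by the surrogate mean (wPLI by
subtraction, clipped at zero since wPLI is a magnitude; dPLI by recentring
about 0.5, which preserves antisymmetry) and retained only when the
rank-based empirical p-value `(1 + #{surrogate as extreme}) / 21` is below
α = 0.05 — attainable only when the observation is more extreme than all
20 surrogates, giving p = 1/21 ≈ 0.048.  The wPLI test is one-sided
(upper); the dPLI test is two-sided on |dPLI − 0.5| (a lead or a lag is
equally reportable), switchable to one-sided.  No multiple-comparison
correction is applied across pairs; the per-test false-positive rate is
verified empirically (≤ α + 3 binomial s.e. on independent channels).
Windows are corrected individually and averaged afterwards.

**Network summaries.**  Node degree is the row sum of the time-averaged
corrected wPLI matrix.  The frontoparietal summary collects
`dpli_avg[f, p]` over frontal–parietal channel pairs within each lateral
hemisphere; a hemisphere lacking frontal or parietal coverage is reported
as missing rather than raised, since per-case channel exclusions routinely
blind one hemisphere.  The anterior–posterior hub index is the
degree-weighted mean of the electrode y-coordinate (posterior −1 …
anterior +1) — a scalar summary of hub topography chosen because no
standard "anteriorization" statistic exists; it is exact for a single
point mass and zero for uniform degree on a symmetric montage.  Hub
directionality is each channel's mean dPLI against all others (> 0.5:
source; < 0.5: target).

## Complexity

Windows are binarized channel-wise against the within-window mean Hilbert
envelope of the broadband (0.1–45 Hz) signal — the complexity chain never
sees the alpha filter, since narrow-band filtering trivially caps
compressibility.  Per-channel, per-window thresholds avoid leaking
between-state amplitude differences into the binarization.  An envelope
whose excursion is below 1e-9 of its mean is treated as constant and
binarizes to all zeros (an analytically flat envelope must not binarize
to rounding noise around its own mean).

LZ76 is the exhaustive-history production complexity: the phrase count of
the parsing in which each phrase is the shortest extension not copyable
from the preceding sequence, with a trailing incomplete phrase counted.
Two independent implementations exist: a direct quadratic scan and a
linear-time suffix-automaton parser (used for alphabets ≤ 4, where the
dense transition table is cheap); they are cross-checked exhaustively on
all binary strings of length ≤ 12 and by fuzzing, and validated against a
brute-force substring-search oracle in the tests.

Three variants per window: median-over-channels univariate LZ76 (a mean
option exists because "median univariate, estimated individually prior to
averaging" admits both readings); concatenated (channel bit-rows joined
end-to-end in the fixed, logged label order — the only order-dependent
variant); joint (the time-ordered sequence of per-sample channel
bit-vectors, each vector one symbol — directly multivariate, collapsing
inter-channel redundancy, and reducing to the univariate value for one
channel or identical channels).  Raw phrase counts are reported without
asymptotic `n/log n` normalization so either convention can be derived.

Normalization divides each window's raw count by the mean count over 10
phase-randomized surrogates of that window (magnitude spectra preserved
exactly, positive-frequency phases i.i.d. uniform, DC and Nyquist bins
untouched, channels independent).  The surrogate count is unspecified in
the source conventions for this normalization; 10 balances the variance of
the normalizing mean against runtime and is configurable.  Linear Gaussian
signals score ≈ 1 (verified within [0.9, 1.1]); envelope-structured
signals score below 1.

## Case pipeline and classification

Each state runs conditioning → epoching → {alpha band → connectivity;
broadband → complexity} and the report compares anesthesia to baseline.
Classification is a pure function of the deltas: feedback change is
paradoxical when mean frontoparietal dPLI increases, hub change
paradoxical when the hub index decreases (posteriorization), complexity
paradoxical when normalized LZC increases; the canonical labels are the
reverse, and |Δ| below tolerance is null.  Default null tolerances —
0.01 (frontoparietal dPLI), 0.05 (hub index), 0.01 (normalized LZC) — are
configurable and embedded in every report; they are needed because the
source observations report directions, not magnitudes.  An optional post
state yields a reversibility block (post within tolerance of baseline,
same tolerances).

Per-state analysis seeds derive from the configured seed and a CRC of the
state's data, so a run is fully reproducible and byte-identical inputs
produce byte-identical metrics regardless of state slot — a perfectly
reversed post state is reported as exactly reversed.

The alpha-power check correlates per-channel changes in alpha band power
with changes in node degree (Spearman rho, permutation p over 10 000
seeded label permutations), to probe whether apparent network
reorganization merely tracks power shifts.

## Synthetic ground truth

The generator produces the features the chain measures, nothing more:

* **Lag graphs** — each coupled pair shares one narrowband (8–13 Hz
  filtered noise) analytic process; the lagging channel receives the
  process rotated by the pair's phase offset.  Rotation of the analytic
  signal shifts phase identically at every in-band frequency, so the
  expected dPLI of a clean pair is exactly 1 — a sharper ground truth than
  delay-coupled oscillators would give.  Channel sums of per-pair
  processes build hubs and chains.
* **Background noise** — 1/f-power-shaped Gaussian noise (flat below
  1 Hz), scaled to a target in-band (8–13 Hz) SNR measured against the
  mean in-band power of the coupled channels.  EEG background is
  broadband; in-band SNR is the quantity that actually governs phase-lag
  detectability.
* **Common source** — positive scalar multiples of one narrowband process;
  the imaginary cross-spectrum is analytically zero.  Default jitter is
  1e-12 relative RMS: large against double-precision rounding, far below
  the degenerate-pair threshold, so the zero-lag fixture is recognized as
  carrying no phase-lag information deterministically.  (With substantial
  jitter the observed index becomes exchangeable with its surrogates and
  ~1/21 of tests would survive by construction — the correct statistical
  behavior, but no longer an exact-zero fixture.)
* **Markov envelopes** — a 10 Hz carrier amplitude-modulated by a
  two-state Markov chain (8 symbols/s, envelope 0.25/1.0, flip probability
  p ∈ [0, 0.5]).  Expected LZC rises with p; p = 0 is the constant-envelope
  minimal-complexity case.

**Scenarios.**  Six named baseline/anesthesia contrasts cover both
directions of each marker: `feedback_increase`/`feedback_decrease` (one
frontal→parietal lead pair per hemisphere, present in one state only),
`hub_posteriorize`/`hub_anteriorize` (a four-spoke star centered on a
frontal vs an occipital channel), `complexity_up`/`complexity_down`
(flip probability 0.1 vs 0.45).  Defaults: 10 channels (the minimal
montage covering five regions per hemisphere), 250 Hz, 40 s per state
(4 windows — enough windows for stable time averages at desk scale),
10 dB in-band SNR, lag π/2, coupling 1.  Effect sizes are free parameters
chosen for detectability at the 20-surrogate / 10-normalization-surrogate
settings; the complexity endpoints sit inside the regime where
surrogate-normalized LZC increases monotonically with flip probability
(below p ≈ 0.1 the nearly-pure-carrier surrogates make the ratio
non-monotone).  Ground truth records signs only — the expected direction
per controlled metric, None for metrics a scenario leaves free.

**What passing the scenario suite shows — and does not.**  Recovery of
the correct direction on ≥ 18/20 seeds per scenario demonstrates that the
chain detects directed coupling, hub topography and compressibility
changes through the full conditioning/correction stack at realistic SNR.
The generator is deliberately not a biophysical model: no volume
conduction beyond scalar mixing, no 1/f aperiodic-slope changes, no
drug-specific spectral dynamics, no non-stationarity within a state, no
artifacts.  Passing therefore validates the estimators and their
calibration, not the clinical interpretability of any marker on real
patient EEG.

## Numerical and interface choices

* EDF output is written by a built-in fixed-layout writer (1-s records,
  16-bit scaling per channel against the printed header values) and read
  back through MNE's independent EDF reader in the round-trip tests;
  amplitudes round-trip within one 16-bit quantization step.  Delimited
  recordings are TSV (header row of labels, samples in rows) with a JSON
  sidecar carrying the sampling rate and state tag.
* Ties in the hub-channel argmax break by label order.  An all-zero degree
  vector yields a null hub index with a warning, not an exception; the
  delta against a null is null.
* All randomness flows through seeded `numpy` generators; surrogate and
  normalization draws are consumed in a fixed loop order, so identical
  inputs, configuration and seed give byte-identical reports.

## Known limitations

* Window-wise alpha filtering slightly attenuates the first and last few
  cycles of each window; with 10-s windows the effect on the phase-lag
  indices is below the surrogate-test resolution.
* The hub index compresses hub topography onto one anterior–posterior
  axis; lateralized hub shifts map to zero.
* The permutation p-value of the alpha-power check treats channels as
  exchangeable, ignoring spatial autocorrelation of the scalp montage.
* Raw LZC phrase counts depend on window length; only within-study
  comparisons at fixed window length are meaningful.
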