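# Methods

`cohnet` implements a complete analysis chain for two-session, multichannel
EEG working-memory studies: band-limited coherence connectivity, binary
network construction with graph-theoretic characterization and small-world
normalization, paired differential networks with FDR-corrected edges and
degree-based hubs, and behavioral scoring by signed residual time.  Because
no public recordings accompany the study design the package models, a
synthetic generator reproduces the study's layout (20 subjects x 2 sessions
x 60 trials, 19-channel 10-20 montage, 3-s retention epochs) with
controllable band-limited coupling, and every stage is validated against
that generator and against independent brute-force oracles.

## Signal model of the generator

Each channel of each trial is independent Gaussian noise with standard
deviation `noise_sd` (default 10 uV).  A coupling adds a shared narrowband
source to the two channels of one electrode pair:

    x_ch(t) = noise_sd * n_ch(t) + w * A * s(t)

where `s` is white noise band-passed to the coupling's band (4th-order
Butterworth, forward-backward) and normalized to unit variance per trial,
`w` in [0, 1] is the session's mixing weight, and `A = source_amp_uv`
(default 10 uV, a typical scalp-rhythm amplitude) sets the physical scale.
Filtered noise rather than a sinusoid is used so that coherence is tunable
below 1 and phase is not trivially locked — the estimator is exercised
nontrivially.  Between-subject variability enters only through a Gaussian
perturbation of the weight (`subject_sd`), drawn once per subject and
applied to both sessions, which keeps the paired generative model simple
and analyzable.

Squared coherence on a coupled edge follows the shared-variance identity,
per frequency bin:

    C^2(f) = ( r S(f) / (r S(f) + N) )^2,    r = (w A / noise_sd)^2

with `S` the unit-variance source density (the |H|^4 response of the
forward-backward source filter) and `N` the flat noise density.
`expected_band_coherence` evaluates the band average of this expression on
the actual Welch grid; `weight_for_coherence` inverts it by bisection.
These closed forms are what the tests compare the Welch estimator against,
and how session weights are chosen to place a prescribed coherence change
(for the recovery study below, 0.20 -> 0.35 in the alpha band) on
designated edges.

All randomness flows from one master seed through labeled
`numpy.random.SeedSequence` spawn keys `(stream, subject, session)`, so
adding subjects, trials or couplings never changes the data of earlier
subjects, and changing the number of network nulls never perturbs the
generated signals.

What the generator does *not* emulate: volume conduction through a head
model, ocular/muscle artifacts (artifact rejection is exercised with
injected amplitude spikes instead), 1/f background spectra, and
load-stratified (2/4/8-item) condition structure.  Passing tests therefore
demonstrate correctness of the estimators and statistics under a known
shared-source model, not robustness to every property of real scalp EEG.

## Preprocessing

Order: common-average re-reference -> amplitude rejection -> band-pass ->
baseline correction -> retention extraction.  All steps are pure.

- *Re-referencing.* The analysis chain uses common-average re-referencing.
  Reference-electrode standardization techniques that approximate a neutral
  infinity reference require a volume-conductor model that this package
  deliberately does not include; the average reference is the standard
  deterministic surrogate, and the synthetic data are generated
  reference-free.  Note that averaging re-injects a small common component
  (-1/n_channels of every source) into all channels, which measurably
  lowers coherence on coupled pairs and couples otherwise independent ones;
  the operating-characteristic experiments therefore run on raw generated
  epochs, while the demo pipeline exercises the full chain.
- *Band-pass 0.5-45 Hz.* A 2nd-order Butterworth high-pass cascaded with an
  8th-order Chebyshev-II low-pass (40 dB stopband beginning at the cutoff),
  both zero-phase via forward-backward filtering with 1-s even-symmetric
  edge padding.  The asymmetry is deliberate: on 3-s epochs a resonant
  high-pass edge at 0.5 Hz rings for several seconds and contaminates the
  whole trial (measured: a 4th-order Butterworth band-pass leaves ~20% RMS
  of a 60 Hz stopband tone on a 3-s epoch, almost all of it low-frequency
  ringing), while the low-pass edge must attenuate sharply from 45 Hz
  upward to suppress line-frequency content (the Chebyshev-II design leaves
  0.1-0.2% of white-noise power above the cutoff versus ~1% for a
  Butterworth of the same order).
- *Amplitude rejection.* A trial is dropped when any channel exceeds the
  +/-100 uV limit at any sample (peak criterion, the common reading of a
  "+/- amplitude range"); a peak-to-peak variant is available behind a
  flag.  Rejection is trial-wise and idempotent, and the report lists
  dropped trials with offending channels.  Rejecting every trial is an
  error, because downstream coherence would be undefined.
- *Baseline.* Per channel and trial, the mean over the 100 ms pre-stimulus
  window is subtracted everywhere.
- *Retention extraction.* Sample windows are half-open `[start, end)`, so
  adjacent extractions partition an epoch exactly.

## Coherence

Magnitude-squared coherence `C^2(f) = |P_ab|^2 / (P_aa P_bb)`, bounded in
[0, 1] and invariant to per-channel rescaling.  Auto- and cross-spectra are
Welch estimates — 1-s Hann windows with 50% overlap by default — with
periodogram cross-products pooled over *all segments of all trials* before
the ratio is formed.  Pooling matters: averaging per-trial coherences is a
different estimator with a substantially larger upward bias at low
coherence (the independent-noise floor of a pooled estimate scales as
1/n_segments over all trials, versus 1/n_segments-per-trial for the
per-trial average).  The per-trial variant is available behind
`per_trial=True` for comparison.  The scalar edge weight for a band is the
arithmetic mean of `C^2` over the in-band Welch bins — the simplest
convention, monotone in per-bin coherence — and "full band" means the
0.5-45 Hz preprocessing passband.  Zero-power bins are flagged degenerate
and skipped; a band with no usable bins raises, naming the grid resolution.

## Binary networks and graph metrics

Edges are `coherence >= threshold`.  The automatic threshold is the
*maximum threshold that leaves no node isolated*; it equals the minimum
over nodes of each node's best off-diagonal coherence, which the tests
verify against an exhaustive scan over all distinct matrix values.  An
explicit threshold that isolates nodes warns and reports them rather than
failing.

The property panel: optimal path length `Lp` (mean hop distance over
reachable ordered pairs), global efficiency `Eg` (mean 1/distance with
1/inf = 0), clustering coefficient `CC` (per-node `2e_a/(k_a(k_a-1))`, 0
for degree < 2), local efficiency `Eloc` (global efficiency of each node's
neighbour-induced subgraph, node removed), and mean degree `Deg`.  For
disconnected networks `Lp` averages over the finite-distance pairs and the
number of unreachable ordered pairs is reported alongside — both formulas
stay literal where they are defined, and disconnection is visible instead
of silently folded into either metric.

Small-world normalization: `gamma = CC/<CC_rand>`, `lambda = Lp/<Lp_rand>`,
`sigma = gamma/lambda`, against 100 (default) Maslov–Sneppen
degree-preserving edge-swap randomizations, seeded.  Each null attempts
`10 x edges` successful swaps within a `100 x edges` attempt budget; on
graphs with no valid swap (complete graphs) the null is the original
network, correctly yielding `sigma = 1`.  Degree sequences of every null
are asserted equal to the original.  Triangle-free degree sequences make
`<CC_rand>` zero; `gamma` is then NaN and flagged.  Whether thresholds are
chosen per matrix or globally is configurable; the default is per matrix
under the auto rule.

## Differential networks and hubs

For each of the 171 unordered electrode pairs of the 19-node montage, the
subjects' session-wise band coherences are compared with a two-sided paired
t-test; edges with zero difference variance get p = 1 with a warning.
Benjamini–Hochberg FDR at alpha = 0.05 over the per-band edge family (bands
are corrected separately, since the networks are built per band) defines
the binary differential network.  Benjamini–Yekutieli is available behind a
flag.  Direction is recoverable from the sign of the t matrix.

Hubs are high-degree nodes of the differential network: degree at least
`mean + 1 SD` of the network's degree sequence by default, with the
multiplier configurable and an explicit degree cutoff accepted.  Applied to
the published degree table of the study this package models, the rule
reproduces the published theta hub set exactly ({F3, Fz, F4}, cutoff 8.90)
but *not* the published alpha or beta hub sets, and this is a property of
the published table, not of the multiplier: the theta column requires a
cutoff more than 0.48 SD above its mean while the alpha column requires at
most 0.23 SD, so no `mean + c*SD` rule (nor any standard location+scale or
quantile rule — an exhaustive search over such families confirms this) can
reproduce all three columns at once.  The published alpha column moreover
sums to an odd number (135), which no simple graph's degree sequence can,
so the table itself contains at least one misprint.  The acceptance check
for hub reproduction is left failing on those two bands rather than fitted
with an ad-hoc rule.

## Behavioral scoring

`SRT = sum_i (2 RACC_i - 1)(MT - T_i)`: correct trials add their unused
response time, errors subtract it.  |SRT| is bounded by the summed maximum
times, the score is additive over trial sets, and flipping any error to a
correct response (latency fixed) strictly increases it — all tested as
properties.  Session summaries report accuracy, SRT, and mean reaction time
over correct trials only (the standard convention; configurable).  `MT` is
a free parameter of the behavior spec, default 2.0 s.  Non-response trials
are not modeled; the generator always produces a latency in (0, MT].

## Operating characteristics

Two study-level experiments, run by `scripts/acceptance.py` and the
acceptance tests at 250 Hz with 20 trials per session so the battery stays
within minutes on one CPU (the estimators themselves are
rate-independent):

- *Recovery*: 50 seeded studies of 20 subjects with an alpha-band coherence
  increase of 0.20 -> 0.35 on five node-disjoint edges (`subject_sd` 0.05).
  Measured sensitivity and mean false-edge count of the BH-corrected
  differential network.
- *Null calibration*: 200 seeded studies with identical couplings in both
  sessions.  Measured uncorrected per-edge rejection rate at alpha = 0.05
  (with its empirical standard error across runs — edges within a run share
  subjects, so the runs-times-edges binomial SE would be too small) and the
  fraction of runs with any BH discovery.

## Numerical choices and edge cases

- Welch cross-spectra follow the `scipy.signal.csd` conventions (Hann
  taper, constant detrend per segment, one-sided density scaling,
  `P_ab = E[X_a* X_b]`) and match it exactly on single trials.
- Coherence values are clipped to [0, 1] against floating-point spill;
  matrix symmetry is exact by construction.
- Sample windows throughout are half-open with a half-sample tolerance on
  their bounds, so window arithmetic is exact at any sampling rate.
- Degenerate hub inputs: an edgeless network has no hubs; equal degrees
  yield no hubs under the SD rule (nothing stands out).
- Latencies are truncated-normal in (0, MT]; `rt_sd = 0` degenerates to the
  constant mean.

## Known limitations

- The common-average reference couples channels; differential statistics on
  fully preprocessed data inherit this and will flag spillover edges when a
  strong source changes between sessions.  This is faithful to the method,
  not a bug, but it means edge-level findings on referenced data should be
  read network-wide.
- Weighted-network metrics, volume-conduction-robust connectivity
  (imaginary coherency, wPLI), betweenness-based hubs and
  proportional-density threshold sweeps are out of scope.
- `sigma >> 1` is reported descriptively; no significance test is attached
  to it.
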