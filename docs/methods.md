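# Methods notes

This note documents the models, conventions and numerical choices behind
`asmconn`, in the spirit of a package reference manual: what is computed,
under which assumptions, and where genuine design freedom existed.

## Synthetic sessions: what they emulate and what they do not

**Stimulation sessions.** Single-pulse stimulation at 1 Hz, 30–120 pulses
per train, one train per stimulated contact pair with 2 s guard intervals.
Each recording channel's evoked response is a deterministic kernel
`w(t) = −A1·exp(−(t−l1)²/2σ1²) − A2·exp(−(t−l2)²/2σ2²)`, two negative-going
Gaussian deflections whose latencies are constrained to the windows in
which N1 (10–30 ms) and N2 (85–250 ms) are defined.  A parametric kernel
was chosen over a recorded template because its latency/amplitude/width map
one-to-one onto the features the pipeline measures, which makes ground-truth
closure exact: every injected parameter is recorded in a truth table and can
be compared against the recovered estimates.  Background noise is 1/f
("pink") with its spectrum flattened below the 1 Hz pulse rate — clinical
amplifiers apply a hardware high-pass that removes electrode drift, and
without that floor the strong sub-1 Hz components would be shared between
successive 1 s trials, breaking the trial-exchangeability that both the real
and simulated permutation analyses rest on.  On top of that: white sensor
noise (30% of the pink SD), a 60 Hz mains sinusoid with 120/180 Hz harmonics
(random phase per channel) so the notch stage is exercised, and a two-sample
biphasic artifact spike at each pulse onset.  The artifact sits at t = 0–1
samples while all feature windows start at 10 ms, so it cannot contaminate
measurements.  Medication-state effects are fractional amplitude changes
and/or latency shifts applied to chosen (pair, channel) kernels only in the
ASM-OFF condition.

Defaults: 60 pulses per train, fs = 1024 Hz (stimulation sessions need
≥ 1 kHz for sample-accurate N1 latency), noise SD 20 µV against a default
100 µV N1 — SNR 5, the regime in which recovery is validated.

**Resting sessions.** Latent slow signals are drawn from N(0, Σ) with Σ the
user-specified target correlation matrix (checked symmetric PSD with unit
diagonal), band-limited to 0.1–1 Hz and re-standardized; each channel is
band-limited 70–200 Hz carrier noise amplitude-modulated as
`carrier·(1 + depth·latent)` plus a weak pink background.  The slow BHA
envelope of such a channel tracks its latent signal, so the BHA-FC matrix
approximates Σ.  The approximation is attenuated (an estimated 0.8
correlation comes out near 0.75 at 600 s with depth 0.5) by envelope
nonlinearity and background noise; validation thresholds account for this.
Defaults: 600 s, fs = 500 Hz (an integer multiple of the 100 Hz BHA rate,
and comfortably above twice the 200 Hz carrier edge), depth 0.5.

What the generator does **not** model: biophysical neural dynamics,
charge/current spread of the stimulus, volume conduction between channels,
non-stationarity across a session, epileptiform transients, or
patient-level covariance beyond the per-patient parameters.  Passing tests
therefore demonstrate correctness of the measurement and inference chain
under realistic noise, not clinical validity on patient data.

**Seeding.** One master seed; per-session seeds are derived as the first
four bytes of SHA-256 over `(master, patient, session, condition)` — stable
across platforms and interpreter runs, bounded below 2³¹.

## Preprocessing

* Notch: third-order Butterworth band-stops at 59–61, 119–121, 179–181 Hz,
  applied forward-backward (zero-phase) as second-order sections; direct-form
  high-order narrow band-stops are numerically fragile, SOS are not.  The
  effective (two-pass) attenuation at 60 Hz exceeds 30 dB.  Bands at or
  above Nyquist are skipped with a warning.
* Bipolar referencing: adjacent same-shaft contacts, derived channel named
  `A1-A2`.  A bipolar channel inherits the more pathological of its
  contacts' zones (SOZ > EPZ > IZ > NIZ) — labels are clinician-assigned per
  contact and no standard exists for derived channels; most-pathological-wins
  is the conservative choice for epileptic-network analyses.  Bad contacts
  are excluded together with every pair they would form.
* Common-average referencing (resting branch) excludes SOZ/EPZ and bad
  channels from the reference (falling back to all channels when fewer than
  two would remain) and subtracts it from every channel.
* Epochs span −250…+500 ms around each pulse — wide enough for the −215…−15
  ms baseline and the 300 ms feature window with margin, short enough not to
  overlap neighbouring 1 Hz pulses.  Per trial and channel the baseline mean
  is subtracted (stimulation alters contact impedance, so each trial carries
  its own offset).  All pulses are kept; only onsets whose window would
  leave the recording are dropped (logged).  Time 0 is the onset sample;
  ms↔samples conversions round half away from zero.

## CCEP features

Single-trial peaks are strict local maxima of |trace| inside the component
window, endpoints excluded; among multiple candidates the largest absolute
amplitude wins (dominant-deflection convention), ties go to the earliest.
No minimum prominence is imposed by default (configurable).  A trial/window
with no local maximum yields an absent feature, and absent features
propagate as missing values — they are dropped listwise per measure by the
statistics, never imputed.  Amplitudes are stored as absolute values;
polarity is not retained.

RMS is computed only from the across-trial average waveform, evaluated by
linear interpolation on a 1 ms grid over half-open windows [10, 300),
[10, 50), [50, 300) ms.  Half-open grids make the two sub-windows an exact
partition: `290·RMS²(10–300) = 40·RMS²(10–50) + 250·RMS²(50–300)`.
Channels belonging to the stimulated pair (or bipolar channels containing a
stimulated contact) are excluded from the recording set.

## BHA and functional connectivity

Morlet transform at 14 log-spaced frequencies in 70–200 Hz, seven cycles,
via `mne.time_frequency.tfr_array_morlet`, one channel at a time to bound
memory.  "Log normalization" is log10(power) followed by a per-frequency
z-score over time (the per-frequency mean-subtraction-only variant is a
flag); z-scoring makes frequencies commensurate before averaging, and
whether to z-score before or after averaging is genuinely open — the
default normalizes before.  Half of the longest wavelet support
(0.5·7/70 Hz = 50 ms) is trimmed from both ends before normalization, and
power is sampled at 10 ms hops (100 Hz).  The slow band is a zero-phase
third-order Butterworth band-pass 0.1–1 Hz; series shorter than six time
constants of the 0.1 Hz corner trigger a warning.  FC is the plain Pearson
correlation matrix of the slow BHA over the whole session; zero-variance
channels yield missing correlations (logged).

## Graph measures

Both sessions' |FC| matrices are thresholded at the 40th percentile (linear
interpolation) of their pooled off-diagonal values, the same threshold for
both conditions, so ON/OFF are compared at matched density; sub-threshold
entries become exactly 0, the diagonal is 0.

* Degree: count of nonzero edges.  Strength: row sum of weights.
* Clustering: Onnela's weighted variant — weights normalized by the global
  maximum, C_i = Σ(ŵ_ij ŵ_jh ŵ_hi)^{1/3} / k_i(k_i−1); this is the common
  weighted-clustering default in brain-network toolboxes.
* Local efficiency: global efficiency of the subgraph induced by a node's
  neighbours, computed on max-normalized weights so the value lands in
  [0, 1].
* Path-based measures use the distance transform d = 1/w (configurable to
  −log w in principle; 1/w is the toolbox convention).  Characteristic path
  length averages over *connected* ordered pairs and carries a
  connectedness flag; global efficiency averages 1/d over all ordered pairs
  with disconnected pairs contributing 0.
* Modularity: best of 10 seeded Louvain runs at resolution 1 (the community
  algorithm is a free choice; Louvain with restarts is standard and cheap).
* Small-worldness: σ = (C/C_rand)/(L/L_rand) against 20 degree-preserving
  Maslov–Sneppen rewired nulls (10·|E| swap attempts, original weights
  reshuffled onto the rewired edges).  Dense graphs that cannot complete
  the requested swaps keep the swaps achieved; complete graphs are left
  unrewired (no swap exists).  σ of an Erdős–Rényi-like graph is ≈ 1.
* Degenerate inputs: n < 3 defines clustering/local efficiency as 0; an
  empty graph reports zeros with `connected=False` and σ = NaN.

## Inference

* Trial permutation test: statistic mean(OFF) − mean(ON); pooled values
  reshuffled preserving group sizes; add-one two-sided empirical
  p = (1 + #{|T_perm| ≥ |T_obs|})/(1 + n_perm), floor 1/(n_perm+1).  The
  two-sided indicator uses absolute values.  Pairs need ≥ 10 valid trials
  per condition (missing features dropped first), otherwise they are
  skipped and logged.  BH-FDR is applied per measure across all pairs of
  all patients jointly — patient identity is not controlled at this stage,
  which is why the RMS analysis exists.
* Zone summaries: per measure and direction (sign of OFF − ON among
  FDR-significant pairs), cell = 100 × significant/tested for that
  stim-zone × rec-zone combination; cells strictly above 5.0% are flagged;
  untested combinations are missing, not zero.
* RMS regression: OLS `rms ~ StateASM + C(patient)` per (window, zone
  pair), StateASM coded OFF = 0 / ON = 1; the patient term is dropped when
  only one patient contributes (logged); cells with < 3 observations or a
  single condition are reported as skipped.  The grid always contains 48
  rows; significance is declared at p < 0.05/48 ≈ 0.00104.
* FC max-statistic test: T(i,j) = |r_ON − r_OFF|; the null swaps
  non-overlapping 60 s blocks (default) between the two sessions at
  matching positions and recomputes both correlation matrices.  Whole-block
  swapping preserves within-session autocorrelation, which sample-level
  shuffling would destroy (and which would wildly inflate the null).
  Contiguous blocks of a slow (0.1–1 Hz) series remain correlated across
  their boundaries, which inflates the observed statistic's variance
  relative to the block-shuffled null (the adjacent-block covariance terms
  cancel under random block signs) and pushes the realized family-wise rate
  to roughly 1.5× nominal in simulation; both the observed and the permuted
  correlations therefore exclude a 5 s guard segment at the start of every
  block, which restores the nominal level (measured ≈ 0.75% at nominal 1%
  over 400 null replicates).  The family-wise threshold realizes the
  99th-percentile-of-max rule through the add-one empirical-p ordering
  (K-th largest null max, K = ⌊α(n_perm+1)⌋), which keeps the level exact
  at finite n_perm where a plain interpolated percentile is slightly
  anticonservative.  Unequal session lengths are truncated to the common
  length with a warning.
* Wilcoxon signed-rank (paired node metrics): zero differences dropped;
  exact null for n ≤ 25, normal approximation with continuity correction
  above; all-zero differences are degenerate and reported as p = 1 with a
  flag.

A side effect worth knowing: an injected pure *amplitude* change also
shifts the measured single-trial *latency* distribution on the affected
channel (lower SNR widens the peak-position distribution inside the search
window).  This is a genuine property of window-constrained peak picking,
not a false positive; recovery tests therefore count contamination on
channels without any injected effect.

## Validation problem sizes

The shipped tests validate at desk scale: stimulation recovery uses one
18-channel session pair with 60 trials/condition at SNR 5 and n_perm = 1000;
the null-FDR characteristic uses 200 pairs × 50 trials × 20 replicate seeds
at n_perm = 1000; FC recovery uses 6-channel 600 s sessions over 10 seeds
and the family-wise-error simulation 100 replicates of 300 s slow-band
series at n_perm = 500 with 20 s blocks.  These sizes were chosen so the
whole suite runs on a laptop-class single core while keeping Monte-Carlo
margins meaningful; all procedures default to the full-scale parameters
(n_perm = 5000 trials / 10000 FC) when run on real sessions.

## Known limitations

* The RMS regression treats patient as a fixed (categorical) effect; no
  mixed-model variant is provided.
* The stimulation-onset detector provided for imported EDF recordings is a
  plain robust-threshold crossing with a refractory period — adequate for
  clean artifacts, not a general solution; simulated and fixture sessions
  carry exact onsets.
* FC inference assumes both sessions share a channel montage; montage
  reconciliation is the caller's job.
* Zone labels are inputs; the package performs no clinical localization.
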