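# Methods

This note documents the models, parameter choices and numerical conventions
behind the package, what the synthetic-data generator does and does not
emulate, and the design decisions made where the method left room.

## Signal model and preprocessing

The input is single- or two-channel forehead EEG (Fp1-A1, Fp2-A2), in µV,
at 500 Hz or 128 Hz depending on device. Processing order is fixed:
band-pass filter → windowing → per-window QC → usability gate → scores.

**Filter.** A 4th-order Butterworth band-pass, 0.5–20 Hz, applied
forward-backward (`sosfiltfilt`), i.e. zero-phase, 8th-order effective
magnitude. Zero phase matters because the downstream embedding is sensitive
to waveform shape; a causal filter would skew slow waves. The band keeps
delta through low beta and removes drift and most EMG. Exposed via
`FilterSpec(low_cut, high_cut, order)`.

**Windowing.** Non-overlapping windows aligned to the record start: 4 s for
the spectral score (so the periodogram grid is exactly 0.25 Hz at either
sampling rate, putting 3 Hz and 10 Hz on exact bins), 2 s for the
topological score (small enough that one window is roughly stationary,
large enough to contain several slow-wave cycles). Trailing partial windows
are dropped. Overlap is deliberately avoided: it would correlate window
scores and complicate the "seconds of clean signal" bookkeeping.

**Per-window QC** (on the filtered signal), in fixed order so rejection
reasons are deterministic:

| check | default | rationale |
|---|---|---|
| max abs amplitude | 200 µV | scalp EEG rarely exceeds ~100 µV; excursions are EMG/ECG/electrode pops |
| min variance | 0.5 µV² | flatline/disconnection; the threshold sits above the ≪ 1 µV² ripple that zero-phase filtering rings into a dead span from the surrounding signal, and two orders of magnitude below any physiological window |
| max fraction of power > 15 Hz | 0.5 | muscle noise that survives the band-pass |

ECG contamination is handled by window rejection, not template subtraction;
no subtraction method is part of the design.

**Usability gate.** A subject-channel is scored only if the passed windows
of that duration cover ≥ 30 s (boundary inclusive: exactly 30 s counts).
The gate applies independently per duration, so a recording may carry a
BSEEG score with a missing TDA score or vice versa; missing scores
serialize as empty CSV cells with the reason (`usable<30s`) kept in the run
manifest.

## BSEEG score

Per 4-s window: one-sided FFT periodogram of the de-meaned window with a
rectangular taper (the target frequencies are exact bins, so no taper is
needed for leakage and Parseval consistency is exact), then

`score = log10( PSD(3 Hz) / PSD(10 Hz) )`.

Single nearest-bin densities are used, not band averages (a ±0.25 Hz
band-average variant is available behind `BseegParams(band_average=True)`).
The log makes the score signed and antisymmetric in the two bands; a raw
ratio is available (`log10=False`). A zero density is floored at 1e-6 × the
smallest positive density so the score is always finite; an all-zero
spectrum is an error (QC rejects flatlines first). The subject score is the
median over windows (mean available) — median because residual artifacts
produce heavy-tailed window scores.

Whether the original method log-scales its reported score and how it
aggregates windows into a subject score are not specified anywhere we could
verify; both are config-exposed here, with the signed log form as default
because the score is described as taking positive values in delirium and
negative in normals — impossible for a raw ratio.

## TDA score

Per 2-s window:

1. **Embedding.** z-score the window (making the score amplitude-invariant)
   and delay-embed with dimension d = 3, lag τ = round(fs/10) ≈ 100 ms.
   The lag is a quarter period of the ~2.5 Hz delta activity the method
   targets, which opens slow waves into loops; for a ~10 Hz rhythm the same
   lag is close to a full period, so regular alpha embeds nearly
   degenerately and contributes little Betti-1 area. That asymmetry is what
   gives the score its direction (slowed > normal). Both parameters are
   config-exposed; the original method's values are unpublished.
2. **Subsampling.** Uniform stride down to ≤ 64 points (deterministic; no
   randomness in the scoring path). The cap bounds the Rips computation at
   C(64,3) ≈ 42k triangles per window, ~0.1 s in the pure-Python reduction.
3. **Persistence.** Degree-1 Vietoris–Rips persistence, computed exactly: a
   union-find pass over edges in filtration order marks the cycle-creating
   edges, then the triangle boundary matrix is reduced over GF(2) with
   columns stored as integer bitmasks ordered by (edge length, index).
   Simplices enter at their largest pairwise distance. Deaths are capped at
   the cloud diameter (`max_filtration="auto"`), which bounds the Betti
   curve's support per window without a global constant; zero-length pairs
   are discarded. The degree-0 diagram is available for diagnostics but is
   not scored.
4. **Betti curve and area.** β₁(ε) = #{pairs: birth ≤ ε < death} on a
   uniform 200-point grid from 0 to the cap; the window score is the
   rectangular-rule area, which converges to Σ(death − birth) as the grid
   refines (error ≤ one grid step × max β₁).

The subject score is the median of window areas minus a configurable
`center_offset` (default 0). The offset exists because the original score
is reported as signed around zero, implying a centering on some reference
cohort that is not specified; raw area is the honest default.

Correctness of the Rips routine is established in the tests against an
independent full boundary-matrix reduction (all simplices of dims 0–2) on
clouds of up to 20 points, plus closed-form cases (unit square: single pair
(1, √2)), isometry invariance and exact scale equivariance.

## Evaluation

Case label: CAM-ICU positive, or DRS ≥ 19, or DOSS ≥ 3, or chart
documentation of delirium.

AUC is the Mann–Whitney estimator with ties counted ½; its variance comes
from the DeLong structural components (per-subject placement values), the
95% CI from a normal approximation clipped to [0, 1]. Two correlated AUCs
on the same subjects are compared with the paired DeLong z (two-sided p);
when the variance of the difference is zero the comparison is flagged
degenerate and p = 1. The operating point fixes sensitivity at a target
(default 0.80) and reports, among actual sweep thresholds reaching it, the
one with maximal specificity — no ROC interpolation, so every reported
point is auditable. Missing scores are dropped pairwise per analysis: each
single-score AUC uses all subjects with that score, the paired test uses
the intersection.

Cohort-table statistics: Pearson chi-square without continuity correction
(this convention reproduces the published demographic comparisons exactly)
and the pooled-variance unpaired t from group summaries. A Wilson interval
for proportions (sensitivity/specificity) is offered; that interval choice
is this package's own.

## Synthetic data generator

`simulate_eeg` mixes two regimes by a slowing index s ∈ [0, 1]:

* alpha rhythm — random-phase 10 Hz (per-subject jitter SD 0.5 Hz in
  cohorts) sinusoid with slow (≤ 0.3 Hz) amplitude modulation, amplitude
  (1−s) × 30 µV;
* diffuse slowing — band-limited Gaussian noise over ±1 Hz around a 2.5 Hz
  center, RMS-matched to a sinusoid of amplitude s × 30 µV. Broadband is
  the point: real slowing occupies the whole delta band, and the 2.5 Hz
  center is deliberately off the 3 Hz scoring bin so the generator is not
  tuned to the score;
* 1/f (pink) background at 10 µV RMS, flattened below 0.5 Hz.

Artifacts are injected at per-minute Poisson rates (defaults: EMG bursts
1/min, ECG spike trains 4/min, drift 0.5/min, flatline 0/min): EMG is a
0.5–2 s, >15 Hz noise burst at 150 µV; ECG a ~1 Hz train of 80 ms biphasic
120 µV transients; drift a <0.3 Hz 150 µV baseline wave (removed by the
high-pass, not by QC); flatline a zeroed 5 s span. `simulate_cohort` draws
per-subject slowing indices Normal(group mean, 0.05) clipped to [0, 1],
with default group means 0.9 (cases) vs 0.1 (controls) at 128 Hz, 120 s.

Everything is reproducible from config + seed.

**What passing tests on this generator do and do not show.** The generator
reproduces the *spectral* structure the scores assume (alpha vs delta
dominance over a 1/f background) and gross artifact classes, so it can
validate the pipeline's plumbing, the scores' directions, and label
recovery under clean separation. It does not model real EEG
nonstationarity, physiological artifact morphology, electrode impedance
effects, medication effects, or borderline clinical presentations — so
synthetic AUCs near 1.0 say nothing about clinical AUCs, and no clinical
performance figure is claimed from simulation.

Because the per-bin periodogram of any stochastic broadband process is
approximately exponentially distributed, a fully slowed recording has a
small (~1%) per-window probability that the 3 Hz bin dips below the 10 Hz
bin; the per-window sign statements in the tests are therefore pinned to
fixed seeds, while the distribution-level guarantee (bin dominance in
≥ 95% of windows; group separation) holds across seeds.

## Numerical and scale choices

* Rips point cap 64 (not larger) keeps the exact pure-Python reduction at
  ~0.1 s/window; with the ~230-point embeddings of 2-s windows this means
  stride-4 subsampling. 500 Hz recordings are decimated (FIR, zero-phase)
  to 125 Hz after filtering and before embedding so point-cloud geometry is
  comparable across devices; the spectral score always runs at native rate.
* Test and acceptance cohorts use 120 s recordings for spectral-only runs
  and 60 s × 24 subjects when the persistence stage runs, keeping full runs
  in the minutes range; these sizes are stated in the acceptance output.
* Edge ties in the Rips filtration are broken by (length, i, j); triangle
  ties by filtration value with stable sort. Any filtration-compatible tie
  break yields the same diagram; fixing one makes runs bit-reproducible.
* DeLong variance vs a 10⁵-resample stratified bootstrap: the two
  estimators agree to ~1–3% relative at n = 40 but carry O(1/n) bias
  relative to each other at n = 6; the tests assert both regimes at
  tolerances reflecting that, not Monte-Carlo noise.

## Known limitations

* The original TDA pipeline's exact parameters (embedding, filtration cap,
  Betti-curve normalization, score centering, per-device tuning) are
  unpublished; this package declares its own documented defaults rather
  than guessing, so absolute TDA score values are not comparable to the
  original — directions and the evaluation machinery are.
* The subject-level score is per recording; multi-day trajectories and
  outcome (mortality) modeling are out of scope.
* The exact Rips reduction is intended for ≤ ~100-point clouds; it is not a
  general-purpose persistence engine.
* EDF support covers the two-channel forehead montage (16-bit, single data
  record on write); full 10–20 montages, annotations, BDF/FIF are out of
  scope.
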