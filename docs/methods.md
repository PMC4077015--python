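# Methods

## Scope

The package implements a complete ASSR/brain-state LFP analysis chain —
channel screening, normalization, evoked and spontaneous spectral
estimation, phase locking, wavelet scalograms, state-transition tables and
two-level group statistics — plus a generative model of the recording
session used to exercise and validate the chain. This note documents the
models, the parameters that matter, the numerical conventions, and what
the synthetic data can and cannot establish.

## Session protocol

A session is: a quiescent pre-stimulus epoch; a 40-Hz ASSR session
(500-ms click trains, one per 20 s); a 20-Hz session (1000-ms trains, one
per 20 s); a quiescent post-stimulus epoch. The reference protocol uses 50
trains per session at a sampling rate of 1.56 kHz. Scaled-down sessions
(fewer trains, shorter quiescent spans) keep tests and demonstrations fast;
wherever a measured quantity depends on the protocol size (noise floors,
group power) the size used is stated with the number.

## Preprocessing conventions

* **Channel screen.** A channel is analyzed only if the peak absolute
  deflection from the pre-onset mean of its trial-averaged *raw* (volt)
  response, within (0, 100 ms] of 40-Hz train onset, exceeds 0.1 mV. The
  absolute deflection (not the signed trough) is used so the screen is
  robust to electrode polarity. If no channel of any recording survives,
  the run aborts — mirroring the termination rule of the in-vivo protocol.
* **Normalization.** Each channel is z-scored with its mean and
  *population* SD over the entire recording; at ~10⁶ samples the
  population/sample distinction is negligible but one convention must be
  fixed. All downstream analysis is in z units; raw volts are kept only
  for the screen.
* **Windows.** All extraction windows are half-open [t₀, t₁) seconds; the
  start sample is floor(t₀·fs) and the length is round((t₁−t₀)·fs), so
  equal windows always yield equal-length segments and 200-ms bins tile a
  10-s span exactly, without overlap.

## Spectral estimation

* **Periodogram.** Mean-removed segment, zero-padded to 4096 samples,
  one-sided, normalized so that the summed natural-grid power equals the
  segment's population variance (Parseval; machine-precision exact, see
  the DFT-oracle tests). The natural resolution at 1560 Hz (0.381 Hz) is
  slightly finer than the reporting grid — 256 evenly spaced bins over
  0–100 Hz, 0.392-Hz spacing — so linear interpolation onto the grid never
  fabricates resolution. No taper is applied to power spectra; a taper is
  used only where the procedure specifies one (phase locking). A 0–200-Hz
  grid is available through the config for wideband spontaneous spectra.
* **Leakage caveat.** The untapered 200-ms window has a sinc response, so
  a strong fundamental leaks into the region of its 2f harmonic and can
  displace spectral peak locations by up to ~2 grid bins (~0.8 Hz). Tests
  of peak structure therefore assert locations at grid resolution, not at
  a single bin.
* **Band summaries.** Band power is the mean over bins with lo ≤ f ≤ hi
  (closed interval), one convention everywhere. An optional line-noise
  notch (e.g. 60 Hz) excludes ±2 Hz around the line frequency from band
  averages; it is off by default because the synthetic data contain no
  line component.
* **Phase locking.** Per trial, a Hanning-tapered window (200 ms, the same
  bin length as every other analysis; the procedure text leaves it open)
  slides with 60 % overlap; per window position PLF(f) is the resultant
  length of across-trial unit phasors; the spectrum is the mean over
  positions. Averaging over positions (rather than pooling windows as
  pseudo-trials) was chosen because pooling conflates within-trial phase
  drift with across-trial consistency. Analytic anchors: identical trials
  give PLF = 1; N phase-random trials give √π/(2√N) (≈0.125 at N = 50);
  von Mises jitter κ gives I₁(κ)/I₀(κ) in the many-trials limit
  (≈0.698 at κ = 2). All three are verified by Monte-Carlo in the tests.
* **Scalogram.** Continuous wavelet transform with the complex Gaussian
  family, order 8 (configurable), scale = f_c·fs/f on a log-spaced grid.
  Magnitudes are divided by scale: with the library's native scaling the
  ridge of a constant-amplitude tone is displaced toward larger scales by
  ~5 %; amplitude normalization makes equal-amplitude tones produce equal
  ridge heights at their true frequencies (verified for 10–80-Hz tones).

## Evoked ASSR quantities

Per channel and session: the evoked spectrum is the trial-average
periodogram of the last 200 ms before train cessation (the steady-state
window, past the N1); the baseline spectrum comes from 200-ms segments
10 s before each train onset; the relative spectrum is their bin-wise
difference (may be negative). For the first train, whose baseline instant
precedes the ASSR session, the segment falls in the pre-stimulus epoch and
is used when inside the recording; otherwise that trial contributes no
baseline segment (logged). N1 amplitude is the peak |deflection from the
pre-onset mean| of the trial-averaged z-scored trace within (0, 100 ms].

## State-transition table

Five epochs: Pre (last 10 s before the first train), ISI after the first,
middle and last train (5–15 s post-onset), and Post (10 s starting 20 min
after the final train, falling back to the last available 10 s of the
post epoch when the recording is shorter — logged). At the full 50-train
protocol the probes are trains 1, 25 and 50; scaled sessions use
first/middle/last with labels naming the actual train index. Each epoch
contributes 50 bins of 200 ms; per-bin spectra are averaged and band
means tabulated per (animal, channel, genotype, epoch, band). The
"combined ISI" summary is the mean of epoch means (not a pooled bin set);
the alternative is one groupby away from the tidy table.

## Group statistics

* Two designs: **per animal** (unweighted channel mean within animal) and
  **per channel**. Both are plain fixed designs; hierarchical modeling of
  channel-within-animal is out of scope by design.
* Two-group contrasts: pooled-variance (Student) t, two-sided, and
  Cohen's d with pooled SD (n−1 denominators), sign convention
  (mean_a − mean_b)/s_pooled. d is scale-invariant and t² equals the
  one-way ANOVA F for two groups (both tested).
* State tables: classic split-plot ANOVA — between factor genotype, within
  factor epoch, subject nested in genotype, no sphericity correction (the
  output carries a `sphericity_corrected = False` flag so users can judge).
  Implemented by direct sums of squares and cross-checked in tests against
  an independent reference implementation and against hand-computed SS to
  1e-10. Degenerate tables (zero error variance) report NaN F with a flag.
* Post-hoc family: paired t over all epoch pairs within each genotype,
  Bonferroni-adjusted with m = total number of pairs tested; m is stated
  in the output. Between-genotype-within-epoch contrasts are available via
  the group-comparison table instead.

## The synthetic session generator

Each channel is the sum of:

1. **Background**: 1/f^α noise (α = 1 by default), synthesized in the
   frequency domain — random complex-Gaussian coefficients with amplitude
   ∝ f^(−α/2), zero DC — for exact spectral control, rescaled to a
   state-dependent SD: `background_gain_quiescent` during pre/post and
   `background_gain_stimulated` during the ASSR sessions, blended with a
   1-s raised-cosine crossfade at epoch boundaries (state changes are not
   physiologically instantaneous).
2. **N1 transient** per train: negative Gaussian deflection, latency
   30 ms, width 15 ms, amplitude 0.2 mV (control default).
3. **Steady-state oscillation** per train at the drive frequency plus a
   2f harmonic at 0.3× amplitude, starting 100 ms after train onset with a
   50-ms ramp — deliberately after the N1, because the analysis window is
   the final 200 ms precisely to avoid N1 contamination. The per-trial
   phase is von Mises(0, κ).

Default physical scales: quiescent background SD 25 µV, so the 0.1-mV
screen sits at ~4 background SDs and the control N1 (0.2 mV) passes it;
steady-state amplitude 50 µV; κ = 8 (PLF ≈ 0.94).

**Genotype contrast** (documented ratios, overridable): mutants get
steady-state amplitude × 0.5, phase concentration × 0.25, quiescent
background gain × 1.5 — while the *stimulated* background gain stays at
the control value. The last point is a modeled assumption: it builds the
state-dependent normalization (elevated quiescent power that becomes
indistinguishable during stimulation) into the generator by construction.
The ratios are qualitative-pattern placeholders, not estimates; nothing
in the source data quantifies the underlying generators.

**Consequences of z-normalization worth knowing.** Because mutants carry
more quiescent variance, their whole-recording SD is larger, which (a)
shrinks the apparent quiescent elevation in z² units (≈1.9–2.1× instead of
the raw 2.25×), (b) pushes the stimulated-state ISI ratio slightly below
parity (≈0.85–0.9×), and (c) lowers mutant N1 amplitudes in z units by
~10 % even though the raw N1 is identical — so with enough trials a
genotype difference in z-scored N1 can reach significance in the
simulation. All three are consequences of the normalization convention
operating on the generative model, not implementation artifacts.

**What the generator does not emulate**: spiking activity and its coupling
to the LFP, line noise, movement/EMG artifacts, electrode drift, the
30-Hz resonance seen under 40-Hz drive in real recordings (treated as an
emergent readout, not injected), laminar or spatial structure across
channels (channels are statistically independent), and any biophysical
circuit mechanism. Passing pattern-recovery tests therefore shows the
*pipeline* recovers directions a generator of this structure embeds — it
says nothing about mechanism in real cortex.

## Problem sizes used in validation

Pattern recovery runs 3 + 3 animals × 4 channels with 10 trains/session
over 20 seeds (the four qualitative directions — lower 35–44-Hz relative
power and PLF at 40-Hz drive, lower 15–24-Hz at 20-Hz drive, elevated
quiescent broadband power, ISI normalization — must each appear in ≥95 %
of seeds). The ISI-normalization direction is operationalized as the ISI
genotype contrast having a smaller |Cohen's d| than the Pre contrast,
since a raw non-significance check would fail at the type-I rate even on a
true null. Harmonic-structure checks use the full 50-train protocol.
Noise-floor and κ-recovery checks use 50 trials × 200 replicates and 2000
trials respectively. Determinism is asserted byte-wise on the full
pipeline at 2 + 2 × 2 channels, 5 trains.

## Known limitations

* EDF export quantizes to 16 bits of the per-channel range and pads the
  final 1-s record; the native .bin+.json pair is the lossless format.
* The periodogram's leakage (no taper) biases peak *locations* by up to
  2 bins near strong neighboring components; band means are unaffected at
  the bands' 9–10-Hz widths.
* The mixed ANOVA assumes a balanced design (every subject × every epoch);
  recordings missing an epoch drop out of that band's table with a warning.
* Per-channel designs treat channels as independent observations, as in
  the source analyses; this overstates effective n when channels are
  correlated (they are, in real arrays).
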