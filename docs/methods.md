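# Methods

This note records the models behind each detector, the tunable parameters
and their defaults, what the synthetic generator does and does not emulate,
and the design choices made where the design was genuinely open.

## Signal representation

All detectors run at 200 Hz. Input records at other rates are resampled
with polyphase FIR anti-aliasing (`scipy.signal.resample_poly`; the
rational rate ratio is approximated to within 1/10000). Output length is
`round(n·target/fs)`. Polyphase filtering is zero-phase in the passband, so
beat fiducials survive resampling to within a sample or two; annotations
are rescaled by the same ratio. Records are cut into non-overlapping 5-min
windows; a trailing partial window is kept (flagged) when at least 60 s
long, else dropped — tails shorter than that give too few beats for any
rhythm statistic.

Sample indexing is 0-based throughout and rhythm episodes are half-open
`[start, end)` intervals, which makes duration arithmetic exact and
overlap tests single comparisons.

## QRS detection

The detector is the classic adaptive-threshold chain: Butterworth band-pass
8–16 Hz (order 2, applied forward-backward so the envelope is not delayed),
5-point central derivative, rectification, 80 ms moving-window integration.
Envelope peaks are accepted as QRS when they exceed
`noise + 0.3125·(signal − noise)`, where signal/noise are running means of
the last 8 accepted/rejected peak amplitudes. A 200 ms refractory period is
enforced; a candidate within 360 ms of the previous beat is rejected as a
T wave when its maximum filtered slope is below half the previous QRS
slope; when the current inter-beat gap exceeds 1.5× the recent mean RR, the
largest sub-threshold peak above half the threshold is recovered
(search-back). Finally each detection is refined to the raw-signal sample
with the largest absolute deviation from the local median within ±80 ms, so
reported beat positions are R peaks, not envelope maxima. Because every
threshold is relative, detection is invariant to positive amplitude
scaling.

## Beat features and fiducials

Seven features per beat: P-R interval, QRS duration, previous RR, next RR,
mean and SD of the RR intervals spanned by the ten beats before and after
(pooled into one statistic each; edges truncate the pool), and R amplitude.
Undefined values (first beat's RR_prev, an undetectable P wave) are NaN,
never zero.

QRS onset/offset are found by scanning outward from R until the signal
stays within 10% of the R deviation from baseline for at least 20 ms; the
boundary is the last supra-threshold sample, the scan range is ±120 ms and
never crosses the midpoint to a neighboring beat. Baseline is the median
over ±0.5 s — wide enough that diastole dominates. The 20 ms hold bridges
the brief sub-threshold gap between the R and S waves. The generator's
`template_qrs_duration` measures the rendered template with the same
convention on a fine grid, which is what makes the ±10 ms feature tests
meaningful. The P wave is the largest deflection 40–240 ms before QRS
onset, accepted when it clears both a 0.02 mV floor and 4% of the R
amplitude.

## VPC rule

A beat is labeled V when it is wide — QRS duration above 1.5× the running
median width of the preceding (up to 50) non-V beats, falling back to the
record median before five such beats exist — and premature — RR_prev below
0.85× the pooled neighborhood mean. Beats with any undefined input are
never labeled V. The two factors are config values; 1.5/0.85 were chosen as
round numbers inside the physiological bands (VPC QRS ≥ 120 ms vs ~80 ms
normal; coupling intervals well short of the sinus cycle) and were fixed
before any scoring.

**Known limitation:** during AF the rule's prematurity condition is
satisfied by roughly a third of beats (the RR series is irregular by
definition), so occasional width over-measurements on the fibrillatory
baseline become V false positives — a few percent of AF beats in the
synthetic corpus. This ectopy/AF interaction is intrinsic to staged
pipelines that classify beats before rhythm; it is surfaced rather than
patched because the RR-correction step (below) removes most of its effect
on AF detection, and VF episodes clear ectopic labels via the override.

## AF detection

Per window: (1) RR correction — every interval adjacent to a V beat is
replaced by the mean of the nearest intervals on either side not themselves
adjacent to a V beat (single neighbor at edges; all-V windows pass through
with a warning), so ventricular prematurity does not masquerade as AF
irregularity; (2) hr_n = 60/RR_n; (3) symbols `sy_n = min(⌊hr/5⌋, 63)` with
saturation at 315 bpm; (4) word values `wv_n = sy_{n−2}·4096 + sy_{n−1}·64
+ sy_n`, a base-64 positional code that is injective on symbol triples;
(5) sample entropy of the word sequence, `SampEn = −ln(A/B)` with
Chebyshev-matching templates, m = 2, r = 0.2× the window's own word SD;
(6) AF iff SampEn ≥ θ_AF = 1.18.

An undefined entropy (A or B zero, or fewer than `min_beats = 100` beats in
the window) yields an *undetermined* decision, distinct from not-AF. A
window whose words are exactly constant is assigned entropy 0 by
continuity. Consecutive AF-positive windows merge into episodes whose
boundaries lie on window boundaries.

θ_AF was calibrated once with `rhythmscan calibrate-af` (20 AF + 20 sinus
synthetic windows, seed 0): the geometric midpoint between the largest
sinus entropy (0.85) and the smallest AF entropy (1.63). Sinus windows
score well above zero because the 30 ms RR jitter of the generator crosses
5-bpm symbol bins; the AF/sinus gap, not the absolute values, carries the
signal. m and r follow the common physiological-series defaults (m = 2,
r = 0.2·SD); r scales with the window's own SD so the decision is invariant
to overall rate level.

## VF detection

2-s segments, mean removed, rectangular-window periodogram (no zero
padding): 0.5 Hz bins at 400 samples. Band maxima: p_vf over bins in
[2.61, 4.95] Hz (both ends inclusive), p_nVF over (0.5, 2.61), p_nVF2 over
(4.95, 10]. With 0.5 Hz bins the edges 2.61/4.95 fall between bins, so
membership is decided on exact bin frequencies and every bin belongs to one
band: in practice p_vf sees 3.0–4.5 Hz, p_nVF 1.0–2.5 Hz, p_nVF2
5.0–10.0 Hz. Decision: VF iff `p_vf/(p_nVF + p_nVF2) ≥ 3.96`, ties
inclusive; a zero denominator with nonzero p_vf is VF, an all-zero segment
is not. "Maximum point" is read as the peak periodogram amplitude in each
band, not band energy, consistent with dominant-frequency analysis of VF.
The ratio is homogeneous, so classification is amplitude-scale invariant.

Consecutive VF segments merge into episodes; a single negative segment
between positives is bridged (`bridge_gaps = 1`, configurable), because
episode-level scoring is fragmentation-sensitive and 2-s dropouts inside a
fibrillation run are measurement noise, not rhythm changes. When the
override flag is on (default), beats inside detected VF episodes have
ectopic labels cleared — a fibrillating signal has no meaningful beat
classes, and spurious V labels inside VF would double-count the event.

## APC perceptron

Single hidden layer (10 units), sigmoid activations on both layers,
weighted cross-entropy loss with inverse-class-frequency sample weights,
full-batch gradient descent (rate 0.01, up to 500 epochs), early stopping
on validation loss with patience 20, stratified 60/20/20
train/validation/test split. Missing features are imputed with training-set
medians and z-scored with training-set statistics; both are stored in the
model so inference is self-contained. All randomness flows from one seed —
retraining is bitwise reproducible. Gradients are exact for the
architecture and are verified against central finite differences in the
tests. The classifier only relabels beats not already V: the VPC stage runs
first and its labels are never overwritten. Ties at probability 0.5 go to
S, favoring sensitivity on the rare class.

The hidden size, rate and stopping rule are package choices (the method
family prescribes none); they are config values, and the pipeline runs with
the APC stage disabled unless a trained model is supplied.

## EC57-style scoring

Beat pairing is greedy nearest-neighbor, one-to-one, within 150 ms; the
candidate list is sorted by |Δt|, so the pairing is symmetric in the two
streams and swapping reference and test swaps Se↔+P exactly. FPR uses
fp/(fp+tn) over paired beats; a statistic with an empty denominator is NaN
and excluded from *average* aggregation (never zero-filled), while *gross*
aggregation pools numerators and denominators first. Episode overlap uses
the any-nonzero-overlap criterion; the refined minimum-overlap episode
rules of the full standard are deliberately not replicated. Record
exclusion lists (paced records and known-artifact records of the public
databases) are config, not code.

## Synthetic generator

Beats are sums of five Gaussians (P, Q, R, S, T) with fixed default
offsets/amplitudes/widths (R: 1.0 mV, σ = 11 ms); a beat's R Gaussian is
centered exactly on an integer sample, and that index is the ground-truth
beat mark, so detector offsets are measured against exact truth. Sinus RR
is the configured rate plus 30 ms Gaussian jitter. APCs are 0.7× premature
with a damped, shifted P and a non-compensatory reset; VPCs are 0.6×
premature, double-width, P-less, 1.25× amplitude, followed by a
compensatory pause; premature complexes are only inserted after a normal
beat (isolated ectopy, as hardware rhythm simulators produce). AF draws RR
i.i.d. uniform(0.35, 1.0) s, suppresses P waves and adds a 0.05 mV
wavering ~5–7 Hz fibrillatory baseline. VF renders no beats: a sinusoid
whose instantaneous frequency follows an Ornstein–Uhlenbeck walk (θ = 1/s,
σ = 0.4 Hz·s^-1/2) clipped to 3–5 Hz, amplitude-modulated ±30% at 0.4 Hz.
Optional white noise at a configured SNR, baseline wander and mains tones.

What the generator does *not* emulate: real QRS morphology variation,
conduction aberrations, fusion beats, atrial flutter, muscle-artifact
noise bursts, and electrode pop. Passing tests therefore demonstrate
algorithmic correctness and internal consistency at realistic rates and
amplitudes — not clinical performance on database recordings, whose
headline numbers depend on those harder morphologies.

## Problem sizes in the shipped checks

The test suite and `scripts/acceptance.py` use 10-record corpora of 10–20
minutes per record, 20+20 windows for the AF separation experiment, 100
random sequences for the entropy oracle, and 1000 random interval
configurations for the scoring oracle — sizes chosen so the full
verification runs comfortably on a laptop while every statistic still has
enough events (hundreds of beats, tens of episodes) to be meaningful.

## Numerical conventions

* Sample entropy counts ordered template pairs i ≠ j over the N−m
  templates whose (m+1)-extension exists; undefined results are `None`,
  never 0.
* `word_values` needs ≥ 3 symbols, else empty; `symbolize` requires
  nonnegative rates and `rr_to_hr` strictly positive intervals (errors
  otherwise).
* The WFDB writer quantizes at the configured gain (default 200 ADC/mV);
  round-tripping a written file is exact, writing an arbitrary float
  signal is exact to half an ADC step.
* Resampling pads/truncates by at most one sample to hit the exact
  `round(n·ratio)` output length.
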