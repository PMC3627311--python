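# Methods

This note documents the models, algorithms and defaults implemented in
`nirschange`, and what the simulation-based tests do and do not establish.

## Paradigm and probe model

The change-detection (oddball) block design alternates baseline blocks of a
repeated background word (/abuna/) with fixed-length target blocks in which a
contrast word — /abna/ (consonant cluster) or /abuuna/ (long vowel) — is
pseudo-randomly interleaved with the background word. Tokens are presented
at a stimulus onset asynchrony (SOA) of 1.5 s; a 9 s target block therefore
holds 6 tokens and baselines of 9–18 s hold 6–12. Baseline durations are
drawn uniformly from the SOA multiples inside the jitter interval: block
lengths are then whole token slots, which is the only reading consistent
with the stated token counts. Sessions begin and end with a baseline, so a
session with *n* target blocks has *n* + 1 baselines; condition counts are
exactly balanced. "Pseudo-random" is pinned down as: near-balanced word
counts within a target block with no run longer than two, and (in multi-token
mode) no immediate repetition of the same recorded token. These constraints
are implementation choices — the stimulus descriptions we follow leave them
open — and they are exposed in `token_sequence` for inspection.

The adult follow-up design crosses target duration (9 s vs 15 s, baselines
9–18 s vs 15–22 s) with token variability (single vs multiple tokens). Both
stimulus conditions appear in each adult session (only the duration blocks
carry a simulated response, since a vowel-length contrast is the native one
for the emulated listeners); 5 (short) or 4 (long) target blocks per
condition put the expected session in the 4–5 minute range.

Word durations are the sums of the mean phoneme durations of the recorded
tokens; two of the three words' printed totals differ from the phoneme sums
by 0.1 ms (rounding), and the phoneme sums are used.

A probe pad is a 2×4 optode lattice with checkerboard source/detector roles
(top-left = source). Adjacent pairs give 10 short channels at the nominal
separation (25 mm infant, 30 mm adult); knight's-move pairs give 4 long
channels at √5 × separation ≈ 55.9 mm (≈56 mm). Channel numbering is
deterministic (row-major, right neighbour before down); since any published
pictorial numbering cannot be recovered reliably from text, ROI membership
(default channels 4, 6, 7 per hemisphere) is configuration, not geometry.
Left/right pads are mirrored, so channel *k*'s hemispheric counterpart is
channel *k* on the other pad.

## Synthetic recordings

Each channel's oxy-Hb series is

```
oxy = Σ_c  a(ch, c) · (boxcar_c ⊛ HRF)  +  noise  +  artifacts
```

with the condition regressor normalised to unit peak so that `a` is directly
the response amplitude in mM·mm, and deoxy-Hb = −0.3 × the oxy response
(the canonical oxy-up/deoxy-down pattern; the ratio is configurable).
The canonical HRF is a double gamma parameterised by its actual time to peak
(5.5 s), undershoot delay (15 s), unit dispersions and a 6:1
peak-to-undershoot ratio, normalised to unit peak. The source texts say
only "canonical"; these values are typical of adult/infant auditory
responses and are fully config-visible.

Noise defaults (all mM·mm, chosen once as plausible continuous-wave
magnitudes — no numeric noise levels are reported for the emulated studies):
white sd 0.03; drift sinusoids of periods 60 s and 180 s with amplitudes
0.02/0.03 and random phases; cardiac 2.5 Hz × 0.01 (an infant heart rate —
the 10 Hz default sampling keeps it below Nyquist); respiratory 0.6 Hz ×
0.008. Motion artifacts are spikes (triangular, default 0.2 s) or lasting
steps, applied to **all** channels of the montage (head movement is
pad-wide) with the stated magnitude appearing in total-Hb (half each in oxy
and deoxy).

The forward optical model is the modified Beer-Lambert law
`OD = E·[oxy; deoxy]` per wavelength with nominal extinction coefficients for
the ~780/830 nm and ~670/850 nm pairs shipped as overridable constants. The
differential pathlength is deliberately left unresolved, hence mM·mm
throughout ("mM/mm" in some texts denotes the same concentration ×
pathlength product).

What the generator does **not** emulate: spatially correlated physiology
across channels, superficial (scalp) contamination distinct from cortical
signal, realistic infant motion dynamics beyond spikes/steps, and
photon-transport effects. Passing tests therefore establish correctness of
the *procedures* and their calibration under stationary structured noise,
not performance on any particular instrument's real data.

## Preprocessing

* **MBLL inversion** solves the 2×2 system per sample; a singular extinction
  matrix is an error and a condition number above 10³ warns (nearly
  proportional rows make the separation noise-amplifying).
* **Band-pass**: zero-phase 3rd-order Butterworth, 0.02–0.7 Hz, applied
  forward–backward. Only the band is prescribed by the method we follow;
  the realisation is ours.
* **Artifact criterion**: on band-passed total-Hb, any sliding 100 ms window
  whose max−min excursion exceeds 1.5 mM·mm flags every sample it covers.
  The alternative derivative-based reading (sample-to-sample change scaled
  to 100 ms) is deliberately not the default; the windowed excursion is the
  more conservative interpretation for sub-sample steps. Flags are pooled
  across the channels of a probe pad; events separated by < 0.5 s merge.
  An event is **major** when its excursion exceeds 2 × threshold or it lasts
  longer than 1 s ("major" is otherwise undefined in the sources; this
  definition is config-exposed). Ordinary events get zero GLM weights
  (± 1 sample padding); major events additionally contribute a 0→1 step
  regressor switching at the event end.

## GLM and responding-channel inference

The per-channel design holds an intercept, one HRF-convolved boxcar per
condition, demeaned sine/cosine detrend pairs with periods 2, 3, …, *n*
minutes up to the session length (none below 2 minutes, with a warning),
and the baseline-shift steps. Fitting is least squares on the weight-1
samples; rank deficiency is reported with the offending column names. The
response statistic is `r`, the correlation between the observed series and
the fitted condition-only prediction on retained samples; `z = β/se` of a
condition beta defines the z-scores used in the adult analysis (the sources
leave "Z-scores obtained from the GLM" undefined; this is the natural
reading).

Chance calibration uses a max-statistic (Westfall–Young style) Monte-Carlo
test with a Freedman–Lane circular-shift surrogate. Each iteration draws
one shift, uniform on [30 s, session − 30 s], and for every channel forms
`y* = nuisance fit + roll(nuisance residual, shift)`: the residual of the
nuisance-only (reduced) model is circularly shifted — preserving its
autocorrelation and, because the shift is shared, the cross-channel
dependence that the max-statistic construction exists to honour — while the
fitted slow trends stay at their true time positions, so their wrap-around
discontinuity never contaminates the null. The full model is refit to each
surrogate, the maximum |r| over the channel family is recorded, and
`p_corrected = (1 + #{max ≥ |r_obs|}) / (1 + N)` with `N = 10,000` by
default. At zero shift the surrogate is exactly the observed series, so
observed and null statistics are the same functional. The per-shift refit
has a closed form — every shift-dependent inner product is a circular
cross-correlation — so the statistic is evaluated for all shifts at once by
FFT, algebraically identical to the explicit surrogate refit (asserted in
the tests) and fast enough to measure family-wise calibration over hundreds
of sessions. The correction family is all channels of a recording;
corrected p is automatically monotone in |r| within a family. A residual
bootstrap would be a reasonable alternative resampling unit; the circular
shift was chosen as the default because it makes no whiteness assumption
about the residuals. Shifting the *raw* series instead (the naive reading)
was measured to inflate the family-wise error by a few points, because slow
drift acquires an artificial discontinuity at the wrap point; the surrogate
scheme removes that distortion. Null-calibration measurements use the
design's stated minimum of 16 target blocks (≈ 6.5 min), where the
empirical family-wise error sits near the nominal 5%; very short sessions
leave few effectively independent shifts and run a point or two above it.

Both ANOVAs (Condition × Hemisphere on betas; duration × token-variability
on z-scores) are classical balanced two-way fully-within-subject
decompositions, each effect tested against its own subject-interaction mean
square; they are cross-checked in the tests against an independent
implementation. Degrees of freedom are the conventional
(levels − 1, (levels − 1)(subjects − 1)).

## FIR reconstruction and laterality

The FIR model uses 20 one-second boxcars per condition at shifts 0–19 s from
each target onset. (The procedure we follow states "20 regressors shifted
by 0, 1, …, 20 s", which would be 21; the count 20 is kept and the shift
list truncated — the bin count is configurable.) Oxy and deoxy are fitted
separately; total-Hb betas are their sums. With the default infant design
the 20 s window can exceed the shortest onset-to-onset gap, in which case a
warning is raised and late bins share variance between consecutive blocks —
the least-squares fit still separates them when baselines are jittered.

The ROI peak is the maximum **absolute** total-Hb beta over the ROI channels
and the bins starting inside [0, 9) s; the signed value at the peak is kept
for reporting. The laterality index is `(L − R)/(L + R)` of the left and
right peak magnitudes — guaranteed in [−1, 1] because magnitudes are
non-negative — undefined (missing) when both are zero. Group summaries
report mean, type-7 (linear interpolation) quartiles and range.

## Validation experiments and problem sizes

`nirschange.experiments` packages the simulation studies used by the tests
and by `scripts/acceptance.py`; all are pure functions of a seed:

* **Family-wise error**: 200 stimulus-free sessions (16 target blocks, full
  noise model, zero amplitude), 1,000 Monte-Carlo iterations each; the
  fraction of sessions declaring any responder should sit near α = 0.05.
* **Beta recovery**: amplitude 0.1 mM·mm against white noise sd 0.01 on an
  8-block session; worst ROI-channel relative error (well under 10%).
* **FIR recovery**: widely spaced blocks (baselines 21–27 s) so the 20 s
  window fits; correlation between recovered and true bin curves, noiseless
  and at noise sd = amplitude/5.
* **Adult 2×2 power**: cohorts of 8 subjects × 4 sessions; ground-truth
  amplitudes 0.08 / 0.05 / 0.05 / 0.03 mM·mm for long-single / long-multi /
  short-single / short-multi (increasing with duration, decreasing with
  token variability), 25% lognormal between-subject spread; the z entering
  the ANOVA is the peak duration-condition z across the left ROI channels.
  Reported: fraction of cohorts with both main effects at α = 0.05.
* **Laterality recovery**: cohorts with left ROI amplitude 0.08 and right
  0.04 mM·mm; the group-mean LI should be positive.

These sizes were chosen to make each suite run in seconds to a couple of
minutes on one CPU while keeping Monte-Carlo error small relative to the
assertions made.

## Known limitations

* The circular-shift null assumes approximate stationarity; abrupt
  non-stationarities that are not flagged as artifacts can distort it.
* Probe-level artifact pooling discards per-channel granularity by design;
  a channel-level mode would require a different exclusion bookkeeping.
* The events format recovers block structure from token rows and SOA
  arithmetic; schedules with silent gaps between blocks are out of scope.
* The ANOVA requires complete balanced cells; subjects with missing cells
  must be excluded upstream.
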