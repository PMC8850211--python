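# Methods

## Protocol model

The protocol is a Method of Constant Stimuli: every combination of stimulus
level × location × repetition is presented exactly once, in seeded
pseudorandom order, on a fixed presentation cycle of 1.7 s (200 ms stimulus
+ 1500 ms interstimulus interval). Defaults: 13 luminance levels in equal
3-dB steps from 3 dB (160 cd/m²) to 39 dB (0.04 cd/m²) on a 10 cd/m²
background, 20 repetitions per level at each of three peripheral locations
(−6.1°, −3.5°), (0°, 7°), (6.1°, −3.5°) and 2 per level at the central
reference (0°, 0°), giving 13 × 62 = 806 regular presentations.

Stimulus intensity uses the perimeter attenuation scale
`dB = 10·log10(anchor/luminance)` anchored at 320 cd/m²; dB values are kept
exact internally and rounded to integers only for display, which reproduces
the conventional printed pairs (3 dB ↔ 160, 39 dB ↔ 0.04).

Catch trials: the total count N is `ceil(regular / (1 − f_fp − f_fn))`, each
kind's count is `round(rate · N)` with any rounding residue absorbed by the
infrathreshold kind, and the combined list is permuted by a single seeded
generator (`numpy.random.default_rng`). At the default 25% + 25% this
doubles 806 to 1612 presentations and yields one catch trial per
`cycle/(f_fp+f_fn)` = 3.4 s on average (21.25 s at clinical 4% + 4% rates).
The expected session is 1612 × 1.7 s ≈ 45.7 min.

One naming caveat: by convention the catch trial that *should* be seen is
called false-negative, but perimetric protocols sometimes label the 0 dB
catch "false-positive" after the device flag it raises. Here `fp_catch` is
the 0 dB suprathreshold kind (error = no response) and `fn_catch` the 40 dB
infrathreshold kind (error = response); the dB assignments are configurable,
and error semantics follow the attenuation, not the label.

## Observer simulator

The simulator exists to give the analysis a cohort with known ground truth.
It makes three deliberate simplifications:

1. **Two-state vigilance.** Episode starts are a Poisson draw
   (`episode_rate` per session, default graded 0–8 across a cohort), with
   exponential durations (mean 60 s) and overlaps merged; vigilance v is 1
   outside episodes and `1 − episode_depth` (default 0.5) inside. A
   continuous vigilance process would be more physiological, but two states
   make the recovery target unambiguous: every analysis claim can be checked
   against the episode intervals.
2. **Frequency-of-seeing detection.** `p(detect) = v · Φ((threshold −
   attenuation)/slope)` with the normal CDF, threshold 30 dB, spread 2.5 dB —
   typical near-foveal normal sensitivity. Undetected presentations elicit a
   guess with probability `base_fp_rate + fp_increment·(1 − v)`
   (defaults 0.03 and 0.15): a constant careless-press floor plus an
   episode-linked increment, so infrathreshold catch errors also rise during
   lapses.
3. **Linear RT in attenuation.** `RT = 312 + 5·dB + 40·[episode] +
   N(0, σ)` ms with σ = 50 ms outside and 50 × 2.5 ms inside episodes,
   truncated to the response window (0, 1700] ms; out-of-window draws count
   as non-responses. A Piéron power law would fit absolute latencies better;
   a linear slope is the simplest monotone model for "dimmer is slower" and
   the analysis only uses ordering and dispersion. The intercept calibrates
   the pooled median RT of a fully vigilant session to ≈ 355 ms, a
   representative normal-observer value; nothing else is calibrated, and no
   simulator default should be read as a population estimate.

An optional `truncate_fraction` stops a session early, emulating aborted
recordings.

What the simulator does *not* model: circadian drift, learning and
within-session sensitivity decline, fixation losses, location-specific
thresholds, response-time autocorrelation beyond the episode structure.
Passing recovery tests therefore show that the pipeline detects
episode-like vigilance structure, not that it captures every failure mode
of real perimetry.

## Series construction

All series share a 1-s grid over the session. RT observations (one per
answered presentation, stamped at stimulus onset) are linearly interpolated
onto the grid; before the first and after the last observation the nearest
value is held. Interpolation spans *every* unanswered presentation — the
main source of gaps is infrathreshold stimuli that correctly go unanswered —
and per-sample provenance flags (`observed` vs interpolated) are kept so
alternative readings can be compared.

RTV is the population variance (divisor n; the divisor is a documented
choice, not a statistical claim) of the RT series over a **trailing** 60-s
window (t − 60, t]. A trailing window, rather than a centred one, is what an
online implementation inside a perimeter could compute during the exam.
Windows before t = 60 s use the partial data available; the error-rate
series likewise counts error events in the trailing window (raw count per
partial window), which keeps the count-conservation property exact: samples
at 60, 120, … s partition the session and sum to the total error count.

Normalization is per subject, (x − min)/(max − min); constant series map to
0. Pooled normalization is available via the series API but not default:
per-subject scaling is what makes one global cut-off meaningful across
observers with different baseline latencies.

The gold-standard mask flags samples with strictly more than 2 errors per
minute — a threshold expressed on the raw per-minute scale, chosen as a
round operating point near the upper tail of normal cohorts; it is a
parameter of `ResponseQualityModel`, and the tests also exercise recomputing
it as a pooled 95th percentile.

## Analysis choices

- ROC positives are grid *seconds* inside the gold-standard mask, pooled
  over all subjects' samples (per-subject weighting would change cohort
  balance; pooling matches the "one global criterion" framing).
  Candidate cut-offs are every distinct pooled value plus ∓∞ sentinels;
  sensitivity uses strict `>`, specificity `≤`.
- AUROC is the trapezoidal area; with ties traversed in ascending
  sensitivity it equals the Mann–Whitney pair-ranking probability with ties
  half-counted, which the tests verify by enumeration.
- The Youden optimum breaks ties toward the larger cut-off (fewer flags);
  its percentile is the inclusive empirical CDF of the pooled values.
- The deviant-value mask uses strict `>` at the cut-off, no morphological
  smoothing of the flagged periods.
- The AI is undefined (NaN) when neither mask flags anything; such subjects
  are excluded from AI medians and meta-correlations — an AI of 0 would
  conflate "nothing happened" with "indicators disagree".
- Spearman ρ is the Pearson correlation of mid-ranks; p-values use the
  t approximation with n − 2 degrees of freedom. Zero rank variance
  (typically an error-free subject) yields a flagged NaN rather than an
  arbitrary value. No multiple-testing correction is applied; reports list
  the per-subject p-values raw.

## Problem sizes and determinism

The default study conditions — 48 subjects × 1612 presentations, episode
rates graded 0–8 — run in about a second, so tests and the acceptance
script use them directly; the recovery checks repeat the full cohort over
20 master seeds. Every random draw descends from one master seed through
`numpy.random.SeedSequence`, so schedules, sessions, reports and manifests
are byte-identical across reruns with the same seed and configuration.

## Known limitations

- The simulator's free parameters mean absolute AUROC/AI/ρ magnitudes are
  properties of the synthetic cohort, not of any patient population; only
  orderings and signs are claimed.
- Interpolated RT samples are not statistically independent of their
  neighbours, and the per-second Spearman p-values inherit that optimism;
  they are reported for ranking, not inference.
- The gold standard itself derives from catch-trial errors, so agreement
  statistics measure consistency between indicators, not accuracy against
  an external vigilance measure.
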