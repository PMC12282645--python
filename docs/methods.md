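# Methods

This note documents the models, conventions and design choices behind
`nightscratch`: what each stage assumes, which parameters matter, what the
synthetic-study generator does and does not emulate, and where the design
was genuinely open.

## Time base and interval algebra

All nightly times are real-valued seconds from a per-night origin — noon of
the evening the night begins — so times are positive and monotone across
midnight and the math core never touches calendar dates (the I/O layer owns
timestamp conversion, `io.night_origin_seconds`). Intervals are half-open
`[start, end)`: adjacency is unambiguous, durations add exactly, and an
event starting exactly on an epoch boundary belongs to one epoch only.
Sub-second precision is kept everywhere; nothing is rounded until reporting.

Boundary conventions are fixed package-wide and mirror the defining
wording of each rule: gap merging (`merge_gaps`, default 3 s) fuses gaps
*strictly* shorter than the threshold; the minimum-duration filter
(default 2 s) is *inclusive*; the short-TSO exclusion (default 3.5 h) is
*strict*; merging is applied before filtering, always. The IoU of two empty
tracks is defined as 1: a motion segment in which neither rater marks
scratching is consensus on "no scratching", not missing data. Raw rater
labels that overlap within one rater are coalesced on ingest
(`normalize_track`), the only behaviour consistent with duration-based IoU.

## Consensus

Bout consensus strictly exceeds the threshold (default 0.765, a config
constant with no derivation here — it enters only as a comparison bound).
Round 1/2 output is the interval-set intersection of the two agreeing
raters, re-normalized; fragments of the intersection may later fall to the
2 s filter, because merging/filtering applies to the finished Reference
(consensus first, post-processing second). Round 3 takes the fifth rater's
labels verbatim. Per-segment consensus (`bout_consensus_segmented`) clips
all raters to externally supplied segment boundaries and concatenates;
segmentation itself is an input, not computed here.

Two agreeing TSO raters (both endpoints within 60 s) are combined by
*averaging* endpoints. This was an open choice — taking the first rater
would also be defensible — but averaging is symmetric in the raters and
unbiased, so it is the default.

## TSO derivation

Device TSO reuses the gap-merge primitive with a 30 min threshold; if
several merged sleep periods survive, the *longest* is the night's main
rest period (another open choice: the source wording implies a single merged
period; the longest is the natural main rest window and is monotone in the
inputs). Exclusion is applied independently per source, so one night can
remain analyzable for the Reference while being dropped for a device — the
per-comparison night counts in the reports therefore differ, by design.
Every record lands either in the analysis set or in the exclusion log with a
reason (`no_tso` or a duration reason); nights are conserved.

## Epoch scoring

The epoch grid is anchored at the start of the Reference∩device TSO window,
per night, and a trailing partial epoch is discarded — all epochs are
equal-length, so pooled counts are comparable across nights. The anchor is
deterministic and source-symmetric; anchoring to wall-clock boundaries would
be equally defensible but adds nothing. Counts are pooled across nights and
participants *before* metrics are formed (micro-averaging); tests assert
that this differs from averaging per-night metrics. Zero-denominator metrics
are reported as absent (`None`) with a logged warning, never coerced to 0 or
1. No clock-alignment correction is applied: the 10 s epoch is itself the
mitigation for imperfect clock synchronization, and the 1 s variant exists
precisely to show the sensitivity to boundary error.

## Night outcomes

Normalized outcomes are `scratch_seconds / tso_hours` and
`bouts / tso_hours`, computed after merge+filter, each source normalized by
its *own* TSO. Participant summaries are offset geometric means
`exp(mean(log(x + δ))) − δ` with δ = 1 in original units (configurable):
both outcomes are right-skewed and log-modelled, but zero-scratch nights are
legitimate data and a plain geometric mean would discard them. Sensitivity
to δ is reportable by re-running with a different offset. Group summaries
are medians and quartiles on the linear scale.

Morning itch responses (0–10 NRS, reporting on the previous night) are valid
when time-stamped between 04:00 and 12:00, *inclusive* at both ends (the
defining phrase "between 4 AM and 12 PM" does not fix inclusivity; inclusive
is the weaker reading). A participant-day with more than one morning
response is dropped entirely. Itch bands default to the conventional NRS
severity cuts 0 / 1–3 / 4–6 / 7–10; band edges are config because no
standard is implied, and overlapping bands are rejected. A morning response
dated D joins the night whose evening date is D − 1.

## Agreement statistics

The agreement model for log outcomes is
`y = μ + β_source + a_participant + b_night(participant) + e`, REML-fitted,
components constrained non-negative (boundary fits are valid and flagged).
Three fitting routes produce identical answers where their domains overlap
and are cross-checked in the tests:

* **balanced closed form** — for a fully balanced design the REML solution
  in the interior equals the balanced-ANOVA estimators; this vectorises
  across bootstrap resamples;
* **profiled REML** — for "complete nights" designs (every analyzable night
  observed by every source; nights per participant free), orthonormal
  within-night contrasts carry the source effects and residual variance in
  closed form, while night means follow a one-way unbalanced model whose
  REML is a one-dimensional profile optimization. Agrees with
  `statsmodels.MixedLM` to ~6 significant digits on unbalanced data;
* **numerical REML** (`statsmodels.MixedLM`) — the general fallback for
  ragged data; non-convergence is flagged with diagnostics, never silently
  replaced.

Data with no residual variation (e.g. identical outcomes across sources)
sit on the REML boundary; a degenerate path reads the components off the
night and participant means directly and reports ICC = 1.

Two ICC definitions are always computed: *adjusted*
`(σ²_p + σ²_n) / (σ²_p + σ²_n + σ²_e)` (fixed source effects excluded from
the denominator, the default and the cited convention's usual output) and
*unadjusted*, whose denominator also carries the population variance of the
fixed source effects — arguably the stricter reading of "absolute
agreement" when sources differ by a constant offset. Both appear in every
report, labelled.

**Bootstrap.** The resampling unit is the participant (cluster bootstrap):
nights within a participant are correlated, and resampling rows would fake
precision. The default interval is **cluster-t**: point estimate ±
t(G−1)-quantile × bootstrap SE, G the number of participants. Raw
percentile and basic (reversed-percentile) intervals are available via
`ci_method`. The default was chosen by calibration on the generator's own
coverage experiment: with a few dozen clusters the percentile interval of a
variance-ratio statistic runs systematically narrow, while the t-based
interval tracks the nominal 95% closely — the acceptance suite recomputes
this coverage at study scale on every run. CI bounds are clipped to [0, 1].
Non-convergent or undefined replicates are dropped and counted; losing more
than 20% flags the result.

**Bland–Altman.** Per-night differences d = DHT − Reference enter an
intercept-only mixed model with a participant random intercept; bias is the
intercept, and the 95% limits of agreement are
bias ± 1.96·√(σ²_between + σ²_within), symmetric by construction. Unpaired
nights are removed upstream. CIs for bias and both limits use the same
cluster bootstrap (percentile); with fewer than two participants the
analysis is refused, and zero-variance differences short-circuit to
zero-width limits.

## Synthetic-study generator

The generator emulates the *structure* of a three-cohort in-home validation
study: 5 healthy volunteers, 9 mild AD, 14 moderate AD; 8 reference nights
per participant spaced 3 days apart; five exchangeable raters (per-rater
overrides allowed); two device presets; morning and evening itch responses
for the AD cohorts.

* **TSO truth**: start ~ N(23:00, 30 min), duration ~ N(8 h, 0.75 h),
  floored at 5 h.
* **Scratch truth**: bout onsets are a homogeneous Poisson process over the
  TSO (no within-night timing structure is claimed anywhere, so none is
  modelled) with cohort base rates 2.4 / 3.51 / 4.64 bouts per hour;
  log-normal participant (σ = 0.45) and night (σ = 0.35) random effects on
  the rate, smaller ones (0.20 / 0.10) on mean bout duration. Bout durations
  are log-normal with the location set so the population mean duration
  equals the cohort's target scratch-seconds-per-hour divided by its target
  bouts-per-hour, floored at 2 s. The finished truth is passed once through
  merge(3 s)+filter(2 s) so it is a fixed point of the pipeline's bout
  post-processing — this is what makes the zero-noise identity test exact.
* **Raters**: per-bout misses (3%), Gaussian endpoint jitter (0.5 s,
  resampled if inverted), spurious bouts as a Poisson process (0.15/h), TSO
  endpoint jitter (20 s) — small enough that rater-vs-rater ICC lands in
  the moderate–good range and round-1 consensus dominates, with occasional
  escalations and TSO adjudications arising naturally.
* **Devices**: per-bout detection is Bernoulli with a logistic probability
  in bout duration; false bouts and jitter as for raters.  The
  accelerometer-like preset has a high false-bout rate (4.5/h → precision
  well below sensitivity); the touchless preset is less sensitive but far
  cleaner (1.3/h). Device sleep reports are the true TSO with a constant
  endpoint bias (+0.42 h / +0.44 h of duration, split across endpoints),
  participant- and night-level Gaussian endpoint errors sized so the
  Bland–Altman limits of agreement match the preset's target width with
  half the variance between participants, and occasional mid-night splits
  with gaps below 30 min that exercise (and are undone by) the sleep-period
  merge rule.
* **Itch**: morning NRS is a rounded, clipped noisy affine map of
  log(1 + true normalized duration), so itch-stratified summaries reproduce
  the qualitative "no itch ≪ mild/moderate" pattern; a small fraction of
  responses is emitted outside the validity window or duplicated to
  exercise the PRO filter. Healthy volunteers carry no itch scale.

All randomness flows through named streams
(`default_rng([seed, participant, night, role])`); no global RNG state is
touched, and equal seeds give byte-identical CSV output.

What the generator does **not** emulate: within-night clustering of bouts,
sleep-stage structure, rater drift or correlated rater errors, device error
dependence on posture or bed sharing, missing nights, or participants
turning the camera off mid-night (the main real-world source of short
reference TSOs). Passing tests therefore demonstrate the *pipeline's*
correctness and the statistics' calibration under a known, structurally
faithful model — not device performance on real recordings.

Each outcome also carries declared log-scale variance components
(`outcome_components`, default (1.0, 0.5, 0.5) → ICC 0.75) used by the
direct mixed-model simulator (`simulate_log_outcomes`) and its closed-form
twin `analytic_icc`; parameter-recovery and coverage experiments simulate
from these rather than through the event model, so the estimand is exact.

## Problem sizes in the validation experiments

The acceptance experiments use the study's own scale: 28 participants × 8
nights × 2 sources for ICC recovery (50 replicates) and bootstrap coverage
(200 replicates × 500 resamples, feasible because the balanced bootstrap is
vectorised), 50 replicates for Bland–Altman recovery, 20 seeded replicates
per condition for the monotonicity checks, 1000 fuzz tracks for the oracle
equivalence, and 20–25 replicate studies for the calibration check (a single
cohort median over 5 participants carries ~±20% seed noise, so calibration
is judged on the Monte-Carlo mean).

## Numerical notes and degenerate inputs

Oracle-comparison fuzz uses endpoints on a 0.5 s lattice, where every
duration, gap and epoch index is exactly representable, so "agrees exactly"
means floating-point equality, not a tolerance. Zero-length intervals are
invalid everywhere; empty tracks are valid and flow through every operation.
`read_events` collects malformed rows (inverted or non-numeric intervals)
into a line-numbered error report instead of failing the file, and reads
floats in round-trip precision so write→read is the identity. Variance
components truncated at zero are flagged `boundary`; all-zero components
make the ICC undefined (reported absent, not 0 or 1).

## Known limitations

The profiled-REML fast path requires complete nights; genuinely ragged
designs fall back to `MixedLM`, whose 500-resample bootstrap is slow
(~minutes). The unadjusted ICC uses the plug-in variance of estimated fixed
effects, which is slightly biased upward for few sources. Bland–Altman
limits assume Gaussian between/within components; heavy-tailed TSO errors
widen true limits beyond the Gaussian formula. The PRO joining rule assumes
night IDs are evening ISO dates; arbitrary night labels need a caller-side
mapping.
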