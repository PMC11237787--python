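# Methods

This note documents the models, rubrics, statistics and design choices in
`inkcog`, the assumptions behind them, and what the synthetic experiments
do and do not demonstrate.

## Ink data model

A session is a stream of timestamped pen (or drag) events, `down`,
`move`, `up`, with integer millisecond times since session start and
pixel coordinates (top-left origin, mirroring the 2160×1620 tablet
raster).  A *stroke* is a maximal down…up run; `move` events between an
`up` and the next `down` are in-air travel and belong to no stroke.
Milliseconds-as-integers makes the timeline identities below exact
rather than approximate; no sampling rate is assumed anywhere, so
streams from any digitizer rate are legal.

Strokes carry component labels (clock: `circle`, `number`, `pointer`;
figure tasks: `global_1..5`, `local_1..4`; drag clock: `number`,
`pointer`).  Labels are supplied, not inferred: geometric component
recognition is out of scope, and a human annotator plays the generator's
role for real data.  Drag-task "strokes" are drag segments — pick-up
(`down`) to drop (`up`) of a draggable element — with `source="drag"`.

## The 17-slot feature catalog

Definitions, for component class *C* (a set of labels; "figure" is the
union of all nine components):

| category | definition |
|---|---|
| thinking time | t(first `down`) − 0 |
| paint time(C) | Σ stroke durations with label ∈ C |
| unpainted time(C) | Σ gaps t(down_i) − t(up_{i−1}) where stroke *i* ∈ C, i ≥ 1 |
| total strokes(C) | number of strokes with label ∈ C |
| pen-up strokes(C) | transitions with equal labels on both sides, label ∈ C |
| frequency(C) | total strokes(C) ÷ paint time(C) in seconds |
| score | rubric total (below) |

Three choices deserve explanation:

* **Gap attribution.**  Every inter-stroke gap is charged to the
  *upcoming* stroke's component: hovering reflects planning the next
  element, and this makes "time for the hand to switch to stroke *i*"
  well defined even across component boundaries.  The gap before stroke
  0 is thinking time, never unpainted time.  Consequence (tested
  exactly): thinking + Σ_C paint + Σ_C unpainted = t(last up).
* **Pen-up strokes** are internal lifts — in-air transitions flanked by
  strokes of the same component.  This is the only lift-derived integer
  distinct from the total count, and it is 0 for a component drawn in
  one continuous stroke.
* **Frequency** divides by on-surface time, not elapsed time; dividing
  by elapsed time would fold the unpainted-time slots (5–7) into the
  frequency slots (14–16) and double-count the in-air signal.

Slots not applicable to a task (e.g. pointer slots in figure tasks) are
*missing* and excluded downstream — never imputed, never zero-filled.
The task applicability sets are: T1–T4 all 17; T5/T6 {1,3,6,9,12,15,17};
T7 {1,2,4,14,17}; T8 {1,5,7,16,17}.  For T8 "global/local drawing time"
are the paint-time sums over the 5 global resp. 4 local components,
while the drawing frequency uses all nine — the column wording implies
the global/local split for times and a whole-figure rate.

## Rubrics

* **Simplified Rey figure** (T5, T6, and T8 verbatim): each of 9
  components scores 2 (accurately drawn ∧ correctly located), 1 (exactly
  one of the two), 0.5 (neither, but identifiable) or 0; total 0–18 in
  0.5 steps.  `identifiable` is consulted only when both accuracy and
  location fail.  T8's dot lattice constrains positions in practice, but
  the rubric is applied unchanged.
* **Schulman clock** (T1–T4): ordinal 1–6.  The published criteria are a
  severity ladder whose exact tier boundaries are not reprinted in our
  source; the boundaries used here (see the table in
  `inkcog/scoring.py`, kept in one place for easy revision) are: 6 —
  clock unrecognizable; 5 — ≥ 7 of 12 digits missing/misplaced; 4 — any
  ordering fault or > 2 layout faults; 3 — hands majorly wrong, layout
  intact; 2 — 1–2 layout faults, a minor hand error, or an unacceptable
  contour; 1 — perfect.  The ladder is antitone in error count and is
  tested over the full annotation lattice.
* **Drag clock** (T7): one point each for numbers position, numbers
  order, pointer indication; 0–3, additive.

Scoring consumes structured annotations rather than raw ink because the
original scores were rater-assigned; the pipeline therefore exercises the
rubric arithmetic, not shape recognition.

## Synthetic cohort generator

The generator's job is to realize, with configurable effect sizes, the
qualitative group contrasts the analysis is built to detect: MCI slower
in the air and on the surface, more internal lifts, lower scores.

* **Timing**: log-normal draws (median, log-σ) for thinking time,
  per-stroke duration, per-transition air gap.  Times are positive and
  right-skewed, which also exercises the Mann-Whitney branch of the
  statistics, as in the real data the analysis mirrors.
* **Stroke structure**: each task is a fixed ordered list of component
  runs; a run emits 1 stroke, or, with probability `internal_lift_prob`,
  `2 + Poisson(max(0, μ − 2))` strokes (shifted Poisson, min 1 overall).
  The clock's twelve digits are modelled as one `number` run: pen-up
  strokes are equal-label transitions, so this keeps "no internal lifts
  ⇒ zero pen-up strokes" true by construction.
* **Scores** go through generated annotations, so the rubric code runs
  on every synthetic session.  `score_shift` is in rubric points
  (negative = worse).  For the figure rubric, E[component weight] ≈
  2 − 2p for per-flag failure probability p, so a shift of s maps to
  p = p₀ + |s|/18; the clock and drag rubrics use analogous scaled
  propensity shifts (coefficients in `simulate.py`).
* **Demographics** are drawn near the matched-cohort marginals (age ≈
  70–71 y, ≈ 6 y education, ≈ 58% women, ≈ 90% right-handed), with the
  eligibility constraints enforced exactly: MCI ⇒ MoCA < 26 ∧ CDR 0.5,
  HC ⇒ MoCA ≥ 26 ∧ CDR 0.
* **Presets**: `default` (moderate contrasts — air median ×1.35,
  durations ×1.15, score −1, lifts .12→.18 — chosen to land the
  downstream in-sample AUCs in the high .8s/low .9s, the plausible
  regime for this kind of screen), `strong` (air ×2, durations ×1.5,
  score −2: the recovery-experiment condition) and `null` (identical
  groups, for calibration).  HC anchors: thinking median 1500 ms,
  stroke duration median 800 ms, air gap median 500 ms, σ ≈ 0.45–0.55 —
  realistic magnitudes for elderly tablet drawing.
* **Reproducibility**: subject *i* uses substream
  `default_rng([seed, i])`, so cohorts are identical across runs and
  under parallel generation.

What the generator does **not** emulate: realistic stroke geometry
(polylines are schematic; all catalog features are time/count based),
pressure/tilt, digitizer noise, correlated deficits across tasks within
a subject (sessions are conditionally independent given group), or the
content of the verbal dual task.  Green synthetic tests therefore
demonstrate the *pipeline's* correctness and calibration, not clinical
performance on real patients.

## Statistics

* **Normality gate**: Lilliefors-corrected KS (plain KS with estimated
  parameters is anticonservative).  Constant samples are degenerate
  non-normal (p = 0).  A t test is used only when both groups pass at
  α = .05; Welch by default (`pooled_t=True` available, since the
  original software's variant is ambiguous).
* **Mann-Whitney**: exact enumeration when both n ≤ 12 with no ties,
  else tie-corrected normal approximation with continuity correction.
* **Hodges-Lehmann**: median of all n·m pairwise MCI − HC differences;
  the 95% CI takes the k-th smallest/largest pairwise difference with
  k = ⌊nm/2 − z₀.₉₇₅√(nm(n+m+1)/12)⌋ (Moses' large-sample rank).
* **Multiplicity**: none — features are filtered at raw P < .05,
  faithful to the analysis reproduced; interpret counts accordingly.
* **Chi-square** (Pearson, no Yates correction, df = k−1) and
  **Spearman** (tie-handled ranks) cover the categorical and
  correlation analyses.

## Diagnostic models

Forward stepwise logistic regression per task over the applicable
features: at each step every unselected candidate is fit and the
smallest likelihood-ratio p enters if < .05; entered variables with LR
removal p > .10 are then dropped; ties break by candidate order;
entry/removal cycles terminate deterministically.  ML fits use Newton
(IRLS) with tol 1e-10; (quasi-)separation falls back to BFGS and is
flagged — with strong synthetic contrasts the figure tasks separate
perfectly in-sample, and their coefficient tables carry infinite Wald
bounds by design rather than silent failure.  OR CIs are Wald
(exp(β ± 1.96 SE)); AUC is the trapezoidal ROC area (= the scaled
concordant-pair count) with a DeLong CI; classification uses a 0.5
probability threshold (interpretable accuracy; a Youden-style threshold
can be passed instead).  Everything is evaluated in-sample, no
cross-validation — matching the reproduced analysis and clearly
optimistic.

A known property worth restating: with per-candidate entry at p < .05
over k candidates, a pure-noise feature enters in ≈ 1 − 0.95^k of null
datasets, and a feature only enters when its nominal effect is
significant — at 50 subjects per group that corresponds to a
single-feature in-sample AUC of roughly 0.61 or more.  Null-cohort
in-sample AUCs are therefore *not* confined near 0.5 whenever selection
is non-empty; this is inherent to unpenalized stepwise selection with
in-sample evaluation, and the calibration experiment reports it
honestly rather than masking it.

## Rendering

Stroke-order pseudocolor: strokes drawn as polylines, colored by index
along viridis (sequential, monotone lightness, so order reads
naturally), later strokes on top.  Colors are deterministic in
(index, stroke count); 8-bit quantization collisions between adjacent
colormap samples are resolved by a minimal blue-channel nudge so any
n ≤ 256 strokes get distinct colors.  Output PNGs are byte-reproducible.

## Problem sizes used in the test suite

Oracle-equivalence checks use 200 random small instances per estimator;
type-I calibration uses 2000 replicate null features at 50 per group;
null-model calibration uses 100 null cohorts of 50+50 subjects;
recovery uses 20 replicate cohorts of 100+100 under the strong preset;
the timeline-partition identity is checked exactly on 1000 generated
sessions.  The full suite runs in roughly two minutes on one CPU.

## Known limitations

* Component labels must be supplied; there is no recognizer.
* The Schulman tier boundaries are this package's concretization of a
  rubric whose fine print is cited but not reprinted in our source.
* In-sample stepwise performance is optimistic (see above); no
  regularized or cross-validated alternative is provided.
* The generator's independence assumptions make multi-task synthetic
  AUCs more homogeneous than real cohorts would be.
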