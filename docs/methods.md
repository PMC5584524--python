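# Methods

## The elicitation model

An expert's belief about a bounded quantity X ∈ [a, b] is elicited with the
hybrid (four-complementary-intervals) method. The expert states three
summaries — a lower plausible limit L, a mode M and an upper plausible
limit H with a ≤ L < M < H ≤ b — and then allocates 100 % of probability to
the four intervals obtained by halving [L, M] and [M, H]. The encoded
belief is the piecewise-constant density with edges
[L, (L+M)/2, M, (M+H)/2, H] and bin densities pᵢ/wᵢ. Two modelling
commitments follow:

- **Hard support.** The density is exactly zero outside [L, H]: the stated
  plausible limits are treated as support bounds, which is what the
  histogram shown back to the expert depicts. A consequence is that the
  encoded distribution carries no tail beyond the expert's limits; the
  smooth beta fit (below) reintroduces one.
- **Normalized internal scale.** All computation happens on [0, 1]. A
  quantity displayed as a count out of N or as a percentage is mapped at
  the I/O boundary, so fitting and pooling have a single code path, and
  encoding is scale-equivariant by construction (tested property-wise).

Moments of the encoded histogram are exact: each bin of midpoint c and
width w contributes p·c to the mean and p·(c² + w²/12) to the second
moment.

The reported mode of an elicited distribution is the expert's stated M
(the histogram carries it), not a bin midpoint; only for histograms that do
not originate from hybrid summaries does the package fall back to the
midpoint of the highest-density bin, ties broken toward the lowest bin for
determinism.

## Consistency rules

Four checks run on every candidate answer; two block, two prompt:

| rule | severity | fires when |
|---|---|---|
| TOTAL_PROB | error | the four probabilities do not sum to 100 % (or any is negative) |
| ORDERING | error | not (scale_min ≤ L < M < H ≤ scale_max) |
| NON_UNIFORM | warning | density does not strictly rise toward M on either side (d₂ ≤ d₁ and d₃ ≤ d₄, tolerance 1e-9) |
| NOT_FULL_RANGE | warning | L and H together span the entire scale |

Uniformity is judged on *density*, not raw probability, because the four
bins have unequal widths: equal probabilities over unequal bins are not a
uniform belief — but they do imply a plateau toward the mode, so the
reminder that M should carry more probability still fires. Warnings
require an explicit confirmation from the expert and never invalidate an
answer by themselves; errors cannot be confirmed away. Skewed but
self-consistent answers are deliberately never flagged.

Probabilities are accepted from users as percentages. Whole-number input
must sum to exactly 100; decimal input is tolerated to 1e-6 (and
renormalised), since decimals only arise from computed, not typed, answers.

## Beta fitting

For a proportion-type quantity the conventional smooth prior is a beta
distribution on the full [0, 1] scale. Two fitters:

- **Method of moments** (closed form): α = m(m(1−m)/v − 1),
  β = (1−m)(m(1−m)/v − 1) from the histogram's exact mean m and variance v.
  Defined only for 0 < v < m(1−m); a degenerate or over-dispersed histogram
  raises rather than returning a pseudo-fit.
- **Least squares on bin masses** (default): minimise
  Σᵢ (F(eᵢ₊₁; α, β) − F(eᵢ; α, β) − pᵢ)² over the four bins, started from
  the moment fit (Beta(2, 2) when moments are infeasible), parameters kept
  positive by optimising on the log scale (Levenberg–Marquardt,
  objective tolerance 1e-10). The minimised value is reported as `gof`;
  because the optimizer starts at the moment fit, the least-squares
  discrepancy never exceeds the moment fit's (enforced, and tested).

The target is bin masses, not density heights, so the objective does not
depend on bin-width bookkeeping — the probabilities are what the expert
actually stated. The beta is *not* truncated to [L, H]; mass outside the
stated limits is permitted and surfaces in `gof`. This matches how beta
priors are used downstream and means `gof = 0` is attainable only when the
histogram's own support already captures essentially all beta mass. The
low-level `fit_beta_bins(edges, probs)` accepts raw (unnormalised) masses
over arbitrary edges; recovery tests use it to refit exact beta bin masses
to machine precision.

Only the beta family is implemented; the front end takes a family tag so
other bounded families can be added without changing call sites.

## Pooling

Panels are combined by the linear opinion pool: the weighted arithmetic
average of member densities, equal weights by default (a weights vector is
accepted for future calibration-based pooling but nothing in this package
computes one). Members have different bin edges, so for export and
plotting the pooled density is tabulated on a common uniform 513-point
grid over the normalized scale and renormalised by the trapezoid rule.

Pooled moments, however, are computed from the exact mixture identities
over member histogram moments — mean = Σ wᵢ mᵢ and
E[X²] = Σ wᵢ (vᵢ + mᵢ²) — rather than from the grid: trapezoid quadrature
of a discontinuous density has O(grid-step) error (~1e-3 at 513 points),
whereas the mixture identities are exact for piecewise-uniform members.
The grid is a rendering; the moments are the estimate. The pooled "sd"
reported in panel summaries is therefore independent of both the grid
resolution and the fitting module; the beta smoothing of a pooled
distribution (for use as an HTA prior) is produced by handing the pooled
moments to the fitter.

Members are accumulated in a canonical content-sorted order so that
pooling and panel summaries are bit-for-bit invariant to the order in
which experts happen to be listed.

Panel summaries report, on the normalized scale: the number of experts,
the mean/min/max of stated modes, the mean plausible range H−L, and the
pooled mean and sd. Completion rates are 100 × completed/randomised per
arm. Arm contrasts tabulate A−B differences of these and flag the arm
whose pooled distribution is tighter (smaller sd, i.e. higher apparent
certainty).

## Session workflow

A session has three sections — introduction (with an electronic consent
gate: refusal aborts with nothing recorded), training (primer text, one or
more attempts at a practice question, a bias reminder covering anchoring,
availability and overconfidence) and the questionnaire (demographics, a
seed question with a knowable answer for later judgement assessment, the
main question, and a 0–100 visual-analogue certainty rating; 0–100 is the
conventional VAS range). The main question loops until an answer passes
validation with all warnings explicitly confirmed *and* the expert accepts
the rendered histogram (face validity); every attempt, its validation
report and its confirmation flag are recorded in order, and the final
answer always equals the last confirmed attempt (an enforced record
invariant).

The interactive channel and the clock are injected, so a recorded
transcript replays to a byte-identical session record — the basis of the
golden-file tests. Timings are recorded for the training and questionnaire
sections; the total is defined as their sum (within 1 s in the record
invariant, to absorb serialised rounding). The distance vs. face-to-face
mode is a recorded label only; the software behaves identically in both,
since the mode is an experimental condition, not a software branch.
Training runs once per session; the configuration would be the place to
allow revisiting it, and the default does not. The seed question is
captured as a single value by default (it asks for one percentage), with a
config switch to elicit it as a full hybrid answer.

Records persist as JSON (schema published in `schemas/`), with an
`anonymize` option that strips free-text demographic answers — the fields
that could identify an expert — while leaving structure intact. Loading
validates the document and reports the JSON path of the first missing
field. Whether experts enter L/M/H as counts on the display scale or as
percentages is a property of the quantity definition; the panel CSV reader
additionally accepts pre-normalized values via `values="normalized"`.

## Synthetic experts

The simulator generates panels whose ground truth is known, emulating a
small primary-care panel asked for the proportion of patients with
alcohol-related hepatic steatosis who would cut drinking on brief GP
advice:

- Panel-level truth: Beta(2.4, 3.9) by default (mean ≈ 0.38, sd ≈ 0.18 —
  a moderately uncertain belief centred near 0.4, the scale typical of
  such panels). Default arm sizes are 8 (facilitated) and 10 randomised to
  distance elicitation with a 0.7 completion probability.
- Between-expert variation: each expert's true beta is obtained by
  jittering the truth's *mean* (Gaussian, default sd 0.10 on [0, 1],
  truncated by redrawing up to 100 times) while holding the variance fixed
  via a moment re-solve. Jittering the mean alone is simpler than
  perturbing both parameters and is sufficient for recovery testing.
- Answers: L and H are the expert's true 1 %/99 % quantiles (tail_prob is
  exposed because "plausible limit" has no canonical probabilistic
  definition, so sensitivity to the choice is testable); M is the true
  mode when it exists (α, β > 1), otherwise the mean; the four interval
  probabilities are the truth's exact bin masses renormalized to [L, H].
- Human granularity: probabilities are rounded to whole percentages with
  largest-remainder repair (ties to the lowest bin), so they always sum to
  exactly 100 — the granularity people type into a questionnaire.

Every simulated answer passes the consistency rules with no errors, and
every expert is deterministic given (seed, index).

What the simulator does **not** model: cognitive biases (anchoring,
overconfidence, availability), facilitation effects, question-order
effects, or non-beta-shaped beliefs. Passing recovery tests therefore
shows the pipeline is faithful to coherent beliefs of beta shape at human
answer granularity — not that real expert panels are free of bias, and not
that two elicitation modes would agree in the field. Because L and H sit
at the 1 % tails, 2 % of each true belief's mass is folded back into
[L, H]; refitting a pooled noiseless panel therefore recovers the true
(α, β) with a small, bounded truncation bias — within 15 % in the tests,
with the tolerance chosen for that bias, not for estimator noise.

## Numerical choices

- Probability normalization tolerance 1e-9 internally (exact for typed
  integer percentages).
- Uniformity tie tolerance 1e-9 on densities.
- Least-squares convergence: ftol/gtol 1e-10 on the objective, log-scale
  parameters, max 5000 evaluations; on failure the moment fit is attached
  to the raised error as a fallback suggestion.
- Pooled grid: 513 uniform points (2⁹ + 1), renormalised by trapezoid;
  moments never come from the grid (see Pooling).
- Feedback rendering: four fixed-width bars proportional to density, with
  a one-character floor so near-zero bins remain visible; byte-identical
  output for identical histograms.
- Degenerate inputs raise typed errors naming the violated constraint
  (ordering, normalization, infeasible moments, undefined rates).

## Design shape

The package exposes both a functional layer (one module per pipeline
stage) and a model/results surface: `ElicitationPanel` is constructed from
data (`from_dataframe` mirrors the panel CSV), and `fit()` returns a
`PanelResults` with per-expert fits, the pooled distribution, summaries, a
`summary()` table and a `plot()`. The session and simulator modules hang
off the same domain types, so a simulated panel, a CSV panel and a panel
assembled from session records are interchangeable inputs.

## Problem sizes

Property suites run at 100–1,000 random draws per invariant (encoding
quadrature at 1,000, fitting recovery at 100, pooling identities at 200
panels, simulator monotonicity at 50 seeded replicates), sizes at which
every suite completes in seconds while exercising the full parameter
ranges. The acceptance script simulates the default two-arm study (8 + 10
experts) end to end.

## Known limitations

- Only the hybrid encoding method is implemented (no fixed-interval
  histogram technique, no bisection); the module layout leaves room for
  additions but none are stubbed.
- Only the beta family is fitted; unbounded scalar quantities are out of
  scope.
- Pooling is linear with externally supplied weights; no
  performance-weighted (seed-question-calibrated) or behavioural
  (consensus/Delphi) aggregation.
- The grid tabulation of a pooled density is a plotting aid; consumers
  needing tail probabilities should use the exact mixture (`pdf`) or the
  fitted beta, not the grid.
- Session delivery (email dispatch, reminders, web front-end) is out of
  scope; the workflow contract, not a questionnaire UI, is the deliverable.
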