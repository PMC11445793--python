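# Methods

This note documents the model implemented by `dreamchart`, the choices made
where the procedure admits more than one reasonable reading, and what the
synthetic test bed does and does not establish about real dream reports.

## Word-level valence scoring

A dream report is assumed to be a pre-cleaned *dream description*:
separating the dream experience from waking commentary is a human editing
step outside the package's scope. Tokenization lowercases the text and
keeps maximal runs of letters and apostrophes (so `don't` survives intact);
digits and standalone punctuation are dropped. The token count is the
report's word count.

Each token is looked up in a sentiment lexicon (VADER file format:
tab-separated token, mean valence, sd) and its mean valence divided by the
lexicon's scale maximum (4.0 for VADER), giving values in [−1, +1]; absent
tokens are neutral (0). Two scoring modes exist because word-level exports
of sentiment tools differ in whether context modifiers are baked in:

* `lexicon_only` (default) — pure per-token lookup. Deterministic and
  context-free, which makes every downstream property exactly testable.
* `vader_heuristics` — additionally applies VADER's published word-level
  context rules within a trailing three-token window: a preceding negation
  multiplies the valence by −0.74, preceding boosters/dampeners add ±0.293
  damped by distance (×1, ×0.95, ×0.9). Sentence-level heuristics
  (capitalization, punctuation emphasis) are deliberately not applied:
  they have no word-level meaning.

The scoring backend is a pluggable contract, so neither mode leaks into
the rest of the pipeline.

The bundled `demo_lexicon_synthetic.tsv` is a hand-written ~190-word
demonstration lexicon (synthetic, not derived from any distributed lexicon
file); real analyses should supply a full lexicon via `--lexicon`.

## Sliding-window standardization

Windows contain `window_length` = 30 tokens and overlap by 29 (stride 1).
Window k's valence sum is divided by the report's window count
W = max(1, L − 29). Dividing by the *count of windows* — not by the window
length — is the literal reading of the procedure's "divided by the number
of windows in the respective dream reports", and it is the only reading
that actually standardizes for varying word counts: dividing by 30 would
be a plain moving average, identical for long and short reports. Because
the question is genuinely ambiguous, the divisor is configurable
(`normalizer: n_windows | window_length | none`); all defaults and all
tests use `n_windows`. Reports shorter than 30 tokens collapse to a single
whole-report window (W = 1) — the least surprising degenerate rule, chosen
because the emulated corpus has a minimum of 46 words and the short case
is otherwise unspecified.

The chart's x-axis is 1…W with unit spacing; areas are therefore in
chart-step × valence units. The units are arbitrary and cancel in every
correlation.

## Peak/trough demarcation

A peak begins at the first chart value above zero and ends at the first
zero after the positive run; troughs symmetrically. Two extensions make
this total on floating-point charts:

* **Interpolated crossings.** Windowed sums rarely hit zero exactly. When
  consecutive values flip sign, a synthetic boundary point is inserted at
  the linear interpolant's zero crossing. This choice preserves exact area
  additivity: the signed segment areas always sum to the trapezoid
  integral of the whole chart.
* **Chart edges.** A chart that starts or ends mid-emotion still counts
  that excursion as a peak/trough; the edge acts as the boundary.

Values with |y| ≤ eps (default 1e−12) are treated as exact zeros so that
sign tests are robust to accumulated rounding in the window sums. A
single positive (negative) value between zeros is a legitimate
single-point peak (trough); with its two zero boundaries it has a
well-defined triangular area.

## Intensities

Each segment's approximated AUC is the trapezoid sum over its points,
boundary zeros included. PEI = Σ peak aAUC (0 with no peaks),
NEI = Σ trough aAUC (≤ 0; 0 with no troughs), OEI = PEI + |NEI|. The
trapezoid rule is used deliberately as the simple first-order method;
higher-order quadrature adds nothing on a piecewise-linear chart.

## Emotion gradient

The macro-level direction of emotional change is summarized by a
least-squares polynomial trendline. Two open choices were fixed as
follows:

* **Degree.** Default 2 — the lowest degree that can capture the
  rise-and-fall shape typical of fluctuating charts — configurable
  per run.
* **Scalar gradient.** A polynomial has no single slope, so the gradient
  is defined as the mean slope over the chart's domain,
  (p(x_W) − p(x₁))/(x_W − x₁). This is the unique definition that reduces
  to the line's slope in the degree-1 case, is antisymmetric under chart
  negation, and is invariant under adding a constant. The degree-1 slope
  is also reported (`linear_slope`) for comparison.

r² = 1 − SSres/SStot, defined as 1 when the chart is constant (SStot = 0,
detected up to float representation wobble). Eligibility is reported, not
enforced: a fit is flagged ineligible when W < degree + 1 or r² falls
below a configurable floor (default 0, i.e. no exclusion) — which charts
to exclude is left to the analyst rather than guessed.

## Correlation protocol

Indicators × external variables are correlated pairwise with Spearman's ρ
when the pair is tie-free, falling back to Pearson's r when ties are
present — ties distort rank correlations badly at small n. "Ties present"
is read as *any duplicated value in either vector* (the most literal
reading; `tie_policy="both"` requires duplicates in both). Missing values
are deleted listwise per pair; at least 3 complete pairs are required.
Spearman p-values use the standard t-approximation. P-values are
uncorrected by default, matching the protocol's explicit choice for
exploratory pilot use; Holm and Benjamini–Hochberg adjustments are
available but off. Significant pairs (p < α, default 0.05) form a signed
edge list suitable for network-style visualization.

The helper `overnight_change(evening, morning)` computes the overnight
percentage change 100·(morning − evening)/evening used for affect
composites; a zero evening score yields a missing value.

## Synthetic test bed

`dreamchart.synthetic` generates reports from explicit scripts: ordered
runs of positive/negative/neutral tokens with amplitudes in multiples of
0.05. Tokens come from a constructed toy lexicon (`posaampj`,
`negbampd`, …) whose valences are assigned, never learned, so ground truth
is exact. Cohort defaults emulate a small overnight-laboratory corpus:
14 reports with word counts uniform on 46–202, emotional runs of 5–20
tokens at amplitudes 0.30–1.00 alternating with neutral runs of 8–35
tokens. External variables are fabricated as linear functions of the true
indicators plus Gaussian noise, giving known expected correlation signs;
a model with zero slope and zero noise is rejected as degenerate.

Two independent brute-force oracles back the tests: an explicit
double-loop sliding window, and a run-length sign scanner plus a
clip-and-integrate area computation on a crossing-augmented grid. The
production code never calls them.

What passing tests show — and what they do not: the synthetic generator
validates the *pipeline arithmetic* (windowing, segmentation, areas,
trend, correlation dispatch) exactly, but its token streams are not
language. Real reports have polysemy, negation scope, lexicon coverage
gaps, and rater-relevant context that no planted-structure test reaches;
external validation against human ratings remains a study-level task.

## Numerical choices and limitations

* Zero tolerance eps = 1e−12 on chart values; area identities are asserted
  to 1e−9, polynomial recovery to 1e−8.
* Sums of peak areas are clipped at 0 from below (symmetrically for
  troughs) to absorb one-ULP sign noise.
* Perfect monotone correlations produce degenerate t-statistics; p-values
  are floored at the smallest positive double so they remain in (0, 1].
* The acceptance script runs one 14-report cohort (the emulated corpus
  size); all its randomness derives from `--seed`.
* Known limitations: no sentence-level compound scoring, no automatic
  dream-commentary stripping, no multilingual lexicons, no
  prominence-based peak detection, and no automatic trend-degree
  selection.
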