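# Methods

## Model

`screeneval` evaluates n sites against m banded indicators. Three weighting
routes produce composite rankings from the awarded-points matrix `X` (n × m):

1. **Subjective.** Each indicator carries an expert-assigned maximum score
   `S_j`; its weight is `W_j^s = S_j / Σ_k S_k`. For the default
   eleven-indicator scheme the scores are (35, 12, 6, 6, 3, 3, 3, 8, 12, 12, 12),
   total 112.
2. **Objective (entropy weight method).** Columns are min–max standardised by
   attribute — positive `(X − min)/(max − min)`, negative
   `(max − X)/(max − min)`, moderate `1 − |X − mean| / max|X − mean|` — then
   shifted by +0.001 so logarithms stay finite. Column proportions
   `P_ij = Y'_ij / Σ_i Y'_ij` give entropies
   `E_j = −(1/ln n) Σ_i P_ij ln P_ij` and weights
   `W_j^o = (1 − E_j) / Σ_k (1 − E_k)`. A column that varies little across
   sites has entropy near 1 and weight near 0: the EWM rewards
   discriminating indicators and is the model's answer to ceiling effects in
   compliance indicators.
3. **Combined (multiplicative synthesis with normalisation).**
   `W_j^c = Π_l W_jl / Σ_k Π_l W_kl` over the L routes being combined
   (here L = 2, subjective × objective, treated as equally important). The
   product form means an indicator must matter under *every* route to retain
   weight, which widens the spread between informative and uninformative
   indicators before renormalisation.

Scores follow as `TWS_i = Σ_j W_j X_ij`; hospitals are ranked by descending
score with competition ranking (ties share the smallest rank; tied rows are
listed lexicographically so output is deterministic). The programme's
"original methodology" is the unit-weight special case (plain point sums); it
is represented as a weight vector of ones with `custom` provenance, exempt
from the sum-to-1 invariant that all subjective/objective/combined/equal
vectors satisfy (tolerance 1e−9).

## Methodology agreement

* **Head–tail consistency** between two rankings over the same n sites:
  `k = floor(0.2 n)`; `x` and `y` count the shared members of the two top-k
  and bottom-k *sets* (order inside the head or tail is ignored);
  `S = (x + y) / (0.4 n)`. Because k is floored while the denominator is
  not, the attainable maximum is `2k / (0.4 n)` — 0.9375 at n = 16, reached
  exactly when both extreme sets coincide.
* **Discrimination degree** of one score profile: scores are sorted
  descending, standardised affinely onto [0, n] via
  `V_i = n (1 − |V'_i − V'_1| / (V'_1 − V'_n))` (best → n, worst → 0), and
  pooled as `(Σ_{i<n} (V_{i+1} − V_i)² + 1) / (2n² − 2n − 1)`. The printed
  form of this formula is typographically ambiguous about a radical; both
  algebraic readings are implemented (`reading="no_radical"`, the default,
  and `"radical"` = the square root of the same quotient) and neither
  published pairwise value is treated as a regression target. D is invariant
  to positive affine transformations of the raw scores, and pairs of
  methodologies are compared by `|D_a − D_b|`, which makes the pairwise
  deltas mutually consistent as differences of per-method scalars (the
  additivity the published pair values themselves exhibit). An
  order-dependent pairwise definition would not guarantee that, which is why
  the per-method-scalar design was chosen.

## Band scoring conventions

Threshold ladders are left-closed/right-open except where a criterion states
otherwise (e.g. "100 % ≤ P", or the inclusive upper edge of the 20–26 %
detection band). Overlapping ladders are resolved by first match in listed
order, except that exact-equality bands (e.g. "P = 0 %") take precedence over
interval bands — the only reading under which a zero completion rate scores
0 rather than the 15-point floor.

Several indicators are scored against external reference standards (national
or provincial target values). Their printed criteria step in "×10 %"
increments whose literal reading produces empty intervals, so they are
implemented as 10 %-step *relative* deviations from the standard: positive
indicators measure the relative shortfall below it (at or above the standard
= top band), moderate indicators the relative absolute deviation on either
side, negative indicators the relative excess above it. The standards
themselves are user configuration (`reference_standard`); scoring a relative
band without one is a configuration error, and no attempt is made to estimate
standards from data. The Age Deviation Degree is accepted as one
pre-aggregated rate per hospital; how a user aggregates its per-age-group
deviations (mean or maximum of absolute deviations) is left to them, since
either feeds the same ladder.

## Numerical choices

* Weights are computed at full precision; published tables print 4 decimals,
  so regression comparisons use absolute tolerance 5e−5 (half a printing
  ULP). Recombining *printed* (already-rounded) vectors can move a
  renormalised product by slightly more than that — two entries of the
  published combined vector differ from the rounded-input recomputation by
  ≈5.3e−5 — which the regression suite reports rather than hides.
* Constant (zero-dispersion) columns: normalisation maps them to the
  midpoint 0.5 with a warning; their entropy weight is 0 without
  special-casing. If *every* column is constant the EWM is degenerate; the
  library raises, and the pipeline driver degrades to equal objective
  weights with a logged warning instead of crashing.
* `0·ln 0` is defined as 0 for custom unshifted inputs; it cannot occur
  after the +0.001 shift.
* Percentage weight changes are signed, `(W_comp − W_base)/W_base × 100`; a
  zero baseline weight is flagged undefined rather than divided through.
* Ranking ties cannot occur in the published panel; the competition +
  lexicographic rule exists for reproducibility on synthetic data.

## Synthetic data

The generator emulates a CNSSS-style panel: n sites (default 16, the
published panel size) × the 11-indicator default scheme, each cell drawn on
the indicator's band-point lattice (real matrices hold awarded points, not
rates). Per-indicator dispersion is configurable — `none` (constant column,
the degenerate ceiling case), `low` (90 % of mass on the top two bands,
emulating the ceiling effect of process-oriented compliance indicators),
`high` (uniform over all bands, the default) — plus a `ceiling_fraction` that
pins a share of sites at maximum points everywhere. Each column has its own
seeded substream, so changing one indicator's dispersion leaves every other
column bit-identical; this makes dispersion-monotonicity properties testable
in isolation. The generator matches real panels in shape, ranges and
dispersion structure only: it does not model correlation between indicators
(real detection rates co-vary), nor any site-level quality factor, so passing
tests demonstrate the pipeline's algebra and invariants, not calibration to
real programme data.

## Known limitations

* The EWM assumes indicator independence; correlated indicators (the three
  risk-factor detection rates, for instance) can jointly over-claim weight.
* Entropy weights are sample-dependent: with n = 16 sites a single outlier
  can move a column's weight materially. No uncertainty quantification on
  ranks (e.g. bootstrap rank stability) is provided.
* The two readings of the discrimination degree differ numerically (one is
  the square root of the other); cross-study comparisons must state the
  reading used.
* Legacy XLS input is not parsed directly; re-save as XLSX or CSV.
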