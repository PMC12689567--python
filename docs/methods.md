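# Methods

## The model

A policy document is coded against a two-level indicator system: first-level
dimensions (default X1..X9), each owning T binary second-level criteria
(default T = 3, 27 criteria in all).  Criterion X_ij is 1 iff the policy
text explicitly addresses it.  The dimension score is the criterion mean
(Σ_j X_ij)/T_i, the PMC index is the sum of the dimension scores, and the
index is classified on a six-band grade scale over [0, 9].  All criteria
carry uniform weight; the schema format reserves a `weight` field but the
default pipeline ignores it, and no rescaling of the 0–9 range is applied.

Grade bands are lower-inclusive / upper-exclusive with a closed top band.
The published band table prints overlapping endpoints ([0,4], [4,5], ...);
the half-open convention is the only one consistent with the published
scorecard, where a policy at exactly 8.00 is graded Perfect and one at
exactly 5.00 is graded Good.

### Exact arithmetic

Dimension scores are held as integer numerators over T (a `Fraction`),
never as rounded floats.  Two-decimal half-up rounding is a display
operation only.  This is what makes sums agree with published tables: a
policy scoring 22/3 displays as 7.33, whereas summing the pre-rounded cell
displays (0.33, 0.67, ...) would give 7.34.  Score tables printed at two
decimals are parsed back to exact thirds (0.33 → 1/3, 0.67 → 2/3) with a
0.005 tolerance; anything else is rejected rather than silently rounded.

Ranking sorts by exact PMC descending; ties keep input order (the published
table ranks two 8.00 policies without stating a rule, so the stable
input-order tie-break is documented rather than guessed).

## The packaged dataset and marginal reconstruction

The bundled fixture transcribes a published evaluation of 22 MQIMPs
(medical-quality intelligent-management policies).  The full 22×27 binary
matrix was never published; the fixture stores the two marginals every
PMC-level quantity depends on: the per-policy first-level scores (as exact
thirds) and the per-criterion ones-counts recovered from printed means by
nearest-integer inversion (`counts_from_means`, rejecting means farther
than 0.005 from any count/n).  Load-time self-checks assert the marginals
are mutually consistent (per-dimension totals agree; grand total 415;
415/66 displays as 6.29).

One dimension's printed criterion statistics are internally impossible for
binary data (means above 1, SDs above 3, a p-value above 1); this is
treated as an erratum.  The fixture keeps the externally attested count for
that dimension's third criterion (1 of 22), imputes the remaining split as
(20, 18) — constrained to sum to 38 by the dimension's score column, with
any split where both counts are ≥ 16 feasible — flags both rows `imputed`,
and excludes the dimension from chi-square reproduction.

`reconstruct_matrix` produces a concrete feasible witness from the
marginals, per dimension, by the classic greedy for 0/1 matrices with given
row and column sums: policies in input order, each policy's ones assigned
to the criteria with the largest remaining column demand, ties by schema
order.  The greedy succeeds whenever the marginals are feasible; marginal
exactness is asserted on every call.  Any witness is equivalent for
PMC-level quantities, which depend on the marginals only.

## Sensitivity scenarios

Stability is probed one indicator at a time under three scenarios:
baseline (unchanged), partial (+30% relative coverage), and full (coverage
to 100%).  Because the corpus-average PMC equals (total ones)/(3n), each
scenario is a closed form: full optimisation adds exactly (n − count) ones,
i.e. Δ = (n − count)/(3n).  The verdict flag compares the grade bands of
the displayed two-decimal averages.

"+30% coverage" is interpreted as a relative increase of the ones-count
(count × 1.3), generally fractional.  The default `expected_value` mode
keeps the fractional count for analytic averaging — the interpretation that
reproduces the published partial value for a count-8 indicator (8 × 1.3 =
10.4 ones → average 6.32).  Whole-policy modes (`round_down`, `round_up`,
deterministic by policy order; `stochastic`, seeded) are provided because a
fractional count has no realisation in an actual coding matrix.  The
published partial value for the count-1 indicator (6.30) is not producible
by any single rule that also yields 6.32 for the count-8 indicators; the
partial column is therefore documented as rule-dependent and only the
expected-value case is asserted.

Target selection takes the k lowest-average dimensions and, within each,
every criterion tied at the dimension's minimum coverage; all tie-breaks
are deterministic by schema order.

## Within-dimension statistics

Each dimension's criteria form a 3×2 contingency table (ones/zeros counts
over n policies).  A Pearson chi-square homogeneity test without continuity
correction — the construction verified to reproduce all eight well-formed
published statistics exactly — asks whether criteria are covered at
different rates.  df = 2, so the p-value has the closed form exp(−χ²/2),
asserted against scipy's distribution function to 1e-10.  A table with an
all-zero column (all criteria saturated or all empty) has no variation to
test: the statistic is defined as 0 with p = 1 and a warning.  Expected
counts below 5 warn but do not block, since small evaluation corpora
routinely violate the rule of thumb.  Per-criterion summaries report the
coverage mean and the n−1 sample SD of a binary column,
sqrt(n·p(1−p)/(n−1)).

## Surface and radar

The nine dimension scores are arranged row-major into a 3×3 surface matrix
((X1,X2,X3),(X4,X5,X6),(X7,X8,X9)).  Smooth rendering uses tensor-product
PCHIP interpolation over the 3×3 control grid: it passes through the nine
control values exactly and, being shape-preserving along each axis, never
leaves [min, max] of the grid — the two guarantees that matter, since only
the qualitative convex/concave reading is meaningful.  (Quadratic or cubic
splines can overshoot on a 3-point grid, which is why they were not used.)
A `tile` mode (nearest-neighbour) is exposed for readers who prefer the
unsmoothed matrix.  At resolution 3 both modes return the control grid.
The radar export flags dimensions below a configurable threshold
(default 0.6).

## Text mining

The front end assists, and does not replace, the human coding step: ranked
term frequencies and a document-level co-occurrence network summarise a
corpus before criteria are coded.  Tokenization is pluggable; the default
segments on Unicode word boundaries, protects multi-word lexicon terms
(matched longest-first), and drops digit-containing tokens wholesale
(partial stripping would invent tokens that never occurred).  Stop-word
filtering takes the union of any number of plain-text lists, case-folded by
default.  Frequency ties rank lexicographically so output is deterministic.
Co-occurrence weight defaults to document-level counting (the window
semantics of legacy content-mining tools are undocumented); a sliding
token-window mode is exposed.  Raw-token and per-document frequency modes
are both available since published frequency tables rarely state which was
used.

## Synthetic data

The coding generator has two modes because tests need both exactness and
realism: `quota` places exactly round(p_j·n) ones per column via a seeded
permutation (coverage recovered exactly; end-to-end, a quota matrix at the
fixture's coverage reproduces the fixture's dimension averages exactly),
and `stochastic` draws independent Bernoulli(p_j) cells (coverage recovered
within binomial confidence intervals; asserted over 100 seeds at n = 500).
The corpus generator realises planted term frequencies and document
co-occurrences exactly by construction — each planted pair occupies
dedicated two-term documents, residual frequency mass goes into single-term
documents — and returns the guaranteed ground truth as a ledger.  A single
integer seed governs all randomness.

What the generators do **not** emulate: correlation between criteria within
a policy (cells are independent given the coverage vector), any semantic
structure in corpora (documents are frequency scaffolds, not language), and
coder disagreement or drift in the human coding step.  Passing tests
therefore demonstrate correctness of the scoring, statistics and recovery
machinery — not that a real corpus would be coded the same way twice.

## Problem sizes

The packaged evaluation is 22 policies × 27 criteria; every reproduction
runs in well under a second.  Property tests use exhaustive enumeration of
3×2 tables up to n = 6, 100-seed coverage sweeps at n = 500, and a
2000-policy stochastic matrix — sizes chosen so the full suite completes in
seconds while the binomial assertions have useful power.

## Known limitations

- The X8 criterion split in the packaged dataset is imputed, not attested;
  chi-square reproduction excludes that dimension.
- The partial-optimisation scenario is interpretation-dependent (see
  above); only the expected-value rule is asserted against the published
  value.
- Uniform weights are assumed throughout; the reserved `weight` field is
  not consumed by the pipeline.
- The default tokenizer is language-agnostic; Chinese corpora need a
  registered segmentation plugin (e.g. jieba) and a domain lexicon to
  reproduce published keyword tables.
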