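# Methods

## Model

A record is a vector of categorical answers over a fixed questionnaire
(177 questions for men, 194 for women). Answer levels fuse severity
and frequency into one weight: A (severe/always) = 1,
B (a little severe/sometimes) = 0.618, C (not severe/seldom) = 0.382,
D (none/never) = 0. Quantification is the unnormalised bilinear form

    value(e) = Σ_q answer_weight(a_q) · W[q, e],

i.e. the answer-weight vector composed with the mapping matrix. No
normalisation is applied at this stage: value orders downstream are
ratios to the per-group maximum, so any global scaling of *W* or of
the answer weights cancels. The model assumes answers contribute
independently and additively; no interaction between symptoms is
modelled except what the element-basis condensation rule captures
through column maxima.

Elements 7 (deficiency) and 8 (excess) are composite eight-principle
judgements without direct question mappings. They receive value 0,
their matrix columns are empty, and they are excluded from value-order
assignment and matching; no rule for deriving them is implemented.
This leaves CT = 45 evaluable elements with per-group counts
6 / 7 / 16 / 16.

## Severity filtering

The *major health state* restricts the sum to severe answers. "Severe"
defaults to level A alone (its label is the only one reading
severe/always); level B may be added via
`SeverityFilter(severe_levels={"A", "B"})`. A record with no severe
answer carries no major-state information: it is flagged by
`batch_quantify` and dropped from severe-mode evaluation reports
rather than counted as a vacuous perfect match.

## Condensation rules

The two quantizers are total, piecewise-constant, monotone
non-decreasing step functions given by explicit interval tables with
literal bracket semantics:

* value basis, domain (0, 100) — normal: [40, 100)→10, [25, 40)→6,
  [10, 25)→4, (0, 10]→2; fuzzy adds secondary levels: [45, 100)→10,
  [40, 45)→8, [35, 40)→8, [30, 35)→6, [25, 30)→5, [20, 25)→5,
  [12, 20)→4, (10, 12)→3, (8, 10]→3, (0, 8]→2.
* ratio basis, domain (0, 1] — normal: [0.6, 1]→10, [0.4, 0.6)→6,
  [0.2, 0.4)→4, (0, 0.2)→2; fuzzy: [0.65, 1]→10, [0.6, 0.65)→8,
  [0.55, 0.6)→8, [0.45, 0.55)→6, [0.4, 0.45)→5, [0.35, 0.4)→5,
  [0.25, 0.35)→4, (0.2, 0.25)→3, (0.15, 0.2]→3, (0, 0.15]→2.

Two boundary quirks follow from the printed brackets and are kept as
stated rather than smoothed: a value of exactly 10 falls in
(8, 10] → 3 (not in (10, 12)), and a ratio of exactly 0.2 falls in
(0.15, 0.2] → 3. The "closeness to a boundary" idea behind the fuzzy
secondary weights (8, 5, 3) is realised entirely by these explicit
secondary intervals — no additional closeness heuristic exists.
Values at or above 100 (or ratios above 1) are domain errors, not
clamped. Element-basis maxima are taken per element column over the
whole matrix; an all-zero column has no maximum and is skipped with a
warning (silently for columns 7 and 8, empty by design).

## Value orders and matched degree

Per group, each element's ratio to the group maximum maps to an order:
[0.95, 1]→8, [0.9, 0.95)→7, [0.85, 0.9)→6, [0.8, 0.85)→5,
[0.6, 0.8)→4, [0.4, 0.6)→3, [0.2, 0.4)→2, (0, 0.2)→1, with order
weights 1, 0.95, 0.9, 0.8, 0.7, 0.6, 0.4, 0.2. A zero value (or a
wholly zero group) yields order 0 with weight 0 — the table has no row
for ratio 0, and absence agreeing with absence is treated as
agreement, so two all-zero groups match vacuously (MDG = 1).

Matching treats an element as mismatched when its order differs
between the reference (original-matrix) and test (condensed-matrix)
runs — a 0/1 indicator, not a graded order distance. The penalty SE_W
of a mismatched element is the order weight of its *reference* order,
since the reference orders are declared the standard. This is the one
genuinely open reading in the formula (the penalty could equally come
from the test order or the larger of the two); `weight_source`
switches among `reference` / `test` / `max`, with `reference` the
documented default. Note that under the default a spurious element in
the test run (reference order 0) costs nothing — a direct consequence
of weighting by the reference order.

MD is the CG/CT-weighted mean of the four MDGs, so MD ∈ [0, 1] and
MD = 1 iff all groups match perfectly. Cohort histograms bin MD in
percent into [95, 100], [90, 95), [85, 90), [80, 85), [75, 80),
[70, 75), [65, 70), [60, 65), [0, 60) — left-closed bins, top bin
closed on both sides; the same nine bins are used for every group
including the integrated one.

## APOSD construction

The published APOSD algorithm is specified elsewhere only by its
semantics — the innermost layer holds the attribute covering the most
objects, and layers order attributes by universality — so the
construction here is a reconstruction that realises exactly that: a
recursive greedy partition. Among the objects reaching a node, the
unused attribute with the largest cover spawns the first child;
objects possessing it descend, the remainder re-partitions into
sibling branches; an object terminates when its attribute set is
exhausted by its path. Consequences, all tested: supports are
non-increasing along paths, each node's support equals its
terminating objects plus its children's supports, every object lies
on exactly one root-to-leaf path whose attributes equal its intent,
and the first layer-1 node has the globally maximal attribute cover.
Equal-support ties are broken by an explicit attribute priority,
defaulting to ascending element index, which makes the tree
deterministic and invariant to object order. The result is kept a
tree (equal branches are not merged into a DAG); star/annular
rendering is left to the DOT consumer.

Context extraction takes, per record, the elements attaining that
record's own maximal order (ties included) — not a fixed global order
8 — so every included record contributes at least one attribute;
records whose orders are all zero are dropped with a warning.

## Synthetic data

The generator emulates the shape of the study setup, not its content:

* matrix — 177 questions by default, each linked to 3–8 uniformly
  chosen evaluable elements with weights ~ Uniform(1, 99); every
  evaluable element is guaranteed at least one link, columns 7/8 stay
  empty. Link counts and the uniform weight law are package choices —
  only the value scale, sparsity, and many-to-many linkage are
  contractual.
* cohort — 670 records by default, male fraction 301/670, answers
  i.i.d. across questions with level probabilities
  A 0.0094, B 0.05, C 0.12, D 0.8206. The A probability is set so
  that with 177 questions about 81% of records contain at least one
  severe answer, mirroring a majority-severe cohort (544 of 670); it
  is a convenience default, not an empirical estimate. Inquiry times
  are Normal(900 s, 180 s) truncated at zero — a plausible quarter
  hour; no field standard exists for the minimum acceptable time, so
  screening takes `min_inquiry_seconds` as a required parameter.

What the synthetic data does *not* model: symptom co-occurrence,
sex-specific answer patterns, or any clinically realistic correlation
between questions and elements. Passing tests therefore demonstrate
the correctness of the machinery (scoring, condensation, matching,
discovery), not clinical validity of any particular matrix, and the
agreement distributions obtained on synthetic matrices need not match
those reported for the real knowledge base. Screening applies three
exclusion criteria with tags: (a) no symptoms (all answers D),
(b) inquiry time below the minimum, (c) all answers at one identical
level; a record is tagged with the first criterion that applies, so an
all-D record is tagged (a) and an all-A record — literal reading of
criterion (c) — is excluded as uniform despite having symptoms.

## Numerical and interface choices

* All rule tables compare with exact floating-point equality at the
  printed endpoints; endpoint sweeps at ± one ulp are part of the test
  suite.
* Generated data uses `numpy.random.default_rng` (PCG64), so a spec
  plus integer seed reproduces bit-identical data across platforms.
* CSV is the canonical interchange (UTF-8, header row mandatory):
  matrices wide (full grid) or long (nonzero triples), cohorts one row
  per record with one column per question, contexts as 1/blank
  cross-tables or long object–attribute pairs. Readers reject
  out-of-domain values rather than coercing. JSON mirrors carry the
  matrix scale; the pipeline writes a manifest with SHA-256 checksums
  of every artifact.
* Scale inference for matrices: positive weights all within
  {2, 3, 4, 5, 6, 8, 10} ⇒ condensed, else original. An original
  matrix that happens to use only those values would be mis-inferred;
  declare the scale explicitly in that case.

## Problem sizes

The acceptance-level checks run at the full study scale — 670 records
by 177 questions, all four condensation rules, and APOSD discovery
with depth-4 chains — which completes in well under a minute; oracle
suites use 1000 random quantification instances and 120 random
contexts up to 12 objects × 10 attributes.

## Known limitations

* The headline cohort statistics of the original study are not
  reproducible here because neither its mapping matrix nor its
  670-record cohort is deposited; only the rule tables, formulas, and
  structural behaviour are verifiable, and the tests do exactly that.
* Elements 7 and 8 are carried as registry entries but never scored.
* The APOSD is a reconstruction from stated semantics; a published
  variant could differ in tie handling or branch merging.
* The questionnaire carries placeholder texts; only counts and the
  sex split are modelled.
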