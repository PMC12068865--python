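# Methods

## The screening instrument and its data model

Each screened article is one `ScreeningRecord`: journal (Circulation, EHJ,
JACC), study type (eight empirical types plus NON_EMPIRICAL), and the coded
response to every instrument item. Availability items form *gated chains*:
whether a statement exists, how availability is claimed (repository,
personal/institutional page, supplement, upon request), and whether the
resource could actually be accessed; the data chain continues with
documentation and completeness. Gated items below a negative gate are
`NOT_APPLICABLE`, never blank, so missingness is always explicit, and
`validate_record` enforces the chain invariants (no "accessible" without a
positive statement, no pre-registration aspects without an accessible
pre-registration, and so on). Validation returns a list of violations rather
than raising, so readers can run strict (abort) or lenient (drop and log).

Non-empirical articles (reviews, editorials, commentaries) retain only the
corpus-wide items — COI, funding, open access, journal, clarity of study
type — and are excluded from scoring, classification and the test battery.

## Accessibility score

Seventeen criteria, one per instrument row, equally weighted; the score is
satisfied/applicable. Two design points deserve emphasis:

* **Constant denominator per study type.** Conditional criteria stay in the
  denominator when their gate is negative (an article with no data statement
  still "could have" satisfied data accessibility, documentation and
  completeness). This makes the denominator a property of the study type
  alone — 17, or 15 for the two materials-exempt types — and makes scores
  comparable within type. The alternative (dropping non-applicable gated
  items per article) would reward saying nothing.
* **No weighting or hierarchy.** Criteria are not ranked; any weighting would
  be an unsupported modeling choice.

A satisfied criterion always implies an applicable one; scores lie in [0, 1]
and flipping any single criterion to satisfied cannot decrease the score
(both are property-tested).

## Repeatability classification

Availability of four resource categories — materials, methods, data,
analysis scripts — drives the classification. "Methods" is the presence of
an accessible pre-registration **or** a linked protocol. Replicability
(repeat with new data) uses {materials, scripts, methods}; reproducibility
(re-analyze the original data) uses {data, scripts, methods}. PARTIAL means
at least one of the triple, FULL all three. Two switchable strictness knobs
exist because the underlying constructs are genuinely ambiguous:

* `strict_access` counts a resource only if it was actually openable during
  screening rather than merely stated available (default: statement-based,
  matching how sharing proportions are usually tabulated);
* `require_methods_aspect` additionally requires the pre-registration or
  protocol to cover the METHODS aspect (default: mere presence).

The 16-row truth table of the classifier is tested exhaustively against a
hand-written oracle, as is monotonicity (adding a resource never downgrades
either status).

## Statistical battery

* **Group summaries**: n, mean, sample SD (ddof = 1); SD is unset for
  singleton groups rather than reported as 0.
* **Two-way ANOVA** of score on study type and journal: ordinary least
  squares with the full interaction model, Type II sums of squares — the
  conventional default for unbalanced factorial designs with no stated factor
  ordering — with the interaction tested from the full model. Fitted via
  statsmodels; with empty cells the design is rank-deficient and is fit by
  pseudoinverse. F and p are recomputed from the sums of squares so that
  degenerate inputs have defined answers: an effect with zero sum of squares
  reports F = 0, p = 1 (constant data); a positive effect over a zero
  residual reports F = ∞, p = 0.
* **Chi-squared homogeneity** (k×2, expected counts from margins, df = k−1,
  no continuity correction) via scipy. Preconditions: positive row and
  column totals.
* **Fisher exact, two-sided**, for 2×2 tables: the sum of hypergeometric
  point probabilities not exceeding the observed table's, margins fixed (the
  point-probability rule; two-sided Fisher definitions differ, so this is
  stated explicitly). Point weights are compared as exact integers
  (binomial-coefficient products), so probability ties are included exactly,
  with no floating-point tolerance; the test suite checks equality with a
  brute-force rational-arithmetic enumeration over all 2×2 tables with
  margins ≤ 20 and cross-checks scipy's implementation.
* **Bonferroni**: min(1, m·p), ceiling at 1, order-preserving; m must be at
  least the family size.
* **`resource_battery`**: per resource, one omnibus k×2 test across the
  retained study types, then every pairwise 2×2 study-type comparison,
  switching to Fisher whenever the observed table has a zero cell (an
  optional stricter trigger, any expected count < 5, is off by default
  because the zero-cell rule is the documented behaviour). Materials tables
  omit the materials-exempt study types. Bonferroni families: the omnibus
  family is the number of resources (4); the pairwise family is the total
  number of pairwise tests across all resources (C(k,2)·4; 24 for four
  types). Both m values are configurable since "the number of tests
  performed" admits either reading. Study types with fewer than
  `min_group_size` empirical articles (default 20) are excluded; the default
  sits just below the smallest retained group in the motivating corpus
  (case studies, n = 21) and is configurable. Significance is read at
  α = 0.05 on adjusted p-values.

## Synthetic-data generator

`default_config()` encodes the study conditions: 639 articles; journal mix
226/193/220 (Circulation/EHJ/JACC); 246/639 non-empirical; and, per
empirical article, marginal item probabilities equal to the screened
corpus's printed fractions — materials stated available 56/393 (openable
1/56), data 125/393 (openable 13/125, documented 9/13), scripts 43/393
(openable 1/43), pre-registration statement 107/393 (accessible 106/107;
aspects: hypotheses 44/106, methods 106/106, analysis plan 27/106), linked
protocol 10/393 (aspects 7/10, 9/10, 5/10), study type clearly stated 0.56,
COI 0.57/0.36/0.07 (has/none/absent), funding statement absent 276/639, open
access 605/639. Gated chains are sampled as Markov chains (statement →
mode → accessible → documented → complete), so generated records satisfy the
schema invariants by construction. One integer seed drives a single
`numpy.random.default_rng` stream; identical seed and config give a
bit-identical RecordSet.

Quantities the corpus summary never printed are single, fixed choices and
are **not calibrated**: the split of the empirical pool across study types
beyond case studies (21/393) — chosen as observational 170, trials 90,
laboratory animal 60, and 13 each for four deliberately small types so that
sample-size exclusion is exercised; the access-mode mix (upon request 0.55,
supplement 0.20, repository 0.15, personal page 0.10, reflecting that
"upon request" dominates); data completeness given documentation (0.5); the
OA-button vs other-means split (even); the funding split of the non-absent
mass (even); and the probability that a negative statement explicitly denies
availability (0.05).

**What the generator does and does not emulate.** Items are sampled
independently given study type: the corpus provides no joint distribution,
and per-study-type prevalences are only partially published. Joint outcomes
— the number of fully reproducible articles, the score distribution's shape,
cross-resource correlations — are therefore *emergent*, and systematically
differ from a real corpus where sharing behaviours correlate strongly
(a group that shares data usually also shares scripts). Likewise all study
types share at identical rates by default, so between-type ANOVA and
battery p-values on default synthetic corpora are null draws. Passing tests
demonstrate that the pipeline's arithmetic, classification and test
machinery are correct, not that synthetic corpora reproduce the joint
behaviour of real literature; corpus-dependent statistics (mean scores by
type/journal, the battery's p-values) are validated structurally and
against closed forms, not against published values, which would require the
per-article dataset.

## Reporting conventions

Percentages round half away from zero at an explicit precision (so 7/393 →
"2%" and 56/393 → "14%"); both 0- and 1-decimal renderings are emitted since
summaries conventionally mix the two. Score histograms use left-closed bins
of width 0.1 with 1.0 folded into the top bin, labeled "0.20–0.29" style.
`summarize` is a pure function of the RecordSet; chain counts (statement ≥
accessible ≥ documented ≥ complete) are non-increasing by construction and
asserted in tests.

## Problem sizes

Tests and the acceptance script run on corpora of 150–10,000 synthetic
articles: 639 (the screened-corpus size) for end-to-end summaries, 1,200 for
battery structure, and 10,000 for calibration checks, where a 3-standard-
error binomial band gives a sharp yet stable criterion. The exhaustive
Fisher check enumerates all 35,650 2×2 tables with margins ≤ 20.

## Known limitations

* The instrument's non-satisfying response options are collapsed into the
  enums of `schema_io`; a Qualtrics-derived export must be mapped to this
  schema by the user (a documented column mapping, not auto-detection).
* The score treats all criteria equally; types of study where unshared
  resources are adequately described in text (case studies especially) are
  under-scored.
* The classifier measures potential, statement-based repeatability;
  "available upon request" counts as available by default.
* Synthetic joint outcomes are uncalibrated (above), so downstream joint
  counts should never be read as predictions of real corpora.
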