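# Methods

This note documents the models and procedures the package implements, the
defaults that matter, what the synthetic generators do and do not emulate,
and the design choices made where the design was genuinely open.

## Staging rule engine

Stage grouping is modeled as a finite pattern-matching problem. The staging
domain is the Cartesian product of closed vocabularies — T ∈ {Tis, T0, T1,
T2, T3, T4}, N ∈ {N0, N1mi, N1, N2, N3}, M ∈ {M0, M1}, and, for prognostic
editions, grade ∈ {G1, G2, G3} and HER2/ER/PR ∈ {positive, negative}. A
rule fixes a subset of dimensions and wildcards the rest; `*` is the only
pattern operator (the published stage-grouping tables are pure
enumerations, so ranges and negation add nothing). T/N subcategories
(T1a/b/c, N2a, …) are deliberately outside the vocabularies and rejected at
parse time: this keeps the domain finite (60 anatomic, 1,440 prognostic
combinations) so that the central safety property — *pairwise disjointness,
hence at most one matching rule per fully specified record* — can be
verified by exhaustive enumeration at load time rather than argued.

Consequences of disjointness: match order is irrelevant (file order is kept
only for reporting), inference is deterministic, and the trace explanation
is canonical — one step per constrained dimension of the unique matching
rule plus a concluding step. Records no rule covers (clinically invalid
combinations such as in-situ disease with nodal involvement) raise a
defined "not classifiable" error; the rule set is *not* padded to cover
them, because exhaustiveness is a property of the published table, not of
the engine.

Cross-edition comparison requires a total order on stages; the published
tables imply but never state one, so the package fixes
0 < IA < IB < IIA < IIB < IIIA < IIIB < IIIC < IV.

The shipped 7th-edition table is the complete 19-criterion anatomic
grouping. The 8th-edition file is an illustrative 30-row prognostic subset:
it refines the T1/T2 node-negative and T1 N1 strata by grade and receptor
status (favorable biology down-stages, unfavorable up-stages), keeps the
anatomic rows elsewhere, and retains the universal M1 → IV rule. The full
407-criterion prognostic table is licensed by the AJCC; users who hold it
can supply it as a rules CSV and the engine validates and applies it
identically. Clinical vs. pathological prognostic grouping is not
distinguished in the encoding — both are just rule sets with different
edition identifiers.

Stage-level annotations (recommended tests, treatment options, comment)
live in a second section of the same rules file, keyed by stage. They are
plain configured lists, not fetched content; an unannotated stage yields an
empty annotation object.

## Provenance graphs

The graph vocabulary uses fixed namespaces (`gprov:` at
`https://w3id.org/gprov#`, W3C `prov:`, `bibo:`, `dct:`) with the node
classes Guideline, Recommendation, FormalRule, EvidenceSentence, Citation,
Grade, DiseaseManagement and Author. Properties with standardized meaning
come from PROV and Dublin Core: rules derive from recommendations via
`prov:wasDerivedFrom`, evidence sentences point at publications via
`prov:hasPrimarySource`, a guideline is linked to the condition it manages
via `prov:used`, containment and bibliographic metadata use `dct:`.

IRIs are minted deterministically from stable identifiers
(`…/recommendation/<id>` etc.), so repeated builds of the same input are
byte-identical and contain no blank nodes — which is what makes the
Turtle round-trip isomorphism test meaningful and cheap. Two modeling
choices keep node counts predictable arithmetic functions of the input:
grades are shared nodes per distinct code (not per recommendation), and
disease management is one node per (guideline, disease) pair. Because
recommendation IRIs derive from the recommendation id alone, the same
recommendation appearing in two guideline editions is a single node with
two containment arcs; the recency query then naturally returns every
edition year, descending, and a missing year yields an explicit
`"unknown"` marker instead of an exception. `expected_counts` recomputes
every node/arc/triple count by plain arithmetic over the input collections,
independently of any RDF machinery, and serves as the oracle for the graph
builder.

Grades attach at recommendation level only; whether a sentence citing
several publications weights them differently is not modeled — citations
are de-duplicated per recommendation and returned sorted. The nine
explanation types (case-based, contextual, contrastive, counterfactual,
everyday, scientific, simulation-based, statistical, trace-based) are a
closed labeling vocabulary, not an ontology reimplementation: staging
traces are tagged trace-based, citation answers scientific, anything else
is tagged explicitly.

## Cohort tables

Orientation is fixed: characteristics in rows, arms in columns (the
dominant Table-1 convention); transposed grids are a declared error. The
sub-header heuristic is *non-empty label cell, all arm cells empty*; it is
the simplest convention consistent with how published tables set off
sections, and the synthetic generator plants sub-headers under exactly this
convention — so the perfect precision/recall the tests show is evidence the
detector implements the convention, not that real PDFs parse cleanly.
Only single-level parents are supported; nested indentation is not
interpreted.

The cell grammar normalizes dash variants (–, —, −), `+/-`, and European
decimal commas before matching, then takes the first matching production:
`a ± b` → mean/SD; `a (b%)` → count/percent; `a [b–c]` or `a (b, c)` →
median/IQR; `a (b–c)` → median/range; `a%` → percent; bare integer → count;
bare decimal → number. The ambiguous `a (b)` form is read as
count (percent) only under a `%` hint from the row label; without a hint it
degrades to text. Unparseable cells and statistics violating sanity bounds
(percent outside [0, 100], median outside its quartiles) degrade to flagged
text, never exceptions — losslessness (every non-empty cell represented) is
the invariant, typedness is best-effort. A decimal comma directly adjacent
to digits inside a parenthetical pair (e.g. `(10,15)` without spaces) is
indistinguishable from a European decimal and is read as one; renderers
that space their IQR separators avoid the ambiguity.

Term normalization is exact folded-string lookup (case, punctuation, unit
suffixes and trailing count markers stripped) in a shipped ~50-entry
mini-lexicon of common demographic/lab/medication/condition terms. There is
no fuzzy matching by design: an unmatched label is preserved verbatim and
flagged, which is the honest behavior for a desk-scale replacement of an
ontology-annotation web service. Units are captured only from parenthesized
label suffixes; no conversion is attempted. Percent-only cells keep percent
only — counts are never imputed from arm size.

Statistics are reified in the RDF output: each (arm, characteristic) pair
owns typed statistic nodes (`sco:Mean`, `sco:StandardDeviation`,
`sco:Median`, `sco:InterquartileRange`, `sco:Range`, `sco:Count`,
`sco:Percent`) carrying values or bounds.

## Fit scoring, star plots, gap queries

The fit criterion is the mean ± k·SD band with k = 1 by default; k is a
parameter because no alternative multiplier is canonical. Median-based
statistics use [q1, q3] (or the reported range); features with no
dispersion statistic are skipped and listed, never silently dropped, so
`evaluated_n + |skipped|` always equals the requested feature count. An
explicit eligibility age range on the study takes precedence over the
summary band for age — a patient below the study's age floor is
out-of-range even if inside mean ± SD. Categorical features are in range
iff the category has nonzero count or percent in the arm. The fit score is
the exact fraction of evaluated features in range.

Star-plot axes are evenly spaced in request order; each axis is min–max
normalized over {patient value, band low, band high}, so all coordinates
lie in [0, 1] and a patient at the band center sits at 0.5. A polygon needs
at least three evaluated features.

Gap queries: "representation" means count > 0 or percent > 0; the
under-representation threshold is a parameter defaulting to 5%. The
"study quality" scenario operationalizes a good treatment-to-effect ratio
as *total size ≥ 1000 and at least one arm ≥ ⅓ of the total* — a size-ratio
reading of the scenario text; no notion of effect heterogeneity beyond arm
sizes is modeled. All three scenarios report the percentage of the corpus
they match.

## Synthetic generators

Each generator threads a single integer seed through one `numpy` RNG
stream. The patient profile (shipped YAML, nothing hard-coded) mirrors the
feature axes of the cohort-similarity application — age, systolic/diastolic
blood pressure, HbA1c, BMI — plus the staging fields, with
registry-plausible category frequencies and survey-plausible truncated
normal distributions. The profile draws each field independently; real
registries have T–N–M and biomarker correlations the generator does not
emulate, so passing tests certify engine correctness on the category
domain, not epidemiological realism.

The corpus generator plants exact corpus-level prevalences by construction:
75% of studies with nonzero African-American (and female) representation,
50% with cohort mean age above 70, and 6% with the quality size structure
(two arms 800/700; non-quality studies are four balanced arms of 300, so
every study is large-scale but only the planted ones satisfy the ⅓-arm
condition). These defaults mirror the corpus-level analysis percentages the
gap queries are designed to reproduce; the analysis path (grid rendering →
assembly → query) never sees the planted flags, only the rendered tables.

Cell values are planted pre-rounded to one decimal so the render → parse
round-trip is bit-exact; integer-valued "plain numbers" are rendered with a
trailing `.0` so the grammar does not reclassify them as counts.

## Problem sizes and numerics

Default verification sizes: the full 60-element anatomic enumeration
(1,440 prognostic) for disjointness and oracle equivalence; 1,000 patients
for the dominance properties; 200 records for cross-edition antisymmetry;
100 recommendations for the provenance round-trip and query/scan
equivalence; 10 seeded grids covering all statistic kinds for cohort
round-trips; 500 (patient, arm) pairs for fit-score recounts; and
100–200-study corpora for gap-query/scan equivalence. All comparisons
against ground truth are exact (integer counts, bit-equal floats from the
rounded rendering); no tolerance tuning is involved. Everything runs in
seconds on one core.

## Known limitations

* The engine stages only records expressible in the closed vocabularies;
  subcategory-level staging needs a vocabulary extension and new tables.
* The 8th-edition file is an illustrative subset, not the licensed table.
* Table parsing assumes a digital grid; no PDF/OCR layer.
* Term matching is exact-after-folding; synonyms outside the mini-lexicon
  are flagged unmatched rather than guessed.
* Gap-query semantics treat each study's reported summary as authoritative;
  there is no weighting by study size or quality beyond the explicit
  quality scenario.
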