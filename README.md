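# semcds

Semantics-enabled clinical decision support: a Python toolkit for
(1) declarative cancer-staging inference with cross-edition comparison and
trace explanations, (2) guideline-provenance knowledge graphs with
competency queries, and (3) cohort summary-table ("Table 1") modeling with
patient–cohort fit scoring and population-gap analysis.

It is written for clinical-informatics researchers and CDS developers who
need the machinery behind point-of-care questions such as *what stage is
this tumor and why*, *where does this treatment suggestion come from*, and
*does the evidence cohort actually resemble my patient*.

## What it computes

**Staging engine** (`semcds.staging`). An edition of the AJCC breast-cancer
stage-grouping tables is a flat list of pattern rules over
(T, N, M, grade, HER2, ER, PR) with `*` wildcards; a rule matches a record
iff every non-wildcard pattern equals the record's value. A validated rule
set is pairwise disjoint — checked by exhaustive enumeration of the finite
staging domain (6·5·2 = 60 anatomic combinations, ×24 biomarker
combinations for prognostic editions) — so inference is a pure lookup that
returns the unique stage with a trace-based explanation. The shipped
7th-edition anatomic table holds its 19 criteria; an illustrative
8th-edition prognostic subset (30 of the 407 published criteria) supports
cross-edition comparison against the total stage order
0 < IA < IB < IIA < IIB < IIIA < IIIB < IIIC < IV
(up-staged / down-staged / no-change).

**Provenance graphs** (`semcds.provenance`). Structured guideline-extract
tables (recommendations, grades, evidence sentences, citations, formal-rule
links) become a typed RDF graph (`gprov:`, `prov:`, `bibo:`, `dct:`
namespaces; `prov:wasDerivedFrom`, `prov:hasPrimarySource`, `prov:used`)
with deterministic IRIs and no blank nodes, serialized as Turtle. Three
competency queries: the source of a decision rule, the publications and
grade supporting a recommendation, and its recency. Answers carry one of
nine fixed explanation-type labels (trace-based, scientific, contrastive, …).

**Cohort tables and analytics** (`semcds.cohorts`, `semcds.analytics`).
A summary grid is parsed with a small cell grammar (`54.3 ± 8.2`,
`123 (45%)`, `12.5 [10–15]`, `140 (80–200)`, bare counts/percents), its
sub-header rows detected (non-empty label, empty value cells), labels
normalized against a shipped mini-lexicon, and each statistic reified as its
own node attached to an (arm, characteristic) pair. The fit score of a
patient against an arm is the fraction of evaluated features inside the
arm's band — mean ± k·SD (default k = 1), IQR or range, eligibility age
limits taking precedence — with star-plot coordinates for visualization.
Gap queries answer three corpus-level scenarios: study match (subgroup
represented), study limitation (subgroup absent or under-represented), and
study quality (total size ≥ threshold with one arm ≥ ⅓ of the total).

`semcds.fixtures` generates seeded synthetic patients, grids, corpora, and
guideline extracts with ground truth, so everything runs offline.

## Worked example

```python
from semcds import staging

bcs7 = staging.bundled_ruleset("bcs7")
bcs8 = staging.bundled_ruleset("bcs8-subset")

record = staging.PatientRecord(
    "p1",
    tnm=staging.TnmCategory("T2", "N0", "M0"),
    biomarkers=staging.BiomarkerProfile("G1", "negative", "positive", "positive"),
)
result = staging.infer_stage(record, bcs7)
print(result.stage, result.rule_id)
print(staging.compare_editions(record, bcs7, bcs8))
```

prints

```
IIA bcs7-07
EditionComparison(record_id='p1', stage_a='IIA', stage_b='IB', verdict='down-staged')
```

— the anatomic 7th edition groups T2 N0 M0 as stage IIA, while the
prognostic subset down-stages the same tumor to IB because of its favorable
biology (grade 1, ER-positive). The same flow is available from the shell:

```bash
semcds gen patients --n 100 --seed 1 --out-dir out/
semcds stage --edition bcs7 --patients out/patients.csv --compare bcs8-subset --out out/staged.json
semcds gen extract --n 25 --seed 0 --out-dir out/extract
semcds kg-build --extract-dir out/extract --rule-links out/extract/rule_links.csv --out-dir out/kg
semcds kg-query --graph out/kg/provenance.ttl --query evidence-for --id rec-003
```

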