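"""Declarative breast-cancer stage-grouping rule engine.

An edition of the AJCC stage-grouping tables is represented as a flat list of
pattern rules: each rule fixes some subset of the staging dimensions
(T, N, M and — for prognostic editions — tumor grade and HER2/ER/PR receptor
status) and leaves the rest as the wildcard ``"*"``.  A rule matches a record
iff every non-wildcard pattern equals the record's value.  A validated rule
set is *pairwise disjoint*: no fully specified record matches two rules, which
is checked by exhaustive enumeration of the finite staging domain (60 T×N×M
combinations, times 24 biomarker combinations when any rule constrains them).

Because rules are disjoint, inference is a pure lookup: at most one rule
matches, and the engine returns its stage together with a trace-based
explanation (one step per constrained dimension).  Records covered by no rule
— clinically invalid combinations such as in-situ disease with nodal
involvement — raise :class:`~semcds.errors.NotClassifiableError` rather than
being forced into a stage.

Cross-edition comparison stages the same record under two rule sets and
reports ``up-staged`` / ``down-staged`` / ``no-change`` against the total
stage order 0 < IA < IB < IIA < IIB < IIIA < IIIB < IIIC < IV.
"""

from __future__ import annotations

import csv
import io
import itertools
import json
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import (
    NotClassifiableError,
    ParseError,
    ValidationError,
    VocabularyError,
)

# Controlled vocabularies.  Subcategories (T1a/b/c, N2a, ...) are deliberately
# excluded so the staging domain stays finite and enumerable; they are parse
# errors, not silently coarsened.
T_CATEGORIES = ("Tis", "T0", "T1", "T2", "T3", "T4")
N_CATEGORIES = ("N0", "N1mi", "N1", "N2", "N3")
M_CATEGORIES = ("M0", "M1")
GRADE_CATEGORIES = ("G1", "G2", "G3")
RECEPTOR_CATEGORIES = ("positive", "negative")

STAGES = ("0", "IA", "IB", "IIA", "IIB", "IIIA", "IIIB", "IIIC", "IV")
_STAGE_RANK = {s: i for i, s in enumerate(STAGES)}

WILDCARD = "*"

ANATOMIC_FIELDS = ("t", "n", "m")
BIOMARKER_FIELDS = ("grade", "her2", "er", "pr")
RULE_FIELDS = ANATOMIC_FIELDS + BIOMARKER_FIELDS

_FIELD_VOCAB = {
    "t": T_CATEGORIES,
    "n": N_CATEGORIES,
    "m": M_CATEGORIES,
    "grade": GRADE_CATEGORIES,
    "her2": RECEPTOR_CATEGORIES,
    "er": RECEPTOR_CATEGORIES,
    "pr": RECEPTOR_CATEGORIES,
}

RULES_HEADER = ("rule_id", "edition", "t", "n", "m", "grade", "her2", "er", "pr", "stage")
ANNOTATIONS_HEADER = ("stage", "recommended_tests", "treatment_options", "comment")


def stage_rank(stage: str) -> int:
    """Position of ``stage`` in the total stage order (0 is lowest)."""
    try:
        return _STAGE_RANK[stage]
    except KeyError:
        raise VocabularyError(f"unknown stage label {stage!r}; expected one of {STAGES}")


def _check_vocab(field_name: str, value: str) -> str:
    vocab = _FIELD_VOCAB[field_name]
    if value not in vocab:
        raise VocabularyError(
            f"unknown {field_name} category {value!r}; expected one of {vocab}"
        )
    return value


@dataclass(frozen=True)
class TnmCategory:
    """Anatomic staging triple: tumor extent, nodal involvement, metastasis."""

    t: str
    n: str
    m: str

    def __post_init__(self) -> None:
        for name in ANATOMIC_FIELDS:
            _check_vocab(name, getattr(self, name))


@dataclass(frozen=True)
class BiomarkerProfile:
    """Prognostic factors: histologic grade and HER2/ER/PR receptor status."""

    grade: str
    her2: str
    er: str
    pr: str

    def __post_init__(self) -> None:
        for name in BIOMARKER_FIELDS:
            _check_vocab(name, getattr(self, name))


@dataclass(frozen=True)
class PatientRecord:
    """Staging inputs plus free-form features used by cohort analytics."""

    record_id: str
    tnm: TnmCategory | None = None
    biomarkers: BiomarkerProfile | None = None
    features: Mapping[str, object] = field(default_factory=dict)

    def staging_values(self) -> dict[str, str | None]:
        values: dict[str, str | None] = dict.fromkeys(RULE_FIELDS)
        if self.tnm is not None:
            values.update(t=self.tnm.t, n=self.tnm.n, m=self.tnm.m)
        if self.biomarkers is not None:
            values.update(
                grade=self.biomarkers.grade,
                her2=self.biomarkers.her2,
                er=self.biomarkers.er,
                pr=self.biomarkers.pr,
            )
        return values


@dataclass(frozen=True)
class StagingRule:
    """One criterion row: a pattern over the staging dimensions and its stage."""

    rule_id: str
    edition: str
    t: str
    n: str
    m: str
    grade: str
    her2: str
    er: str
    pr: str
    stage: str

    def __post_init__(self) -> None:
        for name in RULE_FIELDS:
            value = getattr(self, name)
            if value != WILDCARD:
                _check_vocab(name, value)
        stage_rank(self.stage)

    def pattern(self, field_name: str) -> str:
        return getattr(self, field_name)

    @property
    def constrained_fields(self) -> tuple[str, ...]:
        return tuple(f for f in RULE_FIELDS if self.pattern(f) != WILDCARD)

    def matches(self, values: Mapping[str, str | None]) -> bool:
        for name in RULE_FIELDS:
            pattern = self.pattern(name)
            if pattern != WILDCARD and pattern != values.get(name):
                return False
        return True


@dataclass(frozen=True)
class StageAnnotations:
    """Stage-level care annotations: tests, treatments, free-text comment."""

    recommended_tests: tuple[str, ...] = ()
    treatment_options: tuple[str, ...] = ()
    comment: str = ""


@dataclass(frozen=True)
class StagingResult:
    stage: str
    rule_id: str
    explanation: tuple[str, ...]
    explanation_type: str = "trace-based"


@dataclass(frozen=True)
class EditionComparison:
    record_id: str
    stage_a: str
    stage_b: str
    verdict: str  # "up-staged" | "down-staged" | "no-change"


@dataclass(frozen=True)
class StagingRuleSet:
    """A validated edition: ordered rules plus per-stage annotations.

    File order is preserved for reporting only; disjointness makes match
    order irrelevant to semantics.
    """

    edition: str
    rules: tuple[StagingRule, ...]
    stage_annotations: Mapping[str, StageAnnotations] = field(default_factory=dict)

    @property
    def uses_biomarkers(self) -> bool:
        return any(
            rule.pattern(f) != WILDCARD for rule in self.rules for f in BIOMARKER_FIELDS
        )

    @property
    def required_fields(self) -> tuple[str, ...]:
        constrained = {f for rule in self.rules for f in rule.constrained_fields}
        return tuple(f for f in RULE_FIELDS if f in constrained)

    def stages(self) -> tuple[str, ...]:
        return tuple(sorted({r.stage for r in self.rules}, key=stage_rank))


def _enumeration_domain(uses_biomarkers: bool) -> Iterable[dict[str, str]]:
    dims = [T_CATEGORIES, N_CATEGORIES, M_CATEGORIES]
    names = list(ANATOMIC_FIELDS)
    if uses_biomarkers:
        dims += [GRADE_CATEGORIES, RECEPTOR_CATEGORIES, RECEPTOR_CATEGORIES, RECEPTOR_CATEGORIES]
        names += list(BIOMARKER_FIELDS)
    for combo in itertools.product(*dims):
        yield dict(zip(names, combo))


def validate_ruleset(ruleset: StagingRuleSet) -> StagingRuleSet:
    """Run all rule-set contracts; return the rule set unchanged on success.

    Checks: non-emptiness, unique rule ids, pairwise disjointness by
    exhaustive enumeration of the staging domain, and that every annotated
    stage is produced by at least one rule.
    """
    if not ruleset.rules:
        raise ValidationError(f"no rules in ruleset {ruleset.edition!r}")

    seen: dict[str, StagingRule] = {}
    for rule in ruleset.rules:
        if rule.rule_id in seen:
            raise ValidationError(f"duplicate rule_id {rule.rule_id!r}")
        seen[rule.rule_id] = rule

    for values in _enumeration_domain(ruleset.uses_biomarkers):
        hits = [r for r in ruleset.rules if r.matches(values)]
        if len(hits) > 1:
            pair = ", ".join(r.rule_id for r in hits[:2])
            raise ValidationError(
                f"overlapping rules [{pair}] both match record {values}"
            )

    rule_stages = {r.stage for r in ruleset.rules}
    for stage in ruleset.stage_annotations:
        stage_rank(stage)
        if stage not in rule_stages:
            raise ValidationError(
                f"annotated stage {stage!r} produced by no rule of {ruleset.edition!r}"
            )
    return ruleset


def load_ruleset(path: str | Path, edition: str | None = None) -> StagingRuleSet:
    """Load and validate a rules CSV (with optional annotations section).

    The file holds a ``rule_id,edition,...,stage`` section and, optionally, a
    second section introduced by the header line
    ``stage,recommended_tests,treatment_options,comment`` whose list cells are
    ``;``-separated.  ``#`` lines are comments.  When ``edition`` is given,
    only rows of that edition are kept (an empty selection is an error);
    otherwise the file must contain a single edition.
    """
    path = Path(path)
    try:
        text = path.read_text(encoding="utf-8")
    except OSError as exc:
        raise ParseError(f"cannot read rules file {path}: {exc}") from exc

    rules: list[StagingRule] = []
    annotations: dict[str, StageAnnotations] = {}
    section = "rules"
    header_seen = False
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        row = next(csv.reader(io.StringIO(line)))
        cells = [c.strip() for c in row]
        if tuple(cells) == RULES_HEADER:
            section, header_seen = "rules", True
            continue
        if tuple(cells) == ANNOTATIONS_HEADER:
            section = "annotations"
            continue
        if not header_seen:
            raise ParseError(f"{path}:{lineno}: expected rules header before data")
        if section == "rules":
            if len(cells) != len(RULES_HEADER):
                raise ParseError(
                    f"{path}:{lineno}: expected {len(RULES_HEADER)} fields, got {len(cells)}"
                )
            try:
                rules.append(StagingRule(**dict(zip(RULES_HEADER, cells))))
            except VocabularyError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
        else:
            if len(cells) != len(ANNOTATIONS_HEADER):
                raise ParseError(
                    f"{path}:{lineno}: expected {len(ANNOTATIONS_HEADER)} fields, got {len(cells)}"
                )
            stage, tests, treatments, comment = cells
            annotations[stage] = StageAnnotations(
                recommended_tests=_split_list(tests),
                treatment_options=_split_list(treatments),
                comment=comment,
            )

    if edition is not None:
        rules = [r for r in rules if r.edition == edition]
        if not rules:
            raise ValidationError(f"no rules for edition {edition!r} in {path}")
    else:
        editions = {r.edition for r in rules}
        if len(editions) > 1:
            raise ValidationError(
                f"{path} mixes editions {sorted(editions)}; pass edition= to select one"
            )
        edition = next(iter(editions), "unknown")

    ruleset = StagingRuleSet(
        edition=edition, rules=tuple(rules), stage_annotations=annotations
    )
    return validate_ruleset(ruleset)


def _split_list(cell: str) -> tuple[str, ...]:
    return tuple(part.strip() for part in cell.split(";") if part.strip())


def bundled_ruleset(edition: str) -> StagingRuleSet:
    """Load one of the rule sets shipped with the package (``bcs7``,
    ``bcs8-subset``)."""
    from importlib.resources import as_file, files

    name = {"bcs7": "bcs7_rules.csv", "bcs8-subset": "bcs8_subset_rules.csv"}.get(edition)
    if name is None:
        raise VocabularyError(f"no bundled ruleset {edition!r}")
    with as_file(files("semcds").joinpath("data", name)) as path:
        return load_ruleset(path, edition=edition)


def _record_values(record) -> tuple[str, dict[str, str | None]]:
    """Normalize the accepted record shapes to (record_id, field map)."""
    if isinstance(record, PatientRecord):
        return record.record_id, record.staging_values()
    if isinstance(record, TnmCategory):
        values: dict[str, str | None] = dict.fromkeys(RULE_FIELDS)
        values.update(t=record.t, n=record.n, m=record.m)
        return "record", values
    if isinstance(record, tuple) and len(record) == 2:
        tnm, biomarkers = record
        rec = PatientRecord("record", tnm=tnm, biomarkers=biomarkers)
        return _record_values(rec)
    raise TypeError(f"cannot stage object of type {type(record).__name__}")


def infer_stage(record, ruleset: StagingRuleSet) -> StagingResult:
    """Stage a record under a validated rule set.

    Returns the unique matching rule's stage with a trace explanation.
    Raises :class:`NotClassifiableError` when no rule covers the record and
    :class:`ValidationError` when the record omits a dimension the rule set
    constrains (e.g. biomarkers under a prognostic edition).
    """
    record_id, values = _record_values(record)
    missing = [f for f in ruleset.required_fields if values.get(f) is None]
    if missing:
        raise ValidationError(
            f"record {record_id!r} lacks {missing} required by edition {ruleset.edition!r}"
        )

    hits = [rule for rule in ruleset.rules if rule.matches(values)]
    if not hits:
        shown = {k: v for k, v in values.items() if v is not None}
        raise NotClassifiableError(
            f"record {record_id!r} not classifiable under edition "
            f"{ruleset.edition!r}: {shown}"
        )
    if len(hits) > 1:  # impossible for a validated ruleset
        raise ValidationError(
            f"internal corruption: rules {[r.rule_id for r in hits]} all match"
        )
    rule = hits[0]
    steps = tuple(
        f"{name}={values[name]} matches pattern {rule.pattern(name)} of rule {rule.rule_id}"
        for name in rule.constrained_fields
    ) + (f"therefore stage {rule.stage} (rule {rule.rule_id}, edition {rule.edition})",)
    return StagingResult(stage=rule.stage, rule_id=rule.rule_id, explanation=steps)


def annotations_for(stage: str, ruleset: StagingRuleSet) -> StageAnnotations:
    """Care annotations configured for ``stage`` (empty object when none)."""
    stage_rank(stage)  # vocabulary check
    return ruleset.stage_annotations.get(stage, StageAnnotations())


def compare_editions(
    record, ruleset_a: StagingRuleSet, ruleset_b: StagingRuleSet
) -> EditionComparison:
    """Stage a record under two editions and classify the change."""
    record_id, _ = _record_values(record)
    try:
        result_a = infer_stage(record, ruleset_a)
    except NotClassifiableError as exc:
        raise NotClassifiableError(f"[edition {ruleset_a.edition}] {exc}") from exc
    try:
        result_b = infer_stage(record, ruleset_b)
    except NotClassifiableError as exc:
        raise NotClassifiableError(f"[edition {ruleset_b.edition}] {exc}") from exc

    delta = stage_rank(result_b.stage) - stage_rank(result_a.stage)
    verdict = "no-change" if delta == 0 else ("up-staged" if delta > 0 else "down-staged")
    return EditionComparison(
        record_id=record_id,
        stage_a=result_a.stage,
        stage_b=result_b.stage,
        verdict=verdict,
    )


@dataclass(frozen=True)
class BatchStagingReport:
    entries: tuple[dict, ...]
    stage_counts: Mapping[str, int]
    error_counts: Mapping[str, int]

    @property
    def n_staged(self) -> int:
        return sum(self.stage_counts.values())

    @property
    def n_errors(self) -> int:
        return sum(self.error_counts.values())


def stage_batch(records: Sequence, ruleset: StagingRuleSet) -> BatchStagingReport:
    """Stage many records; per-record errors become entries, never raises."""
    entries: list[dict] = []
    stage_counts: Counter[str] = Counter()
    error_counts: Counter[str] = Counter()
    for record in records:
        record_id, _ = _record_values(record)
        try:
            result = infer_stage(record, ruleset)
        except (NotClassifiableError, ValidationError) as exc:
            kind = type(exc).__name__
            error_counts[kind] += 1
            entries.append(
                {"record_id": record_id, "status": "error", "error": kind,
                 "message": str(exc)}
            )
        else:
            stage_counts[result.stage] += 1
            entries.append(
                {"record_id": record_id, "status": "staged", "stage": result.stage,
                 "rule_id": result.rule_id, "explanation": list(result.explanation),
                 "explanation_type": result.explanation_type}
            )
    return BatchStagingReport(
        entries=tuple(entries),
        stage_counts=dict(stage_counts),
        error_counts=dict(error_counts),
    )


def records_from_csv(path: str | Path) -> list[PatientRecord]:
    """Read patient records from the ``record_id,t,n,m,grade,her2,er,pr,...``
    CSV dialect; extra columns pass through as features."""
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    if "record_id" not in frame.columns:
        raise ParseError(f"{path}: missing required column 'record_id'")
    return [_record_from_mapping(row, f"{path}:{i + 2}") for i, row in frame.iterrows()]


def records_from_json(path: str | Path) -> list[PatientRecord]:
    with open(path, encoding="utf-8") as fh:
        payload = json.load(fh)
    if not isinstance(payload, list):
        raise ParseError(f"{path}: expected a JSON array of records")
    return [_record_from_mapping(obj, f"{path}[{i}]") for i, obj in enumerate(payload)]


def _record_from_mapping(row: Mapping[str, object], where: str) -> PatientRecord:
    def get(key: str) -> str | None:
        value = row.get(key)
        if value is None:
            return None
        value = str(value).strip()
        return value or None

    record_id = get("record_id")
    if not record_id:
        raise ParseError(f"{where}: missing record_id")
    try:
        tnm_vals = [get(k) for k in ANATOMIC_FIELDS]
        tnm = TnmCategory(*tnm_vals) if all(tnm_vals) else None
        bio_vals = [get(k) for k in BIOMARKER_FIELDS]
        biomarkers = BiomarkerProfile(*bio_vals) if all(bio_vals) else None
    except VocabularyError as exc:
        raise ParseError(f"{where}: {exc}") from exc
    features = {
        k: v for k, v in row.items()
        if k not in ("record_id",) + RULE_FIELDS and str(v).strip() != ""
    }
    return PatientRecord(record_id, tnm=tnm, biomarkers=biomarkers, features=features)
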