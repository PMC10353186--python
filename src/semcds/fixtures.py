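"""Seeded synthetic fixtures: patients, cohort grids, guideline extracts.

Every generator is a pure function of its parameters and a single integer
seed (one ``numpy`` RNG stream per call), and everything it emits passes the
consumer module's validators.  Generators return *ground truth* alongside
the artifact so tests can assert exact round-trips:

* :func:`gen_patients` — staging + feature records drawn from the category
  frequencies and numeric distributions in the shipped profile config.
* :func:`gen_cohort_grid` — renders a :class:`CohortSpec` of planted
  statistics into the Table-1 cell grammar, sub-headers included.
* :func:`gen_corpus` — a corpus of assembled studies with *planted
  prevalences* of subgroup representation, older-adult cohorts, and
  size-ratio "quality" structure, for gap-query analyses.
* :func:`gen_guideline_extract` — a recommendations/sentences/citations/
  rule-links CSV bundle with node-count tallies.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .cohorts import CohortGrid, CohortModel, assemble_cohort, default_lexicon
from .errors import ConfigError, ValidationError
from .provenance import Citation, FormalRuleLink, GuidelineExtract, EvidenceSentence
from .staging import (
    BIOMARKER_FIELDS,
    ANATOMIC_FIELDS,
    BiomarkerProfile,
    PatientRecord,
    TnmCategory,
)

DEFAULT_SEED = 0


def load_default_profile() -> dict:
    """The shipped patient-generator profile (category frequencies and
    numeric feature distributions)."""
    from importlib.resources import as_file, files

    with as_file(files("semcds").joinpath("data", "patient_profile.yaml")) as path:
        with open(path, encoding="utf-8") as fh:
            return yaml.safe_load(fh)


def _validate_profile(profile: Mapping) -> None:
    if not isinstance(profile, Mapping) or "categorical" not in profile:
        raise ConfigError("profile must be a mapping with a 'categorical' section")
    for name, freqs in profile["categorical"].items():
        total = sum(freqs.values())
        if not math.isclose(total, 1.0, abs_tol=1e-6):
            raise ConfigError(f"profile category {name!r} frequencies sum to {total}")
    for name, params in profile.get("numeric", {}).items():
        if params.get("dist") not in ("normal", "uniform"):
            raise ConfigError(f"profile numeric {name!r}: unsupported dist")


def gen_patients(
    n: int, seed: int = DEFAULT_SEED, profile: Mapping | None = None
) -> tuple[list[PatientRecord], dict]:
    """Generate ``n`` reproducible patient records.

    TNM and biomarker categories are drawn independently from the profile's
    frequencies; numeric features from its normal/uniform distributions
    (truncated to the configured bounds).  Returns the records and a sidecar
    recording the exact parameters used.
    """
    if n < 0:
        raise ValidationError("n must be ≥ 0")
    profile = profile if profile is not None else load_default_profile()
    _validate_profile(profile)
    rng = np.random.default_rng(seed)

    categorical = profile["categorical"]
    numeric = profile.get("numeric", {})
    draws: dict[str, list[str]] = {}
    for name in sorted(categorical):
        freqs = categorical[name]
        labels = list(freqs)
        probs = np.array([freqs[l] for l in labels], dtype=float)
        probs = probs / probs.sum()
        draws[name] = list(rng.choice(labels, size=n, p=probs)) if n else []

    numbers: dict[str, np.ndarray] = {}
    for name in sorted(numeric):
        params = numeric[name]
        if params["dist"] == "normal":
            sample = rng.normal(params["mean"], params["sd"], size=n)
        else:
            sample = rng.uniform(params["low"], params["high"], size=n)
        lo = params.get("min", -np.inf)
        hi = params.get("max", np.inf)
        numbers[name] = np.clip(sample, lo, hi)

    records = []
    for i in range(n):
        tnm = TnmCategory(*(draws[k][i] for k in ANATOMIC_FIELDS))
        biomarkers = BiomarkerProfile(*(draws[k][i] for k in BIOMARKER_FIELDS))
        features: dict[str, object] = {
            name: draws[name][i]
            for name in sorted(categorical)
            if name not in ANATOMIC_FIELDS + BIOMARKER_FIELDS
        }
        features.update({name: round(float(numbers[name][i]), 1) for name in sorted(numeric)})
        records.append(
            PatientRecord(f"p{i:05d}", tnm=tnm, biomarkers=biomarkers, features=features)
        )
    sidecar = {"n": n, "seed": seed, "profile": _to_plain(profile)}
    return records, sidecar


def _to_plain(obj):
    if isinstance(obj, Mapping):
        return {k: _to_plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_plain(v) for v in obj]
    return obj


def patients_to_frame(records: Sequence[PatientRecord]) -> pd.DataFrame:
    rows = []
    for rec in records:
        row: dict[str, object] = {"record_id": rec.record_id}
        if rec.tnm:
            row.update(t=rec.tnm.t, n=rec.tnm.n, m=rec.tnm.m)
        if rec.biomarkers:
            row.update(
                grade=rec.biomarkers.grade, her2=rec.biomarkers.her2,
                er=rec.biomarkers.er, pr=rec.biomarkers.pr,
            )
        row.update(rec.features)
        rows.append(row)
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# Cohort grids


@dataclass(frozen=True)
class PlannedStat:
    """Ground-truth statistic to plant in one cell."""

    kind: str
    values: Mapping[str, float] = field(default_factory=dict)
    text: str = ""


@dataclass(frozen=True)
class PlannedRow:
    label: str
    per_arm: Mapping[str, PlannedStat]
    group: str | None = None  # sub-header section
    unit: str | None = None


@dataclass(frozen=True)
class CohortSpec:
    """Blueprint of one study grid: arm sizes plus planted statistic rows."""

    study_id: str
    arm_sizes: Mapping[str, int]
    rows: tuple[PlannedRow, ...]
    caption: str = ""
    year: int | None = None
    eligibility: Mapping[str, float] | None = None
    orientation: str = "rows"  # characteristics-in-rows; the only supported one

    def __post_init__(self) -> None:
        for name, size in self.arm_sizes.items():
            if size <= 0:
                raise ValidationError(f"arm {name!r}: size must be > 0")
        for row in self.rows:
            for arm, stat in row.per_arm.items():
                count = stat.values.get("count")
                pct = stat.values.get("percent")
                if count is not None and pct is not None:
                    size = self.arm_sizes.get(arm, 0)
                    if size and abs(100.0 * count / size - pct) > 1.0:
                        raise ValidationError(
                            f"{self.study_id}/{row.label}/{arm}: count {count} and "
                            f"percent {pct} inconsistent with arm size {size}"
                        )


def _fmt(v: float) -> str:
    if float(v).is_integer():
        return str(int(v))
    return f"{v:.10g}"


def _render_stat(stat: PlannedStat) -> str:
    k, v = stat.kind, stat.values
    if k == "mean_sd":
        return f"{_fmt(v['mean'])} ± {_fmt(v['sd'])}"
    if k == "count_percent":
        return f"{int(v['count'])} ({_fmt(v['percent'])}%)"
    if k == "median_iqr":
        return f"{_fmt(v['median'])} [{_fmt(v['q1'])}–{_fmt(v['q3'])}]"
    if k == "median_range":
        return f"{_fmt(v['median'])} ({_fmt(v['low'])}–{_fmt(v['high'])})"
    if k == "count":
        return str(int(v["count"]))
    if k == "percent":
        return f"{_fmt(v['percent'])}%"
    if k == "plain_number":
        # keep a decimal point so the cell grammar does not read it as a count
        value = v["value"]
        return f"{value:.1f}" if float(value).is_integer() else _fmt(value)
    if k == "text":
        return stat.text
    raise ValidationError(f"unsupported statistic kind {stat.kind!r}")


def gen_cohort_grid(spec: CohortSpec) -> tuple[CohortGrid, dict]:
    """Render a :class:`CohortSpec` into a grid plus its ground truth.

    Sub-header rows are emitted whenever the planned ``group`` changes; arm
    sizes are written into the ``(n=…)`` column headers.  Only the
    characteristics-in-rows orientation is supported.
    """
    if spec.orientation != "rows":
        raise ValidationError(
            "transposed (characteristics-in-columns) grids are unsupported"
        )
    arm_names = list(spec.arm_sizes)
    header = ["Characteristic"] + [
        f"{name} (n={spec.arm_sizes[name]})" for name in arm_names
    ]
    cells: list[list[str]] = [header]
    subheaders: list[str] = []
    truth_rows = []
    current_group: str | None = None
    for row in spec.rows:
        if row.group and row.group != current_group:
            cells.append([row.group] + [""] * len(arm_names))
            subheaders.append(row.group)
        current_group = row.group
        label = f"{row.label} ({row.unit})" if row.unit else row.label
        rendered = [
            _render_stat(row.per_arm[name]) if name in row.per_arm else ""
            for name in arm_names
        ]
        cells.append([label] + rendered)
        truth_rows.append(
            {
                "label": label,
                "group": row.group,
                "per_arm": {
                    name: {"kind": stat.kind, "values": dict(stat.values)}
                    for name, stat in row.per_arm.items()
                },
            }
        )
    grid = CohortGrid(
        study_id=spec.study_id,
        cells=tuple(tuple(c) for c in cells),
        caption=spec.caption,
        year=spec.year,
        eligibility=spec.eligibility,
    )
    truth = {
        "study_id": spec.study_id,
        "arm_sizes": dict(spec.arm_sizes),
        "subheaders": subheaders,
        "rows": truth_rows,
    }
    return grid, truth


_LABEL_POOL = (
    # (label, unit, kind, group)
    ("Age", "years", "mean_sd", "Demographics"),
    ("Female", None, "count_percent", "Demographics"),
    ("African American", None, "count_percent", "Demographics"),
    ("BMI", "kg/m2", "mean_sd", "Demographics"),
    ("Current smoker", None, "percent", "Demographics"),
    ("HbA1c", "%", "mean_sd", "Laboratory values"),
    ("Systolic blood pressure", "mmHg", "mean_sd", "Laboratory values"),
    ("Diastolic blood pressure", "mmHg", "mean_sd", "Laboratory values"),
    ("Diabetes duration", "years", "median_iqr", "Laboratory values"),
    ("Triglycerides", "mg/dL", "median_range", "Laboratory values"),
    ("Creatinine", "mg/dL", "plain_number", "Laboratory values"),
    ("Metformin", None, "count_percent", "Medications"),
    ("Insulin", None, "count", "Medications"),
)


def _plant(rng: np.random.Generator, kind: str, arm_size: int) -> PlannedStat:
    if kind == "mean_sd":
        return PlannedStat(kind, {"mean": round(rng.uniform(5, 150), 1),
                                  "sd": round(rng.uniform(0.5, 25), 1)})
    if kind == "count_percent":
        count = int(rng.integers(0, arm_size + 1))
        return PlannedStat(kind, {"count": float(count),
                                  "percent": round(100.0 * count / arm_size, 1)})
    if kind == "median_iqr":
        q1 = round(rng.uniform(1, 50), 1)
        median = round(q1 + rng.uniform(0, 20), 1)
        q3 = round(median + rng.uniform(0, 20), 1)
        return PlannedStat(kind, {"median": median, "q1": q1, "q3": q3})
    if kind == "median_range":
        low = round(rng.uniform(1, 80), 1)
        median = round(low + rng.uniform(0, 60), 1)
        high = round(median + rng.uniform(0, 60), 1)
        return PlannedStat(kind, {"median": median, "low": low, "high": high})
    if kind == "count":
        return PlannedStat(kind, {"count": float(int(rng.integers(0, arm_size + 1)))})
    if kind == "percent":
        return PlannedStat(kind, {"percent": round(rng.uniform(0, 100), 1)})
    if kind == "plain_number":
        return PlannedStat(kind, {"value": round(rng.uniform(0.1, 9.9), 1)})
    raise ValidationError(f"unsupported statistic kind {kind!r}")


def random_cohort_spec(
    study_id: str, seed: int = DEFAULT_SEED, n_arms: int = 2, n_rows: int | None = None
) -> CohortSpec:
    """A randomized spec exercising every supported statistic kind."""
    rng = np.random.default_rng(seed)
    arm_names = [f"Arm {chr(65 + i)}" for i in range(n_arms)]
    arm_sizes = {name: int(rng.integers(50, 900)) for name in arm_names}
    pool = list(_LABEL_POOL)
    n_rows = len(pool) if n_rows is None else min(n_rows, len(pool))
    rows = []
    for label, unit, kind, group in pool[:n_rows]:
        per_arm = {
            name: _plant(rng, kind, arm_sizes[name]) for name in arm_names
        }
        rows.append(PlannedRow(label=label, per_arm=per_arm, group=group, unit=unit))
    return CohortSpec(
        study_id=study_id,
        arm_sizes=arm_sizes,
        rows=tuple(rows),
        caption=f"Baseline characteristics of study {study_id}",
        year=int(2000 + rng.integers(0, 20)),
    )


def gen_corpus(
    n_studies: int = 100,
    seed: int = DEFAULT_SEED,
    representation_prevalence: float = 0.75,
    over70_prevalence: float = 0.50,
    quality_prevalence: float = 0.06,
) -> tuple[list[CohortModel], dict]:
    """A corpus of assembled studies with planted corpus-level prevalences.

    Exactly ``round(p·n)`` studies carry each planted property: nonzero
    African-American (and female) representation; an older-adult cohort
    (mean age above 70); and "quality" size structure (total ≥ 1000 with one
    arm holding ≥ 1/3 of the total — non-quality studies are still large but
    split into four balanced arms, so no arm reaches the fraction).  Every
    study reports a metformin arm row, age, and female representation.
    Returns the models plus ground truth naming each planted set.
    """
    rng = np.random.default_rng(seed)
    lexicon = default_lexicon()
    k_rep = round(representation_prevalence * n_studies)
    k_old = round(over70_prevalence * n_studies)
    k_quality = round(quality_prevalence * n_studies)
    rep_ids = set(range(k_rep))
    old_order = rng.permutation(n_studies)
    old_ids = set(int(i) for i in old_order[:k_old])
    quality_order = rng.permutation(n_studies)
    quality_ids = set(int(i) for i in quality_order[:k_quality])

    models: list[CohortModel] = []
    truth = {"represented": [], "over70": [], "quality": [],
             "prevalences": {
                 "representation": 100.0 * k_rep / n_studies if n_studies else 0.0,
                 "over70": 100.0 * k_old / n_studies if n_studies else 0.0,
                 "quality": 100.0 * k_quality / n_studies if n_studies else 0.0,
             }}
    for i in range(n_studies):
        study_id = f"study-{i:03d}"
        if i in quality_ids:
            arm_sizes = {"Treatment": 800, "Control": 700}
        else:
            arm_sizes = {"Arm A": 300, "Arm B": 300, "Arm C": 300, "Arm D": 300}
        age_mean = round(rng.uniform(72, 80), 1) if i in old_ids else round(
            rng.uniform(48, 64), 1
        )
        rows = [
            PlannedRow(
                "Age",
                {a: PlannedStat("mean_sd", {"mean": age_mean,
                                            "sd": round(rng.uniform(4, 12), 1)})
                 for a in arm_sizes},
                group="Demographics", unit="years",
            ),
            PlannedRow(
                "Female",
                {a: _nonzero_count_percent(rng, s) for a, s in arm_sizes.items()},
                group="Demographics",
            ),
        ]
        if i in rep_ids:
            rows.append(
                PlannedRow(
                    "African American",
                    {a: _nonzero_count_percent(rng, s) for a, s in arm_sizes.items()},
                    group="Demographics",
                )
            )
        rows.append(
            PlannedRow(
                "Metformin",
                {a: _nonzero_count_percent(rng, s) for a, s in arm_sizes.items()},
                group="Medications",
            )
        )
        spec = CohortSpec(
            study_id=study_id, arm_sizes=arm_sizes, rows=tuple(rows),
            caption=f"Synthetic cohort {study_id}",
        )
        grid, _ = gen_cohort_grid(spec)
        models.append(assemble_cohort(grid, lexicon))
        if i in rep_ids:
            truth["represented"].append(study_id)
        if i in old_ids:
            truth["over70"].append(study_id)
        if i in quality_ids:
            truth["quality"].append(study_id)
    return models, truth


def _nonzero_count_percent(rng: np.random.Generator, arm_size: int) -> PlannedStat:
    count = int(rng.integers(1, arm_size))
    return PlannedStat(
        "count_percent",
        {"count": float(count), "percent": round(100.0 * count / arm_size, 1)},
    )


# --------------------------------------------------------------------------
# Guideline extracts

_AUTHOR_POOL = (
    "Adams J", "Baker L", "Chen W", "Diaz M", "Evans R", "Fischer K",
    "Garcia P", "Hughes T", "Ivanova N", "Johnson S", "Kim H", "Lopez A",
)
_VENUE_POOL = ("Diabetes Care", "NEJM", "Lancet", "BMJ", "JAMA")
_CHAPTERS = (
    "Pharmacologic Approaches to Glycemic Treatment",
    "Cardiovascular Disease and Risk Management",
)
_GRADES = ("A", "B", "C", "E")


@dataclass(frozen=True)
class ExtractBundle:
    """In-memory guideline-extract tables plus their CSV frames."""

    extracts: tuple[GuidelineExtract, ...]
    citations: tuple[Citation, ...]
    rule_links: tuple[FormalRuleLink, ...]
    frames: Mapping[str, pd.DataFrame]
    tallies: Mapping[str, int]

    def write(self, directory: str | Path) -> dict[str, Path]:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        paths = {}
        for name, frame in self.frames.items():
            path = directory / f"{name}.csv"
            frame.to_csv(path, index=False)
            paths[name] = path
        return paths


def gen_guideline_extract(
    n_recommendations: int, seed: int = DEFAULT_SEED
) -> ExtractBundle:
    """Generate a guideline-extraction spreadsheet bundle with tallies.

    Emulates the structured file scraped from a diabetes-care guideline:
    one guideline, two chapters, graded recommendations, 1–3 evidence
    sentences each citing 1–3 publications from a shared citation pool, and
    a formal-rule link for every other recommendation.
    """
    if n_recommendations < 0:
        raise ValidationError("n_recommendations must be ≥ 0")
    rng = np.random.default_rng(seed)

    n_citations = max(2, math.ceil(1.5 * n_recommendations)) if n_recommendations else 0
    citations = tuple(
        Citation(
            citation_key=f"c{i:03d}",
            title=f"Randomized trial {i:03d} of glycemic management",
            authors=tuple(
                rng.choice(_AUTHOR_POOL, size=int(rng.integers(1, 4)), replace=False)
            ),
            venue=str(_VENUE_POOL[i % len(_VENUE_POOL)]),
            year=int(1995 + (i % 25)),
            external_id=f"{38000000 + i}",
        )
        for i in range(n_citations)
    )
    keys = [c.citation_key for c in citations]

    extracts = []
    links = []
    n_sentences = 0
    for i in range(n_recommendations):
        rec_id = f"rec-{i:03d}"
        sentences = []
        for j in range(int(rng.integers(1, 4))):
            max_cites = min(3, len(keys))
            cited = tuple(
                sorted(rng.choice(keys, size=int(rng.integers(1, max_cites + 1)),
                                  replace=False))
            )
            sentences.append(
                EvidenceSentence(
                    sentence_index=j,
                    sentence_text=f"Evidence sentence {j} for {rec_id}.",
                    citations=cited,
                )
            )
        n_sentences += len(sentences)
        extracts.append(
            GuidelineExtract(
                guideline_id="cpg-2018",
                guideline_title="Standards of Medical Care in Diabetes",
                publication_year=2018,
                chapter=_CHAPTERS[i % len(_CHAPTERS)],
                recommendation_id=rec_id,
                recommendation_text=f"Recommendation {i:03d} on glycemic treatment.",
                grade=_GRADES[i % len(_GRADES)],
                disease_label="type 2 diabetes",
                disease_code="DOID:9352",
                evidence_sentences=tuple(sentences),
            )
        )
        if i % 2 == 0:
            links.append(
                FormalRuleLink(
                    rule_id=f"dmto-rule-{i:03d}",
                    recommendation_id=rec_id,
                    note=f"Treatment rule {i:03d} annotated from {rec_id}.",
                )
            )

    frames = {
        "recommendations": pd.DataFrame(
            [
                {
                    "guideline_id": e.guideline_id,
                    "guideline_title": e.guideline_title,
                    "publication_year": e.publication_year,
                    "chapter": e.chapter,
                    "recommendation_id": e.recommendation_id,
                    "recommendation_text": e.recommendation_text,
                    "grade": e.grade,
                    "disease_label": e.disease_label,
                    "disease_code": e.disease_code,
                }
                for e in extracts
            ],
            columns=[
                "guideline_id", "guideline_title", "publication_year", "chapter",
                "recommendation_id", "recommendation_text", "grade",
                "disease_label", "disease_code",
            ],
        ),
        "sentences": pd.DataFrame(
            [
                {
                    "recommendation_id": e.recommendation_id,
                    "sentence_index": s.sentence_index,
                    "sentence_text": s.sentence_text,
                    "citation_keys": ";".join(s.citations),
                }
                for e in extracts
                for s in e.evidence_sentences
            ],
            columns=["recommendation_id", "sentence_index", "sentence_text",
                     "citation_keys"],
        ),
        "citations": pd.DataFrame(
            [
                {
                    "citation_key": c.citation_key,
                    "title": c.title,
                    "authors": ";".join(c.authors),
                    "venue": c.venue,
                    "year": c.year,
                    "external_id": c.external_id,
                }
                for c in citations
            ],
            columns=["citation_key", "title", "authors", "venue", "year",
                     "external_id"],
        ),
        "rule_links": pd.DataFrame(
            [
                {"rule_id": l.rule_id, "recommendation_id": l.recommendation_id,
                 "note": l.note}
                for l in links
            ],
            columns=["rule_id", "recommendation_id", "note"],
        ),
    }
    tallies = {
        "n_recommendations": n_recommendations,
        "n_sentences": n_sentences,
        "n_citations": n_citations,
        "n_rule_links": len(links),
        "n_distinct_grades": len({e.grade for e in extracts}),
        "n_guidelines": 1 if n_recommendations else 0,
    }
    return ExtractBundle(
        extracts=tuple(extracts),
        citations=citations,
        rule_links=tuple(links),
        frames=frames,
        tallies=tallies,
    )
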