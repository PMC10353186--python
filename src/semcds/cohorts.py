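"""Cohort summary-table ("Table 1") parsing and study-cohort graphs.

A published cohort summary table reports per-arm descriptive statistics of a
study population: characteristics in rows, study arms in columns.  This
module turns such a grid into a structured study-cohort model:

1. **Sub-header detection** — a row whose label cell is non-empty while every
   arm cell is empty is a section sub-header (e.g. "Demographics"); the
   following data rows inherit it as their parent until the next sub-header.
2. **Cell grammar** — each data cell is parsed into a typed statistic
   (``mean ± sd``, ``count (percent%)``, ``median [q1–q3]``,
   ``median (low–high)``, bare percents/counts/numbers); unparseable cells
   degrade to ``text``, never to an exception.
3. **Term normalization** — characteristic labels are folded
   (case/punctuation/unit-suffix) and looked up in an exact-match
   mini-lexicon of common demographic/lab/medication/condition terms.
4. **Assembly** — arms become study-subject collections with sizes read from
   ``(n=…)`` headers or an ``N`` row; each parsed statistic is reified as its
   own node attached to the (arm, characteristic) pair, both in the Python
   model and in the emitted RDF.

The statistics are kept *reified* — a mean is a node with a value, not a
bare number — so downstream queries can ask "which arms report a standard
deviation for age?" exactly as they would against a study-cohort ontology.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence
from urllib.parse import quote

import pandas as pd
from rdflib import RDF, RDFS, Graph, Literal, Namespace, URIRef
from rdflib.namespace import XSD

from .errors import ParseError, ValidationError

SCO = Namespace("https://w3id.org/sco#")
SCO_BASE = "https://w3id.org/sco/resource/"

STAT_KINDS = (
    "mean_sd", "count_percent", "median_iqr", "median_range",
    "count", "percent", "plain_number", "text",
)

_NUM = r"[+-]?\d+(?:\.\d+)?"
_ARM_N_RE = re.compile(r"^(?P<name>.*?)\s*\(\s*n\s*=\s*(?P<n>[^)]*)\)\s*$", re.IGNORECASE)
_UNIT_RE = re.compile(r"\(([^)]*)\)\s*$")


@dataclass(frozen=True)
class StatValue:
    """One typed descriptive statistic parsed from a grid cell."""

    kind: str
    values: Mapping[str, float] = field(default_factory=dict)
    unit: str | None = None
    raw: str = ""

    def __post_init__(self) -> None:
        if self.kind not in STAT_KINDS:
            raise ValidationError(f"unknown statistic kind {self.kind!r}")

    def get(self, name: str) -> float | None:
        return self.values.get(name)


@dataclass(frozen=True)
class LexiconEntry:
    code: str
    preferred_label: str
    category: str


@dataclass(frozen=True)
class NormalizedTerm:
    surface: str
    matched: bool
    code: str | None = None
    preferred_label: str | None = None
    category: str | None = None


class TermLexicon:
    """Exact-match (after folding) surface-string → concept lexicon."""

    def __init__(self, entries: Mapping[str, LexiconEntry]):
        self.entries = dict(entries)

    def __len__(self) -> int:
        return len(self.entries)

    def lookup(self, label: str) -> LexiconEntry | None:
        return self.entries.get(fold_label(label))

    @classmethod
    def from_csv(cls, path: str | Path) -> "TermLexicon":
        frame = pd.read_csv(path, dtype=str, keep_default_na=False)
        required = ("surface", "code", "preferred_label", "category")
        missing = [c for c in required if c not in frame.columns]
        if missing:
            raise ParseError(f"{path}: missing lexicon column(s) {missing}")
        entries: dict[str, LexiconEntry] = {}
        for _, row in frame.iterrows():
            key = fold_label(row["surface"])
            if key in entries:
                raise ValidationError(f"duplicate folded lexicon surface {key!r}")
            entries[key] = LexiconEntry(
                code=row["code"],
                preferred_label=row["preferred_label"],
                category=row["category"],
            )
        return cls(entries)


def default_lexicon() -> TermLexicon:
    """The mini-lexicon shipped with the package (~40 common Table-1 terms)."""
    from importlib.resources import as_file, files

    with as_file(files("semcds").joinpath("data", "lexicon.csv")) as path:
        return TermLexicon.from_csv(path)


def fold_label(label: str) -> str:
    """Case-fold, strip parenthesized unit suffixes, normalize punctuation,
    and drop a trailing ``n``/``no.`` count marker."""
    text = label.lower()
    text = re.sub(r"\([^)]*\)", " ", text)
    text = re.sub(r"[_,./\-]+", " ", text)
    text = re.sub(r"[^a-z0-9% ]+", " ", text)
    tokens = text.split()
    while tokens and tokens[-1] in {"n", "no", "n%", "%"}:
        tokens.pop()
    return " ".join(tokens)


def normalize_term(label: str, lexicon: TermLexicon) -> NormalizedTerm:
    """Exact folded-string lookup; unmatched labels are preserved and
    flagged, never fuzzily matched."""
    entry = lexicon.lookup(label)
    if entry is None:
        return NormalizedTerm(surface=label, matched=False)
    return NormalizedTerm(
        surface=label,
        matched=True,
        code=entry.code,
        preferred_label=entry.preferred_label,
        category=entry.category,
    )


@dataclass(frozen=True)
class CohortGrid:
    """A rectangular cohort summary grid: header row, then data rows; first
    column holds characteristic labels, remaining columns hold arm cells."""

    study_id: str
    cells: tuple[tuple[str, ...], ...]
    caption: str = ""
    year: int | None = None
    citation_key: str = ""
    eligibility: Mapping[str, float] | None = None  # optional age_min/age_max

    def __post_init__(self) -> None:
        if len(self.cells) < 1:
            raise ValidationError(f"grid {self.study_id!r}: header row required")
        widths = {len(row) for row in self.cells}
        if len(widths) != 1:
            raise ValidationError(
                f"grid {self.study_id!r}: ragged rows (widths {sorted(widths)})"
            )
        if next(iter(widths)) < 2:
            raise ValidationError(f"grid {self.study_id!r}: need ≥2 columns")

    @property
    def n_arms(self) -> int:
        return len(self.cells[0]) - 1

    @classmethod
    def from_csv(cls, path: str | Path, sidecar: str | Path | None = None) -> "CohortGrid":
        path = Path(path)
        sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
        frame = pd.read_csv(path, sep=sep, header=None, dtype=str, keep_default_na=False)
        meta: dict = {"study_id": path.stem}
        if sidecar is not None:
            with open(sidecar, encoding="utf-8") as fh:
                loaded = json.load(fh)
            meta.update({k: loaded[k] for k in
                         ("study_id", "caption", "year", "citation_key", "eligibility")
                         if k in loaded})
        return cls(
            study_id=str(meta["study_id"]),
            cells=tuple(tuple(str(c).strip() for c in row) for row in frame.values),
            caption=str(meta.get("caption", "")),
            year=meta.get("year"),
            citation_key=str(meta.get("citation_key", "")),
            eligibility=meta.get("eligibility"),
        )


def _normalize_cell_text(text: str) -> str:
    """Normalize dash variants, unicode ±, and comma decimal separators."""
    text = text.strip()
    text = text.replace("–", "-").replace("—", "-").replace("−", "-")
    text = text.replace("+/-", "±")
    # European decimal comma: exactly one comma between digits, no dot present
    if text.count(",") >= 1 and "." not in text:
        text = re.sub(r"(?<=\d),(?=\d)", ".", text)
    return text


_PATTERNS = (
    ("mean_sd", re.compile(rf"^(?P<a>{_NUM})\s*±\s*(?P<b>{_NUM})$"),
     ("mean", "sd")),
    ("count_percent", re.compile(rf"^(?P<a>\d+)\s*\(\s*(?P<b>{_NUM})\s*%\s*\)$"),
     ("count", "percent")),
    ("median_iqr", re.compile(rf"^(?P<a>{_NUM})\s*\[\s*(?P<b>{_NUM})\s*-\s*(?P<c>{_NUM})\s*\]$"),
     ("median", "q1", "q3")),
    ("median_iqr", re.compile(rf"^(?P<a>{_NUM})\s*\(\s*(?P<b>{_NUM})\s*,\s*(?P<c>{_NUM})\s*\)$"),
     ("median", "q1", "q3")),
    ("median_range", re.compile(rf"^(?P<a>{_NUM})\s*\(\s*(?P<b>{_NUM})\s*-\s*(?P<c>{_NUM})\s*\)$"),
     ("median", "low", "high")),
    ("percent", re.compile(rf"^(?P<a>{_NUM})\s*%$"), ("percent",)),
)
_COUNT_HINT_RE = re.compile(rf"^(?P<a>\d+)\s*\(\s*(?P<b>{_NUM})\s*\)$")
_INT_RE = re.compile(r"^[+-]?\d+$")
_DEC_RE = re.compile(rf"^{_NUM}$")


def _stat_valid(kind: str, values: Mapping[str, float]) -> bool:
    if any(not _finite(v) for v in values.values()):
        return False
    pct = values.get("percent")
    if pct is not None and not (0.0 <= pct <= 100.0):
        return False
    if kind == "median_iqr":
        if not (values["q1"] <= values["median"] <= values["q3"]):
            return False
    if kind == "median_range":
        if not (values["low"] <= values["median"] <= values["high"]):
            return False
    return True


def _finite(v: float) -> bool:
    return v == v and v not in (float("inf"), float("-inf"))


def parse_stat_cell(text: str, percent_hint: bool = False) -> StatValue:
    """Parse one grid cell into a typed statistic; first matching grammar
    production wins; anything unparseable (or violating a statistic's sanity
    bounds) degrades to ``kind="text"``.

    ``percent_hint`` disambiguates the ``"a (b)"`` form: with a %-hint from
    the row label or column header it reads as count (percent), otherwise as
    a value with a range only when ``b`` is a dashed pair.
    """
    raw = text
    text = _normalize_cell_text(text)
    if not text:
        return StatValue(kind="text", raw=raw)

    for kind, pattern, names in _PATTERNS:
        m = pattern.match(text)
        if m:
            values = {n: float(m.group(g)) for n, g in zip(names, "abc")}
            if _stat_valid(kind, values):
                return StatValue(kind=kind, values=values, raw=raw)
            return StatValue(kind="text", raw=raw)
    if percent_hint:
        m = _COUNT_HINT_RE.match(text)
        if m:
            values = {"count": float(m.group("a")), "percent": float(m.group("b"))}
            if _stat_valid("count_percent", values):
                return StatValue(kind="count_percent", values=values, raw=raw)
            return StatValue(kind="text", raw=raw)
    if _INT_RE.match(text):
        return StatValue(kind="count", values={"count": float(text)}, raw=raw)
    if _DEC_RE.match(text):
        return StatValue(kind="plain_number", values={"value": float(text)}, raw=raw)
    return StatValue(kind="text", raw=raw)


def detect_subheaders(grid: CohortGrid) -> list[int]:
    """Row indices (into ``grid.cells``) of section sub-headers: non-empty
    label cell, all arm cells empty.  The header row is never a sub-header."""
    out = []
    for i, row in enumerate(grid.cells[1:], start=1):
        if row[0].strip() and all(not c.strip() for c in row[1:]):
            out.append(i)
    return out


@dataclass(frozen=True)
class CharacteristicSummary:
    name: str
    normalized: NormalizedTerm
    parent: str | None
    unit: str | None
    stats: Mapping[str, StatValue]  # arm name → statistic


@dataclass(frozen=True)
class StudyArm:
    study_id: str
    arm_name: str
    size: int
    characteristics: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.size < 0:
            raise ValidationError(
                f"arm {self.arm_name!r} of {self.study_id!r}: negative size"
            )


@dataclass(frozen=True)
class CohortModel:
    """Assembled study: arms plus characteristic summaries with reified
    per-arm statistics."""

    study_id: str
    caption: str
    arms: tuple[StudyArm, ...]
    characteristics: tuple[CharacteristicSummary, ...]
    year: int | None = None
    citation_key: str = ""
    eligibility: Mapping[str, float] | None = None

    def arm(self, arm_name: str) -> StudyArm:
        for arm in self.arms:
            if arm.arm_name == arm_name:
                return arm
        raise ValidationError(f"no arm {arm_name!r} in study {self.study_id!r}")

    def arm_stats(self, arm_name: str) -> dict[str, tuple[CharacteristicSummary, StatValue]]:
        """Per-characteristic statistics for one arm, keyed by lexicon code
        when matched, else by folded label."""
        self.arm(arm_name)
        out: dict[str, tuple[CharacteristicSummary, StatValue]] = {}
        for char in self.characteristics:
            stat = char.stats.get(arm_name)
            if stat is None:
                continue
            key = char.normalized.code if char.normalized.matched else fold_label(char.name)
            out.setdefault(key, (char, stat))
        return out

    @property
    def total_size(self) -> int:
        return sum(a.size for a in self.arms)

    def to_dict(self) -> dict:
        return {
            "study_id": self.study_id,
            "caption": self.caption,
            "year": self.year,
            "citation_key": self.citation_key,
            "eligibility": dict(self.eligibility) if self.eligibility else None,
            "arms": [
                {"arm_name": a.arm_name, "size": a.size,
                 "characteristics": list(a.characteristics)}
                for a in self.arms
            ],
            "characteristics": [
                {
                    "name": c.name,
                    "parent": c.parent,
                    "unit": c.unit,
                    "code": c.normalized.code,
                    "matched": c.normalized.matched,
                    "category": c.normalized.category,
                    "stats": {
                        arm: {"kind": s.kind, "values": dict(s.values), "raw": s.raw}
                        for arm, s in c.stats.items()
                    },
                }
                for c in self.characteristics
            ],
        }


def _parse_arm_header(cell: str, where: str) -> tuple[str, int | None]:
    m = _ARM_N_RE.match(cell)
    if not m:
        return cell.strip(), None
    name = m.group("name").strip() or cell.strip()
    raw_n = m.group("n").strip().replace(",", "").replace(" ", "")
    if not raw_n.isdigit():
        raise ValidationError(f"{where}: non-numeric arm size {m.group('n')!r}")
    return name, int(raw_n)


def _extract_unit(label: str) -> str | None:
    m = _UNIT_RE.search(label.strip())
    if m:
        unit = m.group(1).strip()
        return unit or None
    return None


def assemble_cohort(grid: CohortGrid, lexicon: TermLexicon | None = None) -> CohortModel:
    """Assemble a validated grid into a study-cohort model.

    One arm per data column (sizes from ``(n=…)`` headers or an ``N`` row),
    one characteristic per non-sub-header data row, one typed statistic per
    non-empty data cell.  Every non-empty cell survives, either as a typed
    statistic or as a flagged text value (losslessness).
    """
    lexicon = lexicon if lexicon is not None else default_lexicon()
    header = grid.cells[0]
    arm_names: list[str] = []
    arm_sizes: dict[str, int] = {}
    for j, cell in enumerate(header[1:], start=1):
        name, size = _parse_arm_header(cell, f"{grid.study_id} header column {j}")
        if name in arm_names:
            raise ValidationError(f"{grid.study_id}: duplicate arm name {name!r}")
        arm_names.append(name)
        if size is not None:
            arm_sizes[name] = size

    subheaders = set(detect_subheaders(grid))
    parent: str | None = None
    characteristics: list[CharacteristicSummary] = []
    for i, row in enumerate(grid.cells[1:], start=1):
        label = row[0].strip()
        if i in subheaders:
            parent = label
            continue
        if not label and all(not c.strip() for c in row[1:]):
            continue  # fully blank spacer row
        if not label:
            label = f"row {i}"
        if _is_size_row(label, row[1:]):
            for name, cell in zip(arm_names, row[1:]):
                if name not in arm_sizes and cell.strip():
                    arm_sizes[name] = int(cell.strip())
            continue
        percent_hint = "%" in label
        unit = _extract_unit(label)
        stats = {
            name: parse_stat_cell(cell, percent_hint=percent_hint)
            for name, cell in zip(arm_names, row[1:])
            if cell.strip()
        }
        if unit:
            stats = {
                name: StatValue(kind=s.kind, values=s.values, unit=unit, raw=s.raw)
                for name, s in stats.items()
            }
        characteristics.append(
            CharacteristicSummary(
                name=label,
                normalized=normalize_term(label, lexicon),
                parent=parent,
                unit=unit,
                stats=stats,
            )
        )

    arms = tuple(
        StudyArm(
            study_id=grid.study_id,
            arm_name=name,
            size=arm_sizes.get(name, 0),
            characteristics=tuple(c.name for c in characteristics if name in c.stats),
        )
        for name in arm_names
    )
    return CohortModel(
        study_id=grid.study_id,
        caption=grid.caption,
        arms=arms,
        characteristics=tuple(characteristics),
        year=grid.year,
        citation_key=grid.citation_key,
        eligibility=grid.eligibility,
    )


def _is_size_row(label: str, cells: Sequence[str]) -> bool:
    key = label.strip().lower().rstrip(".")
    if key not in {"n", "n=", "no", "number of subjects", "number of participants"}:
        return False
    filled = [c.strip() for c in cells if c.strip()]
    return bool(filled) and all(c.isdigit() for c in filled)


_STAT_NODE_MAP = {
    "mean": ("Mean", "mean"),
    "sd": ("StandardDeviation", "sd"),
    "median": ("Median", "median"),
    "count": ("Count", "count"),
    "percent": ("Percent", "percent"),
    "value": ("Value", "value"),
}


def _sco_iri(*parts: str) -> URIRef:
    return URIRef(SCO_BASE + "/".join(quote(str(p), safe="") for p in parts))


def cohort_to_rdf(model: CohortModel) -> Graph:
    """Emit the arm → characteristic → reified-statistic RDF shape.

    Arms are ``sco:StudySubjectCollection`` nodes; each (arm, characteristic)
    pair gets a ``sco:Characteristic`` node whose statistics are individual
    typed nodes (``sco:Mean``, ``sco:StandardDeviation``, ``sco:Median``,
    ``sco:InterquartileRange``, ``sco:Range``, ``sco:Count``,
    ``sco:Percent``) carrying ``sco:value`` (or lower/upper bounds).
    """
    g = Graph()
    g.bind("sco", SCO)
    g.bind("rdfs", RDFS)
    study = _sco_iri("study", model.study_id)
    g.add((study, RDF.type, SCO.Study))
    if model.caption:
        g.add((study, RDFS.label, Literal(model.caption)))

    for arm in model.arms:
        a = _sco_iri("study", model.study_id, "arm", arm.arm_name)
        g.add((a, RDF.type, SCO.StudySubjectCollection))
        g.add((a, RDFS.label, Literal(arm.arm_name)))
        g.add((a, SCO.size, Literal(arm.size, datatype=XSD.integer)))
        g.add((study, SCO.hasArm, a))

    for char in model.characteristics:
        for arm_name, stat in char.stats.items():
            a = _sco_iri("study", model.study_id, "arm", arm_name)
            c = _sco_iri("study", model.study_id, "arm", arm_name,
                         "characteristic", char.name)
            g.add((c, RDF.type, SCO.Characteristic))
            g.add((c, RDFS.label, Literal(char.name)))
            if char.normalized.matched:
                g.add((c, SCO.code, Literal(char.normalized.code)))
            if char.unit:
                g.add((c, SCO.unit, Literal(char.unit)))
            g.add((a, SCO.hasCharacteristic, c))
            _add_stat_nodes(g, c, stat)
    return g


def _add_stat_nodes(g: Graph, char_node: URIRef, stat: StatValue) -> None:
    if stat.kind == "text":
        g.add((char_node, SCO.textValue, Literal(stat.raw)))
        return
    for name, value in stat.values.items():
        if name in ("q1", "q3", "low", "high"):
            continue
        cls, local = _STAT_NODE_MAP[name]
        node = URIRef(str(char_node) + "/stat/" + local)
        g.add((node, RDF.type, SCO[cls]))
        g.add((node, SCO.value, Literal(value, datatype=XSD.double)))
        g.add((char_node, SCO.hasStatistic, node))
    if stat.kind == "median_iqr":
        node = URIRef(str(char_node) + "/stat/iqr")
        g.add((node, RDF.type, SCO.InterquartileRange))
        g.add((node, SCO.lowerBound, Literal(stat.values["q1"], datatype=XSD.double)))
        g.add((node, SCO.upperBound, Literal(stat.values["q3"], datatype=XSD.double)))
        g.add((char_node, SCO.hasStatistic, node))
    if stat.kind == "median_range":
        node = URIRef(str(char_node) + "/stat/range")
        g.add((node, RDF.type, SCO.Range))
        g.add((node, SCO.lowerBound, Literal(stat.values["low"], datatype=XSD.double)))
        g.add((node, SCO.upperBound, Literal(stat.values["high"], datatype=XSD.double)))
        g.add((char_node, SCO.hasStatistic, node))
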