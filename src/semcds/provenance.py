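"""Guideline-provenance knowledge graphs.

Builds a typed RDF graph linking clinical-decision rules to the guideline
recommendations they derive from, and those recommendations to their
evidence sentences, cited publications, authors, grades, and the managed
disease.  The graph answers the three provenance competency questions a
point-of-care user asks of a decision-support suggestion:

* *Where does this treatment suggestion come from?* — follow
  ``prov:wasDerivedFrom`` from the formal rule to its recommendation(s) and
  their containing guideline/chapter (:func:`query_source_of`).
* *Which research publications support the recommendation?* — collect the
  citations reachable through evidence sentences (:func:`query_evidence_for`).
* *How recent is this recommendation?* — the publication year(s) of the
  guideline edition(s) containing it (:func:`query_recency`).

IRIs are minted deterministically from stable identifiers, so repeated
builds of the same extract are bit-identical and never contain blank nodes.
Answers carry one of nine fixed explanation-type labels; citation-backed
answers are ``scientific``, staging traces are ``trace-based``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence
from urllib.parse import quote

import pandas as pd
from rdflib import RDF, RDFS, Graph, Literal, Namespace, URIRef
from rdflib.compare import isomorphic
from rdflib.namespace import DCTERMS, XSD

from .errors import NotFoundError, ParseError, ValidationError, VocabularyError
from .staging import StagingResult

GPROV = Namespace("https://w3id.org/gprov#")
PROV = Namespace("http://www.w3.org/ns/prov#")
BIBO = Namespace("http://purl.org/ontology/bibo/")
DCT = DCTERMS
BASE = "https://w3id.org/gprov/resource/"

EXPLANATION_TYPES = (
    "case-based",
    "contextual",
    "contrastive",
    "counterfactual",
    "everyday",
    "scientific",
    "simulation-based",
    "statistical",
    "trace-based",
)

_REC_COLUMNS = (
    "guideline_id", "guideline_title", "publication_year", "chapter",
    "recommendation_id", "recommendation_text", "grade",
    "disease_label", "disease_code",
)
_SENT_COLUMNS = ("recommendation_id", "sentence_index", "sentence_text", "citation_keys")
_CIT_COLUMNS = ("citation_key", "title", "authors", "venue", "year", "external_id")
_LINK_COLUMNS = ("rule_id", "recommendation_id", "note")


@dataclass(frozen=True)
class EvidenceSentence:
    sentence_index: int
    sentence_text: str
    citations: tuple[str, ...]


@dataclass(frozen=True)
class GuidelineExtract:
    """One extracted recommendation with its guideline context and evidence."""

    guideline_id: str
    guideline_title: str
    publication_year: int | None
    chapter: str
    recommendation_id: str
    recommendation_text: str
    grade: str
    disease_label: str = ""
    disease_code: str = ""
    evidence_sentences: tuple[EvidenceSentence, ...] = ()


@dataclass(frozen=True)
class Citation:
    citation_key: str
    title: str
    authors: tuple[str, ...]
    venue: str = ""
    year: int | None = None
    external_id: str = ""

    def __post_init__(self) -> None:
        if not self.authors:
            raise ValidationError(
                f"citation {self.citation_key!r} has no authors; "
                "every published document has at least one author"
            )


@dataclass(frozen=True)
class FormalRuleLink:
    rule_id: str
    recommendation_id: str
    note: str = ""


@dataclass(frozen=True)
class ExplanationLabel:
    label: str
    subject_id: str
    rationale: str = ""

    def __post_init__(self) -> None:
        if self.label not in EXPLANATION_TYPES:
            raise VocabularyError(
                f"unknown explanation type {self.label!r}; "
                f"expected one of {EXPLANATION_TYPES}"
            )


def _read_csv(path: Path, required: Sequence[str]) -> pd.DataFrame:
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise ParseError(f"{path}: missing required column(s) {missing}")
    return frame


def _opt_int(raw: str, where: str) -> int | None:
    raw = raw.strip()
    if not raw:
        return None
    try:
        return int(raw)
    except ValueError:
        raise ParseError(f"{where}: not an integer year: {raw!r}")


def load_extract(
    directory: str | Path,
) -> tuple[list[GuidelineExtract], list[Citation]]:
    """Load ``recommendations.csv``, ``sentences.csv`` and ``citations.csv``
    from a directory and resolve all cross-references.

    Raises :class:`ParseError` on missing columns, :class:`ValidationError`
    on a duplicate recommendation id within a guideline or a sentence citing
    an unknown citation key.
    """
    directory = Path(directory)
    recs = _read_csv(directory / "recommendations.csv", _REC_COLUMNS)
    sents = _read_csv(directory / "sentences.csv", _SENT_COLUMNS)
    cits = _read_csv(directory / "citations.csv", _CIT_COLUMNS)

    citations: dict[str, Citation] = {}
    for _, row in cits.iterrows():
        key = row["citation_key"].strip()
        if key in citations:
            raise ValidationError(f"duplicate citation_key {key!r}")
        citations[key] = Citation(
            citation_key=key,
            title=row["title"],
            authors=tuple(a.strip() for a in row["authors"].split(";") if a.strip()),
            venue=row["venue"],
            year=_opt_int(row["year"], f"citations.csv key {key}"),
            external_id=row["external_id"],
        )

    sentences: dict[str, list[EvidenceSentence]] = {}
    for _, row in sents.iterrows():
        rec_id = row["recommendation_id"].strip()
        keys = tuple(k.strip() for k in row["citation_keys"].split(";") if k.strip())
        for key in keys:
            if key not in citations:
                raise ValidationError(
                    f"sentence for recommendation {rec_id!r} cites unknown "
                    f"citation key {key!r}"
                )
        sentences.setdefault(rec_id, []).append(
            EvidenceSentence(
                sentence_index=int(row["sentence_index"]),
                sentence_text=row["sentence_text"],
                citations=keys,
            )
        )

    extracts: list[GuidelineExtract] = []
    seen: set[tuple[str, str]] = set()
    for _, row in recs.iterrows():
        rec_id = row["recommendation_id"].strip()
        key = (row["guideline_id"].strip(), rec_id)
        if key in seen:
            raise ValidationError(
                f"duplicate recommendation_id {rec_id!r} in guideline {key[0]!r}"
            )
        seen.add(key)
        extracts.append(
            GuidelineExtract(
                guideline_id=key[0],
                guideline_title=row["guideline_title"],
                publication_year=_opt_int(
                    row["publication_year"], f"recommendation {rec_id}"
                ),
                chapter=row["chapter"],
                recommendation_id=rec_id,
                recommendation_text=row["recommendation_text"],
                grade=row["grade"].strip(),
                disease_label=row["disease_label"],
                disease_code=row["disease_code"],
                evidence_sentences=tuple(
                    sorted(sentences.get(rec_id, []), key=lambda s: s.sentence_index)
                ),
            )
        )
    return extracts, list(citations.values())


def load_rule_links(path: str | Path) -> list[FormalRuleLink]:
    frame = _read_csv(Path(path), _LINK_COLUMNS)
    return [
        FormalRuleLink(row["rule_id"].strip(), row["recommendation_id"].strip(), row["note"])
        for _, row in frame.iterrows()
    ]


def _iri(kind: str, *parts: str) -> URIRef:
    safe = "/".join(quote(str(p), safe="") for p in parts)
    return URIRef(f"{BASE}{kind}/{safe}")


def _fold_author(name: str) -> str:
    return " ".join(name.lower().replace(",", " ").replace(".", " ").split())


@dataclass
class ProvenanceGraph:
    """A built provenance graph plus the id→IRI indexes queries traverse."""

    graph: Graph = field(default_factory=Graph)

    def __post_init__(self) -> None:
        self.graph.bind("gprov", GPROV)
        self.graph.bind("prov", PROV)
        self.graph.bind("bibo", BIBO)
        self.graph.bind("dct", DCT)
        self.graph.bind("rdfs", RDFS)

    def __len__(self) -> int:
        return len(self.graph)

    def serialize(self, destination: str | Path | None = None) -> str:
        data = self.graph.serialize(format="turtle")
        if destination is not None:
            Path(destination).write_text(data, encoding="utf-8")
        return data

    @classmethod
    def parse(cls, source: str | Path) -> "ProvenanceGraph":
        pg = cls()
        pg.graph.parse(source, format="turtle")
        return pg

    def isomorphic_to(self, other: "ProvenanceGraph") -> bool:
        return isomorphic(self.graph, other.graph)

    def node_counts(self) -> dict[str, int]:
        """Instances per node class, by local class name."""
        counts: dict[str, int] = {}
        for cls in ("Guideline", "Recommendation", "FormalRule", "EvidenceSentence",
                    "Citation", "Grade", "DiseaseManagement"):
            counts[cls] = sum(1 for _ in self.graph.subjects(RDF.type, GPROV[cls]))
        counts["Author"] = sum(1 for _ in self.graph.subjects(RDF.type, BIBO.Author))
        return counts

    def arc_count(self, predicate: URIRef) -> int:
        return sum(1 for _ in self.graph.triples((None, predicate, None)))


def build_graph(
    extracts: Iterable[GuidelineExtract],
    citations: Iterable[Citation],
    rule_links: Iterable[FormalRuleLink] = (),
) -> ProvenanceGraph:
    """Convert validated extract tables into a provenance graph.

    Node counts are deterministic functions of the input: one ``Guideline``
    per guideline id, one ``Recommendation`` per recommendation id, one
    ``EvidenceSentence`` per sentence, one ``Citation`` per citation record,
    one ``Grade`` per distinct grade code, one ``Author`` per distinct
    (case/punctuation-folded) author name, one ``DiseaseManagement`` per
    (guideline, disease) pair, and ``prov:wasDerivedFrom`` arcs equal to the
    number of rule links.
    """
    extracts = list(extracts)
    citations = list(citations)
    rule_links = list(rule_links)

    pg = ProvenanceGraph()
    g = pg.graph

    rec_ids = {e.recommendation_id for e in extracts}
    for link in rule_links:
        if link.recommendation_id not in rec_ids:
            raise ValidationError(
                f"rule link {link.rule_id!r} targets unknown recommendation "
                f"{link.recommendation_id!r}"
            )

    for cit in citations:
        c = _iri("citation", cit.citation_key)
        g.add((c, RDF.type, GPROV.Citation))
        g.add((c, DCT.identifier, Literal(cit.citation_key)))
        g.add((c, DCT.title, Literal(cit.title)))
        if cit.venue:
            g.add((c, DCT.source, Literal(cit.venue)))
        if cit.year is not None:
            g.add((c, DCT.date, Literal(cit.year, datatype=XSD.gYear)))
        if cit.external_id:
            g.add((c, BIBO.pmid, Literal(cit.external_id)))
        for name in cit.authors:
            a = _iri("author", _fold_author(name))
            g.add((a, RDF.type, BIBO.Author))
            g.add((a, RDFS.label, Literal(name)))
            g.add((c, DCT.creator, a))

    for ext in extracts:
        gl = _iri("guideline", ext.guideline_id)
        g.add((gl, RDF.type, GPROV.Guideline))
        g.add((gl, DCT.title, Literal(ext.guideline_title)))
        if ext.publication_year is not None:
            g.add((gl, GPROV.publicationYear, Literal(ext.publication_year)))
        if ext.disease_label:
            dm = _iri("disease-management", ext.guideline_id, ext.disease_label.lower())
            g.add((dm, RDF.type, GPROV.DiseaseManagement))
            g.add((dm, RDFS.label, Literal(ext.disease_label)))
            if ext.disease_code:
                g.add((dm, DCT.identifier, Literal(ext.disease_code)))
            g.add((gl, PROV.used, dm))

        rec = _iri("recommendation", ext.recommendation_id)
        g.add((rec, RDF.type, GPROV.Recommendation))
        g.add((rec, DCT.identifier, Literal(ext.recommendation_id)))
        g.add((rec, DCT.description, Literal(ext.recommendation_text)))
        g.add((rec, DCT.isPartOf, gl))
        if ext.chapter:
            g.add((rec, GPROV.chapter, Literal(ext.chapter)))
        if ext.grade:
            gr = _iri("grade", ext.grade)
            g.add((gr, RDF.type, GPROV.Grade))
            g.add((gr, RDFS.label, Literal(ext.grade)))
            g.add((rec, GPROV.hasGrade, gr))

        for sent in ext.evidence_sentences:
            s = _iri("sentence", ext.recommendation_id, str(sent.sentence_index))
            g.add((s, RDF.type, GPROV.EvidenceSentence))
            g.add((s, DCT.description, Literal(sent.sentence_text)))
            g.add((rec, GPROV.hasEvidenceSentence, s))
            for key in sent.citations:
                g.add((s, PROV.hasPrimarySource, _iri("citation", key)))

    for link in rule_links:
        r = _iri("rule", link.rule_id)
        g.add((r, RDF.type, GPROV.FormalRule))
        g.add((r, DCT.identifier, Literal(link.rule_id)))
        g.add((r, PROV.wasDerivedFrom, _iri("recommendation", link.recommendation_id)))
        if link.note:
            g.add((r, RDFS.comment, Literal(link.note)))
    return pg


def expected_counts(
    extracts: Iterable[GuidelineExtract],
    citations: Iterable[Citation],
    rule_links: Iterable[FormalRuleLink] = (),
) -> dict[str, int]:
    """Closed-form node/arc/triple counts implied by the build contract.

    Computed by arithmetic over the input collections, independently of any
    RDF machinery, so it can serve as an oracle against the built graph.
    """
    extracts = list(extracts)
    citations = list(citations)
    rule_links = list(rule_links)

    guidelines: dict[str, GuidelineExtract] = {}
    dm_pairs: set[tuple[str, str]] = set()
    grades: set[str] = set()
    rec_ids: set[str] = set()
    n_sentences = 0
    n_sentence_citation_arcs = 0
    n_rec_triples = 0
    for ext in extracts:
        guidelines.setdefault(ext.guideline_id, ext)
        if ext.disease_label:
            dm_pairs.add((ext.guideline_id, ext.disease_label.lower()))
        if ext.grade:
            grades.add(ext.grade)
        rec_ids.add(ext.recommendation_id)
        n_sentences += len(ext.evidence_sentences)
        n_sentence_citation_arcs += sum(len(s.citations) for s in ext.evidence_sentences)
        # per-recommendation triples: type+id+text+isPartOf (+chapter)(+grade arc)
        n_rec_triples += 4 + (1 if ext.chapter else 0) + (1 if ext.grade else 0)

    authors: set[str] = set()
    n_cit_triples = 0
    for cit in citations:
        authors.update(_fold_author(a) for a in cit.authors)
        n_cit_triples += (
            3
            + (1 if cit.venue else 0)
            + (1 if cit.year is not None else 0)
            + (1 if cit.external_id else 0)
            + len(cit.authors)  # dct:creator arcs
        )

    n_guideline_triples = sum(
        2 + (1 if e.publication_year is not None else 0)
        for e in guidelines.values()
    ) + len(dm_pairs)  # prov:used arcs
    n_dm_triples = sum(
        2 + (1 if _dm_has_code(extracts, gid, dl) else 0) for gid, dl in dm_pairs
    )
    rules = {l.rule_id for l in rule_links}
    n_rule_triples = 2 * len(rules) + len(rule_links) + sum(
        1 for l in rule_links if l.note
    )

    counts = {
        "Guideline": len(guidelines),
        "Recommendation": len(rec_ids),
        "FormalRule": len(rules),
        "EvidenceSentence": n_sentences,
        "Citation": len(citations),
        "Grade": len(grades),
        "DiseaseManagement": len(dm_pairs),
        "Author": len(authors),
        "wasDerivedFrom_arcs": len(rule_links),
        "hasPrimarySource_arcs": n_sentence_citation_arcs,
    }
    counts["triples"] = (
        n_guideline_triples
        + n_dm_triples
        + n_rec_triples
        + 2 * len(grades)
        + 3 * n_sentences  # type + text + hasEvidenceSentence arc
        + n_sentence_citation_arcs
        + n_cit_triples
        + 2 * len(authors)
        + n_rule_triples
    )
    return counts


def _dm_has_code(extracts, guideline_id: str, disease_lower: str) -> bool:
    return any(
        e.guideline_id == guideline_id
        and e.disease_label.lower() == disease_lower
        and e.disease_code
        for e in extracts
    )


def _require(node_iter, what: str, key: str):
    nodes = sorted(set(node_iter))
    if not nodes:
        raise NotFoundError(f"unknown {what} {key!r}")
    return nodes


def query_source_of(pg: ProvenanceGraph, rule_id: str) -> list[dict]:
    """Answer *where does this treatment suggestion come from?* for a rule.

    Returns one entry per linked recommendation (a rule may derive from
    several), order-stable by recommendation id.
    """
    g = pg.graph
    rule = _iri("rule", rule_id)
    recs = _require(g.objects(rule, PROV.wasDerivedFrom), "rule", rule_id)
    answers = []
    for rec in recs:
        guideline = next(g.objects(rec, DCT.isPartOf), None)
        answers.append(
            {
                "recommendation_id": str(next(g.objects(rec, DCT.identifier), "")),
                "recommendation_text": str(next(g.objects(rec, DCT.description), "")),
                "chapter": str(next(g.objects(rec, GPROV.chapter), "")),
                "guideline_title": (
                    str(next(g.objects(guideline, DCT.title), "")) if guideline else ""
                ),
                "explanation_type": "trace-based",
            }
        )
    return sorted(answers, key=lambda a: a["recommendation_id"])


def query_evidence_for(pg: ProvenanceGraph, recommendation_id: str) -> dict:
    """Answer *which research publications support the recommendation?*

    Citations are de-duplicated across evidence sentences and sorted by
    citation key; the recommendation's grade rides along.  A recommendation
    with no evidence sentences yields an empty citation list.
    """
    g = pg.graph
    rec = _iri("recommendation", recommendation_id)
    if (rec, RDF.type, GPROV.Recommendation) not in g:
        raise NotFoundError(f"unknown recommendation {recommendation_id!r}")
    grade_node = next(g.objects(rec, GPROV.hasGrade), None)
    grade = str(next(g.objects(grade_node, RDFS.label), "")) if grade_node else ""

    seen: dict[str, dict] = {}
    for sent in g.objects(rec, GPROV.hasEvidenceSentence):
        for cit in g.objects(sent, PROV.hasPrimarySource):
            key = str(next(g.objects(cit, DCT.identifier), ""))
            if key in seen:
                continue
            seen[key] = {
                "citation_key": key,
                "title": str(next(g.objects(cit, DCT.title), "")),
                "authors": sorted(str(l) for l in _author_labels(g, cit)),
                "venue": str(next(g.objects(cit, DCT.source), "")),
                "year": _literal_int(next(g.objects(cit, DCT.date), None)),
                "external_id": str(next(g.objects(cit, BIBO.pmid), "")),
            }
    return {
        "recommendation_id": recommendation_id,
        "grade": grade,
        "citations": [seen[k] for k in sorted(seen)],
        "explanation_type": "scientific",
    }


def _author_labels(g: Graph, citation) -> Iterable[Literal]:
    for author in g.objects(citation, DCT.creator):
        yield from g.objects(author, RDFS.label)


def _literal_int(lit) -> int | None:
    if lit is None:
        return None
    try:
        return int(str(lit))
    except ValueError:
        return None


def query_recency(pg: ProvenanceGraph, recommendation_id: str) -> dict:
    """Answer *how recent is this recommendation?*

    Returns the publication years of every guideline edition containing the
    recommendation, descending.  A containing guideline without a recorded
    year yields the ``"unknown"`` recency marker rather than an exception.
    """
    g = pg.graph
    rec = _iri("recommendation", recommendation_id)
    if (rec, RDF.type, GPROV.Recommendation) not in g:
        raise NotFoundError(f"unknown recommendation {recommendation_id!r}")
    years: list[int] = []
    for guideline in g.objects(rec, DCT.isPartOf):
        year = _literal_int(next(g.objects(guideline, GPROV.publicationYear), None))
        if year is not None:
            years.append(year)
    years = sorted(set(years), reverse=True)
    return {
        "recommendation_id": recommendation_id,
        "years": years,
        "recency": years[0] if years else "unknown",
    }


def tag_explanation(
    pg: ProvenanceGraph, subject_id: str, label: str, rationale: str = ""
) -> ExplanationLabel:
    """Attach one of the nine explanation-type labels to a graph node.

    ``subject_id`` may be a full IRI or a minted id (recommendation, rule or
    citation); the node must already exist in the graph.
    """
    tag = ExplanationLabel(label=label, subject_id=subject_id, rationale=rationale)
    g = pg.graph
    node = URIRef(subject_id) if subject_id.startswith("http") else None
    if node is None:
        for kind in ("recommendation", "rule", "citation", "guideline"):
            candidate = _iri(kind, subject_id)
            if (candidate, None, None) in g:
                node = candidate
                break
    if node is None or (node, None, None) not in g:
        raise NotFoundError(f"no graph node for subject {subject_id!r}")
    g.add((node, GPROV.explanationType, Literal(label)))
    if rationale:
        g.add((node, GPROV.explanationRationale, Literal(rationale)))
    return tag


def explanations_of(pg: ProvenanceGraph, subject_id: str) -> list[str]:
    g = pg.graph
    node = URIRef(subject_id) if subject_id.startswith("http") else None
    if node is None:
        for kind in ("recommendation", "rule", "citation", "guideline"):
            candidate = _iri(kind, subject_id)
            if (candidate, None, None) in g:
                node = candidate
                break
    if node is None:
        return []
    return sorted(str(l) for l in g.objects(node, GPROV.explanationType))


def explanation_for_result(result: StagingResult) -> ExplanationLabel:
    """Staging traces are trace-based explanations by construction."""
    return ExplanationLabel(
        label="trace-based",
        subject_id=result.rule_id,
        rationale="; ".join(result.explanation),
    )
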