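"""Abstract ingestion, sentence splitting and the document-centric schema.

A :class:`Document` holds exactly one title and any number of sentences,
entity mentions and relations.  Sentences carry character offsets into the
concatenated title+abstract text (0-based, half-open, Unicode code points)
so that evidence text can always be recovered by slicing.  Documents
serialize to a JSON dialect, one document per line for corpora.
"""

from __future__ import annotations

import csv
import io
import json
import logging
import re
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field, asdict
from typing import Iterable, Iterator, List, Optional, TextIO, Union

logger = logging.getLogger(__name__)

__all__ = [
    "Sentence",
    "EntityMention",
    "Relation",
    "Document",
    "ValidationError",
    "read_abstracts",
    "split_sentences",
    "serialize_document",
    "deserialize_document",
    "write_corpus",
    "read_corpus",
    "relations_to_csv",
]

# Entity classes used across the package.
MIRNA = "MIRNA"
GENE = "GENE"
DISEASE = "DISEASE"
PROCESS = "PROCESS"
FLUID = "FLUID"
TRANSPORTER = "TRANSPORTER"

ENTITY_CLASSES = (MIRNA, GENE, DISEASE, PROCESS, FLUID, TRANSPORTER)

# Relation families.
FAMILY_TARGET = "mirna_target"
FAMILY_GENE = "mirna_gene"
FAMILY_GENE_MIRNA = "gene_mirna"
FAMILY_PROCESS = "mirna_process"
FAMILY_DISEASE_ROLE = "disease_role"
FAMILY_DIFFEXPR = "diffexpr"
FAMILY_EXTRACELLULAR = "extracellular"

RELATION_FAMILIES = (
    FAMILY_TARGET,
    FAMILY_GENE,
    FAMILY_GENE_MIRNA,
    FAMILY_PROCESS,
    FAMILY_DISEASE_ROLE,
    FAMILY_DIFFEXPR,
    FAMILY_EXTRACELLULAR,
)


class ValidationError(ValueError):
    """Raised when a record violates the document schema."""


@dataclass
class Sentence:
    """A sentence span inside the concatenated title+abstract text."""

    index: int
    text: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValidationError(
                f"sentence {self.index}: end ({self.end}) must exceed start ({self.start})"
            )


@dataclass
class EntityMention:
    """A typed, offset-anchored, normalized span inside one sentence.

    Offsets are relative to the sentence text (0-based, half-open).
    ``canonical_id`` may be empty only when ``"unmapped"`` is in ``flags``.
    """

    id: str
    entity_class: str
    sentence_index: int
    start: int
    end: int
    surface: str
    canonical_id: str = ""
    flags: List[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.entity_class not in ENTITY_CLASSES:
            raise ValidationError(f"unknown entity class: {self.entity_class!r}")
        if not (0 <= self.start < self.end):
            raise ValidationError(
                f"mention {self.id}: bad offsets [{self.start}, {self.end})"
            )
        if not self.canonical_id and "unmapped" not in self.flags:
            raise ValidationError(
                f"mention {self.id}: empty canonical_id without 'unmapped' flag"
            )


@dataclass
class Relation:
    """A family-tagged relation over mention ids with sentence provenance.

    ``tag`` carries the family-specific label (polarity, role or
    direction); ``attrs`` carries free-form extras such as descriptor
    strings or provenance tags.
    """

    id: str
    family: str
    mirna_id: str
    partner_id: str
    partner_canonical: str
    tag: str
    sentence_index: int
    rule_id: str = ""
    evidence: str = ""
    attrs: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.family not in RELATION_FAMILIES:
            raise ValidationError(f"unknown relation family: {self.family!r}")


@dataclass
class Document:
    """One abstract: one title, many sentences, entities and relations."""

    pmid: str
    title: str
    sentences: List[Sentence] = field(default_factory=list)
    entities: List[EntityMention] = field(default_factory=list)
    relations: List[Relation] = field(default_factory=list)

    def validate(self) -> "Document":
        if not isinstance(self.title, str):
            raise ValidationError("title: missing or not a string")
        for i, sent in enumerate(self.sentences):
            if sent.index != i:
                raise ValidationError(
                    f"sentences: index {sent.index} at position {i} (must be contiguous 0..n-1)"
                )
            if i and sent.start < self.sentences[i - 1].end:
                raise ValidationError(f"sentences: span {i} overlaps span {i - 1}")
        n = len(self.sentences)
        for ent in self.entities:
            if not (0 <= ent.sentence_index < n):
                raise ValidationError(
                    f"entities: mention {ent.id} references sentence {ent.sentence_index} "
                    f"of {n}"
                )
        ids = {e.id for e in self.entities}
        for rel in self.relations:
            if not (0 <= rel.sentence_index < n):
                raise ValidationError(
                    f"relations: {rel.id} references sentence {rel.sentence_index} of {n}"
                )
            for mid in (rel.mirna_id, rel.partner_id):
                if mid and mid not in ids:
                    raise ValidationError(
                        f"relations: {rel.id} references unknown mention {mid}"
                    )
        return self

    def sentence_entities(self, index: int) -> List[EntityMention]:
        return [e for e in self.entities if e.sentence_index == index]

    def entity_by_id(self, mention_id: str) -> EntityMention:
        for e in self.entities:
            if e.id == mention_id:
                return e
        raise KeyError(mention_id)


# ---------------------------------------------------------------------------
# Sentence splitting
# ---------------------------------------------------------------------------

# Tokens that end with a period but do not terminate a sentence.
_ABBREVIATIONS = {
    "vs.", "al.", "et al.", "e.g.", "i.e.", "cf.", "ca.", "approx.",
    "fig.", "figs.", "dr.", "no.", "nos.", "st.", "jr.", "sr.", "etc.",
    "resp.", "spp.", "sp.", "var.", "ref.", "refs.", "eq.", "eqs.",
}

_BOUNDARY_RE = re.compile(r"[.!?]+[\"'”’)\]]*\s+")


def split_sentences(text: str) -> List[Sentence]:
    """Split ``text`` into sentences with stable character offsets.

    Rule-based: a sentence ends at ``. ! ?`` followed by whitespace and an
    upper-case letter or digit, unless the final token is a known
    abbreviation or a single capital initial, or the period sits inside a
    number (``P = 0.013``).  Offsets are 0-based half-open code points into
    ``text``; slicing reproduces the sentence text exactly.
    """
    sentences: List[Sentence] = []
    if not text or not text.strip():
        return sentences

    boundaries: List[int] = []
    for m in _BOUNDARY_RE.finditer(text):
        end = m.end()
        punct_start = m.start()
        # character after the whitespace must start a new sentence;
        # lowercase starts are allowed after a newline and for miRNA names
        if end < len(text) and not (text[end].isupper() or text[end].isdigit()):
            if "\n" not in m.group() and not re.match(
                r"(?:miR[-\s]|let-7|[a-z]{3}-(?:miR|let))", text[end:]
            ):
                continue
        # look back at the token containing the punctuation
        tok_start = punct_start
        while tok_start > 0 and not text[tok_start - 1].isspace():
            tok_start -= 1
        token = text[tok_start : punct_start + 1].lower()
        if token in _ABBREVIATIONS:
            continue
        # two-word abbreviations like "et al."
        prev_end = tok_start - 1
        prev_start = prev_end
        while prev_start > 0 and not text[prev_start - 1].isspace():
            prev_start -= 1
        if prev_end > 0 and f"{text[prev_start:prev_end].lower()} {token}" in _ABBREVIATIONS:
            continue
        # single capital initial ("J. Smith")
        if len(token) == 2 and token[0].isalpha():
            continue
        # decimal point inside a number never reaches here (no whitespace after)
        boundaries.append(punct_start + len(m.group().rstrip()))

    boundaries.append(len(text))
    cursor = 0
    for b in boundaries:
        raw = text[cursor:b]
        stripped = raw.strip()
        if stripped:
            start = cursor + (len(raw) - len(raw.lstrip()))
            end = start + len(stripped)
            sentences.append(Sentence(index=len(sentences), text=text[start:end], start=start, end=end))
        cursor = b
    return sentences


def document_from_text(pmid: str, title: str, abstract: str) -> Document:
    """Build a Document whose sentence offsets index the concatenated text.

    The concatenated text is ``title + "\\n" + abstract``; when the title is
    non-empty it becomes sentence 0, so abstract sentence *k* (1-based)
    carries index *k*.
    """
    full = title + ("\n" if title and abstract else "") + abstract
    return Document(pmid=pmid, title=title, sentences=split_sentences(full)).validate()


# ---------------------------------------------------------------------------
# Abstract readers
# ---------------------------------------------------------------------------

def _read_tsv(stream: TextIO) -> Iterator[tuple]:
    for lineno, line in enumerate(stream, start=1):
        line = line.rstrip("\n")
        if not line:
            continue
        parts = line.split("\t")
        if len(parts) < 3:
            raise ValueError(
                f"line {lineno}: expected 3 tab-separated columns (pmid, title, abstract), "
                f"got {len(parts)}"
            )
        yield parts[0], parts[1], "\t".join(parts[2:])


def _read_medline_xml(stream) -> Iterator[tuple]:
    try:
        tree = ET.parse(stream)
    except ET.ParseError as exc:
        raise ValueError(f"malformed Medline XML at {exc.position}: {exc}") from exc
    root = tree.getroot()
    for article in root.iter("PubmedArticle"):
        pmid_el = article.find(".//MedlineCitation/PMID")
        title_el = article.find(".//Article/ArticleTitle")
        abstract_parts = [
            "".join(el.itertext()) for el in article.findall(".//Abstract/AbstractText")
        ]
        pmid = (pmid_el.text or "").strip() if pmid_el is not None else ""
        title = "".join(title_el.itertext()).strip() if title_el is not None else ""
        abstract = " ".join(p.strip() for p in abstract_parts if p and p.strip())
        yield pmid, title, abstract


def read_abstracts(source: Union[str, TextIO], fmt: Optional[str] = None) -> List[Document]:
    """Read abstracts from Medline XML or 3-column TSV into Documents.

    ``fmt`` is ``"xml"``, ``"tsv"`` or None (sniffed: leading ``<`` means
    XML).  Records with an empty abstract are skipped with a warning; a
    duplicate pmid replaces the earlier record (last wins) with a warning.
    """
    if isinstance(source, str):
        stream: TextIO = io.StringIO(source)
    else:
        stream = source
    if fmt is None:
        head = stream.read(1)
        rest = stream.read()
        text = head + rest
        fmt = "xml" if text.lstrip()[:1] == "<" else "tsv"
        stream = io.StringIO(text)

    records = _read_medline_xml(stream) if fmt == "xml" else _read_tsv(stream)

    by_pmid: dict = {}
    order: List[str] = []
    for pmid, title, abstract in records:
        if not abstract.strip():
            logger.warning("pmid %s: empty abstract, record skipped", pmid)
            continue
        if pmid in by_pmid:
            logger.warning("pmid %s: duplicate record, last wins", pmid)
        else:
            order.append(pmid)
        by_pmid[pmid] = document_from_text(pmid, title, abstract)
    return [by_pmid[p] for p in order]


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

def serialize_document(doc: Document) -> str:
    """Serialize a Document to a single-line JSON record."""
    doc.validate()
    return json.dumps(asdict(doc), ensure_ascii=False, sort_keys=True)


def _require(record: dict, key: str):
    if key not in record:
        raise ValidationError(f"record missing field: {key}")
    return record[key]


def deserialize_document(record: Union[str, dict]) -> Document:
    """Inverse of :func:`serialize_document`; validates the schema."""
    if isinstance(record, str):
        try:
            record = json.loads(record)
        except json.JSONDecodeError as exc:
            raise ValidationError(f"record is not valid JSON: {exc}") from exc
    if not isinstance(record, dict):
        raise ValidationError("record: expected a JSON object")
    try:
        doc = Document(
            pmid=str(_require(record, "pmid")),
            title=_require(record, "title"),
            sentences=[Sentence(**s) for s in record.get("sentences", [])],
            entities=[EntityMention(**e) for e in record.get("entities", [])],
            relations=[Relation(**r) for r in record.get("relations", [])],
        )
    except TypeError as exc:
        raise ValidationError(f"record field error: {exc}") from exc
    if not isinstance(doc.title, str):
        raise ValidationError("title: must be a string")
    return doc.validate()


def write_corpus(docs: Iterable[Document], stream: TextIO) -> int:
    """Write documents as JSON lines; returns the number written."""
    n = 0
    for doc in docs:
        stream.write(serialize_document(doc) + "\n")
        n += 1
    return n


def read_corpus(stream: Union[str, TextIO]) -> List[Document]:
    """Read a JSON-lines corpus."""
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    return [deserialize_document(line) for line in stream if line.strip()]


# ---------------------------------------------------------------------------
# CSV export
# ---------------------------------------------------------------------------

CSV_COLUMNS = [
    "pmid",
    "sentence_index",
    "relation_family",
    "role_or_direction",
    "mirna_id",
    "partner_id",
    "partner_type",
    "evidence_text",
]


def relations_to_csv(docs: Iterable[Document], stream: TextIO) -> int:
    """Export all relations as CSV rows; returns the row count."""
    writer = csv.writer(stream)
    writer.writerow(CSV_COLUMNS)
    n = 0
    for doc in docs:
        by_id = {e.id: e for e in doc.entities}
        for rel in doc.relations:
            mirna = by_id.get(rel.mirna_id)
            partner = by_id.get(rel.partner_id)
            writer.writerow(
                [
                    doc.pmid,
                    rel.sentence_index,
                    rel.family,
                    rel.tag,
                    mirna.canonical_id if mirna else rel.mirna_id,
                    rel.partner_canonical or (partner.canonical_id if partner else ""),
                    partner.entity_class if partner else rel.attrs.get("partner_class", ""),
                    rel.evidence,
                ]
            )
            n += 1
    return n
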