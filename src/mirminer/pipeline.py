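"""End-to-end annotation and extraction over documents.

Ties the entity recognizers to the relation extractors: ``annotate``
fills ``Document.entities`` (miRNA regex detection plus one dictionary
match per lexicon, overlaps resolved by longest span then fixed class
priority), ``extract`` fills ``Document.relations``.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources as importlib_resources
from typing import Dict, Iterable, List, Optional

from . import corpus_io
from .corpus_io import Document, EntityMention, Relation
from .lexicons import (
    CLASS_PRIORITY,
    Lexicon,
    build_disease_lexicon,
    build_gene_lexicon,
    build_location_lexicon,
    build_process_lexicon,
)
from .ner_mirna import detect_mirna_mentions
from .rel_extracellular import extract_extracellular
from .rel_gene import extract_gene_relations
from .rel_roles import extract_diffexpr, extract_disease_roles, extract_process_relations

__all__ = ["Resources", "default_resources", "annotate", "extract", "process_corpus"]


@dataclass
class Resources:
    """The lexicon bundle driving non-miRNA entity recognition."""

    gene: Lexicon
    disease: Lexicon
    process: Lexicon
    fluid: Lexicon
    transporter: Lexicon

    @property
    def lexicons(self) -> List[Lexicon]:
        return [self.gene, self.disease, self.process, self.fluid, self.transporter]

    def preferred_name(self, canonical_id: str) -> str:
        for lex in self.lexicons:
            name = lex.preferred_name(canonical_id)
            if name != canonical_id:
                return name
        return canonical_id


def _data_text(name: str) -> str:
    return (importlib_resources.files("mirminer") / "data" / name).read_text(
        encoding="utf-8"
    )


def default_resources(mined_terms: Optional[Iterable[str]] = None) -> Resources:
    """Load the bundled desk-scale lexicons."""
    if mined_terms is None:
        mined_terms = [
            line.strip()
            for line in _data_text("mined_process_terms.txt").splitlines()
            if line.strip() and not line.startswith("#")
        ]
    fluid_list = [l for l in _data_text("fluids.txt").splitlines() if l.strip()]
    transporter_list = [
        l for l in _data_text("transporters.txt").splitlines() if l.strip()
    ]
    fluids, transporters = build_location_lexicon(
        fluid_list, transporter_list, _data_text("bto_subset.obo")
    )
    return Resources(
        gene=build_gene_lexicon(_data_text("genes.tsv").splitlines()),
        disease=build_disease_lexicon(_data_text("doid_subset.obo")),
        process=build_process_lexicon(
            _data_text("go_bp_subset.obo"), _data_text("pw_subset.obo"), mined_terms
        ),
        fluid=fluids,
        transporter=transporters,
    )


def annotate(doc: Document, resources: Resources) -> Document:
    """Detect and normalize all entity mentions in-place.

    Overlapping candidates resolve by longest span, then the fixed class
    priority MIRNA > GENE > DISEASE > PROCESS > FLUID > TRANSPORTER.
    Mention ids are reassigned document-wide in reading order.
    """
    from .lexicons import match_lexicon

    all_mentions: List[EntityMention] = []
    for sentence in doc.sentences:
        candidates: List[EntityMention] = list(detect_mirna_mentions(sentence))
        for lex in resources.lexicons:
            candidates.extend(match_lexicon(sentence, lex))
        candidates.sort(
            key=lambda m: (
                -(m.end - m.start),
                CLASS_PRIORITY.get(m.entity_class, 99),
                m.start,
                m.canonical_id,
            )
        )
        chosen: List[EntityMention] = []
        for cand in candidates:
            if any(not (cand.end <= c.start or cand.start >= c.end) for c in chosen):
                continue
            chosen.append(cand)
        chosen.sort(key=lambda m: m.start)
        all_mentions.extend(chosen)

    for k, mention in enumerate(all_mentions):
        mention.id = f"e{k}"
    doc.entities = all_mentions
    doc.relations = []
    return doc.validate()


def extract(doc: Document) -> Document:
    """Run all relation extractors and store generic relations in-place."""
    by_id: Dict[str, EntityMention] = {e.id: e for e in doc.entities}

    def canonical(mention_id: str) -> str:
        m = by_id.get(mention_id)
        return (m.canonical_id or m.id) if m else ""

    relations: List[Relation] = []
    k = 0

    def next_id() -> str:
        nonlocal k
        k += 1
        return f"r{k - 1}"

    for rel in extract_gene_relations(doc):
        relations.append(rel.to_relation(next_id(), canonical(rel.gene)))
    for rel in extract_process_relations(doc):
        relations.append(rel.to_relation(next_id(), canonical(rel.process)))
    roles = extract_disease_roles(doc)
    diffexpr = extract_diffexpr(doc)
    # a differential-expression frame is a specific disease aspect: it
    # pre-empts the residual OTHER role for the same miRNA and sentence
    de_keys = {(canonical(r.mirna), r.sentence_index) for r in diffexpr}
    for rel in roles:
        if rel.role == "OTHER" and (canonical(rel.mirna), rel.sentence_index) in de_keys:
            continue
        relations.append(rel.to_relation(next_id()))
    for rel in diffexpr:
        relations.append(rel.to_relation(next_id()))
    for rel in extract_extracellular(doc):
        relations.append(rel.to_relation(next_id(), canonical(rel.location)))

    for rel in relations:
        if not rel.evidence and 0 <= rel.sentence_index < len(doc.sentences):
            rel.evidence = doc.sentences[rel.sentence_index].text
    doc.relations = relations
    return doc.validate()


def process_corpus(
    docs: Iterable[Document], resources: Optional[Resources] = None
) -> List[Document]:
    """Annotate and extract over a corpus; returns the same documents."""
    if resources is None:
        resources = default_resources()
    out = []
    for doc in docs:
        out.append(extract(annotate(doc, resources)))
    return out
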