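"""Pairing circulating miRNAs with biofluids and transporter forms.

Step 1 (PROXIMITY) uses precision-oriented same-sentence patterns: a
location term modifying an miRNA noun phrase, "<mirna> in <fluid>",
"exosomal <mirna>", "<fluid> levels of <mirna>".  Step 2
(PATIENT_CONTEXT) detects patient-context sentences — sentences that
describe the subjects/samples of the study — and links the biofluids
they mention to the miRNAs analyzed elsewhere in the abstract.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import List, Sequence, Set, Tuple

from .corpus_io import (
    FAMILY_EXTRACELLULAR,
    FLUID,
    MIRNA,
    TRANSPORTER,
    Document,
    EntityMention,
    Relation,
)
from .parse_layer import build_parse, lemma_candidates
from .rel_roles import EXPRESSION_CUES

__all__ = [
    "ExtracellularRelation",
    "PCSentence",
    "extract_proximity_pairs",
    "detect_pc_sentences",
    "link_pc_pairs",
    "extract_extracellular",
]

PROXIMITY = "PROXIMITY"
PATIENT_CONTEXT = "PATIENT_CONTEXT"

PROXIMITY_WINDOW = 5

# tokens allowed between a location and the miRNA it modifies
_CONNECTOR_WORDS = {
    "mirna", "mirnas", "microrna", "micrornas", "mir", "mirs",
    "levels", "level", "expression", "of", "derived", "based",
    "circulating", "only", "one",
}

ANALYSIS_VERBS = {"analyze", "analyse", "measure", "quantify", "detect",
                  "profile", "assess", "examine", "evaluate"}

_PC_CUES = [
    ("pc:fluid_of_n_patients", re.compile(r"\b(?:of|from)\s+\d+\s+patients\b", re.I)),
    ("pc:n_patients", re.compile(r"\b\d+\s+patients\b", re.I)),
    ("pc:patients_with", re.compile(r"\bpatients\s+with\b", re.I)),
    ("pc:samples_collected", re.compile(
        r"\bsamples?\s+(?:were\s+|was\s+)?(?:collected|obtained|taken)\b", re.I)),
    ("pc:fluid_samples", re.compile(
        r"\b(?:serum|plasma|urine|blood|saliva|sputum)\s+samples?\b", re.I)),
    ("pc:patients_enrolled", re.compile(
        r"\bpatients?\s+(?:were\s+)?(?:enrolled|recruited|included)\b", re.I)),
]


@dataclass
class ExtracellularRelation:
    mirna: str             # mention id
    location: str          # mention id
    location_class: str    # FLUID | TRANSPORTER
    method: str            # PROXIMITY | PATIENT_CONTEXT
    mirna_sentence: int
    location_sentence: int
    rule_id: str = ""

    def __post_init__(self) -> None:
        if self.method == PROXIMITY and self.mirna_sentence != self.location_sentence:
            raise ValueError("PROXIMITY pairs must be same-sentence")

    def to_relation(self, rel_id: str, location_canonical: str = "") -> Relation:
        return Relation(
            id=rel_id,
            family=FAMILY_EXTRACELLULAR,
            mirna_id=self.mirna,
            partner_id=self.location,
            partner_canonical=location_canonical,
            tag="",
            sentence_index=self.mirna_sentence,
            rule_id=self.rule_id,
            attrs={
                "partner_class": self.location_class,
                "method": self.method,
                "location_sentence": self.location_sentence,
            },
        )


@dataclass
class PCSentence:
    sentence_index: int
    cue: str
    locations: List[str] = field(default_factory=list)  # mention ids


def _locations(mentions: Sequence[EntityMention]) -> List[EntityMention]:
    return [m for m in mentions if m.entity_class in (FLUID, TRANSPORTER)]


def extract_proximity_pairs(
    doc: Document, window: int = PROXIMITY_WINDOW
) -> List[ExtracellularRelation]:
    """Same-sentence miRNA–location pairs in close textual proximity.

    A pair is emitted when the location precedes the miRNA with only
    connector tokens between them (the "<fluid> miRNA, <mirna>" /
    "<fluid> levels of <mirna>" shapes) or the miRNA is followed by
    "in/from/within <location>" — both within the token window.
    """
    out: List[ExtracellularRelation] = []
    seen: Set[Tuple] = set()
    for sentence in doc.sentences:
        mentions = doc.sentence_entities(sentence.index)
        mirnas = [m for m in mentions if m.entity_class == MIRNA]
        locations = _locations(mentions)
        if not mirnas or not locations:
            continue
        graph = build_parse(sentence)
        for loc in locations:
            l_first = graph.token_at(loc.start)
            l_last = graph.token_at(max(loc.end - 1, loc.start))
            for mi in mirnas:
                m_first = graph.token_at(mi.start)
                m_last = graph.token_at(max(mi.end - 1, mi.start))
                if None in (l_first, l_last, m_first, m_last):
                    continue
                rule = ""
                if l_last < m_first and m_first - l_last <= window + 1:
                    between = graph.tokens[l_last + 1 : m_first]
                    if all(t.word.lower() in _CONNECTOR_WORDS or not t.word for t in between):
                        rule = "excell:modifier"
                elif m_last < l_first and l_first - m_last <= window:
                    between = {t.word.lower() for t in graph.tokens[m_last + 1 : l_first]}
                    if between & {"in", "from", "within"}:
                        rule = "excell:in_fluid"
                if not rule:
                    continue
                key = (mi.canonical_id or mi.id, loc.canonical_id or loc.id)
                if key in seen:
                    continue
                seen.add(key)
                out.append(
                    ExtracellularRelation(
                        mirna=mi.id,
                        location=loc.id,
                        location_class=loc.entity_class,
                        method=PROXIMITY,
                        mirna_sentence=sentence.index,
                        location_sentence=sentence.index,
                        rule_id=rule,
                    )
                )
    return out


def detect_pc_sentences(doc: Document) -> List[PCSentence]:
    """Detect patient-context sentences.

    A PC sentence matches at least one subject/sample cue pattern; it is
    linkable only when it also contains a location mention.
    """
    out: List[PCSentence] = []
    for sentence in doc.sentences:
        for cue_id, pattern in _PC_CUES:
            if pattern.search(sentence.text):
                locs = _locations(doc.sentence_entities(sentence.index))
                out.append(
                    PCSentence(
                        sentence_index=sentence.index,
                        cue=cue_id,
                        locations=[m.id for m in locs],
                    )
                )
                break
    return out


def _analysis_sentence_mirnas(doc: Document) -> List[EntityMention]:
    """miRNA mentions in expression or analysis statements."""
    hits: List[EntityMention] = []
    for sentence in doc.sentences:
        mentions = doc.sentence_entities(sentence.index)
        mirnas = [m for m in mentions if m.entity_class == MIRNA]
        if not mirnas:
            continue
        is_analysis = False
        for tok in sentence.text.split():
            word = tok.strip(".,;:()[]").lower()
            if word in EXPRESSION_CUES:
                is_analysis = True
                break
            if lemma_candidates(tok) & ANALYSIS_VERBS:
                is_analysis = True
                break
        if is_analysis:
            hits.extend(mirnas)
    return hits


def link_pc_pairs(
    doc: Document,
    pc_sentences: Sequence[PCSentence],
    existing: Sequence[ExtracellularRelation] = (),
) -> List[ExtracellularRelation]:
    """Pair linkable PC locations with the abstract's analyzed miRNAs.

    Each location mentioned in a PC sentence is paired with every miRNA
    mention occurring in an expression/analysis statement; pairs already
    found by PROXIMITY are not duplicated.
    """
    canon = {e.id: e.canonical_id or e.id for e in doc.entities}
    existing_keys = {
        (canon.get(r.mirna, r.mirna), canon.get(r.location, r.location))
        for r in existing
    }
    out: List[ExtracellularRelation] = []
    seen: Set[Tuple] = set(existing_keys)
    analyzed = _analysis_sentence_mirnas(doc)
    for pc in pc_sentences:
        for loc_id in pc.locations:
            loc = doc.entity_by_id(loc_id)
            for mi in analyzed:
                key = (canon.get(mi.id, mi.id), canon.get(loc_id, loc_id))
                if key in seen:
                    continue
                seen.add(key)
                out.append(
                    ExtracellularRelation(
                        mirna=mi.id,
                        location=loc_id,
                        location_class=loc.entity_class,
                        method=PATIENT_CONTEXT,
                        mirna_sentence=mi.sentence_index,
                        location_sentence=pc.sentence_index,
                        rule_id=f"excell:pc:{pc.cue}",
                    )
                )
    return out


def extract_extracellular(doc: Document) -> List[ExtracellularRelation]:
    """Run both steps and concatenate (proximity first, no duplicates)."""
    proximity = extract_proximity_pairs(doc)
    pc = detect_pc_sentences(doc)
    return proximity + link_pc_pairs(doc, pc, existing=proximity)
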