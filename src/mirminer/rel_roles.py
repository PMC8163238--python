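"""miRNA–process relations, disease-role classification and
differential-expression statements.

Three extractors share the connection-cue vocabulary:

* ``extract_process_relations`` — regulation / involvement / association
  links between an miRNA and a biological process or pathway mention.
* ``extract_disease_roles`` — copular "is_a" patterns whose complement
  head noun decides BIOMARKER vs THERAPEUTIC_TARGET, connection patterns
  with outcome/treatment term lexicons, and a residual OTHER role that
  only fires when nothing more specific did.  The disease argument is
  resolved same-sentence first, then from the title, then from the
  nearest prior disease mention; provenance is always recorded.
* ``extract_diffexpr`` — comparative frames (expression cue + direction
  word + "in <sample>" [+ comparison marker + control phrase]); the
  sample and control descriptors are captured verbatim, minus leading
  determiners/quantifiers.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Set, Tuple

from .corpus_io import (
    DISEASE,
    FAMILY_DIFFEXPR,
    FAMILY_DISEASE_ROLE,
    FAMILY_PROCESS,
    MIRNA,
    PROCESS,
    Document,
    EntityMention,
    Relation,
)
from .parse_layer import (
    ParseGraph,
    build_parse,
    coordination_groups,
    find_triggers,
    group_distance,
    group_token_span,
    is_negated,
    lemma_candidates,
    DEFAULT_WINDOW,
)

__all__ = [
    "ProcessRelation",
    "DiseaseRoleRelation",
    "DiffExprRelation",
    "extract_process_relations",
    "extract_disease_roles",
    "extract_diffexpr",
]

# --- shared vocabularies (configuration, not fixed truth) ------------------

REGULATION_POSITIVE = {"promote", "enhance", "induce", "increase", "upregulate",
                       "up-regulate", "accelerate", "stimulate"}
REGULATION_NEGATIVE = {"suppress", "inhibit", "attenuate", "reduce", "repress",
                       "decrease", "downregulate", "down-regulate", "block", "impair"}
INVOLVEMENT = {"involve", "contribute", "mediate", "play", "participate", "confer"}
ASSOCIATION = {"associate", "correlate", "link", "relate", "implicate"}

CONNECTION_NOUNS = {"role", "roles", "impact", "involvement", "association"}

IS_A_CUES = {"is", "are", "as", "was", "were", "be", "become", "becomes",
             "became", "represent", "represents", "emerged", "emerge"}

BIOMARKER_HEADS = {"marker", "markers", "biomarker", "biomarkers",
                   "indicator", "indicators", "predictor", "predictors"}
BIOMARKER_QUALIFIERS = {"diagnostic", "prognostic", "predictive", "potential",
                        "novel", "promising", "candidate"}
THERAPEUTIC_PHRASES = [
    ("therapeutic", "target"),
    ("drug", "target"),
    ("anticancer", "target"),
    ("anti-cancer", "target"),
    ("molecular", "target"),
    ("treatment", "target"),
]

OUTCOME_TERMS = {"survival", "prognosis", "outcome", "outcomes",
                 "recurrence", "metastasis"}
TREATMENT_TERMS = {"resistance", "sensitivity", "response", "chemosensitivity",
                   "radiosensitivity", "chemoresistance", "radioresistance",
                   "chemotherapy", "radiotherapy", "therapy"}
TREATMENT_PHRASES = [("radiation", "treatment")]

EXPRESSION_CUES = {"expression", "level", "levels", "abundance"}

DIRECTION_DOWN = {"reduced", "decreased", "lower", "downregulated",
                  "down-regulated", "underexpressed", "diminished", "declined"}
DIRECTION_UP = {"elevated", "increased", "higher", "upregulated",
                "up-regulated", "overexpressed", "over-expressed", "raised"}

COMPARISON_MARKERS = [("compared", "to"), ("compared", "with"),
                      ("relative", "to"), ("versus",), ("vs",), ("vs.",), ("than",)]

ROLE_OUTCOME = "OUTCOME"
ROLE_TREATMENT = "TREATMENT"
ROLE_BIOMARKER = "BIOMARKER"
ROLE_THERAPEUTIC_TARGET = "THERAPEUTIC_TARGET"
ROLE_OTHER = "OTHER"

UNSPECIFIED_DISEASE = "term:unspecified-disease"


@dataclass
class ProcessRelation:
    mirna: str
    process: str
    relation: str  # regulation_positive | regulation_negative | involvement | association
    sentence_index: int
    rule_id: str

    def to_relation(self, rel_id: str, process_canonical: str = "") -> Relation:
        return Relation(
            id=rel_id,
            family=FAMILY_PROCESS,
            mirna_id=self.mirna,
            partner_id=self.process,
            partner_canonical=process_canonical,
            tag=self.relation,
            sentence_index=self.sentence_index,
            rule_id=self.rule_id,
            attrs={"partner_class": PROCESS},
        )


@dataclass
class DiseaseRoleRelation:
    mirna: str
    disease: str  # canonical DOID or unmapped slug
    role: str
    sentence_index: int
    disease_provenance: str  # same_sentence | title | nearest_prior | none
    qualifier: str = ""
    rule_id: str = ""

    def to_relation(self, rel_id: str) -> Relation:
        return Relation(
            id=rel_id,
            family=FAMILY_DISEASE_ROLE,
            mirna_id=self.mirna,
            partner_id="",
            partner_canonical=self.disease,
            tag=self.role,
            sentence_index=self.sentence_index,
            rule_id=self.rule_id,
            attrs={
                "partner_class": DISEASE,
                "disease_provenance": self.disease_provenance,
                "qualifier": self.qualifier,
            },
        )


@dataclass
class DiffExprRelation:
    mirna: str
    disease: str
    direction: str  # up | down
    sample_descriptor: str
    comparison_descriptor: str
    sentence_index: int
    disease_provenance: str = "none"

    def to_relation(self, rel_id: str) -> Relation:
        return Relation(
            id=rel_id,
            family=FAMILY_DIFFEXPR,
            mirna_id=self.mirna,
            partner_id="",
            partner_canonical=self.disease,
            tag=self.direction,
            sentence_index=self.sentence_index,
            rule_id="diffexpr:frame",
            attrs={
                "partner_class": DISEASE,
                "sample": self.sample_descriptor,
                "comparison": self.comparison_descriptor,
                "disease_provenance": self.disease_provenance,
            },
        )


# ---------------------------------------------------------------------------
# miRNA–process (connection framework)
# ---------------------------------------------------------------------------

def extract_process_relations(
    doc: Document, window: int = DEFAULT_WINDOW
) -> List[ProcessRelation]:
    """Link miRNA mentions to process/pathway mentions.

    Regulation triggers give regulation_positive/negative, involvement
    and association triggers give their own tags; conjunction over
    process mentions distributes.  Regulation additionally requires the
    miRNA group to precede the trigger (the miRNA is the agent).
    """
    out: List[ProcessRelation] = []
    seen: Set[Tuple] = set()
    for sentence in doc.sentences:
        mentions = doc.sentence_entities(sentence.index)
        mirnas = [m for m in mentions if m.entity_class == MIRNA]
        processes = [m for m in mentions if m.entity_class == PROCESS]
        if not mirnas or not processes:
            continue
        graph = build_parse(sentence)
        mirna_groups = coordination_groups(graph, mirnas)
        process_groups = coordination_groups(graph, processes)
        trigger_sets = [
            ("regulation_positive", REGULATION_POSITIVE, True),
            ("regulation_negative", REGULATION_NEGATIVE, True),
            ("involvement", INVOLVEMENT, False),
            ("association", ASSOCIATION, False),
        ]
        for tag, lemmas, agent_before in trigger_sets:
            for trig in find_triggers(graph, lemmas):
                if is_negated(graph, trig):
                    continue
                for mgroup in mirna_groups:
                    _, m_last = group_token_span(graph, mgroup)
                    if agent_before and m_last >= trig:
                        continue
                    if group_distance(graph, mgroup, trig) > window:
                        continue
                    for pgroup in process_groups:
                        if group_distance(graph, pgroup, trig) > window:
                            continue
                        for mi in mgroup:
                            for pr in pgroup:
                                key = (tag, mi.canonical_id or mi.id,
                                       pr.canonical_id or pr.id, sentence.index)
                                if key in seen:
                                    continue
                                seen.add(key)
                                out.append(
                                    ProcessRelation(
                                        mirna=mi.id,
                                        process=pr.id,
                                        relation=tag,
                                        sentence_index=sentence.index,
                                        rule_id=f"process:{tag}",
                                    )
                                )
    return out


# ---------------------------------------------------------------------------
# Disease-argument resolution
# ---------------------------------------------------------------------------

def _resolve_disease(
    doc: Document, sentence_index: int
) -> Tuple[str, str, str]:
    """Return (canonical disease id, provenance, mention id or "")."""
    same = [
        e for e in doc.sentence_entities(sentence_index) if e.entity_class == DISEASE
    ]
    if same:
        return same[0].canonical_id or same[0].id, "same_sentence", same[0].id
    title = [e for e in doc.sentence_entities(0) if e.entity_class == DISEASE]
    if title and sentence_index != 0:
        return title[0].canonical_id or title[0].id, "title", title[0].id
    prior = [
        e
        for e in doc.entities
        if e.entity_class == DISEASE and e.sentence_index < sentence_index
    ]
    if prior:
        best = max(prior, key=lambda e: (e.sentence_index, -e.start))
        return best.canonical_id or best.id, "nearest_prior", best.id
    return UNSPECIFIED_DISEASE, "none", ""


# ---------------------------------------------------------------------------
# Disease roles
# ---------------------------------------------------------------------------

def _word(tokens, i) -> str:
    return tokens[i].word.lower() if 0 <= i < len(tokens) else ""


def _phrase_hits(words: List[str], phrases: Sequence[Tuple[str, ...]]) -> bool:
    for phrase in phrases:
        n = len(phrase)
        for i in range(len(words) - n + 1):
            if tuple(words[i : i + n]) == phrase:
                return True
    return False


def _is_a_roles(
    graph: ParseGraph, mgroup: List[EntityMention], window: int
) -> List[Tuple[str, str]]:
    """(role, qualifier) pairs from a copular cue after an miRNA group."""
    tokens = graph.tokens
    _, last = group_token_span(graph, mgroup)
    roles: List[Tuple[str, str]] = []
    for i in range(last + 1, min(last + 5, len(tokens))):
        if _word(tokens, i) not in IS_A_CUES:
            continue
        if is_negated(graph, i):
            continue
        comp = [t.word.lower() for t in tokens[i + 1 : i + 1 + window]]
        if any(w in BIOMARKER_HEADS for w in comp):
            quals = [w for w in comp if w in BIOMARKER_QUALIFIERS]
            roles.append((ROLE_BIOMARKER, " ".join(dict.fromkeys(quals))))
        if _phrase_hits(comp, THERAPEUTIC_PHRASES) or _phrase_hits(
            comp, [("target", "for")]
        ):
            roles.append((ROLE_THERAPEUTIC_TARGET, ""))
        if roles:
            break
    return roles


def _has_connection_cue(graph: ParseGraph) -> bool:
    lemmas = (
        ASSOCIATION | INVOLVEMENT | REGULATION_POSITIVE | REGULATION_NEGATIVE
    )
    for tok in graph.tokens:
        if lemma_candidates(tok.surface) & lemmas:
            return True
        if tok.word.lower() in CONNECTION_NOUNS:
            return True
    return False


def extract_disease_roles(
    doc: Document, window: int = DEFAULT_WINDOW
) -> List[DiseaseRoleRelation]:
    """Classify each miRNA's role in a disease context.

    Role partition per (mirna, disease, sentence): copular-pattern roles
    (BIOMARKER, THERAPEUTIC_TARGET) and term-lexicon roles (OUTCOME,
    TREATMENT) may co-fire on distinct matches; OTHER fires only when no
    specific role did and a disease mention plus a connection cue exist.
    """
    out: List[DiseaseRoleRelation] = []
    seen: Set[Tuple] = set()

    def emit(rel: DiseaseRoleRelation, mirna_canonical: str) -> None:
        key = (mirna_canonical, rel.disease, rel.role, rel.sentence_index)
        if key not in seen:
            seen.add(key)
            out.append(rel)

    for sentence in doc.sentences:
        mentions = doc.sentence_entities(sentence.index)
        mirnas = [m for m in mentions if m.entity_class == MIRNA]
        if not mirnas:
            continue
        graph = build_parse(sentence)
        mirna_groups = coordination_groups(graph, mirnas)
        disease_id, provenance, _ = _resolve_disease(doc, sentence.index)
        diseases_here = [m for m in mentions if m.entity_class == DISEASE]
        has_cue = _has_connection_cue(graph)
        specific_mirnas: Set[str] = set()

        for mgroup in mirna_groups:
            # (a) is_a framework: complement head noun decides the role
            for role, qualifier in _is_a_roles(graph, mgroup, window):
                for mi in mgroup:
                    specific_mirnas.add(mi.id)
                    emit(
                        DiseaseRoleRelation(
                            mirna=mi.id,
                            disease=disease_id,
                            role=role,
                            sentence_index=sentence.index,
                            disease_provenance=provenance,
                            qualifier=qualifier,
                            rule_id=f"role:is_a:{role.lower()}",
                        ),
                        mi.canonical_id or mi.id,
                    )

            # (b) connection patterns with outcome / treatment lexicons
            if has_cue:
                words = [t.word.lower() for t in graph.tokens]
                for role, terms, phrases in (
                    (ROLE_OUTCOME, OUTCOME_TERMS, []),
                    (ROLE_TREATMENT, TREATMENT_TERMS, TREATMENT_PHRASES),
                ):
                    hit = False
                    for idx, w in enumerate(words):
                        if w in terms and group_distance(graph, mgroup, idx) <= window:
                            hit = True
                            break
                    if not hit and phrases:
                        for phrase in phrases:
                            n = len(phrase)
                            for idx in range(len(words) - n + 1):
                                if tuple(words[idx : idx + n]) == phrase and (
                                    group_distance(graph, mgroup, idx) <= window
                                ):
                                    hit = True
                                    break
                    if hit:
                        for mi in mgroup:
                            specific_mirnas.add(mi.id)
                            emit(
                                DiseaseRoleRelation(
                                    mirna=mi.id,
                                    disease=disease_id,
                                    role=role,
                                    sentence_index=sentence.index,
                                    disease_provenance=provenance,
                                    rule_id=f"role:connection:{role.lower()}",
                                ),
                                mi.canonical_id or mi.id,
                            )

        # (c) residual association with an in-sentence disease mention
        if diseases_here and has_cue:
            for mgroup in mirna_groups:
                for dis in diseases_here:
                    d_idx = graph.token_at(dis.start)
                    if d_idx is None or group_distance(graph, mgroup, d_idx) > window:
                        continue
                    for mi in mgroup:
                        if mi.id in specific_mirnas:
                            continue
                        emit(
                            DiseaseRoleRelation(
                                mirna=mi.id,
                                disease=dis.canonical_id or dis.id,
                                role=ROLE_OTHER,
                                sentence_index=sentence.index,
                                disease_provenance="same_sentence",
                                rule_id="role:other",
                            ),
                            mi.canonical_id or mi.id,
                        )
    return out


# ---------------------------------------------------------------------------
# Differential expression
# ---------------------------------------------------------------------------

_QUANTIFIER_WORDS = {"the", "a", "an", "all", "both", "some", "out", "of",
                     "about", "approximately", "total", "these", "those"}

_DESCRIPTOR_STOPS = {"compared", "versus", "vs", "vs.", "relative", "than",
                     "over", "during", "throughout", "at", "after", "before",
                     "by", "using", "with", "and", "for", "in", "from"}


def _capture_phrase(tokens, start: int, stops: Set[str], limit: int = 8) -> str:
    words: List[str] = []
    for tok in tokens[start : start + limit]:
        w = tok.word
        if not w or w.lower() in stops:
            break
        words.append(w)
        if tok.surface.rstrip().endswith((".", ",", ";", ":", ")")):
            break
    while words and (words[0].lower() in _QUANTIFIER_WORDS or re.fullmatch(r"\d+", words[0])):
        words.pop(0)
    return " ".join(words)


def _find_comparison(tokens, start: int) -> Tuple[Optional[int], str]:
    """Locate a comparison marker at/after ``start``; returns
    (index after the marker, marker text)."""
    words = [t.word.lower() for t in tokens]
    for i in range(start, len(tokens)):
        for marker in COMPARISON_MARKERS:
            n = len(marker)
            if tuple(words[i : i + n]) == marker:
                return i + n, " ".join(marker)
    return None, ""


def extract_diffexpr(
    doc: Document, window: int = DEFAULT_WINDOW
) -> List[DiffExprRelation]:
    """Extract comparative differential-expression frames.

    A frame needs a known direction word with an miRNA group in reach and
    at least one of an "in <sample>" phrase or a comparison marker;
    direction words outside the up/down map never emit a relation.
    """
    out: List[DiffExprRelation] = []
    seen: Set[Tuple] = set()
    for sentence in doc.sentences:
        mentions = doc.sentence_entities(sentence.index)
        mirnas = [m for m in mentions if m.entity_class == MIRNA]
        if not mirnas:
            continue
        graph = build_parse(sentence)
        tokens = graph.tokens
        mirna_groups = coordination_groups(graph, mirnas)
        disease_id, provenance, _ = _resolve_disease(doc, sentence.index)
        has_expression_cue = any(t.word.lower() in EXPRESSION_CUES for t in tokens)
        for idx, tok in enumerate(tokens):
            w = tok.word.lower()
            if w in DIRECTION_UP:
                direction = "up"
            elif w in DIRECTION_DOWN:
                direction = "down"
            else:
                continue
            if is_negated(graph, idx):
                continue
            # sample phrase: first "in <phrase>" after the direction word
            sample = ""
            sample_at = None
            for j in range(idx + 1, min(idx + 1 + window, len(tokens))):
                if _word(tokens, j) == "in":
                    sample = _capture_phrase(tokens, j + 1, _DESCRIPTOR_STOPS)
                    sample_at = j + 1
                    break
            comp_at, _marker = _find_comparison(tokens, idx + 1)
            comparison = (
                _capture_phrase(tokens, comp_at, _DESCRIPTOR_STOPS) if comp_at else ""
            )
            if not sample and not comparison:
                continue  # frame incomplete
            for mgroup in mirna_groups:
                _, m_last = group_token_span(graph, mgroup)
                if m_last >= idx:
                    continue  # direction word qualifies a preceding miRNA
                if group_distance(graph, mgroup, idx) > window and not has_expression_cue:
                    continue
                if group_distance(graph, mgroup, idx) > max(window, 10):
                    continue
                for mi in mgroup:
                    key = (mi.canonical_id or mi.id, direction, sentence.index)
                    if key in seen:
                        continue
                    seen.add(key)
                    out.append(
                        DiffExprRelation(
                            mirna=mi.id,
                            disease=disease_id,
                            direction=direction,
                            sample_descriptor=sample,
                            comparison_descriptor=comparison,
                            sentence_index=sentence.index,
                            disease_provenance=provenance,
                        )
                    )
    return out
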