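"""miRNA–gene relation extraction (three families, with polarity).

Families: MIRNA_TARGET (a direct-target trigger fired), MIRNA_GENE (the
miRNA regulates the gene's expression) and GENE_MIRNA (the gene regulates
the miRNA's expression).  Under level-B parsing, the mention group
preceding the trigger is the agent and the group following it the theme;
a passive-voice cue ("was ... by") swaps the roles.  Coordination
distributes: a trigger with a conjoined gene list yields one relation per
gene.  When a direct-target trigger and a generic regulation trigger both
fire on a pair in one sentence, only the MIRNA_TARGET relation survives.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Set, Tuple

from .corpus_io import (
    FAMILY_GENE,
    FAMILY_GENE_MIRNA,
    FAMILY_TARGET,
    GENE,
    MIRNA,
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

__all__ = ["GeneRelation", "extract_gene_relations", "TARGET_TRIGGERS",
           "NEGATIVE_TRIGGERS", "POSITIVE_TRIGGERS"]

POSITIVE = "positive"
NEGATIVE = "negative"
UNSPECIFIED = "unspecified"

# Trigger inventories are configuration, not fixed truth.
TARGET_TRIGGERS: Set[str] = {"target"}
NEGATIVE_TRIGGERS: Set[str] = {
    "suppress", "inhibit", "repress", "downregulate", "down-regulate",
    "reduce", "silence", "decrease", "attenuate", "abolish",
}
POSITIVE_TRIGGERS: Set[str] = {
    "induce", "increase", "upregulate", "up-regulate", "enhance",
    "promote", "elevate", "activate",
}


@dataclass
class GeneRelation:
    family: str
    mirna: str            # mention id
    gene: str             # mention id
    polarity: str
    sentence_index: int
    rule_id: str
    evidence: str

    def to_relation(self, rel_id: str, gene_canonical: str = "") -> Relation:
        return Relation(
            id=rel_id,
            family=self.family,
            mirna_id=self.mirna,
            partner_id=self.gene,
            partner_canonical=gene_canonical,
            tag=self.polarity,
            sentence_index=self.sentence_index,
            rule_id=self.rule_id,
            evidence=self.evidence,
            attrs={"partner_class": GENE},
        )


def _passive_swap(graph: ParseGraph, trigger: int, window: int) -> bool:
    """True for "X was <trigger> ... by Y" frames (roles swap)."""
    before = {t.word.lower() for t in graph.tokens[max(0, trigger - 2) : trigger]}
    if not before & {"was", "were", "is", "are", "been", "be"}:
        return False
    after = graph.tokens[trigger + 1 : trigger + 1 + window]
    return any(t.word.lower() == "by" for t in after)


def _nearest_group(
    groups: Sequence[List[EntityMention]],
    graph: ParseGraph,
    trigger: int,
    side: str,
    window: int,
) -> Optional[List[EntityMention]]:
    """Nearest coordination group strictly before/after a trigger token."""
    best, best_dist = None, None
    for group in groups:
        first, last = group_token_span(graph, group)
        if side == "before" and last >= trigger:
            continue
        if side == "after" and first <= trigger:
            continue
        dist = group_distance(graph, group, trigger)
        if dist <= window and (best_dist is None or dist < best_dist):
            best, best_dist = group, dist
    return best


def extract_gene_relations(
    doc: Document, window: int = DEFAULT_WINDOW
) -> List[GeneRelation]:
    """Extract the three miRNA–gene relation families from a document.

    One relation per (family, mirna, gene, sentence) after deduplication;
    MIRNA_TARGET beats generic regulation on the same pair (its polarity
    turns positive only when an explicit positive trigger co-fired).
    """
    relations: List[GeneRelation] = []
    for sentence in doc.sentences:
        mentions = doc.sentence_entities(sentence.index)
        mirnas = [m for m in mentions if m.entity_class == MIRNA]
        genes = [m for m in mentions if m.entity_class == GENE]
        if not mirnas or not genes:
            continue
        graph = build_parse(sentence)
        mirna_groups = coordination_groups(graph, mirnas)
        gene_groups = coordination_groups(graph, genes)

        # direct-target triggers: class constraints force the argument
        # assignment, so word order does not matter
        for trig in find_triggers(graph, TARGET_TRIGGERS):
            if is_negated(graph, trig):
                continue
            near_mirnas = [
                m
                for g in mirna_groups
                if group_distance(graph, g, trig) <= window
                for m in g
            ]
            near_genes = [
                m
                for g in gene_groups
                if group_distance(graph, g, trig) <= window
                for m in g
            ]
            for mi in near_mirnas:
                for ge in near_genes:
                    relations.append(
                        GeneRelation(
                            family=FAMILY_TARGET,
                            mirna=mi.id,
                            gene=ge.id,
                            polarity=NEGATIVE,
                            sentence_index=sentence.index,
                            rule_id="gene:target",
                            evidence=sentence.text,
                        )
                    )

        # generic regulation triggers: direction decided by agent class
        for polarity, lemmas in ((NEGATIVE, NEGATIVE_TRIGGERS), (POSITIVE, POSITIVE_TRIGGERS)):
            for trig in find_triggers(graph, lemmas):
                if is_negated(graph, trig):
                    continue
                all_groups = mirna_groups + gene_groups
                agent = _nearest_group(all_groups, graph, trig, "before", window)
                theme = _nearest_group(all_groups, graph, trig, "after", window)
                if agent is None or theme is None:
                    continue
                if _passive_swap(graph, trig, window):
                    agent, theme = theme, agent
                a_cls = agent[0].entity_class
                t_cls = theme[0].entity_class
                if a_cls == MIRNA and t_cls == GENE:
                    family = FAMILY_GENE
                    pairs = [(mi, ge) for mi in agent for ge in theme]
                elif a_cls == GENE and t_cls == MIRNA:
                    family = FAMILY_GENE_MIRNA
                    pairs = [(mi, ge) for ge in agent for mi in theme]
                else:
                    continue
                for mi, ge in pairs:
                    relations.append(
                        GeneRelation(
                            family=family,
                            mirna=mi.id,
                            gene=ge.id,
                            polarity=polarity,
                            sentence_index=sentence.index,
                            rule_id=f"gene:regulation:{polarity}",
                            evidence=sentence.text,
                        )
                    )

    return _deduplicate(relations, doc)


def _deduplicate(relations: List[GeneRelation], doc: Document) -> List[GeneRelation]:
    """Specificity then uniqueness, on normalized argument identity.

    Pairs with a MIRNA_TARGET relation drop their generic relations (the
    target polarity turns positive if a positive regulation co-fired);
    then at most one relation per (family, mirna, gene, sentence), where
    mirna/gene identity is the mention's canonical id when available.
    """
    canon = {e.id: e.canonical_id or e.id for e in doc.entities}

    def pair_key(rel: GeneRelation) -> Tuple:
        return (canon.get(rel.mirna, rel.mirna), canon.get(rel.gene, rel.gene),
                rel.sentence_index)

    target_pairs = {pair_key(r) for r in relations if r.family == FAMILY_TARGET}
    positive_pairs = {
        pair_key(r)
        for r in relations
        if r.family != FAMILY_TARGET and r.polarity == POSITIVE
    }
    out: List[GeneRelation] = []
    seen: Set[Tuple] = set()
    for rel in relations:
        key = pair_key(rel)
        if rel.family != FAMILY_TARGET and key in target_pairs:
            continue
        if rel.family == FAMILY_TARGET and key in positive_pairs:
            rel.polarity = POSITIVE
        dedup_key = (rel.family,) + key
        if dedup_key in seen:
            continue
        seen.add(dedup_key)
        out.append(rel)
    return out
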