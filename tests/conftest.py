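import random

import pytest

from mirminer.corpus_io import (
    ENTITY_CLASSES,
    RELATION_FAMILIES,
    Document,
    EntityMention,
    Relation,
    Sentence,
)
from mirminer.pipeline import default_resources


@pytest.fixture(scope="session")
def resources():
    return default_resources()


_WORDS = [
    "alpha", "beta", "gamma", "delta", "cells", "tumor", "tissue",
    "expression", "signal", "growth", "analysis", "study", "level",
]


def make_document(rng: random.Random) -> Document:
    """A random schema-valid document for round-trip/property tests."""
    n_sent = rng.randint(1, 5)
    sentences = []
    cursor = 0
    for i in range(n_sent):
        words = [rng.choice(_WORDS) for _ in range(rng.randint(2, 6))]
        text = " ".join(words) + "."
        start = cursor
        end = start + len(text)
        sentences.append(Sentence(index=i, text=text, start=start, end=end))
        cursor = end + 1
    entities = []
    for i, sent in enumerate(sentences):
        for _ in range(rng.randint(0, 2)):
            words = sent.text[:-1].split(" ")
            w = rng.randrange(len(words))
            start = sum(len(x) + 1 for x in words[:w])
            end = start + len(words[w])
            unmapped = rng.random() < 0.2
            entities.append(
                EntityMention(
                    id=f"e{len(entities)}",
                    entity_class=rng.choice(ENTITY_CLASSES),
                    sentence_index=i,
                    start=start,
                    end=end,
                    surface=sent.text[start:end],
                    canonical_id="" if unmapped else f"GO:{rng.randrange(10**7):07d}",
                    flags=["unmapped"] if unmapped else [],
                )
            )
    relations = []
    if entities:
        for k in range(rng.randint(0, 2)):
            ent = rng.choice(entities)
            partner = rng.choice(entities)
            relations.append(
                Relation(
                    id=f"r{k}",
                    family=rng.choice(RELATION_FAMILIES),
                    mirna_id=ent.id,
                    partner_id=partner.id,
                    partner_canonical=partner.canonical_id,
                    tag=rng.choice(["", "up", "down", "positive"]),
                    sentence_index=ent.sentence_index,
                    rule_id="t",
                    evidence=sentences[ent.sentence_index].text,
                    attrs={"k": str(k)},
                )
            )
    return Document(
        pmid=str(rng.randrange(10**7)),
        title=rng.choice(_WORDS).capitalize() + " study.",
        sentences=sentences,
        entities=entities,
        relations=relations,
    ).validate()
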