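"""Seeded synthetic abstracts with gold annotations, plus a P/R/F1 scorer.

Templates cover every relation family the extractors know (target
statement, regulation statement, gene→miRNA statement, process
regulation, copular biomarker / therapeutic target, outcome association,
treatment resistance, unspecified disease association,
differential-expression frame, fluid proximity, patient-context pair).
Each quota item instantiates exactly one template in its own document, so
the gold size equals the quota sum.  Distractor sentences (trigger-free
co-occurrence, negated triggers, lookalike tokens) are inserted at the
configured rate.  A single seeded generator instance is threaded through
all sampling — same config, byte-identical corpus.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

from .corpus_io import (
    FAMILY_DIFFEXPR,
    FAMILY_DISEASE_ROLE,
    FAMILY_EXTRACELLULAR,
    FAMILY_GENE,
    FAMILY_GENE_MIRNA,
    FAMILY_PROCESS,
    FAMILY_TARGET,
    Document,
    document_from_text,
)
from .ner_mirna import normalize_mirna
from .pipeline import Resources, default_resources

__all__ = [
    "GeneratorConfig",
    "GoldRelation",
    "TEMPLATE_KINDS",
    "generate_corpus",
    "score",
    "records_from_documents",
]

TEMPLATE_KINDS = (
    "target",
    "regulation_neg",
    "regulation_pos",
    "gene_mirna",
    "process_pos",
    "process_neg",
    "biomarker",
    "therapeutic_target",
    "outcome",
    "treatment",
    "other_role",
    "diffexpr_up",
    "diffexpr_down",
    "fluid_proximity",
    "pc_pair",
)

_MIRNAS = [
    "miR-21", "miR-155", "miR-34a", "let-7b", "miR-200b", "miR-145",
    "miR-122", "miR-221", "miR-19a", "miR-429", "miR-181a", "miR-30c",
    "miR-206", "miR-17", "miR-125b", "miR-31", "miR-143", "miR-375",
]
_GENES = [
    "PTEN", "ROCK1", "EZH2", "EGFR", "BMI1", "XIAP", "CDK6", "BCL2",
    "VEGFA", "STAT3", "ZEB1", "PDCD4", "TIMP3", "KRAS", "CCND1",
]
_DISEASES = [
    "breast cancer", "stomach cancer", "colorectal cancer", "lung cancer",
    "hepatocellular carcinoma", "prostate cancer", "ovarian cancer",
    "melanoma", "pancreatic cancer",
]
_PROCESSES = [
    "apoptosis", "cell proliferation", "cell migration", "angiogenesis",
    "autophagy", "invasion", "tumor growth",
    "epithelial to mesenchymal transition",
]
_FLUIDS = ["serum", "plasma", "urine", "saliva"]

_TITLE = "A study of microRNA function in human specimens."


@dataclass
class GeneratorConfig:
    seed: int = 0
    n_documents: int = 100
    quotas: Optional[Dict[str, int]] = None
    distractor_rate: float = 0.0

    def resolved_quotas(self) -> Dict[str, int]:
        if self.quotas is not None:
            unknown = set(self.quotas) - set(TEMPLATE_KINDS)
            if unknown:
                raise ValueError(f"unknown template kinds in quotas: {sorted(unknown)}")
            return dict(self.quotas)
        base = self.n_documents // len(TEMPLATE_KINDS)
        rest = self.n_documents % len(TEMPLATE_KINDS)
        return {
            kind: base + (1 if i < rest else 0)
            for i, kind in enumerate(TEMPLATE_KINDS)
        }


@dataclass
class GoldRelation:
    pmid: str
    family: str
    tag: str            # polarity / role / direction, "" where n/a
    mirna: str          # normalized family id
    partner: str        # canonical partner id
    sentence_index: int

    def key(self) -> Tuple[str, str, str, str, str]:
        return (self.pmid, self.family, self.mirna, self.partner, self.tag)


def _canonical(resources: Resources, lexicon_name: str, surface: str) -> str:
    lex = getattr(resources, lexicon_name)
    entry = lex.lookup(surface)
    if entry is None:
        raise ValueError(f"lexicon {lexicon_name!r} cannot satisfy surface {surface!r}")
    return entry.canonical_id


def _build_template(
    kind: str, rng: random.Random, resources: Resources
) -> Tuple[List[str], List[Tuple[str, str, str, str, int]]]:
    """Returns (abstract sentences, gold stubs).

    A gold stub is (family, tag, mirna surface, partner canonical id,
    sentence offset within the abstract).
    """
    mi = rng.choice(_MIRNAS)
    gene = rng.choice(_GENES)
    disease = rng.choice(_DISEASES)
    process = rng.choice(_PROCESSES)
    fluid = rng.choice(_FLUIDS)
    gene_id = _canonical(resources, "gene", gene)
    disease_id = _canonical(resources, "disease", disease)
    process_id = _canonical(resources, "process", process)
    fluid_id = _canonical(resources, "fluid", fluid)

    if kind == "target":
        return (
            [f"Luciferase assays confirmed that {mi} directly targets {gene} in human cells."],
            [(FAMILY_TARGET, "negative", mi, gene_id, 0)],
        )
    if kind == "regulation_neg":
        return (
            [f"{mi} overexpression markedly suppressed {gene} in vitro."],
            [(FAMILY_GENE, "negative", mi, gene_id, 0)],
        )
    if kind == "regulation_pos":
        return (
            [f"{mi} significantly enhanced {gene} expression in cultured cells."],
            [(FAMILY_GENE, "positive", mi, gene_id, 0)],
        )
    if kind == "gene_mirna":
        return (
            [f"{gene} increased {mi} expression in cultured fibroblasts."],
            [(FAMILY_GENE_MIRNA, "positive", mi, gene_id, 0)],
        )
    if kind == "process_pos":
        return (
            [f"Functional experiments revealed that {mi} promotes {process} in vitro."],
            [(FAMILY_PROCESS, "regulation_positive", mi, process_id, 0)],
        )
    if kind == "process_neg":
        return (
            [f"Ectopic {mi} strongly inhibited {process} in these cells."],
            [(FAMILY_PROCESS, "regulation_negative", mi, process_id, 0)],
        )
    if kind == "biomarker":
        return (
            [f"{mi} may serve as a promising prognostic marker for {disease}."],
            [(FAMILY_DISEASE_ROLE, "BIOMARKER", mi, disease_id, 0)],
        )
    if kind == "therapeutic_target":
        return (
            [f"{mi} could be a novel therapeutic target for the treatment of {disease}."],
            [(FAMILY_DISEASE_ROLE, "THERAPEUTIC_TARGET", mi, disease_id, 0)],
        )
    if kind == "outcome":
        return (
            [f"High {mi} expression is associated with poor survival in patients with {disease}."],
            [(FAMILY_DISEASE_ROLE, "OUTCOME", mi, disease_id, 0)],
        )
    if kind == "treatment":
        return (
            [f"{mi} is associated with resistance to chemotherapy in {disease}."],
            [(FAMILY_DISEASE_ROLE, "TREATMENT", mi, disease_id, 0)],
        )
    if kind == "other_role":
        return (
            [f"Altered {mi} expression is closely associated with {disease}."],
            [(FAMILY_DISEASE_ROLE, "OTHER", mi, disease_id, 0)],
        )
    if kind == "diffexpr_up":
        return (
            [
                f"{mi} expression was significantly elevated in {disease} tissues "
                "compared with adjacent normal tissues."
            ],
            [(FAMILY_DIFFEXPR, "up", mi, disease_id, 0)],
        )
    if kind == "diffexpr_down":
        return (
            [
                f"{mi} expression was markedly reduced in {disease} tissues "
                "compared with matched controls."
            ],
            [(FAMILY_DIFFEXPR, "down", mi, disease_id, 0)],
        )
    if kind == "fluid_proximity":
        return (
            [f"{fluid.capitalize()} {mi} was readily detectable in all specimens."],
            [(FAMILY_EXTRACELLULAR, "", mi, fluid_id, 0)],
        )
    if kind == "pc_pair":
        return (
            [
                f"{fluid.capitalize()} samples were collected from 30 patients with {disease}.",
                f"The levels of {mi} were analyzed by qRT-PCR.",
            ],
            [(FAMILY_EXTRACELLULAR, "", mi, fluid_id, 1)],
        )
    raise ValueError(f"unknown template kind: {kind!r}")


def _distractor(rng: random.Random) -> str:
    mi = rng.choice(_MIRNAS)
    gene = rng.choice(_GENES)
    kind = rng.randrange(3)
    if kind == 0:  # co-occurrence without trigger
        return f"{mi} and {gene} were observed in the same cohort."
    if kind == 1:  # negated trigger
        return f"However, {mi} did not suppress {gene} in these assays."
    return "The MIRROR trial was reported separately."  # lookalike token


def generate_corpus(
    config: GeneratorConfig, resources: Optional[Resources] = None
) -> Tuple[List[Document], List[GoldRelation]]:
    """Generate a seeded synthetic corpus with gold-standard relations.

    One document per quota item (cross-sentence cues such as
    patient-context linking stay confined to their own abstract);
    additional distractor-only documents pad the corpus up to
    ``n_documents``.  Raises when the quotas exceed ``n_documents``.
    """
    if resources is None:
        resources = default_resources()
    quotas = config.resolved_quotas()
    total = sum(quotas.values())
    if total > config.n_documents:
        raise ValueError(
            f"quota sum {total} exceeds n_documents {config.n_documents}"
        )
    rng = random.Random(config.seed)
    docs: List[Document] = []
    gold: List[GoldRelation] = []
    items: List[str] = [k for k in TEMPLATE_KINDS for _ in range(quotas.get(k, 0))]
    n_pad = config.n_documents - total

    for i, kind in enumerate(items):
        pmid = f"S{i:05d}"
        sentences, stubs = _build_template(kind, rng, resources)
        insert_at = None
        if rng.random() < config.distractor_rate:
            insert_at = rng.randrange(len(sentences) + 1)
            sentences = sentences[:insert_at] + [_distractor(rng)] + sentences[insert_at:]
        doc = document_from_text(pmid, _TITLE, " ".join(sentences))
        if len(doc.sentences) != len(sentences) + 1:
            raise RuntimeError(
                f"template {kind!r} split into {len(doc.sentences) - 1} sentences"
            )
        docs.append(doc)
        for family, tag, mirna_surface, partner, offset in stubs:
            if insert_at is not None and insert_at <= offset:
                offset += 1
            gold.append(
                GoldRelation(
                    pmid=pmid,
                    family=family,
                    tag=tag,
                    mirna=normalize_mirna(mirna_surface),
                    partner=partner,
                    sentence_index=offset + 1,  # title is sentence 0
                )
            )

    for j in range(n_pad):
        pmid = f"D{j:05d}"
        docs.append(document_from_text(pmid, _TITLE, _distractor(rng)))
    return docs, gold


# ---------------------------------------------------------------------------
# Scoring
# ---------------------------------------------------------------------------

def records_from_documents(docs: Iterable[Document]) -> List[Tuple[str, str, str, str, str]]:
    """Comparable (pmid, family, mirna, partner, tag) tuples for scoring."""
    records = []
    for doc in docs:
        by_id = {e.id: e for e in doc.entities}
        for rel in doc.relations:
            mirna = by_id.get(rel.mirna_id)
            mirna_norm = mirna.canonical_id if mirna and mirna.canonical_id else rel.mirna_id
            partner = rel.partner_canonical
            if not partner:
                p = by_id.get(rel.partner_id)
                partner = (p.canonical_id or p.id) if p else ""
            tag = "" if rel.family == FAMILY_EXTRACELLULAR else rel.tag
            records.append((doc.pmid, rel.family, mirna_norm, partner, tag))
    return records


def score(
    predicted: Sequence[Tuple[str, str, str, str, str]],
    gold: Sequence[GoldRelation],
) -> Dict[str, Dict[str, float]]:
    """Precision/recall/F1 per relation family and overall.

    A prediction matches a gold item iff (pmid, family, normalized miRNA,
    normalized partner, role/direction where applicable) agree; matching
    is set-based over unique keys.  P is 0 (not undefined) for an empty
    prediction set against a non-empty gold.
    """
    pred_keys = {tuple(p) for p in predicted}
    gold_keys = {g.key() for g in gold}
    families = sorted({k[1] for k in pred_keys | gold_keys})

    def prf(pred: set, gold_set: set) -> Dict[str, float]:
        matches = len(pred & gold_set)
        if not pred and not gold_set:
            return {"precision": 1.0, "recall": 1.0, "f1": 1.0,
                    "n_pred": 0, "n_gold": 0, "n_match": 0}
        p = matches / len(pred) if pred else 0.0
        r = matches / len(gold_set) if gold_set else 0.0
        f1 = 2 * p * r / (p + r) if (p + r) else 0.0
        return {"precision": p, "recall": r, "f1": f1,
                "n_pred": len(pred), "n_gold": len(gold_set), "n_match": matches}

    out = {"overall": prf(pred_keys, gold_keys)}
    for family in families:
        out[family] = prf(
            {k for k in pred_keys if k[1] == family},
            {k for k in gold_keys if k[1] == family},
        )
    return out
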