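"""Document index with miRNA-centric, context-centric and disease-centric
query modes, aspect views and summaries.

The store is a local stand-in for the original web-service design: the
same boolean AND/OR query semantics are evaluated over an inverted token
index built from the documents themselves, and every query implicitly
intersects with the miRNA cue filter (miR OR miRNA OR microRNA).
Indices are derived data — rebuildable from the documents alone.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Set, Union

from .corpus_io import (
    DISEASE,
    FAMILY_DIFFEXPR,
    FAMILY_DISEASE_ROLE,
    FAMILY_EXTRACELLULAR,
    FAMILY_GENE,
    FAMILY_GENE_MIRNA,
    FAMILY_PROCESS,
    FAMILY_TARGET,
    FLUID,
    GENE,
    MIRNA,
    PROCESS,
    TRANSPORTER,
    Document,
)
from .lexicons import Lexicon, parse_obo

__all__ = [
    "CorpusIndex",
    "QueryExpression",
    "parse_query",
    "build_index",
    "query_mirna",
    "query_context",
    "query_disease",
    "aspect_view",
    "filter_rows",
    "sort_rows",
    "summarize_counts",
    "ASPECTS",
]

_TOKEN_RE = re.compile(r"[a-z0-9]+(?:-[a-z0-9]+)*")

_MIRNA_CUE_EXACT = {"mir", "mirs", "mirna", "mirnas", "microrna", "micrornas"}
_MIRNA_CUE_PREFIX = ("mir-", "mirna-", "microrna-", "let-7")

ASPECTS = {
    "gene_regulation": (FAMILY_TARGET, FAMILY_GENE, FAMILY_GENE_MIRNA),
    "process": (FAMILY_PROCESS,),
    "disease_roles": (FAMILY_DISEASE_ROLE,),
    "diffexpr": (FAMILY_DIFFEXPR,),
    "extracellular": (FAMILY_EXTRACELLULAR,),
}


def tokenize_text(text: str) -> List[str]:
    """Case-folded alphanumeric+hyphen tokens ("miR-21" stays whole)."""
    return _TOKEN_RE.findall(text.casefold())


def _doc_text(doc: Document) -> str:
    parts = [doc.title] + [s.text for s in doc.sentences]
    return "\n".join(parts)


def _has_mirna_cue(doc: Document) -> bool:
    for tok in tokenize_text(_doc_text(doc)):
        if tok in _MIRNA_CUE_EXACT or tok.startswith(_MIRNA_CUE_PREFIX):
            return True
    return False


# ---------------------------------------------------------------------------
# Boolean query expressions
# ---------------------------------------------------------------------------

@dataclass
class QueryExpression:
    """Boolean tree over case-insensitive keyword literals."""

    op: str  # "lit" | "and" | "or"
    literal: str = ""
    children: List["QueryExpression"] = field(default_factory=list)

    @staticmethod
    def lit(text: str) -> "QueryExpression":
        if not text.strip():
            raise ValueError("empty query literal")
        return QueryExpression(op="lit", literal=text.strip().casefold())

    @staticmethod
    def and_(*children: "QueryExpression") -> "QueryExpression":
        return QueryExpression(op="and", children=list(children))

    @staticmethod
    def or_(*children: "QueryExpression") -> "QueryExpression":
        return QueryExpression(op="or", children=list(children))


def parse_query(text: str) -> QueryExpression:
    """Parse a keyword query with AND/OR separators and parentheses.

    Bare adjacent words form a phrase literal; AND binds tighter than OR.
    """
    tokens = re.findall(r"\(|\)|\bAND\b|\bOR\b|[^()\s]+", text)
    pos = 0

    def peek() -> Optional[str]:
        return tokens[pos] if pos < len(tokens) else None

    def parse_or() -> QueryExpression:
        nonlocal pos
        node = parse_and()
        while peek() == "OR":
            pos += 1
            node = QueryExpression.or_(node, parse_and())
        return node

    def parse_and() -> QueryExpression:
        nonlocal pos
        node = parse_atom()
        while peek() == "AND":
            pos += 1
            node = QueryExpression.and_(node, parse_atom())
        return node

    def parse_atom() -> QueryExpression:
        nonlocal pos
        tok = peek()
        if tok == "(":
            pos += 1
            node = parse_or()
            if peek() != ")":
                raise ValueError(f"unbalanced parenthesis in query: {text!r}")
            pos += 1
            return node
        words = []
        while peek() not in (None, "(", ")", "AND", "OR"):
            words.append(tokens[pos])
            pos += 1
        if not words:
            raise ValueError(f"expected a keyword in query: {text!r}")
        return QueryExpression.lit(" ".join(words))

    if not text.strip():
        raise ValueError("empty query")
    node = parse_or()
    if pos != len(tokens):
        raise ValueError(f"trailing tokens in query: {text!r}")
    return node


# ---------------------------------------------------------------------------
# Index
# ---------------------------------------------------------------------------

@dataclass
class CorpusIndex:
    documents: Dict[str, Document] = field(default_factory=dict)
    family_index: Dict[str, Set[str]] = field(default_factory=dict)
    token_index: Dict[str, Set[str]] = field(default_factory=dict)
    disease_index: Dict[str, Set[str]] = field(default_factory=dict)

    def pmids(self) -> List[str]:
        return sorted(self.documents)


def build_index(docs: Iterable[Document]) -> CorpusIndex:
    """Build the inverted indices; deterministic and rebuildable."""
    index = CorpusIndex()
    for doc in docs:
        index.documents[doc.pmid] = doc
    for pmid in sorted(index.documents):
        doc = index.documents[pmid]
        for tok in set(tokenize_text(_doc_text(doc))):
            index.token_index.setdefault(tok, set()).add(pmid)
        for ent in doc.entities:
            if ent.entity_class == MIRNA and ent.canonical_id:
                index.family_index.setdefault(ent.canonical_id, set()).add(pmid)
            elif ent.entity_class == DISEASE and ent.canonical_id:
                index.disease_index.setdefault(ent.canonical_id, set()).add(pmid)
    return index


def _eval_expr(index: CorpusIndex, expr: QueryExpression) -> Set[str]:
    if expr.op == "lit":
        if " " in expr.literal:
            return {
                pmid
                for pmid, doc in index.documents.items()
                if expr.literal in _doc_text(doc).casefold()
            }
        return set(index.token_index.get(expr.literal, set()))
    sets = [_eval_expr(index, child) for child in expr.children]
    if expr.op == "and":
        out = sets[0]
        for s in sets[1:]:
            out = out & s
        return out
    out = set()
    for s in sets:
        out |= s
    return out


def query_mirna(index: CorpusIndex, family: str) -> List[Document]:
    """miRNA-centric search: documents mentioning the given family id."""
    pmids = index.family_index.get(family.strip().casefold(), set())
    return [index.documents[p] for p in sorted(pmids)]


def query_context(
    index: CorpusIndex, expr: Union[str, QueryExpression]
) -> List[Document]:
    """Context-centric search: ``expr AND (miR OR miRNA OR microRNA)``."""
    if isinstance(expr, str):
        expr = parse_query(expr)
    pmids = _eval_expr(index, expr)
    return [
        index.documents[p]
        for p in sorted(pmids)
        if _has_mirna_cue(index.documents[p])
    ]


def query_disease(
    index: CorpusIndex, doid_or_name: str, do_file: str
) -> List[Document]:
    """Disease-centric search via DOID (or official name) synonym expansion."""
    terms = parse_obo(do_file)
    wanted = None
    key = doid_or_name.strip()
    for term in terms:
        if term.id == key or term.name.casefold() == key.casefold():
            wanted = term
            break
    if wanted is None:
        raise KeyError(f"unknown disease identifier or name: {doid_or_name!r}")
    literals = [QueryExpression.lit(wanted.name)]
    literals += [QueryExpression.lit(s) for s in wanted.synonyms if s.strip()]
    expr = literals[0] if len(literals) == 1 else QueryExpression.or_(*literals)
    return query_context(index, expr)


# ---------------------------------------------------------------------------
# Aspect views
# ---------------------------------------------------------------------------

def aspect_view(
    results: Sequence[Document],
    aspect: str,
    resources=None,
) -> List[Dict[str, str]]:
    """Tabulate the relations of one aspect over a result set.

    Rows carry pmid, evidence sentence, surfaces and normalized ids, so
    substring filters catch synonyms through the normalized columns.
    """
    if aspect not in ASPECTS:
        raise KeyError(f"unknown aspect {aspect!r}; choose from {sorted(ASPECTS)}")
    families = ASPECTS[aspect]
    rows: List[Dict[str, str]] = []
    for doc in results:
        by_id = {e.id: e for e in doc.entities}
        for rel in doc.relations:
            if rel.family not in families:
                continue
            mirna = by_id.get(rel.mirna_id)
            partner = by_id.get(rel.partner_id)
            partner_canonical = rel.partner_canonical or (
                partner.canonical_id if partner else ""
            )
            partner_name = partner_canonical
            if resources is not None and partner_canonical:
                partner_name = resources.preferred_name(partner_canonical)
            rows.append(
                {
                    "pmid": doc.pmid,
                    "sentence_index": str(rel.sentence_index),
                    "relation_family": rel.family,
                    "role_or_direction": rel.tag,
                    "mirna_surface": mirna.surface if mirna else "",
                    "mirna_id": mirna.canonical_id if mirna else "",
                    "partner_surface": partner.surface if partner else "",
                    "partner_id": partner_canonical,
                    "partner_name": partner_name,
                    "method": str(rel.attrs.get("method", "")),
                    "evidence": rel.evidence,
                }
            )
    return rows


def filter_rows(
    rows: Sequence[Dict[str, str]], needle: str, column: Optional[str] = None
) -> List[Dict[str, str]]:
    """Case-insensitive substring filter over one column or all columns."""
    needle = needle.casefold()
    out = []
    for row in rows:
        values = [row.get(column, "")] if column else list(row.values())
        if any(needle in str(v).casefold() for v in values):
            out.append(row)
    return out


def sort_rows(rows: Sequence[Dict[str, str]], column: str, reverse: bool = False):
    """Stable sort by one column."""
    return sorted(rows, key=lambda r: str(r.get(column, "")), reverse=reverse)


# ---------------------------------------------------------------------------
# Summary
# ---------------------------------------------------------------------------

def summarize_counts(index: CorpusIndex) -> Dict[str, object]:
    """Unique entity counts per class and relation counts per family."""
    unique: Dict[str, Set[str]] = {
        cls: set() for cls in (MIRNA, GENE, DISEASE, PROCESS, FLUID, TRANSPORTER)
    }
    families: Dict[str, int] = {}
    n_relations = 0
    for pmid in sorted(index.documents):
        doc = index.documents[pmid]
        for ent in doc.entities:
            if ent.canonical_id:
                unique[ent.entity_class].add(ent.canonical_id)
        for rel in doc.relations:
            families[rel.family] = families.get(rel.family, 0) + 1
            n_relations += 1
    return {
        "documents": len(index.documents),
        "unique_mirnas": len(unique[MIRNA]),
        "unique_genes": len(unique[GENE]),
        "unique_processes": len(unique[PROCESS]),
        "unique_diseases": len(unique[DISEASE]),
        "unique_locations": len(unique[FLUID] | unique[TRANSPORTER]),
        "relations_total": n_relations,
        "relations_per_family": dict(sorted(families.items())),
    }
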