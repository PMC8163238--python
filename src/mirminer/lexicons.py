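"""Dictionaries for non-miRNA entity recognition and normalization.

Lexicons map normalized surface forms to canonical ontology identifiers
(NCBI Gene ID, DOID, GO, PW, BTO or a transporter-form token) with
longest-match, token-boundary-respecting lookup.  "Closest match" is
operationalized as exact case-insensitive string matching after whitespace
normalization — no fuzzy matching, by design.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Set, TextIO, Tuple, Union

from .corpus_io import (
    DISEASE,
    FLUID,
    GENE,
    PROCESS,
    TRANSPORTER,
    EntityMention,
    Sentence,
)

__all__ = [
    "LexiconEntry",
    "Lexicon",
    "OboTerm",
    "parse_obo",
    "build_process_lexicon",
    "mine_process_terms",
    "build_location_lexicon",
    "build_gene_lexicon",
    "build_disease_lexicon",
    "map_mesh_to_doid",
    "match_lexicon",
    "slugify",
]

# Fixed priority for resolving equal-length overlap ties across classes.
CLASS_PRIORITY = {"MIRNA": 0, GENE: 1, DISEASE: 2, PROCESS: 3, FLUID: 4, TRANSPORTER: 5}

_ID_SYNTAX = {
    "GO": re.compile(r"^GO:\d{7}$"),
    "PW": re.compile(r"^PW:\d{7}$"),
    "DOID": re.compile(r"^DOID:\d+$"),
    "BTO": re.compile(r"^BTO:\d{7}$"),
}

_WORD_RE = re.compile(r"\w+(?:['’\-/]\w+)*", re.UNICODE)


def normalize_surface(surface: str) -> str:
    """Case-fold and collapse whitespace."""
    return re.sub(r"\s+", " ", surface.strip()).casefold()


def slugify(term: str) -> str:
    """Stable identifier slug for terms without an ontology match."""
    return "term:" + re.sub(r"[^a-z0-9]+", "-", normalize_surface(term)).strip("-")


@dataclass(frozen=True)
class LexiconEntry:
    surface: str
    canonical_id: str
    entity_class: str
    source: str = ""
    preferred_name: str = ""

    def __post_init__(self):
        if not normalize_surface(self.surface):
            raise ValueError("lexicon entry with empty surface")
        prefix = self.canonical_id.split(":", 1)[0]
        pattern = _ID_SYNTAX.get(prefix)
        if pattern and not pattern.match(self.canonical_id):
            raise ValueError(f"malformed {prefix} identifier: {self.canonical_id!r}")


class Lexicon:
    """Surface → canonical-id index with deterministic longest-match lookup."""

    def __init__(self, entity_class: str, entries: Iterable[LexiconEntry] = ()):
        self.entity_class = entity_class
        self._by_surface: Dict[str, List[LexiconEntry]] = {}
        self._names: Dict[str, str] = {}  # canonical_id -> preferred name
        self.max_words = 0
        for entry in entries:
            self.add(entry)

    def add(self, entry: LexiconEntry) -> None:
        key = normalize_surface(entry.surface)
        bucket = self._by_surface.setdefault(key, [])
        if any(e.canonical_id == entry.canonical_id for e in bucket):
            return  # no duplicate (surface, canonical_id) pairs
        bucket.append(entry)
        bucket.sort(key=lambda e: e.canonical_id)
        self.max_words = max(self.max_words, len(key.split()))
        if entry.preferred_name and entry.canonical_id not in self._names:
            self._names[entry.canonical_id] = entry.preferred_name

    def lookup(self, surface: str) -> Optional[LexiconEntry]:
        bucket = self._by_surface.get(normalize_surface(surface))
        return bucket[0] if bucket else None

    def preferred_name(self, canonical_id: str) -> str:
        return self._names.get(canonical_id, canonical_id)

    def surfaces(self) -> List[str]:
        return sorted(self._by_surface)

    def __len__(self) -> int:
        return sum(len(b) for b in self._by_surface.values())

    def __contains__(self, surface: str) -> bool:
        return normalize_surface(surface) in self._by_surface


# ---------------------------------------------------------------------------
# OBO parsing (minimal flat-file reader for Term stanzas)
# ---------------------------------------------------------------------------

@dataclass
class OboTerm:
    id: str
    name: str = ""
    synonyms: List[str] = field(default_factory=list)
    xrefs: List[str] = field(default_factory=list)
    namespace: str = ""
    obsolete: bool = False


_SYNONYM_RE = re.compile(r'^"(.*)"\s*(?:\w+)?')


def parse_obo(source: Union[str, TextIO]) -> List[OboTerm]:
    """Parse ``[Term]`` stanzas from an OBO 1.2/1.4 flat file.

    Only the fields needed for lexicon building are read: id, name,
    synonym (quoted string), xref, namespace, is_obsolete.
    """
    if hasattr(source, "read"):
        text = source.read()
    else:
        text = source
    terms: List[OboTerm] = []
    current: Optional[OboTerm] = None
    in_term = False
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("!")[0].strip() if not raw.strip().startswith('"') else raw.strip()
        if not line:
            continue
        if line.startswith("["):
            if current is not None:
                terms.append(current)
                current = None
            in_term = line == "[Term]"
            continue
        if not in_term:
            continue
        if ":" not in line:
            raise ValueError(f"unparseable OBO line {lineno} in stanza "
                             f"{current.id if current else '?'}: {raw!r}")
        key, _, value = line.partition(":")
        key = key.strip()
        value = value.strip()
        if key == "id":
            current = OboTerm(id=value)
        elif current is None:
            continue
        elif key == "name":
            current.name = value
        elif key == "synonym":
            m = _SYNONYM_RE.match(value)
            if m:
                current.synonyms.append(m.group(1))
        elif key == "xref":
            current.xrefs.append(value.split()[0] if value else value)
        elif key == "namespace":
            current.namespace = value
        elif key == "is_obsolete":
            current.obsolete = value.lower().startswith("true")
    if current is not None:
        terms.append(current)
    return terms


# ---------------------------------------------------------------------------
# Builders
# ---------------------------------------------------------------------------

def _obo_entries(terms: Sequence[OboTerm], entity_class: str, source: str) -> Iterable[LexiconEntry]:
    for term in terms:
        if term.obsolete or not term.name:
            continue
        yield LexiconEntry(term.name, term.id, entity_class, source, preferred_name=term.name)
        for syn in term.synonyms:
            yield LexiconEntry(syn, term.id, entity_class, source, preferred_name=term.name)


def build_process_lexicon(
    go_obo: Union[str, TextIO],
    pw_obo: Union[str, TextIO],
    mined_terms: Iterable[str] = (),
) -> Lexicon:
    """Combine GO biological-process terms, pathway-ontology terms and
    text-mined candidate terms into one PROCESS lexicon.

    Mined terms that exactly match (case-insensitively) an ontology name
    or synonym take that ontology identifier; the rest get a stable slug
    with source ``"mined"``.
    """
    lex = Lexicon(PROCESS)
    for entry in _obo_entries(parse_obo(go_obo), PROCESS, "GO"):
        lex.add(entry)
    for entry in _obo_entries(parse_obo(pw_obo), PROCESS, "PW"):
        lex.add(entry)
    for term in mined_terms:
        if not term.strip():
            continue
        hit = lex.lookup(term)
        if hit is not None:
            lex.add(LexiconEntry(term, hit.canonical_id, PROCESS, "mined",
                                 preferred_name=hit.preferred_name))
        else:
            lex.add(LexiconEntry(term, slugify(term), PROCESS, "mined",
                                 preferred_name=normalize_surface(term)))
    return lex


_CUE_RE = re.compile(
    r"\b(?:cellular processes|biological processes|processes)\s*,?\s*"
    r"(?:such as|including)\s+",
    re.IGNORECASE,
)
_LIST_STOP_RE = re.compile(r"[.;:()]| \bwhich\b | \bthat\b ", re.IGNORECASE)
_DETERMINERS = {"the", "a", "an", "this", "these", "those", "their", "its", "other"}


def mine_process_terms(sentences: Iterable[Union[str, Sentence]]) -> List[str]:
    """Harvest process terms from cue + enumerated-list patterns.

    A cue phrase ("cellular processes" | "biological processes" |
    "processes") followed by "such as"/"including" introduces a comma/and
    separated list; each item is emitted trimmed of determiners.
    """
    out: List[str] = []
    seen: Set[str] = set()
    for sent in sentences:
        text = sent.text if isinstance(sent, Sentence) else sent
        for cue in _CUE_RE.finditer(text):
            tail = text[cue.end():]
            stop = _LIST_STOP_RE.search(tail)
            if stop:
                tail = tail[: stop.start()]
            items = re.split(r",\s*|\s+\band\b\s+|\s+\bor\b\s+", tail)
            for item in items:
                words = [w for w in item.strip().split() if w]
                while words and words[0].lower() in _DETERMINERS:
                    words = words[1:]
                term = " ".join(words).strip()
                if term and normalize_surface(term) not in seen:
                    seen.add(normalize_surface(term))
                    out.append(term)
    return out


def build_location_lexicon(
    fluid_list: Iterable[str],
    transporter_list: Iterable[str],
    bto_obo: Union[str, TextIO, None] = None,
) -> Tuple[Lexicon, Lexicon]:
    """Build the (FLUID, TRANSPORTER) lexicon pair.

    Fluids are normalized to BTO identifiers where an exact
    case-insensitive name/synonym match exists; otherwise they keep a slug
    and are flagged unmapped (source ``"unmapped"``).  Transporter forms
    keep class TRANSPORTER with slug canonical ids; a surface may map onto
    a different canonical form (``"exosomal<TAB>exosome"``).
    """
    bto = Lexicon(FLUID)
    if bto_obo is not None:
        for entry in _obo_entries(parse_obo(bto_obo), FLUID, "BTO"):
            bto.add(entry)
    fluids = Lexicon(FLUID)
    for term in fluid_list:
        term = term.strip()
        if not term:
            continue
        hit = bto.lookup(term)
        if hit is not None:
            fluids.add(LexiconEntry(term, hit.canonical_id, FLUID, "BTO",
                                    preferred_name=normalize_surface(term)))
        else:
            fluids.add(LexiconEntry(term, slugify(term), FLUID, "unmapped",
                                    preferred_name=normalize_surface(term)))
    transporters = Lexicon(TRANSPORTER)
    for term in transporter_list:
        term = term.strip()
        if not term:
            continue
        if "\t" in term:
            surface, canon = term.split("\t", 1)
        else:
            surface, canon = term, term
        transporters.add(
            LexiconEntry(surface, slugify(canon), TRANSPORTER, "list",
                         preferred_name=normalize_surface(canon))
        )
    return fluids, transporters


def build_gene_lexicon(rows: Iterable[Union[str, Tuple[str, str]]]) -> Lexicon:
    """Build a GENE lexicon from (symbol, NCBI Gene ID) rows or TSV lines.

    The first surface seen for an id becomes its preferred name, so list
    the official symbol before its synonyms.
    """
    lex = Lexicon(GENE)
    for row in rows:
        if isinstance(row, str):
            row = row.rstrip("\n")
            if not row or row.startswith("#"):
                continue
            parts = row.split("\t")
            if len(parts) < 2:
                raise ValueError(f"gene lexicon row needs 2 columns: {row!r}")
            surface, gene_id = parts[0], parts[1]
        else:
            surface, gene_id = row
        preferred = lex.preferred_name(gene_id)
        lex.add(LexiconEntry(surface, gene_id, GENE, "gene-list",
                             preferred_name=preferred if preferred != gene_id else surface))
    return lex


def build_disease_lexicon(doid_obo: Union[str, TextIO]) -> Lexicon:
    """DISEASE lexicon keyed directly to DOIDs (names + exact synonyms)."""
    lex = Lexicon(DISEASE)
    for entry in _obo_entries(parse_obo(doid_obo), DISEASE, "DOID"):
        lex.add(entry)
    return lex


def map_mesh_to_doid(
    mesh_ids: Iterable[str], doid_obo: Union[str, TextIO]
) -> Tuple[Dict[str, Set[str]], List[str]]:
    """Map MESH identifiers to the DOIDs whose xref lines cite them.

    Returns ``(mapping, unmapped)``; a MESH id cited by several DOIDs keeps
    all of them (no arbitration).
    """
    by_mesh: Dict[str, Set[str]] = {}
    for term in parse_obo(doid_obo):
        for xref in term.xrefs:
            norm = xref.replace("MSH:", "MESH:")
            if norm.startswith("MESH:"):
                by_mesh.setdefault(norm, set()).add(term.id)
    mapping: Dict[str, Set[str]] = {}
    unmapped: List[str] = []
    for mesh in mesh_ids:
        key = mesh if mesh.startswith("MESH:") else f"MESH:{mesh}"
        if key in by_mesh:
            mapping[mesh] = set(by_mesh[key])
        else:
            unmapped.append(mesh)
    return mapping, unmapped


# ---------------------------------------------------------------------------
# Matching
# ---------------------------------------------------------------------------

def match_lexicon(
    sentence: Union[str, Sentence],
    lexicon: Lexicon,
    sentence_index: int = 0,
    id_prefix: str = "e",
) -> List[EntityMention]:
    """Case-insensitive, token-boundary, longest-match-wins matching.

    Returns non-overlapping mentions; offsets are relative to the sentence
    text.  Mentions of unmapped entries carry the ``unmapped`` flag.
    """
    if isinstance(sentence, Sentence):
        text = sentence.text
        sentence_index = sentence.index
    else:
        text = sentence
    tokens = [(m.group(), m.start(), m.end()) for m in _WORD_RE.finditer(text)]
    candidates: List[Tuple[int, int, LexiconEntry]] = []
    max_n = max(lexicon.max_words, 1)
    for i in range(len(tokens)):
        for n in range(min(max_n, len(tokens) - i), 0, -1):
            start = tokens[i][1]
            end = tokens[i + n - 1][2]
            entry = lexicon.lookup(text[start:end])
            if entry is not None:
                candidates.append((start, end, entry))
    return select_mentions(candidates, sentence_index, id_prefix, text)


def select_mentions(
    candidates: List[Tuple[int, int, LexiconEntry]],
    sentence_index: int,
    id_prefix: str,
    text: str,
) -> List[EntityMention]:
    """Resolve overlaps: longest span wins; equal-length ties resolve by
    fixed class priority, then left position, then canonical id."""
    ordered = sorted(
        candidates,
        key=lambda c: (
            -(c[1] - c[0]),
            CLASS_PRIORITY.get(c[2].entity_class, 99),
            c[0],
            c[2].canonical_id,
        ),
    )
    chosen: List[Tuple[int, int, LexiconEntry]] = []
    for start, end, entry in ordered:
        if any(not (end <= s or start >= e) for s, e, _ in chosen):
            continue
        chosen.append((start, end, entry))
    chosen.sort(key=lambda c: c[0])
    mentions = []
    for k, (start, end, entry) in enumerate(chosen):
        flags = ["unmapped"] if entry.source == "unmapped" else []
        mentions.append(
            EntityMention(
                id=f"{id_prefix}{k}",
                entity_class=entry.entity_class,
                sentence_index=sentence_index,
                start=start,
                end=end,
                surface=text[start:end],
                canonical_id=entry.canonical_id,
                flags=flags,
            )
        )
    return mentions
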