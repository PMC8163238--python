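"""Shared syntactic substrate for the relation extractors.

Two compliance levels: level A wraps an external dependency parser (none
is bundled); level B, the default, is a linear chain graph (token i →
i+1) under which all pattern matching degrades to token-window semantics.
Lemma matching is a fixed suffix-stripping table, not a lemmatizer, so
behavior is deterministic.
"""

from __future__ import annotations

import logging
import math
import re
from collections import deque
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple, Union

from .corpus_io import EntityMention, Sentence

logger = logging.getLogger(__name__)

__all__ = [
    "Token",
    "ParseGraph",
    "PatternRule",
    "MatchResult",
    "build_parse",
    "match_rule",
    "shortest_path",
    "lemma_candidates",
    "UNREACHABLE",
    "DEFAULT_WINDOW",
    "DEFAULT_PATH_BOUND",
]

UNREACHABLE = math.inf
DEFAULT_WINDOW = 8
DEFAULT_PATH_BOUND = 4

_WS_TOKEN_RE = re.compile(r"\S+")

NEGATION_TOKENS = {"not", "no", "neither", "nor", "never", "cannot", "n't"}


@dataclass
class Token:
    index: int
    surface: str
    start: int
    end: int
    pos: str = "X"

    @property
    def word(self) -> str:
        """Surface stripped of leading/trailing punctuation."""
        return self.surface.strip(".,;:()[]{}'\"“”‘’!?")


@dataclass
class ParseGraph:
    sentence_index: int
    tokens: List[Token]
    arcs: List[Tuple[int, int, str]] = field(default_factory=list)
    level: str = "B"

    def neighbours(self, i: int) -> Iterable[int]:
        for head, dep, _ in self.arcs:
            if head == i:
                yield dep
            elif dep == i:
                yield head

    def token_at(self, char_pos: int) -> Optional[int]:
        """Index of the token whose span contains ``char_pos``."""
        for tok in self.tokens:
            if tok.start <= char_pos < tok.end:
                return tok.index
        return None


@dataclass
class PatternRule:
    rule_id: str
    trigger: Set[str]                       # lemma set
    slots: List[Tuple[str, str]]            # (role name, entity class)
    path_bound: int = DEFAULT_PATH_BOUND
    window_bound: int = DEFAULT_WINDOW
    output_tag: str = ""
    negation_guard: bool = True

    def __post_init__(self) -> None:
        if not self.slots:
            raise ValueError(f"rule {self.rule_id}: needs at least one slot")
        if self.path_bound < 1:
            raise ValueError(f"rule {self.rule_id}: path bound must be >= 1")
        if self.window_bound < self.path_bound:
            raise ValueError(f"rule {self.rule_id}: window bound < path bound")


@dataclass
class MatchResult:
    rule_id: str
    trigger_index: int
    fillers: Dict[str, str]                 # role -> mention id
    sentence_index: int
    output_tag: str = ""


def tokenize(text: str) -> List[Token]:
    """Whitespace tokenization; spans tile the non-whitespace text."""
    return [
        Token(index=i, surface=m.group(), start=m.start(), end=m.end())
        for i, m in enumerate(_WS_TOKEN_RE.finditer(text))
    ]


def build_parse(sentence: Union[str, Sentence], backend=None) -> ParseGraph:
    """Build the parse graph for a sentence.

    With ``backend`` (a callable returning (tokens, arcs)) the graph is
    level A; otherwise — or on backend failure — a level-B linear chain.
    """
    if isinstance(sentence, Sentence):
        text, index = sentence.text, sentence.index
    else:
        text, index = sentence, 0
    if backend is not None:
        try:
            tokens, arcs = backend(text)
            return ParseGraph(sentence_index=index, tokens=tokens, arcs=list(arcs), level="A")
        except Exception as exc:  # pragma: no cover - backend specific
            logger.warning("parser backend failed (%s); falling back to level B", exc)
    tokens = tokenize(text)
    arcs = [(i, i + 1, "next") for i in range(len(tokens) - 1)]
    return ParseGraph(sentence_index=index, tokens=tokens, arcs=arcs, level="B")


def shortest_path(graph: ParseGraph, i: int, j: int) -> float:
    """Breadth-first undirected path length; unreachable → +inf."""
    if i == j:
        return 0
    seen = {i}
    queue = deque([(i, 0)])
    while queue:
        node, dist = queue.popleft()
        for nxt in graph.neighbours(node):
            if nxt == j:
                return dist + 1
            if nxt not in seen:
                seen.add(nxt)
                queue.append((nxt, dist + 1))
    return UNREACHABLE


# ---------------------------------------------------------------------------
# Lemmas
# ---------------------------------------------------------------------------

_IRREGULAR = {
    "found": "find",
    "showed": "show",
    "shown": "show",
    "bound": "bind",
    "binds": "bind",
    "is": "be",
    "are": "be",
    "was": "be",
    "were": "be",
    "been": "be",
    "be": "be",
    "has": "have",
    "had": "have",
}


def lemma_candidates(token: str) -> Set[str]:
    """Candidate lemmas for a token via fixed suffix stripping.

    Returns a set; a trigger matches when its lemma intersects the set
    ("suppressed" → {suppress, ...}, "targets" → {target, ...}).
    """
    word = token.strip(".,;:()[]{}'\"“”‘’!?").lower()
    if not word:
        return set()
    out = {word}
    if word in _IRREGULAR:
        out.add(_IRREGULAR[word])
        return out
    if word.endswith("ies") and len(word) > 4:
        out.add(word[:-3] + "y")
    if word.endswith("es") and len(word) > 3:
        out.add(word[:-2])
    if word.endswith("s") and not word.endswith("ss") and len(word) > 3:
        out.add(word[:-1])
    if word.endswith("ed") and len(word) > 4:
        stem = word[:-2]
        out.update({stem, stem + "e"})
        if len(stem) > 2 and stem[-1] == stem[-2]:
            out.add(stem[:-1])
    if word.endswith("ing") and len(word) > 5:
        stem = word[:-3]
        out.update({stem, stem + "e"})
        if len(stem) > 2 and stem[-1] == stem[-2]:
            out.add(stem[:-1])
    return out


def has_lemma(token: str, lemmas: Set[str]) -> bool:
    return bool(lemma_candidates(token) & lemmas)


def find_triggers(graph: ParseGraph, lemmas: Set[str]) -> List[int]:
    """Indices of tokens whose lemma candidates intersect ``lemmas``."""
    return [t.index for t in graph.tokens if lemma_candidates(t.surface) & lemmas]


def is_negated(graph: ParseGraph, trigger_index: int, reach: int = 3) -> bool:
    """True when a negation token governs/immediately precedes the trigger.

    Level-B approximation: a negation token (or "fails/failed to") within
    ``reach`` tokens before the trigger.
    """
    lo = max(0, trigger_index - reach)
    for tok in graph.tokens[lo:trigger_index]:
        word = tok.word.lower()
        if word in NEGATION_TOKENS or word.endswith("n't"):
            return True
        if word in {"fails", "failed", "fail"}:
            return True
    return False


def mention_token_index(graph: ParseGraph, mention: EntityMention) -> Optional[int]:
    return graph.token_at(mention.start)


def token_distance(graph: ParseGraph, i: int, j: int) -> float:
    """Path length under level A; |i-j| under level B."""
    if graph.level == "B":
        return abs(i - j)
    return shortest_path(graph, i, j)


def match_rule(
    rule: PatternRule,
    graph: ParseGraph,
    mentions: Sequence[EntityMention],
) -> List[MatchResult]:
    """Run one declarative rule over a parse graph.

    A match needs a trigger token whose lemma set intersects the rule's
    triggers and, for every slot, a mention of the required class whose
    head token lies within the path bound (level A) or window bound
    (level B) of the trigger.  Negation-guarded rules are suppressed when
    a negation token precedes the trigger.  All slot assignments are
    returned, ordered deterministically.
    """
    bound = rule.path_bound if graph.level == "A" else rule.window_bound
    results: List[MatchResult] = []
    for trig in find_triggers(graph, rule.trigger):
        if rule.negation_guard and is_negated(graph, trig):
            continue
        per_slot: List[List[EntityMention]] = []
        for _, entity_class in rule.slots:
            fillers = []
            for mention in mentions:
                if mention.entity_class != entity_class:
                    continue
                idx = mention_token_index(graph, mention)
                if idx is None:
                    continue
                if token_distance(graph, trig, idx) <= bound:
                    fillers.append(mention)
            per_slot.append(sorted(fillers, key=lambda m: m.start))
        if not all(per_slot):
            continue
        combos: List[Dict[str, str]] = [{}]
        for (role, _), fillers in zip(rule.slots, per_slot):
            combos = [
                {**combo, role: m.id}
                for combo in combos
                for m in fillers
                if m.id not in combo.values()
            ]
        for combo in combos:
            results.append(
                MatchResult(
                    rule_id=rule.rule_id,
                    trigger_index=trig,
                    fillers=combo,
                    sentence_index=graph.sentence_index,
                    output_tag=rule.output_tag,
                )
            )
    results.sort(key=lambda r: (r.trigger_index, sorted(r.fillers.items())))
    return results


# ---------------------------------------------------------------------------
# Coordination helpers shared by the extractors
# ---------------------------------------------------------------------------

_COORD_WORDS = {"and", "or", "including", "as", "well", "such", "plus", "namely", "both"}


def coordination_groups(
    graph: ParseGraph, mentions: Sequence[EntityMention]
) -> List[List[EntityMention]]:
    """Group same-class mentions joined only by commas/conjunctions.

    A trigger relating to any group member distributes over the whole
    group ("p-AKT, EZH2, EGFR, BMI1 and XIAP" is one group).
    """
    by_class: Dict[str, List[EntityMention]] = {}
    for m in sorted(mentions, key=lambda m: m.start):
        by_class.setdefault(m.entity_class, []).append(m)
    groups: List[List[EntityMention]] = []
    for cls_mentions in by_class.values():
        current = [cls_mentions[0]]
        for prev, nxt in zip(cls_mentions, cls_mentions[1:]):
            i = mention_token_index(graph, prev)
            j = mention_token_index(graph, nxt)
            if i is None or j is None:
                joined = False
            else:
                prev_end_tok = graph.token_at(max(prev.end - 1, prev.start))
                between = graph.tokens[(prev_end_tok if prev_end_tok is not None else i) + 1 : j]
                joined = all(t.word.lower() in _COORD_WORDS or not t.word for t in between)
            if joined:
                current.append(nxt)
            else:
                groups.append(current)
                current = [nxt]
        groups.append(current)
    groups.sort(key=lambda g: g[0].start)
    return groups


def group_token_span(graph: ParseGraph, group: Sequence[EntityMention]) -> Tuple[int, int]:
    """(first, last) token index covered by a coordination group."""
    first = mention_token_index(graph, group[0])
    last = graph.token_at(max(group[-1].end - 1, group[-1].start))
    if last is None:
        last = mention_token_index(graph, group[-1])
    return (first if first is not None else 0, last if last is not None else 0)


def group_distance(graph: ParseGraph, group: Sequence[EntityMention], index: int) -> float:
    """Distance from a token index to the nearest edge of a group."""
    first, last = group_token_span(graph, group)
    if first <= index <= last:
        return 0
    return min(token_distance(graph, index, first), token_distance(graph, index, last))
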