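"""miRNA mention detection and miRBase-style family normalization.

Detection is regular-expression based over the surface dialects seen in
abstracts (miR-21, miRNA-21, microRNA 21, hsa-miR-17-5p, let-7b-5p,
miR-125b-1, ...).  Enumerations share their prefix across items
("miR-19a/b" yields two mentions).  Normalization maps any detected
surface to a lowercase family identifier: species prefixes, arm suffixes
and genomic-copy numerals are stripped; paralog letters are preserved so
that mir-18a and mir-18b stay distinct families.
"""

from __future__ import annotations

import re
from typing import List, Union

from .corpus_io import MIRNA, EntityMention, Sentence

__all__ = [
    "NormalizationError",
    "detect_mirna_mentions",
    "normalize_mirna",
]


class NormalizationError(ValueError):
    """Raised when a surface form cannot be reduced to a family id."""


_DASH = "‐‑‒–—−"

_MIR_RE = re.compile(
    rf"(?P<prefix>[a-z]{{3,4}}[-{_DASH}])?"
    rf"(?P<head>micro[ ]?rnas?|mirnas?|mir)"
    rf"(?P<sep>[-{_DASH}\s])?"
    r"(?P<num>\d+)"
    r"(?P<letter>[a-z])?"
    r"(?P<tail>(?:-\d+(?![0-9]*p))*)"
    r"(?P<arm>-[35]p)?",
    re.IGNORECASE,
)

_LET_RE = re.compile(
    rf"(?P<prefix>[a-z]{{3,4}}[-{_DASH}])?"
    rf"(?P<head>let)"
    rf"(?P<sep>[-{_DASH}\s])?"
    r"(?P<num>7)"
    r"(?P<letter>[a-z])?"
    r"(?P<tail>(?:-\d+(?![0-9]*p))*)"
    r"(?P<arm>-[35]p)?",
    re.IGNORECASE,
)

# items of a shared-prefix enumeration: "miR-19a/b", "miR-10a/10b"
_ENUM_ITEM_RE = re.compile(r"/\s*(?P<item>\d+[a-z]?(?:-[35]p)?|[a-z](?:-[35]p)?)", re.IGNORECASE)

# single split letter after a numeric token ("miR-30 c"); 'a' and 'i' are
# excluded because they are English words
_OCR_LETTER_RE = re.compile(r" (?P<letter>[b-hj-z])(?![A-Za-z0-9])")


def _is_boundary(text: str, pos: int) -> bool:
    """True when ``pos`` does not sit inside an alphanumeric token."""
    if pos <= 0 or pos >= len(text):
        return True
    return not text[pos].isalnum()


def normalize_mirna(surface: str) -> str:
    """Normalize a detected miRNA surface to its family identifier.

    The result has shape ``mir-<number><letter?>`` or ``let-7<letter?>``:
    lowercase, species prefix stripped, arm suffix (-5p/-3p) stripped and
    the genomic-copy numeral after a paralog letter dropped
    (``miR-125b-1`` → ``mir-125b``).  Idempotent.  Cluster notations
    (``miR-17-92``) and anything outside the dialect raise
    :class:`NormalizationError`.
    """
    s = surface.strip().casefold()
    s = re.sub(f"[{_DASH}]", "-", s)
    s = re.sub(r"\s+", " ", s)
    s = re.sub(r"(\d) ([a-z])(?![a-z0-9])", r"\1\2", s)  # OCR split letter
    s = re.sub(r"^[a-z]{3,4}-(?=(?:mir|mirna|microrna|micro rna|let))", "", s)
    m = re.match(r"^(?:micro ?rnas?|mirnas?|mir)[- ]?(\d+)([a-z])?((?:-\d+)*)(-[35]p)?$", s)
    if m:
        num, letter, tail, _arm = m.groups()
        if tail:
            parts = [int(p) for p in tail.strip("-").split("-")]
            if letter is None and any(p > 3 for p in parts):
                raise NormalizationError(f"cluster notation, not a family: {surface!r}")
        return f"mir-{num}{letter or ''}"
    m = re.match(r"^let[- ]?7([a-z])?((?:-\d+)*)(-[35]p)?$", s)
    if m:
        letter = m.group(1)
        return f"let-7{letter or ''}"
    raise NormalizationError(f"unrecognized miRNA surface: {surface!r}")


def _canonical_or_flags(name: str) -> tuple:
    try:
        return normalize_mirna(name), []
    except NormalizationError:
        flags = ["unmapped"]
        if re.search(r"-\d+-\d+$", name.strip()):
            flags.insert(0, "cluster")
        return "", flags


def detect_mirna_mentions(
    sentence: Union[str, Sentence], sentence_index: int = 0, id_prefix: str = "m"
) -> List[EntityMention]:
    """Detect miRNA mentions in one sentence.

    Matches are word-boundary guarded, enumerations are expanded into one
    mention per item (the extra items span only their own text but carry
    the reconstructed canonical id), and OCR-style split paralog letters
    ("miR-30 c") are repaired into the mention.  Cluster notations are
    detected and flagged ``cluster`` instead of being normalized.
    """
    if isinstance(sentence, Sentence):
        text = sentence.text
        sentence_index = sentence.index
    else:
        text = sentence

    found: List[tuple] = []  # (start, end, full_name)
    for pattern in (_MIR_RE, _LET_RE):
        for m in pattern.finditer(text):
            start, end = m.start(), m.end()
            if start > 0 and (text[start - 1].isalnum() or text[start - 1] in "-" + _DASH):
                continue
            if m.group("head").lower() == "let" and m.group("sep") is None:
                continue  # "let7" without separator is rare; "lethal7" guard
            name = text[start:end]
            # OCR repair: single split letter right after a bare numeric token
            if (
                m.group("letter") is None
                and not m.group("tail")
                and not m.group("arm")
                and _is_boundary(text, end)
            ):
                ocr = _OCR_LETTER_RE.match(text, end)
                if ocr:
                    end = ocr.end()
                    name = text[start:end]
            if not _is_boundary(text, end):
                continue
            found.append((start, end, name))
            # enumeration items share the detected prefix
            head = m.group("head") + (m.group("sep") or "-")
            pos = end
            while pos < len(text) and text[pos] == "/":
                item_m = _ENUM_ITEM_RE.match(text, pos)
                if not item_m or not _is_boundary(text, item_m.end()):
                    break
                item = item_m.group("item")
                if item[0].isdigit():
                    full = f"{head}{item}"
                else:
                    full = f"{head}{m.group('num')}{item}"
                found.append((item_m.start("item"), item_m.end(), full))
                pos = item_m.end()

    # longest-match-wins de-overlap (let/mir alternation may double-hit)
    found.sort(key=lambda f: (f[0] - f[1], f[0]))
    chosen: List[tuple] = []
    for start, end, name in found:
        if any(not (end <= s or start >= e) for s, e, _ in chosen):
            continue
        chosen.append((start, end, name))
    chosen.sort(key=lambda f: f[0])

    mentions = []
    for k, (start, end, name) in enumerate(chosen):
        canonical, flags = _canonical_or_flags(name)
        mentions.append(
            EntityMention(
                id=f"{id_prefix}{k}",
                entity_class=MIRNA,
                sentence_index=sentence_index,
                start=start,
                end=end,
                surface=text[start:end],
                canonical_id=canonical,
                flags=flags,
            )
        )
    return mentions
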