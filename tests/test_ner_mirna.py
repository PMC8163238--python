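import random
import re

import pytest
from hypothesis import given, settings, strategies as st

from mirminer.ner_mirna import (
    NormalizationError,
    _LET_RE,
    _MIR_RE,
    detect_mirna_mentions,
    normalize_mirna,
)


class TestDetect:
    def test_single_mention(self):
        mentions = detect_mirna_mentions("miR-340 over-expression suppressed several oncogenes")
        assert [m.surface for m in mentions] == ["miR-340"]
        assert mentions[0].canonical_id == "mir-340"

    def test_enumeration_expansion(self):
        mentions = detect_mirna_mentions("oncomiRs, such as miR-17-5p, miR-19a/b, miR-21")
        assert [m.canonical_id for m in mentions] == ["mir-17", "mir-19a", "mir-19b", "mir-21"]

    def test_numbered_enumeration(self):
        mentions = detect_mirna_mentions("levels of miR-10a/10b were altered")
        assert [m.canonical_id for m in mentions] == ["mir-10a", "mir-10b"]

    def test_boundary_guard(self):
        assert detect_mirna_mentions("The MIRROR study was large.") == []
        assert detect_mirna_mentions("familiar-21 is not an miRNA") == []

    def test_conjunction_of_dialects(self):
        mentions = detect_mirna_mentions("microRNAs let-7d and miR-205 are markers")
        assert [m.canonical_id for m in mentions] == ["let-7d", "mir-205"]

    def test_surface_equals_slice(self):
        text = "Strangely, hsa-miR-17-5p and miR-30 c were measured."
        for m in detect_mirna_mentions(text):
            assert text[m.start : m.end] == m.surface

    def test_ocr_split_letter_repaired(self):
        mentions = detect_mirna_mentions("levels of miR-30 c and miR-206 remained elevated")
        assert mentions[0].surface == "miR-30 c"
        assert mentions[0].canonical_id == "mir-30c"

    def test_cluster_flagged_not_normalized(self):
        mentions = detect_mirna_mentions("the miR-17-92 cluster is amplified")
        assert len(mentions) == 1
        assert "cluster" in mentions[0].flags and "unmapped" in mentions[0].flags
        assert mentions[0].canonical_id == ""

    def test_dash_and_space_variants(self):
        for text in ["miR 21 is high", "miR–21 is high", "MicroRNA 21 is high"]:
            mentions = detect_mirna_mentions(text)
            assert len(mentions) == 1 and mentions[0].canonical_id == "mir-21"

    @settings(max_examples=150, deadline=None)
    @given(st.text(alphabet="abcmiRletMIR-0123456789 ", min_size=1, max_size=40))
    def test_exhaustive_substring_oracle(self, text):
        """Brute force: every boundary-delimited substring is tried against
        the regex set; maximal matching spans must agree with detection."""
        candidates = []
        for i in range(len(text)):
            for j in range(i + 1, len(text) + 1):
                before_ok = i == 0 or not (text[i - 1].isalnum() or text[i - 1] == "-")
                after_ok = j == len(text) or not text[j].isalnum()
                if not (before_ok and after_ok):
                    continue
                sub = text[i:j]
                if _MIR_RE.fullmatch(sub) or _LET_RE.fullmatch(sub):
                    if " " in sub:  # keep the oracle free of OCR/space repair
                        continue
                    candidates.append((i, j))
        maximal = [
            (i, j)
            for (i, j) in candidates
            if not any((a <= i and j <= b and (a, b) != (i, j)) for a, b in candidates)
        ]
        detected = [(m.start, m.end) for m in detect_mirna_mentions(text)]
        for span in maximal:
            assert any(not (span[1] <= s or span[0] >= e) for s, e in detected), (
                text,
                span,
                detected,
            )
        for s, e in detected:
            assert any(not (e <= i or s >= j) for i, j in candidates) or " " in text[s:e] or "/" in text[max(0,s-1):e]


class TestNormalize:
    @pytest.mark.parametrize(
        "surface,family",
        [
            ("let-7b-5p", "let-7b"),
            ("hsa-miR-17-5p", "mir-17"),
            ("microRNA-29b", "mir-29b"),
            ("MicroRNA 21", "mir-21"),
            ("miRNA-21", "mir-21"),
            ("miR-125b-1", "mir-125b"),
            ("mmu-miR-155", "mir-155"),
            ("miR–21", "mir-21"),
            ("miR-30 c", "mir-30c"),
            ("let-7", "let-7"),
            ("Let-7i", "let-7i"),
        ],
    )
    def test_dialects(self, surface, family):
        assert normalize_mirna(surface) == family

    def test_idempotence_over_dialect_grammar(self):
        for prefix in ["", "hsa-", "mmu-"]:
            for head in ["miR", "mir", "miRNA", "microRNA", "MicroRNA"]:
                for sep in ["-", " "]:
                    for num, letter in [("21", ""), ("18", "a"), ("18", "b"), ("125", "b")]:
                        for copy in ["", "-1"]:
                            for arm in ["", "-5p", "-3p"]:
                                if copy and not letter:
                                    continue
                                surface = f"{prefix}{head}{sep}{num}{letter}{copy}{arm}"
                                fam = normalize_mirna(surface)
                                assert normalize_mirna(fam) == fam
                                assert re.fullmatch(r"(mir-\d+[a-z]?|let-7[a-z]?)", fam)

    def test_paralog_letters_never_collapse(self):
        assert normalize_mirna("miR-18a") != normalize_mirna("miR-18b")
        assert normalize_mirna("hsa-miR-18a-5p") == "mir-18a"

    def test_cluster_raises(self):
        with pytest.raises(NormalizationError):
            normalize_mirna("miR-17-92")

    def test_garbage_raises(self):
        with pytest.raises(NormalizationError):
            normalize_mirna("BRCA1")

    def test_no_silent_drops(self):
        # every detected mention is normalized or flagged
        rng = random.Random(5)
        texts = [
            "miR-21 and miR-17-92 with let-7b/c and hsa-miR-10a/10b here",
            "miRNA-155, microRNA 29b and miR-30 c were assayed",
        ]
        for text in texts:
            for m in detect_mirna_mentions(text):
                assert m.canonical_id or "unmapped" in m.flags
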