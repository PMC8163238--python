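import random

import pytest

from conftest import make_document
from mirminer.corpus_io import document_from_text
from mirminer.corpus_store import (
    QueryExpression,
    aspect_view,
    build_index,
    filter_rows,
    parse_query,
    query_context,
    query_disease,
    query_mirna,
    sort_rows,
    summarize_counts,
    tokenize_text,
)
from mirminer.pipeline import annotate, extract, process_corpus
from mirminer.synth_corpus import GeneratorConfig, generate_corpus

DOID_SNIPPET = """
[Term]
id: DOID:684
name: hepatocellular carcinoma
synonym: "HCC" EXACT []
synonym: "liver cell carcinoma" EXACT []
"""


def _random_docs(n, seed=0):
    rng = random.Random(seed)
    docs = []
    for i in range(n):
        words = [rng.choice(["alpha", "beta", "mirna", "miR-21", "serum", "tumor"])
                 for _ in range(rng.randint(3, 8))]
        docs.append(document_from_text(f"p{i}", "Title here.", " ".join(words) + "."))
    return docs


class TestBuildIndex:
    def test_empty(self):
        index = build_index([])
        assert index.documents == {} and index.token_index == {}

    def test_family_index(self, resources):
        doc = annotate(document_from_text("1", "", "miR-21 was studied."), resources)
        index = build_index([doc])
        assert index.family_index == {"mir-21": {"1"}}

    def test_token_index_full_scan_oracle(self):
        docs = _random_docs(50, seed=3)
        index = build_index(docs)
        for token in ["alpha", "mir-21", "serum", "zzz"]:
            expected = {
                d.pmid for d in docs if token in tokenize_text(
                    "\n".join([d.title] + [s.text for s in d.sentences])
                )
            }
            assert index.token_index.get(token, set()) == expected

    def test_rebuild_idempotent(self):
        docs = _random_docs(20, seed=5)
        a, b = build_index(docs), build_index(docs)
        assert a.token_index == b.token_index and a.family_index == b.family_index


class TestQueryMirna:
    def test_absent_family_empty(self):
        assert query_mirna(build_index(_random_docs(5)), "mir-9999") == []

    def test_normalization_oracle(self, resources):
        # surface dialect differs from the queried family id
        doc = annotate(document_from_text("7", "", "microRNA-21 was elevated here."), resources)
        index = build_index([doc])
        assert [d.pmid for d in query_mirna(index, "mir-21")] == ["7"]

    def test_results_subset_of_corpus(self, resources):
        docs = [annotate(d, resources) for d in _random_docs(10, seed=1)]
        index = build_index(docs)
        results = query_mirna(index, "mir-21")
        assert {d.pmid for d in results} <= {d.pmid for d in docs}


class TestQueryContext:
    def test_mirna_cue_required(self):
        docs = [
            document_from_text("1", "", "alpha beta gamma."),
            document_from_text("2", "", "alpha miR-21 gamma."),
        ]
        index = build_index(docs)
        assert [d.pmid for d in query_context(index, "alpha")] == ["2"]

    def test_boolean_monotonicity(self):
        index = build_index(_random_docs(50, seed=9))
        a, b = QueryExpression.lit("alpha"), QueryExpression.lit("beta")
        or_result = {d.pmid for d in query_context(index, QueryExpression.or_(a, b))}
        and_result = {d.pmid for d in query_context(index, QueryExpression.and_(a, b))}
        assert and_result <= or_result

    def test_full_scan_oracle(self):
        docs = _random_docs(50, seed=11)
        index = build_index(docs)
        expr = parse_query("alpha AND (serum OR tumor)")
        got = {d.pmid for d in query_context(index, expr)}
        expected = set()
        for d in docs:
            toks = set(
                tokenize_text("\n".join([d.title] + [s.text for s in d.sentences]))
            )
            if "alpha" in toks and ("serum" in toks or "tumor" in toks):
                if any(t in {"mirna", "mir"} or t.startswith(("mir-", "let-7")) for t in toks):
                    expected.add(d.pmid)
        assert got == expected

    def test_parse_errors(self):
        with pytest.raises(ValueError):
            parse_query("")
        with pytest.raises(ValueError):
            parse_query("(alpha AND")


class TestQueryDisease:
    def test_synonym_expansion(self, resources):
        # oracle: OBO scan gives name + 2 synonyms -> 3-literal OR query
        docs = [
            annotate(document_from_text("1", "", "HCC and miR-122 were linked."), resources),
            annotate(document_from_text("2", "", "hepatocellular carcinoma with miR-21."), resources),
            annotate(document_from_text("3", "", "Unrelated miR-9 text."), resources),
        ]
        index = build_index(docs)
        got = {d.pmid for d in query_disease(index, "DOID:684", DOID_SNIPPET)}
        assert got == {"1", "2"}

    def test_name_resolves(self, resources):
        doc = annotate(document_from_text("1", "", "HCC and miR-122 were linked."), resources)
        index = build_index([doc])
        assert query_disease(index, "hepatocellular carcinoma", DOID_SNIPPET)

    def test_unknown_doid_errors(self):
        with pytest.raises(KeyError):
            query_disease(build_index([]), "DOID:99999", DOID_SNIPPET)


@pytest.fixture(scope="module")
def extracted(resources):
    texts = [
        ("1", "miR-21 directly targets PTEN in glioma cells."),
        ("2", "Phosphatase and tensin homolog was suppressed by miR-221 here."),
        ("3", "miR-29b promotes apoptosis in these cells."),
    ]
    return [
        extract(annotate(document_from_text(p, "", t), resources))
        for p, t in texts
    ]


class TestAspectView:

    def test_row_count_matches_relations(self, extracted):
        rows = aspect_view(extracted, "gene_regulation")
        expected = sum(
            1
            for d in extracted
            for r in d.relations
            if r.family in ("mirna_target", "mirna_gene", "gene_mirna")
        )
        assert len(rows) == expected

    def test_filter_catches_synonym_via_normalization(self, extracted, resources):
        rows = aspect_view(extracted, "gene_regulation", resources=resources)
        hits = filter_rows(rows, "PTEN")
        assert {r["pmid"] for r in hits} == {"1", "2"}

    def test_filter_never_increases(self, extracted):
        rows = aspect_view(extracted, "gene_regulation")
        assert len(filter_rows(rows, "mir")) <= len(rows)

    def test_sort_stable(self, extracted):
        rows = aspect_view(extracted, "gene_regulation")
        tagged = [dict(r, order=str(i)) for i, r in enumerate(rows)]
        sorted_rows = sort_rows(tagged, "relation_family")
        for a, b in zip(sorted_rows, sorted_rows[1:]):
            if a["relation_family"] == b["relation_family"]:
                assert int(a["order"]) < int(b["order"])

    def test_unknown_aspect(self, extracted):
        with pytest.raises(KeyError):
            aspect_view(extracted, "nope")


class TestSummarizeCounts:
    def test_empty_zero(self):
        summary = summarize_counts(build_index([]))
        assert summary["documents"] == 0
        assert summary["unique_mirnas"] == 0
        assert summary["relations_total"] == 0

    def test_generator_bookkeeping_oracle(self, resources):
        docs, gold = generate_corpus(
            GeneratorConfig(seed=13, n_documents=45, distractor_rate=0.0), resources
        )
        process_corpus(docs, resources)
        summary = summarize_counts(build_index(docs))
        expected_per_family = {}
        for g in gold:
            expected_per_family[g.family] = expected_per_family.get(g.family, 0) + 1
        assert summary["relations_per_family"] == expected_per_family
        assert summary["relations_total"] == len(gold)

    def test_permutation_invariant(self, resources):
        docs, _ = generate_corpus(
            GeneratorConfig(seed=2, n_documents=20, distractor_rate=0.0), resources
        )
        process_corpus(docs, resources)
        a = summarize_counts(build_index(docs))
        b = summarize_counts(build_index(list(reversed(docs))))
        assert a == b
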