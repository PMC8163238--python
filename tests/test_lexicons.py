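import pytest

from mirminer.corpus_io import FLUID, GENE, PROCESS, TRANSPORTER
from mirminer.lexicons import (
    Lexicon,
    LexiconEntry,
    build_gene_lexicon,
    build_location_lexicon,
    build_process_lexicon,
    map_mesh_to_doid,
    match_lexicon,
    mine_process_terms,
    parse_obo,
    slugify,
)

GO_SNIPPET = """
[Term]
id: GO:0006915
name: apoptotic process
synonym: "apoptosis" EXACT []

[Term]
id: GO:0008219
name: cell death
"""

PW_SNIPPET = """
[Term]
id: PW:0000008
name: Wnt signaling pathway
"""


class TestParseObo:
    def test_names_and_synonyms(self):
        terms = parse_obo(GO_SNIPPET)
        assert [t.id for t in terms] == ["GO:0006915", "GO:0008219"]
        assert terms[0].synonyms == ["apoptosis"]

    def test_unparseable_stanza_named(self):
        with pytest.raises(ValueError, match="GO:0006915"):
            parse_obo("[Term]\nid: GO:0006915\nbroken line without separator\n")

    def test_xrefs(self):
        terms = parse_obo("[Term]\nid: DOID:1\nname: x\nxref: MESH:D1 trailing\n")
        assert terms[0].xrefs == ["MESH:D1"]


class TestProcessLexicon:
    def test_synonyms_share_one_id(self):
        # oracle: OBO parse gives 2 surfaces for GO:0006915
        lex = build_process_lexicon(GO_SNIPPET, PW_SNIPPET)
        assert lex.lookup("apoptosis").canonical_id == "GO:0006915"
        assert lex.lookup("apoptotic process").canonical_id == "GO:0006915"

    def test_empty_mined_terms(self):
        lex = build_process_lexicon(GO_SNIPPET, PW_SNIPPET, [])
        assert len(lex) == 4  # 3 GO surfaces + 1 PW name

    def test_mined_term_matching_go_name_gets_go_id(self):
        lex = build_process_lexicon(GO_SNIPPET, PW_SNIPPET, ["cell death"])
        assert lex.lookup("cell death").canonical_id == "GO:0008219"

    def test_mined_term_without_match_gets_slug(self):
        lex = build_process_lexicon(GO_SNIPPET, PW_SNIPPET, ["endothelial permeability"])
        entry = lex.lookup("endothelial permeability")
        assert entry.canonical_id == slugify("endothelial permeability")
        assert entry.source == "mined"


class TestMineProcessTerms:
    def test_three_listed_terms(self):
        terms = mine_process_terms(
            ["These miRNAs affect cellular processes such as migration, invasion and cell death."]
        )
        assert terms == ["migration", "invasion", "cell death"]

    def test_no_cue(self):
        assert mine_process_terms(["miR-21 and PTEN co-occur here."]) == []

    def test_including_variant(self):
        # oracle: split "X and Y" on the conjunction
        assert mine_process_terms(["processes including X and Y."]) == ["X", "Y"]

    def test_determiners_trimmed(self):
        terms = mine_process_terms(["biological processes such as the cell cycle and an immune response."])
        assert terms == ["cell cycle", "immune response"]

    def test_closure_with_lexicon(self):
        sentence = "It alters cellular processes such as migration, invasion and cell death."
        mined = mine_process_terms([sentence])
        lex = build_process_lexicon(GO_SNIPPET, PW_SNIPPET, mined)
        surfaces = {m.surface.lower() for m in match_lexicon(sentence, lex)}
        assert {t.lower() for t in mined} <= surfaces


class TestLocationLexicon:
    def test_bto_normalization(self, resources):
        entry = resources.fluid.lookup("serum")
        assert entry.canonical_id.startswith("BTO:")

    def test_seminal_plasma_present(self, resources):
        entry = resources.fluid.lookup("seminal plasma")
        assert entry is not None and entry.entity_class == FLUID

    def test_unmatched_fluid_flagged(self):
        fluids, _ = build_location_lexicon(["mystery fluid"], [], None)
        entry = fluids.lookup("mystery fluid")
        assert entry.source == "unmapped"
        assert entry.canonical_id == slugify("mystery fluid")

    def test_empty_transporters(self):
        fluids, transporters = build_location_lexicon(["serum"], [], None)
        assert len(transporters) == 0 and len(fluids) == 1

    def test_transporter_class(self, resources):
        assert resources.transporter.lookup("exosomal").entity_class == TRANSPORTER
        assert resources.transporter.lookup("exosomal").canonical_id == slugify("exosome")


class TestMeshToDoid:
    OBO = """
[Term]
id: DOID:1
name: one
xref: MESH:D100

[Term]
id: DOID:2
name: two
xref: MESH:D200

[Term]
id: DOID:3
name: three
xref: MESH:D200
"""

    def test_singleton(self):
        mapping, unmapped = map_mesh_to_doid(["MESH:D100"], self.OBO)
        assert mapping == {"MESH:D100": {"DOID:1"}} and unmapped == []

    def test_absent_listed_unmapped(self):
        mapping, unmapped = map_mesh_to_doid(["MESH:D999"], self.OBO)
        assert mapping == {} and unmapped == ["MESH:D999"]

    def test_two_doids_retained(self):
        mapping, _ = map_mesh_to_doid(["MESH:D200"], self.OBO)
        assert mapping["MESH:D200"] == {"DOID:2", "DOID:3"}

    def test_bare_id_accepted(self):
        mapping, _ = map_mesh_to_doid(["D100"], self.OBO)
        assert mapping["D100"] == {"DOID:1"}


class TestMatchLexicon:
    def test_single_process_mention(self, resources):
        mentions = match_lexicon("apoptosis in cells", resources.process)
        assert len(mentions) == 1
        assert mentions[0].entity_class == PROCESS

    def test_longest_match_wins(self):
        lex = Lexicon(PROCESS)
        lex.add(LexiconEntry("cell", "GO:0000001", PROCESS))
        lex.add(LexiconEntry("cell death", "GO:0008219", PROCESS))
        text = "induces cell death quickly"
        mentions = match_lexicon(text, lex)
        # oracle: exhaustive span check — "cell death" covers "cell"
        assert [m.surface for m in mentions] == ["cell death"]

    def test_gene_synonym_same_id(self, resources):
        a = match_lexicon("PTEN is lost", resources.gene)
        b = match_lexicon("phosphatase and tensin homolog is lost", resources.gene)
        assert a[0].canonical_id == b[0].canonical_id == "5728"

    def test_token_boundary_respected(self, resources):
        assert match_lexicon("serumal nonsense", resources.fluid) == []

    def test_no_overlaps_and_surfaces_in_lexicon(self, resources):
        text = "Serum and plasma apoptosis in blood serum samples"
        mentions = match_lexicon(text, resources.fluid)
        spans = sorted((m.start, m.end) for m in mentions)
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            assert e1 <= s2
        for m in mentions:
            assert m.surface.casefold() in {s for s in resources.fluid.surfaces()}

    def test_case_insensitive(self, resources):
        assert match_lexicon("SERUM sample", resources.fluid)[0].surface == "SERUM"


def test_duplicate_entries_collapse():
    lex = Lexicon(GENE)
    lex.add(LexiconEntry("PTEN", "5728", GENE))
    lex.add(LexiconEntry("PTEN", "5728", GENE))
    assert len(lex) == 1


def test_empty_surface_rejected():
    with pytest.raises(ValueError, match="empty surface"):
        LexiconEntry("   ", "5728", GENE)


def test_malformed_ontology_id_rejected():
    with pytest.raises(ValueError, match="GO"):
        LexiconEntry("x", "GO:12", PROCESS)
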