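from mirminer.corpus_io import document_from_text
from mirminer.pipeline import annotate
from mirminer.rel_roles import (
    ROLE_BIOMARKER,
    ROLE_OTHER,
    ROLE_OUTCOME,
    ROLE_THERAPEUTIC_TARGET,
    ROLE_TREATMENT,
    extract_diffexpr,
    extract_disease_roles,
    extract_process_relations,
)


def _doc(text, resources, title=""):
    return annotate(document_from_text("t", title, text), resources)


def _canon(doc, mention_id):
    return doc.entity_by_id(mention_id).canonical_id


class TestProcessRelations:
    def test_conjoined_positive_regulation(self, resources):
        doc = _doc(
            "MicroRNA-29b promotes high-fat diet-stimulated endothelial permeability "
            "and apoptosis in apoE knock-out mice by down-regulating MT1 expression.",
            resources,
        )
        rels = extract_process_relations(doc)
        pairs = {(_canon(doc, r.mirna), _canon(doc, r.process), r.relation) for r in rels}
        assert pairs == {
            ("mir-29b", "term:endothelial-permeability", "regulation_positive"),
            ("mir-29b", "GO:0006915", "regulation_positive"),
        }

    def test_promoting_proliferation(self, resources):
        doc = _doc("In glioma, miR-221 promotes cell proliferation by targeting PTEN.", resources)
        rels = extract_process_relations(doc)
        assert any(
            r.relation == "regulation_positive" and _canon(doc, r.process) == "GO:0008283"
            for r in rels
        )

    def test_no_process_mention(self, resources):
        doc = _doc("miR-21 suppressed PTEN in these cells.", resources)
        assert extract_process_relations(doc) == []

    def test_involvement_and_association(self, resources):
        doc = _doc("miR-34a is involved in apoptosis and autophagy.", resources)
        rels = extract_process_relations(doc)
        assert {(r.relation, _canon(doc, r.process)) for r in rels} == {
            ("involvement", "GO:0006915"),
            ("involvement", "GO:0006914"),
        }

    def test_process_class_invariant(self, resources):
        doc = _doc("miR-221 enhances invasion in these cells.", resources)
        for rel in extract_process_relations(doc):
            assert doc.entity_by_id(rel.process).entity_class == "PROCESS"


class TestDiseaseRoles:
    def test_biomarker(self, resources):
        doc = _doc(
            "From a clinical point of view, our study emphasizes miR-122 as a "
            "diagnostic and prognostic marker for HCC progression.",
            resources,
        )
        rels = extract_disease_roles(doc)
        assert len(rels) == 1
        rel = rels[0]
        assert rel.role == ROLE_BIOMARKER
        assert rel.disease == "DOID:684"
        assert rel.disease_provenance == "same_sentence"
        assert "diagnostic" in rel.qualifier and "prognostic" in rel.qualifier

    def test_therapeutic_target(self, resources):
        doc = _doc(
            "Our data suggest that miR-429 may serve as a potential anticancer "
            "target for the treatment of HCC.",
            resources,
        )
        rels = extract_disease_roles(doc)
        assert [(r.role, _canon(doc, r.mirna)) for r in rels] == [
            (ROLE_THERAPEUTIC_TARGET, "mir-429")
        ]

    def test_outcome(self, resources):
        doc = _doc(
            "High miR-21 expression is associated with poor survival and poor "
            "therapeutic outcome.",
            resources,
        )
        rels = extract_disease_roles(doc)
        assert [(r.role, _canon(doc, r.mirna)) for r in rels] == [(ROLE_OUTCOME, "mir-21")]

    def test_treatment(self, resources):
        doc = _doc(
            "The role of miR-181a in conferring cellular resistance to radiation "
            "treatment was validated both in cell culture models and in mouse "
            "tumor xenograft models.",
            resources,
        )
        rels = extract_disease_roles(doc)
        assert [(r.role, _canon(doc, r.mirna)) for r in rels] == [(ROLE_TREATMENT, "mir-181a")]

    def test_four_other_relations(self, resources):
        doc = _doc(
            "Altered expression of miR-21, miR-31, miR-143 and miR-145 is related "
            "to clinicopathologic features of colorectal cancer.",
            resources,
        )
        rels = extract_disease_roles(doc)
        assert all(r.role == ROLE_OTHER and r.disease == "DOID:9256" for r in rels)
        assert {_canon(doc, r.mirna) for r in rels} == {
            "mir-21", "mir-31", "mir-143", "mir-145",
        }
        assert len(rels) == 4

    def test_prognostic_markers_copular_plural(self, resources):
        doc = _doc(
            "Low-level expression of microRNAs let-7d and miR-205 are prognostic "
            "markers of head and neck squamous cell carcinoma.",
            resources,
        )
        rels = extract_disease_roles(doc)
        assert {(r.role, _canon(doc, r.mirna)) for r in rels} == {
            (ROLE_BIOMARKER, "let-7d"),
            (ROLE_BIOMARKER, "mir-205"),
        }

    def test_title_provenance(self, resources):
        doc = _doc(
            "miR-7 may serve as a prognostic marker in these patients.",
            resources,
            title="MicroRNA profiling in stomach cancer.",
        )
        rels = extract_disease_roles(doc)
        assert len(rels) == 1
        assert rels[0].disease == "DOID:10534"
        assert rels[0].disease_provenance == "title"

    def test_role_partition_other_suppressed(self, resources):
        doc = _doc(
            "miR-122 may serve as a prognostic marker for hepatocellular carcinoma.",
            resources,
        )
        rels = extract_disease_roles(doc)
        assert {r.role for r in rels} == {ROLE_BIOMARKER}

    def test_dedup_per_key(self, resources):
        doc = _doc(
            "miR-21 is associated with poor survival and poor prognosis in lung cancer.",
            resources,
        )
        rels = extract_disease_roles(doc)
        keys = [( _canon(doc, r.mirna), r.disease, r.role, r.sentence_index) for r in rels]
        assert len(keys) == len(set(keys))

    def test_provenance_always_recorded(self, resources):
        doc = _doc("miR-21 is associated with poor survival here.", resources)
        for rel in extract_disease_roles(doc):
            assert rel.disease_provenance in {"same_sentence", "title", "nearest_prior", "none"}


class TestDiffExpr:
    def test_reduced_in_tumors(self, resources):
        doc = _doc(
            "Extrapolation of this study to human primary HCCs revealed that miR-122 "
            "expression was significantly (P = 0.013) reduced in 10 out of 20 tumors "
            "compared to the pair-matched control tissues.",
            resources,
        )
        rels = extract_diffexpr(doc)
        assert len(rels) == 1
        rel = rels[0]
        assert rel.direction == "down"
        assert _canon(doc, rel.mirna) == "mir-122"
        assert rel.sample_descriptor == "tumors"
        assert rel.comparison_descriptor == "pair-matched control tissues"

    def test_elevated_pair(self, resources):
        doc = _doc(
            "We found that levels of miR-30 c and miR-206 remained significantly "
            "elevated in DMD patients relative to controls over the entire study length.",
            resources,
        )
        rels = extract_diffexpr(doc)
        assert {(_canon(doc, r.mirna), r.direction) for r in rels} == {
            ("mir-30c", "up"),
            ("mir-206", "up"),
        }
        assert all(r.comparison_descriptor == "controls" for r in rels)

    def test_incomplete_frame_guard(self, resources):
        doc = _doc("miR-21 levels were elevated significantly.", resources)
        assert extract_diffexpr(doc) == []

    def test_unknown_direction_word_never_emits(self, resources):
        doc = _doc("miR-21 expression was altered in tumors compared to controls.", resources)
        assert extract_diffexpr(doc) == []

    def test_direction_before_mirna_not_linked(self, resources):
        doc = _doc("TGF-β1 increased miR-34a expression in cardiac fibroblasts.", resources)
        assert extract_diffexpr(doc) == []

    def test_disease_resolution_same_sentence(self, resources):
        doc = _doc(
            "miR-375 expression was markedly reduced in stomach cancer tissues "
            "compared with matched controls.",
            resources,
        )
        rels = extract_diffexpr(doc)
        assert rels[0].disease == "DOID:10534"
        assert rels[0].disease_provenance == "same_sentence"
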