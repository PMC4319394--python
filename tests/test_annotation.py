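"""RDF annotation: qualifiers, identifiers.org URIs, MIRIAM URNs."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from cellsim import annotation as ann
from cellsim.document import parse_cellml, serialize_cellml
from cellsim.errors import MissingSubjectError, RdfParseError, \
    VocabularyError
from cellsim.simulation import SimulationSetup, run_simulation

CHEBI_CA = ann.CompactIdentifier("chebi", "CHEBI:29108")
IS_VERSION_OF = ann.Qualifier("biology", "isVersionOf")


def test_calcium_is_version_of(decay_model):
    triple = ann.add_annotation(decay_model, "Ca_i", IS_VERSION_OF, CHEBI_CA)
    assert triple.predicate \
        == "http://biomodels.net/biology-qualifiers/isVersionOf"
    assert triple.object == "http://identifiers.org/chebi/CHEBI:29108"
    listed = ann.list_annotations(decay_model, "Ca_i")
    assert listed == [triple]


def test_adding_same_triple_twice_is_idempotent(decay_model):
    ann.add_annotation(decay_model, "Ca_i", IS_VERSION_OF, CHEBI_CA)
    ann.add_annotation(decay_model, "Ca_i", IS_VERSION_OF, CHEBI_CA)
    assert len(ann.list_annotations(decay_model)) == 1


def test_unknown_qualifier_term_lists_valid_ones():
    with pytest.raises(VocabularyError, match="isVersionOf"):
        ann.Qualifier("biology", "isKindaLike")


def test_missing_subject_error(decay_model):
    with pytest.raises(MissingSubjectError):
        ann.add_annotation(decay_model, "nope", IS_VERSION_OF, CHEBI_CA)


def test_minting_attaches_deterministic_id(decay_model):
    var = decay_model.components[0].variable("a")
    assert var.cmeta_id is None
    triple = ann.add_annotation(decay_model, var, IS_VERSION_OF, CHEBI_CA)
    assert var.cmeta_id == "id_00001"
    assert triple.subject_id == "id_00001"


def test_fresh_model_has_no_annotations(fhn_model):
    assert ann.list_annotations(fhn_model) == []


def test_two_annotations_sorted_deterministically(decay_model):
    t1 = ann.add_annotation(decay_model, "Ca_i",
                            ann.Qualifier("biology", "is"), CHEBI_CA)
    t2 = ann.add_annotation(decay_model, "Ca_i", IS_VERSION_OF, CHEBI_CA)
    listed = ann.list_annotations(decay_model)
    assert listed == sorted(listed, key=lambda t: (t.subject, t.predicate,
                                                   t.object))
    assert {t1, t2} == set(listed)


def test_seeded_miriam_urn_converted_and_flagged(decay_text):
    rdf = ('<rdf:RDF xmlns:rdf="http://www.w3.org/1999/02/22-rdf-syntax-ns#"'
           ' xmlns:bqbiol="http://biomodels.net/biology-qualifiers/">'
           '<rdf:Description rdf:about="#Ca_i">'
           '<bqbiol:isVersionOf rdf:resource='
           '"urn:miriam:obo.go:GO%3A0005248"/>'
           "</rdf:Description></rdf:RDF>")
    model = parse_cellml(decay_text.replace("</model>", rdf + "\n</model>"))
    (triple,) = ann.list_annotations(model)
    assert triple.object == "http://identifiers.org/obo.go/GO:0005248"
    assert triple.deprecated_source


class TestUrnConversion:
    def test_percent_decoding(self):
        assert ann.urn_to_identifiers_uri("urn:miriam:obo.go:GO%3A0005248") \
            == "http://identifiers.org/obo.go/GO:0005248"

    def test_plain_id(self):
        assert ann.urn_to_identifiers_uri("urn:miriam:uniprot:P12345") \
            == "http://identifiers.org/uniprot/P12345"

    def test_non_urn_rejected(self):
        with pytest.raises(ValueError):
            ann.urn_to_identifiers_uri("http://identifiers.org/x/y")

    @given(collection=st.from_regex(r"[a-z0-9._]{1,12}", fullmatch=True),
           local=st.from_regex(r"[A-Za-z0-9:._-]{1,16}", fullmatch=True))
    def test_round_trip_on_urn_grammar(self, collection, local):
        from urllib.parse import quote
        urn = f"urn:miriam:{collection}:" + quote(local, safe="")
        uri = ann.urn_to_identifiers_uri(urn)
        assert ann.identifiers_uri_to_urn(uri) == urn


_qualifiers = st.one_of(
    st.sampled_from(ann.BIOLOGY_QUALIFIERS).map(
        lambda t: ann.Qualifier("biology", t)),
    st.sampled_from(ann.MODEL_QUALIFIERS).map(
        lambda t: ann.Qualifier("model", t)))
_refs = st.builds(ann.CompactIdentifier,
                  st.from_regex(r"[a-z0-9._]{1,10}", fullmatch=True),
                  st.from_regex(r"[A-Za-z0-9:._-]{1,12}", fullmatch=True))


@given(triples=st.lists(st.tuples(_qualifiers, _refs), max_size=6))
def test_triple_set_round_trips_through_serialization(decay_text, triples):
    model = parse_cellml(decay_text, base_locator="decay.cellml")
    for qual, ref in triples:
        ann.add_annotation(model, "Ca_i", qual, ref)
    before = ann.list_annotations(model)
    reparsed = parse_cellml(serialize_cellml(model),
                            base_locator="decay.cellml")
    assert ann.list_annotations(reparsed) == before


def test_corrupted_rdf_detected_but_model_simulable(invalid_suite):
    from cellsim.runtime import build_runtime
    model = parse_cellml(invalid_suite["corrupted-rdf"])
    with pytest.raises(RdfParseError) as exc:
        ann.extract_rdf(model)
    assert exc.value.line is not None
    store = run_simulation(build_runtime(model),
                           SimulationSetup(0.0, 1.0, 0.1))
    assert store.capacity == 11


def test_annotation_never_perturbs_simulation(decay_model, decay_runtime):
    """DataStores before and after annotating are bitwise identical."""
    from cellsim.runtime import build_runtime
    setup = SimulationSetup(0.0, 10.0, 0.1)
    before = run_simulation(build_runtime(decay_model), setup)
    ann.add_annotation(decay_model, "Ca_i", IS_VERSION_OF, CHEBI_CA)
    annotated = parse_cellml(serialize_cellml(decay_model),
                             base_locator="decay.cellml")
    assert ann.list_annotations(annotated)   # annotation survived
    after = run_simulation(build_runtime(annotated), setup)
    assert before.equal(after)


def test_zero_triples_serialize_without_rdf_block(decay_model):
    ann.embed_rdf(decay_model, [])
    assert "rdf" not in serialize_cellml(decay_model).lower()
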