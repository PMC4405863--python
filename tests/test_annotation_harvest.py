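import warnings

import pytest

from sbmlfeatures import (
    FormatError,
    InputError,
    build_corpus_index,
    df_filter,
    index_records,
    method2_topdown,
    normalize_identifier,
    parse_sbml_annotations,
)

from helpers import (
    chain_taxonomy,
    index_from_counts,
    records_for,
    small_tree,
)

SBML_DOC = """<?xml version="1.0" encoding="UTF-8"?>
<sbml xmlns="http://www.sbml.org/sbml/level2/version4" level="2" version="4">
  <model id="mod1" metaid="mod1">
    <annotation>
      <rdf:RDF xmlns:rdf="http://www.w3.org/1999/02/22-rdf-syntax-ns#"
               xmlns:bqmodel="http://biomodels.net/model-qualifiers/">
        <rdf:Description rdf:about="#mod1">
          <bqmodel:isDescribedBy>
            <rdf:Bag>
              <rdf:li rdf:resource="http://identifiers.org/pubmed/12345"/>
            </rdf:Bag>
          </bqmodel:isDescribedBy>
        </rdf:Description>
      </rdf:RDF>
    </annotation>
    <listOfSpecies>
      <species id="s1" metaid="meta_s1">
        <annotation>
          <rdf:RDF xmlns:rdf="http://www.w3.org/1999/02/22-rdf-syntax-ns#"
                   xmlns:bqbiol="http://biomodels.net/biology-qualifiers/">
            <rdf:Description rdf:about="#meta_s1">
              <bqbiol:is>
                <rdf:Bag>
                  <rdf:li rdf:resource="urn:miriam:obo.go:GO%3A0006402"/>
                  <rdf:li rdf:resource="http://identifiers.org/chebi/CHEBI:4167"/>
                </rdf:Bag>
              </bqbiol:is>
            </rdf:Description>
          </rdf:RDF>
        </annotation>
      </species>
    </listOfSpecies>
    <listOfReactions>
      <reaction id="r1" sboTerm="SBO:0000252"/>
    </listOfReactions>
  </model>
</sbml>
"""

EMPTY_SBML = """<?xml version="1.0"?>
<sbml xmlns="http://www.sbml.org/sbml/level3/version1/core" level="3" version="1">
  <model id="empty"/>
</sbml>
"""


@pytest.mark.parametrize(
    "uri, expected",
    [
        ("http://identifiers.org/chebi/CHEBI:4167", ("CHEBI", "CHEBI:4167")),
        ("urn:miriam:obo.go:GO%3A0051234", ("GO", "GO:0051234")),
        ("urn:miriam:obo.go:GO:0051234", ("GO", "GO:0051234")),
        ("https://identifiers.org/GO:0006402", ("GO", "GO:0006402")),
        ("http://identifiers.org/biomodels.sbo/SBO:0000064", ("SBO", "SBO:0000064")),
        ("http://identifiers.org/uniprot/P04637", ("other", "P04637")),
        ("SBO:0000252", ("SBO", "SBO:0000252")),
        ("http://identifiers.org/syn/SYN:0000012", ("SYN", "SYN:0000012")),
        ("urn:miriam:syn:SYN%3A0000012", ("SYN", "SYN:0000012")),
        ("not a uri at all", (None, "not a uri at all")),
        ("http://example.org/foo", (None, "http://example.org/foo")),
    ],
)
def test_normalize_identifier(uri, expected):
    assert normalize_identifier(uri) == expected


class TestParseSbml:
    def test_extracts_rdf_and_sboterm_records(self, tmp_path):
        p = tmp_path / "m.xml"
        p.write_text(SBML_DOC)
        records = parse_sbml_annotations(p)
        by_concept = {r.concept_id: r for r in records}
        go = by_concept["GO:0006402"]
        assert (go.model_id, go.element_id, go.qualifier, go.ontology) == (
            "mod1", "meta_s1", "bqbiol:is", "GO")
        assert by_concept["CHEBI:4167"].ontology == "CHEBI"
        sbo = by_concept["SBO:0000252"]
        assert (sbo.qualifier, sbo.element_id) == ("sboTerm", "r1")
        pub = by_concept["12345"]
        assert (pub.qualifier, pub.element_id) == ("bqmodel:isDescribedBy", "mod1")
        assert len(records) == 4

    def test_model_without_annotations_yields_nothing(self, tmp_path):
        p = tmp_path / "m.xml"
        p.write_text(EMPTY_SBML)
        assert parse_sbml_annotations(p) == []

    def test_malformed_xml(self, tmp_path):
        p = tmp_path / "m.xml"
        p.write_text("<sbml><unclosed>")
        with pytest.raises(InputError):
            parse_sbml_annotations(p)

    def test_non_sbml_xml(self, tmp_path):
        p = tmp_path / "m.xml"
        p.write_text("<notes><p>hello</p></notes>")
        with pytest.raises(FormatError):
            parse_sbml_annotations(p)


class TestCorpusIndex:
    def test_aggregated_ef_conservation(self):
        t = small_tree()  # T:r -> T:p -> {T:a, T:b}
        idx = index_from_counts(t, {"T:a": 2, "T:b": 3})
        assert idx.EF("T:p") == 5
        assert idx.EF("T:r") == 5
        assert idx.entity_probability("T:p") == 1.0
        assert idx.entity_probability("T:r") == 1.0

    def test_chain_aggregation(self):
        t = chain_taxonomy("T:r", "T:x", "T:y")
        idx = index_from_counts(t, {"T:x": 1, "T:y": 3})
        assert idx.EF("T:x") == 4
        assert idx.entity_probability("T:y") == 0.75

    def test_document_frequency_counts_models(self):
        t = small_tree()
        records = records_for(t, {"T:a": 1}, "M0") + records_for(
            t, {"T:a": 1}, "M1")
        idx = index_records(records, ["M0", "M1"], t)
        assert idx.direct_count["T:a"] == 2
        assert idx.doc_freq["T:a"] == 2
        assert idx.doc_freq["T:r"] == 2

    def test_unresolved_records_are_excluded_from_counts(self):
        t = small_tree()
        records = records_for(t, {"T:a": 1}) + records_for(t, {"GO:9": 1})
        idx = index_records(records, ["M0"], t)
        assert idx.EF(t.root) == 1
        assert [r.concept_id for r in idx.unresolved] == ["GO:9"]

    def test_model_order_invariance(self, study_taxonomy, tmp_path):
        from sbmlfeatures import FixtureSpec, generate_corpus

        t = study_taxonomy
        paths, _ = generate_corpus(
            FixtureSpec(seed=4, n_models=4), t, tmp_path / "m")
        fwd = build_corpus_index(paths, t)
        rev = build_corpus_index(list(reversed(paths)), t)
        assert fwd.ef == rev.ef
        assert fwd.doc_freq == rev.doc_freq
        assert fwd.models == rev.models

    def test_direct_counts_sum_to_resolved_records(self, study_taxonomy):
        from helpers import corpus_index
        from sbmlfeatures import FixtureSpec

        idx = corpus_index(study_taxonomy, FixtureSpec(seed=9, n_models=6))
        assert sum(idx.direct_count.values()) == len(idx.records)
        assert all(n >= 1 for n in idx.direct_count.values())

    def test_doc_freq_monotone_up_the_taxonomy(self, study_taxonomy):
        from helpers import corpus_index
        from sbmlfeatures import FixtureSpec

        t = study_taxonomy
        idx = corpus_index(t, FixtureSpec(seed=12, n_models=6))
        for cid in idx.doc_freq:
            for p in t.parents(cid):
                assert idx.doc_freq.get(p, 0) >= idx.doc_freq[cid]

    def test_empty_model_list_rejected(self, study_taxonomy):
        with pytest.raises(InputError):
            build_corpus_index([], study_taxonomy)


class TestDfFilter:
    def test_low_thresholds_are_identity(self):
        t = small_tree()
        idx = index_from_counts(t, {"T:a": 2})
        assert df_filter(idx, 0) is idx
        assert df_filter(idx, 1) is idx

    def test_rare_concepts_removed(self):
        t = small_tree()
        records = records_for(t, {"T:a": 1}, "M0") + records_for(
            t, {"T:a": 1, "T:b": 1}, "M1")
        idx = index_records(records, ["M0", "M1"], t)
        out = df_filter(idx, 2)
        assert out.direct_count.get("T:b", 0) == 0
        assert out.EF("T:a") == 2
        assert out.EF(t.root) == 2

    def test_filtering_everything_gives_empty_extraction(self):
        t = small_tree()
        idx = index_from_counts(t, {"T:a": 1})  # one model only
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            out = df_filter(idx, 5)
            assert out.EF(t.root) == 0
            fs = method2_topdown(t, out)
        assert len(fs) == 0

    def test_negative_threshold_rejected(self):
        t = small_tree()
        idx = index_from_counts(t, {"T:a": 1})
        with pytest.raises(InputError):
            df_filter(idx, -1)
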