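"""Candidate extraction, PubTator round-trips, and abstract-level splits."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from weakrel import (
    AnnotatedAbstract,
    EntityAnnotation,
    ReferenceGraph,
    assign_splits,
    extract_candidates,
    filter_entities_to_graph,
    parse_pubtator,
    read_candidates,
    write_candidates,
    write_pubtator,
)
from weakrel.corpus import EDGE_TYPE_SIGNATURES, segment_sentences
from weakrel.errors import ConfigurationError, PubtatorParseError


def _abstract(title, body, annotations):
    doc = AnnotatedAbstract("123", title, body)
    full = doc.full_text
    for start, etype, norm in annotations:
        # annotations located by surface text for readability
        s = full.index(start)
        doc.annotations.append(
            EntityAnnotation("123", s, s + len(start), start, etype, norm)
        )
    return doc


class TestParsePubtator:
    def test_empty_stream(self):
        assert parse_pubtator("") == []

    def test_single_block_single_annotation(self):
        text = (
            "42|t|BRCA1 in cancer\n"
            "42|a|A study of breast cancer risk.\n"
            "42\t27\t40\tbreast cancer\tDisease\tD001943\n"
        )
        docs = parse_pubtator(text)
        assert len(docs) == 1
        (doc,) = docs
        assert doc.document_id == "42"
        assert len(doc.annotations) == 1
        ann = doc.annotations[0]
        assert doc.full_text[ann.start:ann.end] == "breast cancer"

    def test_span_mismatch_drops_annotation_keeps_document(self, caplog):
        text = (
            "42|t|Title here\n"
            "42|a|Body here.\n"
            "42\t0\t5\twrong\tDisease\tD1\n"
        )
        with caplog.at_level("WARNING"):
            docs = parse_pubtator(text)
        assert len(docs) == 1
        assert docs[0].annotations == []
        assert "mismatch" in caplog.text

    @pytest.mark.parametrize(
        "bad",
        [
            "42|x|oops\n",
            "42|t|Title\n43|a|wrong pmid\n",
            "42|t|Title\n42|a|Body\n42\t0\tbad\tx\tDisease\tD1\n",
            "42|t|Title\n42|a|Body\n99\t0\t1\tT\tDisease\tD1\n",
        ],
    )
    def test_malformed_block_raises_with_location(self, bad):
        with pytest.raises(PubtatorParseError) as err:
            parse_pubtator(bad)
        assert err.value.line_number is not None

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(st.data())
    def test_round_trip_identity_on_random_well_formed_blocks(self, data):
        word = st.text(
            alphabet="abcdefgxyz", min_size=1, max_size=6
        )
        n_docs = data.draw(st.integers(1, 4))
        docs = []
        for d in range(n_docs):
            title = " ".join(data.draw(st.lists(word, min_size=1, max_size=4)))
            body = " ".join(data.draw(st.lists(word, min_size=1, max_size=10)))
            doc = AnnotatedAbstract(f"pmid{d}", title, body)
            full = doc.full_text
            for _ in range(data.draw(st.integers(0, 3))):
                start = data.draw(st.integers(0, len(full) - 1))
                end = data.draw(st.integers(start + 1, len(full)))
                doc.annotations.append(
                    EntityAnnotation(
                        f"pmid{d}", start, end, full[start:end], "Gene", "G1"
                    )
                )
            docs.append(doc)
        text = write_pubtator(docs)
        assert write_pubtator(parse_pubtator(text)) == text
        reparsed = parse_pubtator(text)
        assert [d.document_id for d in reparsed] == [d.document_id for d in docs]
        assert [len(d.annotations) for d in reparsed] == [
            len(d.annotations) for d in docs
        ]


class TestFilterToGraph:
    def test_empty_graph_removes_all_annotations(self):
        doc = _abstract("BRCA1 study", "About BRCA1 only.",
                        [("BRCA1", "Gene", "G1")])
        out = filter_entities_to_graph([doc], ReferenceGraph())
        assert len(out) == 1 and out[0].annotations == []

    def test_membership_filtering(self, toy_graph):
        doc = _abstract(
            "c1 g1 unknown", "body.",
            [("c1", "Compound", "c1"), ("g1", "Gene", "g1"),
             ("unknown", "Gene", "zzz")],
        )
        out = filter_entities_to_graph([doc], toy_graph)
        kept = {a.normalized_id for a in out[0].annotations}
        assert kept == {"c1", "g1"}

    def test_all_in_graph_is_identity(self, toy_graph):
        doc = _abstract("c1 g1", "body.",
                        [("c1", "Compound", "c1"), ("g1", "Gene", "g1")])
        out = filter_entities_to_graph([doc], toy_graph)
        assert [a.normalized_id for a in out[0].annotations] == ["c1", "g1"]


class TestExtractCandidates:
    def test_example_gene_disease_sentence(self):
        body = "PTK6 may be a novel therapeutic target for pancreatic cancer"
        doc = _abstract(
            "A report.", body,
            [("PTK6", "Gene", "G1"), ("pancreatic cancer", "Disease", "D1")],
        )
        cands = extract_candidates(doc, "DaG")
        assert len(cands) == 1
        cand = cands[0]
        assert cand.edge_type == "DaG"
        # canonical (Disease, Gene) ordering
        assert cand.mention_pair[0].entity_type == "Disease"
        assert cand.mention_pair[1].entity_type == "Gene"
        m = cand.mention_pair[1]
        assert cand.sentence_text[m.start:m.end] == "PTK6"

    def test_single_entity_yields_nothing(self):
        doc = _abstract("A report.", "Only PTK6 here.", [("PTK6", "Gene", "G1")])
        assert extract_candidates(doc, "DaG") == []

    def test_pair_enumeration_matches_brute_force(self):
        body = "BRCA1 and TP53 relate to breast cancer"
        doc = _abstract(
            "A report.", body,
            [("BRCA1", "Gene", "G1"), ("TP53", "Gene", "G2"),
             ("breast cancer", "Disease", "D1")],
        )
        assert len(extract_candidates(doc, "DaG")) == 2
        gig = extract_candidates(doc, "GiG")
        assert len(gig) == 1
        assert gig[0].pair_ids == ("G1", "G2")  # lexicographic for GiG

    def test_counts_equal_brute_force_on_random_abstracts(self, rng):
        for _ in range(20):
            n_ent = int(rng.integers(2, 6))
            types = rng.choice(["Gene", "Disease", "Compound"], n_ent)
            words = [f"ent{i}x" for i in range(n_ent)]
            body = " ".join(words)
            doc = _abstract(
                "T.", body,
                [(w, t, f"id{i}") for i, (w, t) in enumerate(zip(words, types))],
            )
            for edge, (ta, tb) in EDGE_TYPE_SIGNATURES.items():
                got = len(extract_candidates(doc, edge))
                anns = doc.annotations
                if ta == tb:
                    ms = [a for a in anns if a.entity_type == ta]
                    want = len(list(itertools.combinations(ms, 2)))
                else:
                    want = sum(a.entity_type == ta for a in anns) * sum(
                        a.entity_type == tb for a in anns
                    )
                assert got == want

    def test_overlapping_mentions_skipped(self, caplog):
        doc = AnnotatedAbstract("1", "T.", "breast cancer gene")
        full = doc.full_text
        s = full.index("breast cancer")
        doc.annotations = [
            EntityAnnotation("1", s, s + 13, "breast cancer", "Disease", "D1"),
            EntityAnnotation("1", s + 7, s + 13, "cancer", "Gene", "G1"),
        ]
        with caplog.at_level("WARNING"):
            assert extract_candidates(doc, "DaG") == []

    def test_sentence_segmentation_rule(self):
        spans = segment_sentences("One sentence. Another one! A third? done")
        texts = ["One sentence. Another one! A third? done"[a:b] for a, b in spans]
        assert texts == ["One sentence.", "Another one!", "A third? done"]


class TestAssignSplits:
    def test_empty_input(self):
        assert assign_splits([], seed=0).assignment == {}

    def test_determinism_and_per_document_stability(self):
        ids = [f"doc{i}" for i in range(500)]
        a = assign_splits(ids, seed=7)
        b = assign_splits(ids, seed=7)
        assert a.assignment == b.assignment
        # a document's split does not depend on which other documents exist
        c = assign_splits(ids[:100], seed=7)
        assert all(c[d] == a[d] for d in ids[:100])

    def test_fractions_concentrate_on_probabilities(self):
        n = 20_000
        ids = [f"doc{i}" for i in range(n)]
        fr = assign_splits(ids, seed=3).fractions()
        for split, p in zip(("train", "tune", "test"), (0.7, 0.2, 0.1)):
            se = np.sqrt(p * (1 - p) / n)
            assert abs(fr[split] - p) < 3 * se

    def test_bad_probabilities_rejected(self):
        with pytest.raises(ConfigurationError):
            assign_splits(["a"], probabilities=(0.5, 0.2, 0.2), seed=0)


class TestCandidateTsv:
    def test_round_trip(self, tmp_path, small_bundle):
        cands = small_bundle.candidates["CbG"][:20]
        path = tmp_path / "cands.tsv"
        write_candidates(cands, path)
        back = read_candidates(path)
        assert len(back) == len(cands)
        for a, b in zip(cands, back):
            assert a.candidate_id == b.candidate_id
            assert a.tokens == b.tokens
            assert a.pos_tags == b.pos_tags
            assert a.dependency_edges == [tuple(e) for e in b.dependency_edges]
            assert a.pair_ids == b.pair_ids
            assert a.split == b.split and a.gold_label == b.gold_label
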