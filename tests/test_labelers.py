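"""Label-function factories and the label matrix."""

import numpy as np
import pytest

from conftest import make_candidate
from weakrel import (
    DependencyClusterSet,
    LabelFunction,
    LabelMatrix,
    LabelVote,
    apply_label_functions,
    make_db_negative_lf,
    make_db_positive_lf,
    make_dependency_cluster_lf,
    make_distance_lf,
    make_keyword_lf,
    make_verb_presence_lf,
)
from weakrel.errors import AnnotationError, ConfigurationError, ContractError
from weakrel.labelers import shortest_dependency_path


@pytest.fixture
def cbg_candidates(toy_graph):
    return [
        make_candidate(["c1tok", "binds", "g1tok"], (0, "Compound", "c1"),
                       (2, "Gene", "g1"), cid="a:CbG:0"),
        make_candidate(["c1tok", "binds", "g3tok"], (0, "Compound", "c1"),
                       (2, "Gene", "g3"), cid="b:CbG:0"),
        make_candidate(["c2tok", "near", "g2tok"], (0, "Compound", "c2"),
                       (2, "Gene", "g2"), cid="c:CbG:0"),
    ]


class TestDatabaseFunctions:
    def test_positive_fires_on_known_pair(self, toy_graph, cbg_candidates):
        lf = make_db_positive_lf(toy_graph, "CbG")
        assert lf(cbg_candidates[0]) == LabelVote.POSITIVE
        assert lf(cbg_candidates[1]) == LabelVote.ABSTAIN

    def test_negative_fires_on_absent_pair(self, toy_graph, cbg_candidates):
        lf = make_db_negative_lf(toy_graph, "CbG")
        assert lf(cbg_candidates[1]) == LabelVote.NEGATIVE
        assert lf(cbg_candidates[0]) == LabelVote.ABSTAIN

    def test_empty_graph_always_abstains_positive(self, cbg_candidates):
        from weakrel import ReferenceGraph

        lf = make_db_positive_lf(ReferenceGraph(), "CbG")
        assert all(lf(c) == LabelVote.ABSTAIN for c in cbg_candidates)

    def test_pair_exclusivity_exhaustive(self, toy_graph, cbg_candidates):
        pos = make_db_positive_lf(toy_graph, "CbG")
        neg = make_db_negative_lf(toy_graph, "CbG")
        for cand in cbg_candidates:
            votes = (pos(cand), neg(cand))
            assert LabelVote.ABSTAIN in votes  # never both fire


class TestKeywordFunction:
    def test_example_phrase(self):
        cand = make_candidate(
            "PTK6 may be a novel therapeutic target for pancreatic cancer".split(),
            (0, "Gene", "G1"), (8, "Disease", "D1"), edge_type="DaG",
        )
        lf = make_keyword_lf({"novel therapeutic target"}, LabelVote.POSITIVE)
        assert lf(cand) == LabelVote.POSITIVE

    def test_absent_phrase_abstains(self):
        cand = make_candidate(["c1", "near", "g1"])
        lf = make_keyword_lf({"binds"}, LabelVote.POSITIVE)
        assert lf(cand) == LabelVote.ABSTAIN

    def test_case_insensitive(self):
        cand = make_candidate(["c1", "BINDS", "g1"])
        lf = make_keyword_lf({"binds"}, LabelVote.POSITIVE)
        assert lf(cand) == LabelVote.POSITIVE

    def test_between_mentions_scope(self):
        cand = make_candidate(["binds", "c1", "filler", "g1"],
                              (1, "Compound", "c1"), (3, "Gene", "g1"))
        sentence_lf = make_keyword_lf({"binds"}, LabelVote.POSITIVE)
        between_lf = make_keyword_lf({"binds"}, LabelVote.POSITIVE,
                                     scope="between")
        assert sentence_lf(cand) == LabelVote.POSITIVE
        assert between_lf(cand) == LabelVote.ABSTAIN

    def test_empty_phrase_set_rejected(self):
        with pytest.raises(ConfigurationError):
            make_keyword_lf(set(), LabelVote.POSITIVE)


class TestDistanceFunction:
    @pytest.mark.parametrize(
        "tokens,m2_idx,max_gap,expected",
        [
            (["c1", "g1"], 1, 2, LabelVote.POSITIVE),          # gap 0
            (["c1", "a", "b", "c", "d", "e", "g1"], 6, 2,
             LabelVote.ABSTAIN),                                # gap 5
            (["c1", "a", "b", "g1"], 3, 2, LabelVote.POSITIVE), # gap == max
        ],
    )
    def test_boundary_convention(self, tokens, m2_idx, max_gap, expected):
        cand = make_candidate(tokens, (0, "Compound", "c1"),
                              (m2_idx, "Gene", "g1"))
        lf = make_distance_lf(max_gap, LabelVote.POSITIVE)
        gap = len(cand.tokens_between_mentions())
        assert gap == m2_idx - 1  # token-count oracle
        assert lf(cand) == expected


class TestVerbPresenceFunction:
    def test_verb_present_abstains(self):
        cand = make_candidate(["c1", "binds", "g1"], tags=["NNP", "VBZ", "NNP"])
        assert make_verb_presence_lf()(cand) == LabelVote.ABSTAIN

    def test_all_nominal_votes_negative(self):
        cand = make_candidate(["c1", "study", "g1"], tags=["NNP", "NN", "NNP"])
        assert make_verb_presence_lf()(cand) == LabelVote.NEGATIVE

    def test_missing_tags_is_annotation_error(self):
        cand = make_candidate(["c1", "binds", "g1"])
        with pytest.raises(AnnotationError):
            make_verb_presence_lf()(cand)


class TestDependencyClusterFunction:
    def _cand(self):
        return make_candidate(
            ["c1", "binds", "g1"], tags=["NNP", "VBZ", "NNP"],
            deps=[(1, 0, "nsubj"), (1, 2, "dobj")],
        )

    def test_matching_pattern_fires(self):
        clusters = DependencyClusterSet(
            {"bind": [(("nsubj", "binds"), ("dobj", "*"))]}
        )
        lf = make_dependency_cluster_lf(clusters)
        assert lf(self._cand()) == LabelVote.POSITIVE

    def test_empty_cluster_set_abstains(self):
        lf = make_dependency_cluster_lf(DependencyClusterSet({}))
        assert lf(self._cand()) == LabelVote.ABSTAIN

    def test_disconnected_mentions_abstain(self, caplog):
        cand = make_candidate(["c1", "x", "g1"], deps=[(0, 1, "dep")])
        clusters = DependencyClusterSet({"any": [(("*", "*"),)]})
        with caplog.at_level("WARNING"):
            assert make_dependency_cluster_lf(clusters)(cand) == LabelVote.ABSTAIN

    def test_agrees_with_brute_force_path_matcher(self, small_bundle):
        # exhaustive BFS oracle over all paths on corpus candidates
        import collections

        def oracle_path(cand):
            (a_lo, _), (b_lo, _) = cand.mention_token_spans()
            adj = collections.defaultdict(list)
            for h, d, r in cand.dependency_edges:
                adj[h].append((d, r))
                adj[d].append((h, r))
            best = None
            queue = collections.deque([(a_lo, [])])
            seen = {a_lo}
            while queue:
                node, path = queue.popleft()
                if node == b_lo:
                    best = path
                    break
                for nxt, rel in adj[node]:
                    if nxt not in seen:
                        seen.add(nxt)
                        queue.append(
                            (nxt, path + [(rel, cand.tokens[nxt].lower())])
                        )
            return best

        for cand in small_bundle.candidates["CbG"][:20]:
            assert shortest_dependency_path(cand) == oracle_path(cand)


class TestApplyLabelFunctions:
    def test_single_abstain_function(self):
        cand = make_candidate(["c1", "x", "g1"])
        lf = LabelFunction("abstain", "CbG", "TP",
                           lambda c: LabelVote.ABSTAIN)
        m = apply_label_functions([cand], [lf])
        assert m.votes.shape == (1, 1) and m.votes[0, 0] == 0

    def test_matrix_matches_cell_by_cell_oracle(self, toy_graph, cbg_candidates):
        lfs = [
            make_db_positive_lf(toy_graph, "CbG"),
            make_db_negative_lf(toy_graph, "CbG"),
            make_keyword_lf({"binds"}, LabelVote.POSITIVE),
        ]
        m = apply_label_functions(cbg_candidates, lfs)
        for i, cand in enumerate(cbg_candidates):
            for j, lf in enumerate(lfs):
                assert m.votes[i, j] == int(lf(cand))

    def test_permuting_functions_permutes_columns(self, toy_graph, cbg_candidates):
        lfs = [
            make_db_positive_lf(toy_graph, "CbG"),
            make_keyword_lf({"binds"}, LabelVote.POSITIVE),
        ]
        a = apply_label_functions(cbg_candidates, lfs)
        b = apply_label_functions(cbg_candidates, lfs[::-1])
        assert np.array_equal(a.votes, b.votes[:, ::-1])
        assert a.lf_ids == b.lf_ids[::-1]

    def test_purity_identical_matrices(self, toy_graph, cbg_candidates):
        lfs = [make_db_positive_lf(toy_graph, "CbG")]
        a = apply_label_functions(cbg_candidates, lfs)
        b = apply_label_functions(cbg_candidates, lfs)
        assert np.array_equal(a.votes, b.votes)

    def test_raising_predicate_becomes_abstain(self, cbg_candidates, caplog):
        def boom(c):
            raise RuntimeError("internal failure")

        lfs = [LabelFunction("boom", "CbG", "TP", boom)]
        with caplog.at_level("WARNING"):
            m = apply_label_functions(cbg_candidates, lfs)
        assert (m.votes == 0).all()
        assert "failed" in caplog.text


class TestLabelMatrix:
    def test_vote_domain_enforced(self):
        with pytest.raises(ContractError):
            LabelMatrix(np.array([[2]]), ["c"], ["lf"])

    def test_serialization_uses_conventional_integers(self, tmp_path):
        m = LabelMatrix(np.array([[1, -1, 0]], dtype=np.int8), ["c0"],
                        ["a", "b", "c"])
        path = tmp_path / "m.tsv"
        m.write_tsv(path)
        text = path.read_text().splitlines()
        assert text[1].split("\t")[1:] == ["1", "0", "-1"]
        back = LabelMatrix.read_tsv(path)
        assert np.array_equal(back.votes, m.votes)

    def test_column_subset_with_replacement_renames_duplicates(self):
        m = LabelMatrix(np.array([[1, -1]], dtype=np.int8), ["c0"], ["a", "b"])
        sub = m.column_subset([0, 0, 1])
        assert sub.lf_ids == ["a", "a#1", "b"]
        assert np.array_equal(sub.votes, np.array([[1, 1, -1]]))
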