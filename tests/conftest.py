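import numpy as np
import pytest

from weakrel import (
    AnnotatedAbstract,
    CandidateSentence,
    CorpusConfig,
    EntityAnnotation,
    ReferenceGraph,
    generate_corpus,
)


def make_candidate(
    tokens,
    m1=(0, "Compound", "c1"),
    m2=(2, "Gene", "g1"),
    edge_type="CbG",
    tags=None,
    deps=None,
    gold=None,
    cid="doc0:CbG:0",
):
    """Build a toy candidate from token indices of the two mentions."""
    sentence = " ".join(tokens)
    starts = []
    cursor = 0
    for tok in tokens:
        starts.append(cursor)
        cursor += len(tok) + 1
    mentions = []
    for idx, etype, norm in (m1, m2):
        mentions.append(
            EntityAnnotation(
                "doc0", starts[idx], starts[idx] + len(tokens[idx]),
                tokens[idx], etype, norm,
            )
        )
    return CandidateSentence(
        candidate_id=cid,
        document_id="doc0",
        sentence_text=sentence,
        tokens=list(tokens),
        pos_tags=list(tags) if tags is not None else None,
        dependency_edges=list(deps) if deps is not None else None,
        mention_pair=(mentions[0], mentions[1]),
        edge_type=edge_type,
        gold_label=gold,
    )


@pytest.fixture(scope="session")
def toy_graph():
    g = ReferenceGraph()
    for nid, ntype in [
        ("c1", "Compound"), ("c2", "Compound"),
        ("g1", "Gene"), ("g2", "Gene"), ("g3", "Gene"),
        ("d1", "Disease"),
    ]:
        g.add_node(nid, ntype)
    g.add_edge("c1", "g1", "CbG")
    g.add_edge("c2", "g2", "CbG")
    g.add_edge("g1", "g2", "GiG")
    g.add_edge("d1", "g1", "DaG")
    g.add_edge("c1", "d1", "CtD")
    return g


@pytest.fixture(scope="session")
def small_bundle():
    """A small two-edge synthetic corpus shared across test modules."""
    return generate_corpus(
        CorpusConfig(n_abstracts=400, edge_types=("CbG", "DaG"), seed=11)
    )


@pytest.fixture
def rng():
    return np.random.default_rng(0)
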