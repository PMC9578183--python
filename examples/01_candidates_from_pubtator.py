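"""Parse an entity-annotated abstract and extract candidate sentences.

Builds a tiny PubTator-dialect document, filters its annotations against a
toy reference graph, and extracts Disease-associates-Gene candidates.
"""

from weakrel import (
    ReferenceGraph,
    extract_candidates,
    filter_entities_to_graph,
    parse_pubtator,
)

PUBTATOR = """\
1001|t|A kinase report.
1001|a|PTK6 may be a novel therapeutic target for pancreatic cancer. Unrelated text follows.
1001\t17\t21\tPTK6\tGene\tG_PTK6
1001\t60\t77\tpancreatic cancer\tDisease\tD_panc
"""

graph = ReferenceGraph()
graph.add_node("G_PTK6", "Gene")
graph.add_node("D_panc", "Disease")
graph.add_edge("D_panc", "G_PTK6", "DaG")

abstracts = filter_entities_to_graph(parse_pubtator(PUBTATOR), graph)
candidates = extract_candidates(abstracts[0], "DaG")

print(f"{len(candidates)} DaG candidate(s) extracted")
for cand in candidates:
    d, g = cand.mention_pair
    print(f"  sentence: {cand.sentence_text!r}")
    print(f"  pair: ({d.normalized_id}, {g.normalized_id})")
# One candidate: the sentence co-mentioning the gene and the disease.  The
# pair is in canonical (Disease, Gene) order regardless of mention order.
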