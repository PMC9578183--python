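"""End-to-end edge promotion on a high-signal synthetic corpus.

Corpus -> label functions -> generative label model -> discriminative
classifier -> max-aggregated pair scores -> equal-error-rate threshold ->
recalled and novel knowledge-graph edges.
"""

from weakrel import (
    CorpusBundle,
    CorpusConfig,
    DiscriminativeConfig,
    ScoredSet,
    aggregate_pair_scores,
    apply_label_functions,
    equal_error_threshold,
    featurize,
    fit_label_model,
    generate_corpus,
    posterior_probability,
    predict_scores,
    promote_and_score,
    train_discriminative,
)

bundle = generate_corpus(
    CorpusConfig(
        n_abstracts=1000, edge_types=("CbG",), cue_strength=0.95,
        reference_graph_coverage=1.0, seed=7,
    )
)
pools = bundle.lf_pools["CbG"]
lfs = pools["DB"] + pools["TP"]
train = bundle.train_candidates("CbG")
tune = bundle.tune_labeled["CbG"]

matrix = apply_label_functions(train, lfs)
fitted = fit_label_model(matrix, seed=1)
annotations = posterior_probability(fitted, matrix)
clf = train_discriminative(featurize(train), annotations,
                           DiscriminativeConfig(seed=1))

all_cands = bundle.candidates["CbG"]
scores = predict_scores(clf, featurize(all_cands))
threshold = equal_error_threshold(
    ScoredSet(predict_scores(clf, featurize(tune)),
              CorpusBundle.gold_vector(tune))
)
report = promote_and_score(
    aggregate_pair_scores(all_cands, scores), threshold, bundle.graph, "CbG"
)
print(f"equal-error threshold : {threshold:.3f}")
print(f"reference edges (with a candidate sentence): {report.n_reference}")
print(f"recalled              : {report.n_recalled} "
      f"({100 * report.recall_fraction:.1f}%)")
print(f"novel above threshold : {report.n_novel}")
# Most reference edges are recovered because every true pair is both in the
# graph and supported by cue-bearing sentences; novel edges are pairs whose
# sentences score high but which the graph does not yet contain.
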