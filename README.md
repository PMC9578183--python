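# weakrel

Weak-supervision (data-programming) relation extraction for biomedical
literature, from entity-annotated abstracts to knowledge-graph edges.

Curating sentence-level training labels for biomedical relation extraction
is expensive: each relationship class (disease–gene association,
compound–disease treatment, compound–gene binding, gene–gene interaction)
needs thousands of labeled candidate sentences.  `weakrel` implements the
data-programming alternative end to end:

1. **Candidate extraction** — parse PubTator-dialect abstracts, keep
   annotations whose normalized ids exist in a typed reference graph
   (Hetionet-shaped), and emit one candidate sentence per type-compatible
   co-mention pair, with abstracts split 70/20/10 into train/tune/test.
2. **Label functions (LFs)** — small predicates voting
   positive / negative / abstain per candidate: distant supervision against
   the reference graph (Λ_DB fires positive when the pair is a known edge;
   a separate Λ_¬DB fires negative when it is not), plus text patterns
   (keyword cues, inter-mention distance, verb presence, dependency-path
   clusters).
3. **Generative label model** — the true class Y ∈ {±1} is latent and the m
   LFs are conditionally independent noisy voters.  Per function j a
   labeling factor (weight β_j, fires when the vote is not abstain) and an
   accuracy factor (±α_j for agreement/disagreement with Y) define
   P_θ(Λ, Y); training minimizes the l2-penalized marginal negative
   log-likelihood  θ̂ = argmin_θ Σ −log Σ_Y P_θ(Λ, Y)  by seeded mini-batch
   SGD (learning rate 1e-3, 250 epochs).  The posterior
   P(Y=+1 | Λ_i) = σ(2(γ + Λ_iᵀα)) provides a probabilistic training label
   per candidate; a function's implied accuracy is logistic(2α_j).
4. **Discriminative model** — a classifier trained on those probabilistic
   annotations as soft cross-entropy targets (10 epochs, Adam, lr 0.001);
   the shipped representation is a hashed sparse n-gram model with entity
   placeholders, and a transformer head satisfies the same protocol.
5. **Transfer experiment** — the core question: do text-pattern LFs written
   for one edge type help another?  Sample k LFs with replacement from
   within-edge / off-edge / pooled sources (k = five evenly spaced sizes up
   to the pool size, 50 repeats each), refit the label model, and score
   AUROC/AUPR on hand-labeled tune sentences with bootstrap CIs.
6. **Edge promotion** — group candidate scores by co-mention pair, take the
   max per pair, calibrate a cutoff at the equal error rate (FPR = FNR) on
   labeled tune data, and report recalled vs novel graph edges.

A fully seeded synthetic-data module generates every input — corpora with
per-edge cue vocabularies of controllable cross-edge overlap, reference
graphs with configurable coverage and distractor edges, and simulated label
matrices with known per-function accuracy/propensity — so the entire
pipeline is testable on a laptop with no downloads.

## Worked example

`examples/02_label_model_recovery.py` simulates 8 label functions with
known accuracies on 10,000 candidates and fits the label model on the votes
alone:

```
function   true acc   recovered
     lf1   0.658      0.657
     lf4   0.875      0.878
     lf5   0.915      0.887
     lf7   0.842      0.843
mean |error| = 0.0067
```

The model recovers each function's reliability to a few hundredths without
seeing a single gold label — the property that lets noisy, cheap label
functions replace hand annotation.

`examples/04_edge_promotion.py` runs the full chain on a high-signal
synthetic corpus (cue strength 0.95, full graph coverage) and prints:

```
equal-error threshold : 0.822
reference edges (with a candidate sentence): 27
recalled              : 27 (100.0%)
novel above threshold : 20
```

i.e. every reference edge supported by at least one candidate sentence is
recovered at the calibrated cutoff, and 20 high-scoring pairs absent from
the graph are proposed as novel edges.

The other examples cover candidate extraction from PubTator text
(`01`), the within-edge vs off-edge transfer curves (`03`), and the
one-call pipeline with its run manifest (`05`).  A thin CLI mirrors the
stages: `weakrel demo`, `weakrel experiment --config run.yaml`,
`weakrel promote --scores ... --graph ...`, etc.

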