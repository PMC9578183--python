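# Methods

## The generative label model

Each candidate sentence carries a latent class Y ∈ {+1, −1} and a row of m
ternary votes Λ_i (internally +1 positive, −1 negative, 0 abstain).  The
model is log-linear with, per label function j,

* a **labeling factor** with weight β_j that fires whenever the vote is not
  abstain — the function's propensity to label at all, assumed independent
  of Y;
* an **accuracy factor** with weight α_j contributing +α_j when the vote
  agrees with Y (positive with Y=+1, negative with Y=−1) and −α_j when it
  disagrees;

plus a class-prior factor γ·Y.  Functions are conditionally independent
given Y, so the per-function normalizer z_j = 1 + 2e^{β_j} cosh α_j is
class-independent and both the marginal likelihood and the posterior

P(Y=+1 | Λ_i) = σ(2(γ + Λ_iᵀ α))

are closed-form.  With parameters mapped from known generative quantities
(α_j = ½ logit(accuracy_j), β_j solving the firing-rate equation,
γ = ½ logit(class balance)) this posterior equals the conditionally
independent Bayes posterior exactly, which the tests exploit as an oracle.
The implied accuracy of a fitted function is logistic(2α_j); the implied
firing rate is 2e^{β}coshα / (1 + 2e^{β}coshα).

**Training.** Mini-batch SGD on the mean marginal negative log-likelihood,
learning rate 1e-3, 250 epochs, batch size 64, weights initialized at 0.1
so accuracy semantics start above coin flip; the l2 penalty (default 0,
grid-searched over five evenly spaced values from 0.01 to 5 when a labeled
dev split is available) covers α and β but not γ.  Training is
deterministic given the seed (which controls only the batch shuffle) and
aborts with an error naming the epoch if the loss goes non-finite.

Two numerical choices deserve explanation:

* **Mini-batch rather than full-batch gradient descent.**  At the fixed
  learning rate and epoch budget, full-batch descent moves the weights by
  ~0.05 in total — far short of typical optima (α ≈ 1 for an 85%-accurate
  function) — so per-epoch mini-batching supplies the optimization steps
  the fixed budget otherwise lacks.
* **The class-prior weight is frozen for the first half of training.**
  Real label-function pools violate the independence assumption (several
  database functions are subsets of one another; cue-based functions fire
  on the same sentences).  Under that misspecification the marginal
  likelihood has a one-class optimum — prior → 1, the negative-voting
  database function re-interpreted as an inverted labeler — which we
  verified by closed-form EM: the degenerate solution attains *lower* NLL
  than any correctly oriented one.  Freezing γ while the accuracy weights
  orient, together with the small fixed learning rate and epoch count
  (effectively early stopping), keeps SGD in the well-oriented basin.  On
  correctly specified simulated matrices the same schedule converges to
  the true parameters.  How class balance should interact with a learned
  prior is a genuinely open corner of this model family; fixing the
  balance externally is the other common resolution.

## Label functions and their encoding

Votes are a three-valued enum; serialized matrices use 1 (positive),
0 (negative), −1 (abstain).  The database pair is deliberately split —
Λ_DB: positive/abstain, Λ_¬DB: negative/abstain — so that neither function
labels every sentence and the model is not dragged toward a single class;
the two never both fire on one candidate.  Keyword functions abstain (not
vote negative) when their cue is absent: absence of one phrase is weak
evidence.  The verb-presence function votes negative only when no VB* tag
occurs.  Dependency-cluster functions match the shortest dependency path
between the two mentions against (relation, lemma) patterns and abstain on
disconnected parses.

## The synthetic corpus

The generator is the ground truth for every recovery and trend test.  Per
edge type it emits one pre-segmented, pre-tagged template sentence per
abstract: a positive sentence embeds a cue from the edge's positive
vocabulary with probability `cue_strength` (default 0.9, adjacent to the
mentions); a negative sentence embeds a negative cue, a verbless filler
template, or — with probability 1 − cue_strength — a misleading positive
cue.  Class balance defaults to 0.3 (positives a minority, as in curated
relation benchmarks).  The reference graph contains a configurable
fraction (`reference_graph_coverage`, default 0.75) of the true-positive
pairs plus distractor edges (default rate 0.1) whose co-mentions are
negative sentences, so distant supervision has both false negatives and
false positives.  Cue vocabularies are disjoint across edge types unless a
pairwise overlap fraction is configured; overlap is constructed exactly
(round(f·|V|) shared phrases), which is the knob that makes off-edge label
functions transfer by construction.  Hand-labeled tune/test subsets default
to 1,000 sentences per edge type.

Generated LF pools default to the curated-suite distribution
(DB/TP = 7/30 DaG, 3/22 CtD, 9/20 CbG, 9/28 GiG).  The DB pool is the
Λ_DB/Λ_¬DB pair plus random 60% graph-subset variants (partially
overlapping databases); the TP pool cycles positive-keyword,
negative-keyword, dependency-cluster and cue-gated distance factories over
sliding 3-cue vocabulary windows.  Distance and verb patterns are gated on
the edge vocabulary inside generated pools: ungated structural patterns
would be informative on every synthetic edge type, which would contradict
the intended off-edge-uninformative design (and, as duplicated identical
columns, they pathologically violate the label model's independence
assumption).  The ungated factories remain available in the library.

What the corpus does **not** emulate: natural lexical diversity, multiple
sentences or entity pairs per abstract (the templates are one candidate per
abstract), parser noise in POS/dependency layers, and correlation between
cue presence and entity identity.  Passing tests therefore demonstrate the
pipeline's statistical machinery — vote combination, reliability recovery,
transfer and calibration logic — not robustness to real-text variation.

## Experiments and evaluation

Sampling sizes are five evenly spaced integers from 1 to the pool size
(interior points rounded, ties up; duplicates collapsed).  Sampling is with
replacement; per-repeat seeds hash (design seed, source, size, repeat) so
any sub-grid reproduces in isolation.  The tune split is the metric surface
for sampling curves; the test split is reserved for final discriminative
evaluation.  The "ALL" source is the union of every edge's text-pattern
pool, including the target's own.  AUROC is the rank-sum estimator with
ties counted half; AUPR is uninterpolated average precision with stable
tie-breaking.  Confidence intervals are percentile bootstrap over 1,000
resampled means (plain run percentiles are also available).  The
discriminative stage repeats 3 times per grid point, against 50 for the
generative stage.

Problem sizes used by the shipped checks: oracle-equivalence enumerates all
3^m vote patterns for m ≤ 5; recovery fits 50 simulated matrices of
n = 10,000 × m = 8; the transfer comparison uses four edge types × 2,000
candidates with 50 repeats at each pool's largest sample size (the point
where the separation claim is made); the promotion demo uses 1,500
candidates at cue strength 0.95 and full graph coverage.

## Edge promotion

Pair scores are the max over each pair's candidate scores.  The decision
threshold minimizes |FPR − FNR| over all midpoints between adjacent
distinct calibration scores (ties toward the lower threshold), with the
rule score ≥ threshold → positive.  Recall is reported against two
denominators: reference edges restricted to pairs with at least one
candidate sentence (the default — an edge never mentioned cannot be
recalled by a sentence classifier) and the unrestricted count, flagged when
the restricted denominator is empty.  On the high-signal synthetic demo the
recall bound (≥ 0.8) is the generator's signal ceiling; real-text noise
yields much lower absolute recall without invalidating the calibration
logic.

## Discriminative stage

Features are hashed unigrams/bigrams over placeholder-substituted tokens
(mentions replaced by entity-type placeholders, so surface identity cannot
leak) plus a bucketed inter-mention distance, L2-normalized per row —
without normalization, sentence length biases the score scale under Adam's
per-coordinate steps.  The trainer minimizes probability-weighted
cross-entropy (hard 0/1 targets reduce it to standard cross-entropy) with
mini-batch Adam, 10 epochs, learning rate 0.001, batch size 8.  Any object
scoring feature vectors in [0, 1] satisfies the classifier protocol, which
is the plugin point for transformer encoders with a frozen body and
trained classification head.

## Known limitations

* The independence assumption is structural: correlated functions inflate
  confidence and, at full likelihood convergence, can invert a minority
  voter (see above).  Learning the dependency structure is out of scope.
* Posterior probabilities on misspecified pools are positively biased even
  when the ranking is good; downstream consumers that need calibrated
  probabilities should recalibrate on labeled data (the equal-error-rate
  step does exactly this for promotion).
* The bundled sentence segmenter is a punctuation heuristic; synthetic
  corpora are pre-segmented so no result depends on it.
* Entity recognition/normalization is upstream and out of scope; candidate
  extraction trusts the annotation payload.
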