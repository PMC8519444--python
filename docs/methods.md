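# Methods

## Data model

A knowledge base is a deduplicated set of triples *(h, r, t)* over four
entity types (chemical, gene, disease, symptom). Entities carry
type-prefixed identifiers `/c|/g|/d|/s/ + zero-padded decimal`, assigned
deterministically in sorted order of canonical name, and each relation has
a fixed (head type, tail type) signature that every triple must satisfy.
The five canonical relations and their one-sentence descriptions
("a chemical is related to a gene", …, "a disease contains a symptom") are
built in; additional relations can be declared. All file formats are UTF-8,
tab-separated, headerless; whitespace-only lines are skipped; duplicate
triples are collapsed silently with a logged count; self-interactions
(head = tail, as in protein-interaction data) are retained but flagged.

Name normalization resolves raw names case-insensitively through canonical
names and synonyms of a per-type dictionary. Unresolved names raise in
strict mode (curated runs); otherwise a fresh identifier is minted and
logged, so synthetic pipelines never silently shrink.

Train/valid/test splitting samples a fixed number of triples per relation
without replacement from a seeded generator; the seed is recorded in the
split artifact.

## Scoring models

**TransE.** Energy `‖h + r − t‖` (L1 or L2). Training minimizes the margin
loss `max(0, γ + E(fact) − E(corruption))` by SGD with one sampled
corruption per fact; entity vectors are renormalized to unit L2 at the
start of each epoch, relation vectors once at initialization (uniform
`±6/√k`, as in the original translation-embedding scheme).

**ConvKB / KGED.** Both convolve the `k×3` triple matrix with δ filters of
shape `n×3` for each window height `n ∈ {3, 4, 5}` (δ filters *per size* —
forced by the feature-vector dimension `3δ(k−3)`); KGED adds a second bank
over the `l×3` description matrix. Feature maps are concatenated in the
fixed order (window size ascending, then filter index, then window
position); the scoring vector `w` has length `3δ(k−3) + 3δ(l−3)`. The two
banks Θ₁, Θ₂ and `w` are shared across all triples but are distinct
parameter sets. In evaluation mode the score is computed as the sum of the
two branch dot products, which makes a KGED model with a zeroed description
branch bit-identical to ConvKB.

**Sign convention.** The ranking loss is
`L = Σ softplus(l·f) + (λ/2)‖w‖²` with labels `l ∈ {+1, −1}`. As printed
with `l = +1` for facts, minimizing drives fact scores negative. The public
contract everywhere in this package is *higher score = more plausible*, so
the training loop feeds facts with the internal label −1 (and corruptions
with +1); this flips only the orientation of the optimum, not its
geometry. `kged_loss` itself implements the formula verbatim.

**Negative sampling.** Training corruptions replace exactly one slot (head
or tail, equal probability) with another entity of that slot's type;
candidates that are themselves known facts anywhere in the KG are rejected
and resampled. Full enumeration of the corruption set defines validity
only; training uses `neg_per_pos` sampled corruptions per fact (default 1;
the desk configuration uses 2).

**Optimization.** Adam (β₁ = 0.9, β₂ = 0.999, ε = 1e−8) over analytic
gradients — the convolutional score has a short closed-form backward pass,
so no autodiff framework is needed; the gradients are verified against
central finite differences (relative error < 1e−4) in the test suite.
Dropout (inverted, applied to the concatenated feature vector only in
training mode) regularizes the model; requesting dropout at evaluation time
raises. Non-finite loss aborts training with a diagnostic. The per-batch
loss is averaged over batch elements (the regularizer added once per
batch), which rescales the learning rate but not the optimum.

**Initialization.** Entity/relation vectors from a TransE pre-training run
(default 3000 epochs at full scale; the desk configuration uses 50); they
remain trainable afterwards (configurable). Description vectors come from
the text encoder applied to each entity's description — falling back to the
canonical name when no description is on file, logged — and to the relation
description sentences; they are frozen during training (configurable), and
their bit-stability is asserted after every run. Filters are zero-mean
normal (scale 0.1), biases zero, `w` normal with scale `1/√len(w)`, all
drawn from the seeded generator.

## Hyperparameters

| parameter | full-scale default | desk-scale (tests) | meaning |
|---|---|---|---|
| k | 50 | 16 | triple embedding dimension |
| l | 512 | 32 | description embedding dimension |
| filter sizes | {3,4,5} | {3,4,5} | convolution window heights |
| δ | 500 | 8 | filters per window size |
| dropout | 0.7 | 0.2 | on concatenated features |
| learning rate | 1e−4 | 3e−3 | Adam step size |
| batch size | 128 | 128 | facts per minibatch |
| λ | 1e−4 | 1e−4 | L2 weight on `w` |
| epochs | 200 | 100 | training passes |
| neg_per_pos | 1 | 2 | sampled corruptions per fact |
| TransE pre-train | 3000 | 50 | initialization epochs |
| TransE (own) | k=50, lr=0.01, L1, γ=2, batch 100 | — | baseline config |

The desk-scale values were calibrated once on a single generator seed so
that a 100-epoch run memorizes its training set with margin, then frozen;
they are the package's standing small-problem configuration, not tuned per
experiment.

## Text encoder

The description branch consumes vectors from any object satisfying the
`TextEncoder` contract (deterministic `encode: text → R^l`). The bundled
`HashingTextEncoder` hashes lower-cased word unigrams and bigrams into `l`
signed buckets (BLAKE2, stable across processes) and L2-normalizes; texts
sharing tokens map to nearby unit vectors. It is a lexical encoder — it
captures token overlap, not meaning — which suffices for a frozen embedding
whose geometry mirrors textual similarity. An adapter around a pre-trained
sentence encoder (512-dimensional output) can be plugged in for real
corpora.

## Evaluation protocol

Candidate pools are *typed* by default (a chemical head is replaced only by
chemicals); an `all`-entities mode is available. The filter set for the
filtered setting is train ∪ valid ∪ test (configurable). Rank = 1 + number
of strictly higher-scoring candidates, with ties contributing one half each
(mid-rank; optimistic/pessimistic selectable — tie handling matters for
constant or quantized scorers). Per relation: MR head, MR tail, MR both
= (head + tail)/2, and top-percent columns
`100·MR/|typed pool|` (half-up, 2 decimals; the pool is the raw type count,
not the filtered count). The overall row is the *unweighted* mean of the
per-relation mean ranks; Hits@10 is computed over the pooled test triples.
Model comparison reports absolute and relative deltas (`(baseline −
candidate)/baseline` for MR, `candidate − baseline` for Hits@10) and, over
ten paired repeats, win counts graded `-` (≤7), `*` (8), `**` (9), `***`
(10).

## Disease-gene prioritization

Every gene is scored in the head slot against all other genes under the
gene–gene relation; unordered pairs keep the maximum of the two directional
scores (the scorer is not symmetric); self-pairs are dropped; ties in the
descending sort break by the identifier pair, then ranks run 1..M. For
leakage-free inference of disease-associated genes, the (disease, relate,
gene) triples of the target disease must be removed from the KG before
training — the package provides the triple-set operations; the removal is
an input-preparation step.

Subnetworks take the top-N edges touching at least one seed gene. Edges
are unweighted for centrality (inference scores are kept as edge metadata
only; `w_ji = 1`). Closeness and betweenness are computed within connected
components, with the component's size in the normalization — this is the
natural reading of the formulas (which assume connectivity) but does affect
cross-component comparability; isolated nodes get closeness 0. Eigenvector
centrality is a power iteration on the adjacency shifted by `A.max()·I`
(same eigenvectors; the shift prevents period-2 oscillation on bipartite
components), normalized to unit maximum, raising with the residual on
non-convergence. Degree is reported both raw and normalized by `|V| − 1`.

Gene rankings sort a centrality column descending, breaking ties by raw
degree descending then label ascending; seed genes are *not* excluded —
known disease genes legitimately dominate the top. Precision@k is the
percentage of the top-k genes in the benchmark; benchmark symbols are
resolved through the gene dictionary, with unmatched symbols logged, never
silently dropped. Precision–recall curves step by 10; the recall
denominator defaults to the benchmark genes present among the ranked genes
(`benchmark_in_network`) — the mode under which published precision/recall
pairs reconcile — with the full benchmark size selectable.

## Synthetic data

The generator emulates the *shape* of a curated biomedical KB: the four
entity types, the five relation signatures, descriptions whose text
correlates with the latent structure, and planted disease–gene ground
truth. Mechanism: entities are assigned round-robin to `n_blocks` latent
modules; a triple is sampled between aligned blocks with probability
`p_within = 0.5` and elsewhere with `p_noise = 0.005`; 10% of within-block
positives are withheld as held-out test material (never emitted); the genes
of one designated block are the planted disease-associated set, of which a
random half serve as seed genes. Defaults give ~200 entities and ~1500
triples — small enough for a full train/evaluate/prioritize cycle in under
a minute on one CPU, large enough for the signal to be unambiguous.

What it does *not* emulate: the heavy-tailed degree distribution, the
million-triple scale and its ATPE (~31.6; generated graphs sit around 7 and
that value is reported, not targeted), relation imbalance, synonymy noise
in names, and descriptions whose signal is semantic rather than lexical.
Passing tests therefore demonstrate that the machinery recovers a planted,
well-separated signal end-to-end — not that it matches published
performance on the curated KB, which requires the full data and orders of
magnitude more compute.

## Numerical and reporting choices

* Printed-table rounding is half-up (1 decimal for MR/Hits, 2 for
  percentages); Python's banker's rounding is deliberately avoided.
* Cosine-distance profiles bin `1 − cosine` (clipped to [0, 1]) into 10
  equal bins, distance 1 in the top bin; zero-norm windows are skipped with
  a logged count.
* Checkpoints are single `.npz` archives embedding the config, identifier
  lists, all parameter arrays, and the seed.
* Determinism: every stochastic step draws from `numpy` generators seeded
  from the configuration; identical seeds reproduce training bit-for-bit on
  the same platform.

## Known limitations

* Training is pure numpy on one CPU; the full-scale configuration
  (δ = 500, k = 50, l = 512, millions of triples) is documented but not
  practical here — the code targets desk-scale studies.
* The ReLU activation is the only one supported by the analytic backward
  pass (tanh is available for scoring only).
* The bundled encoder is lexical; description signal that is semantic but
  not lexical requires plugging in a real sentence encoder.
* Whether validation triples should drive epoch selection is left to the
  caller; training runs a fixed epoch budget and records the loss history.
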