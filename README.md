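# kged

Convolutional knowledge-graph embedding of typed biomedical triples with
entity descriptions, filtered link-prediction evaluation, and disease-gene
prioritization from the inferred gene–gene interaction network.

## The problem

Curated biomedical databases can be integrated into a knowledge graph whose
facts are triples *(h, r, t)* over four entity types — chemicals, genes,
diseases, symptoms — connected by five typed relations (chemical–gene,
chemical–disease, disease–gene, gene–gene, disease–symptom). Link
prediction over such a graph proposes new biological relationships, and the
predicted gene–gene interactions can be mined further: build a
disease-specific subnetwork around known seed genes and rank its genes by
network centrality to nominate new disease-associated genes.

## Models

* **TransE** — translation energy `E_r(h, t) = ‖h + r − t‖_{L1/L2}` with
  margin-ranking SGD; low energy means plausible.
* **ConvKB** — the embeddings are stacked into a matrix `A = [h, r, t] ∈
  R^{k×3}` and convolved with a bank of `n×3` filters (`n ∈ {3, 4, 5}`, δ
  filters per size); the ReLU feature maps are concatenated and projected
  with a weight vector: `f_r(h, t) = concat(g([h, r, t] * Ω)) · w`.
* **KGED** — ConvKB plus a second branch over *description* embeddings
  `B = [h_d, r_d, t_d] ∈ R^{l×3}` produced by a sentence encoder and frozen
  during training:

  `f(h, r, t) = concat(X, Y) · w`,  `X = concat(g(A * Θ₁))`,
  `Y = concat(g(B * Θ₂))`

  trained with the softplus ranking loss
  `L = Σ log(1 + exp(l·f)) + (λ/2)‖w‖²` over facts and sampled corrupted
  triples, using Adam. Entity/relation embeddings are initialized by TransE
  pre-training; description embeddings come from a pluggable text encoder
  (a deterministic feature-hashing encoder ships with the package, so
  everything runs offline).

Evaluation uses the *filtered* ranking protocol: each test triple's head
(then tail) is replaced by every candidate of the slot's type, candidates
that are themselves known facts are removed, and the true entity's rank
among the scored candidates is recorded. Reported metrics are mean rank
(MR, lower better) and Hits@10 (higher better), per relation and overall.

The prioritization pipeline scores all gene pairs under the gene–gene
relation, keeps the top-N edges touching at least one seed gene, computes
closeness, betweenness, degree, and eigenvector centrality on the resulting
subnetwork, and scores the top-ranked genes against a benchmark gene set
(precision@k and precision–recall curves).

## Worked example

Everything below runs offline on a synthetic block-model knowledge graph
(~200 entities, 4 latent modules per type) whose descriptions leak the
latent module, so both scoring branches carry signal:

```python
import dataclasses
from kged import *
from kged.kg import NameDictionary

spec = SyntheticKGSpec(seed=0)
kg, truth = generate_kg(spec)                       # 1467 triples, 200 entities
split = split_triples(kg, 25, 25, seed=0)           # 125 test, 125 valid
descriptions = generate_descriptions(kg, truth)
encoder = HashingTextEncoder(DESK_CONFIG.l)
config = dataclasses.replace(DESK_CONFIG, seed=0)

model = train_kged(kg, split, descriptions, encoder, config)
print(evaluate(model, sorted(split.test), kg).to_tsv())
```

```
relation    mr_head  mr_tail  mr_both  top_pct_head  top_pct_tail  hits_head  hits_tail  hits_both
c_relate_d  3.76     3.52     3.64     9.40          8.80
c_relate_g  2.56     3.84     3.20     6.40          4.80
d_have_s    6.84     6.12     6.48     17.10         15.30
d_relate_g  3.48     5.52     4.50     8.70          6.90
g_relate_g  7.60     7.32     7.46     9.50          9.15
ALL         4.85     5.26     5.06                                 90.40      83.20      86.80
```

A mean rank of ~5 among 40–80 typed candidates and Hits@10 of 86.8% show
the model recovering the planted block structure from held-out facts.
Continuing into the prioritization pipeline:

```python
edges = infer_gene_edges(model, kg.entities_by_type["gene"])
seeds, bench = make_benchmark(truth)                # planted disease genes
net = build_subnetwork(edges, 1000, seeds)
table = centrality_table(net)
gene_dict = NameDictionary.from_entities(kg.entities.values(), "gene")
bench_ids = bench.normalized_ids(gene_dict)
for m in ("closeness", "betweenness", "degree", "eigenvector"):
    print(m, precision_at_k(rank_genes(table, m), bench_ids, 10))
```

```
closeness 100.0
betweenness 100.0
degree 100.0
eigenvector 100.0
```

All ten top-centrality genes belong to the planted disease-associated gene
set, for every centrality measure — far above the ~50% a random ordering of
the subnetwork's genes achieves.

The same pipeline is available from the shell:

```sh
kged synth --out run/data --seed 0
kged train --model kged --train run/data/train.tsv --valid run/data/valid.tsv \
     --test run/data/test.tsv --descriptions run/data/descriptions.tsv \
     --out run/model --k 16 --l 32 --delta 8 --epochs 100
kged evaluate --checkpoint run/model/checkpoint.npz --train run/data/train.tsv \
     --valid run/data/valid.tsv --test run/data/test.tsv --out run/eval
kged network --checkpoint run/model/checkpoint.npz --seeds run/data/seed_genes.txt \
     --benchmark run/data/benchmark_genes.txt \
     --descriptions run/data/descriptions.tsv --out run/net
```

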