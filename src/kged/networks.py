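"""Disease-gene prioritization from model-inferred gene-gene interactions.

Pipeline: (1) score every ordered (head gene, relate, tail gene) pair with a
trained model and pool the predictions into a ranked list of unordered
gene-gene edges; (2) cut the list at the top N edges and keep those touching
at least one disease seed gene, yielding an undirected, unweighted
subnetwork; (3) rank the subnetwork's genes by closeness, betweenness,
degree, or eigenvector centrality; (4) score the top-k ranked genes against
a benchmark gene set (precision@k, precision-recall curves).

Centrality definitions (V = node set, N(v) = neighbours of v):

* closeness      CC(v) = (|V| - 1) / sum_u distance(v, u)
* betweenness    CB(v) = sum over pairs of (fraction of shortest paths
                 through v) / ((|V| - 1)(|V| - 2) / 2)
* degree         CD(v) = |N(v)| / (|V| - 1)
* eigenvector    CE(v) = (1/lambda) sum_{u in N(v)} w_uv CE(u),
                 normalized to unit maximum.

On disconnected graphs, closeness and betweenness are computed within each
connected component with |V| replaced by the component's size; this affects
cross-component comparability and is deliberate (the formulas above assume
a connected graph).  Edge weights default to 1 everywhere; inference scores
are kept only as edge metadata.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from ._util import round_half_up
from .kg import NameDictionary, Triple

logger = logging.getLogger(__name__)

CENTRALITY_MEASURES = ("closeness", "betweenness", "degree", "eigenvector")


class ScoredEdge(NamedTuple):
    gene_a: str
    gene_b: str
    score: float
    rank: int


@dataclass
class GeneNetwork:
    """Undirected, unweighted gene graph anchored on seed genes."""

    graph: nx.Graph
    seed_genes: frozenset[str]

    @property
    def nodes(self) -> list[str]:
        return sorted(self.graph.nodes)

    def __len__(self) -> int:
        return self.graph.number_of_nodes()


@dataclass(frozen=True)
class BenchmarkGeneSet:
    name: str
    symbols: frozenset[str]

    def normalized_ids(self, dictionary: NameDictionary) -> frozenset[str]:
        """Resolve benchmark symbols to gene ids; unmatched symbols logged."""
        ids = []
        missing = []
        for s in sorted(self.symbols):
            eid = dictionary.lookup(s)
            if eid is None:
                missing.append(s)
            else:
                ids.append(eid)
        if missing:
            logger.warning(
                "benchmark %s: %d symbols not in gene dictionary: %s",
                self.name, len(missing), ", ".join(missing[:10]),
            )
        return frozenset(ids)


# ---------------------------------------------------------------------------
# edge inference and subnetwork construction


def infer_gene_edges(
    model,
    gene_ids: Sequence[str],
    relation: str = "g_relate_g",
    batch_size: int = 4096,
) -> list[ScoredEdge]:
    """Score all ordered gene pairs and pool them into ranked unordered edges.

    Each gene is placed in the head slot and scored against every other gene
    as tail.  Unordered pairs are deduplicated keeping the maximum of the two
    directional scores; self-pairs are dropped.  Edges are sorted by score
    descending (ties broken by the gene-id pair, ascending) and given ranks
    1..M.

    When the model was trained for leakage-free disease-gene inference, the
    (disease, relate, gene) triples of the target diseases must have been
    removed from the KG before training.
    """
    genes = list(gene_ids)
    if not genes:
        raise ValueError("empty gene list")
    best: dict[tuple[str, str], float] = {}
    for head in genes:
        tails = [g for g in genes if g != head]
        if not tails:
            continue
        for start in range(0, len(tails), batch_size):
            chunk = tails[start : start + batch_size]
            scores = model.score_batch([head] * len(chunk), relation, chunk)
            for tail, s in zip(chunk, scores):
                key = (head, tail) if head < tail else (tail, head)
                s = float(s)
                if key not in best or s > best[key]:
                    best[key] = s
    ordered = sorted(best.items(), key=lambda kv: (-kv[1], kv[0]))
    return [
        ScoredEdge(a, b, s, rank)
        for rank, ((a, b), s) in enumerate(ordered, start=1)
    ]


def build_subnetwork(
    edges: Sequence[ScoredEdge], top_n: int, seeds: Iterable[str]
) -> GeneNetwork:
    """Top-N edge cut restricted to edges touching at least one seed gene."""
    if top_n > len(edges):
        raise ValueError(f"top_n={top_n} exceeds the {len(edges)} available edges")
    seed_set = frozenset(seeds)
    g = nx.Graph()
    for e in sorted(edges, key=lambda e: e.rank)[:top_n]:
        if e.gene_a == e.gene_b:
            continue
        if e.gene_a in seed_set or e.gene_b in seed_set:
            g.add_edge(e.gene_a, e.gene_b, score=e.score, rank=e.rank)
    if g.number_of_edges() == 0:
        logger.warning("no top-%d edge touches a seed gene; empty network", top_n)
    return GeneNetwork(graph=g, seed_genes=seed_set)


# ---------------------------------------------------------------------------
# centrality measures


def closeness(network: GeneNetwork) -> dict[str, float]:
    """Closeness centrality, per connected component (see module docstring).

    Isolated nodes get 0 (their distance sum is empty), logged.
    """
    g = network.graph
    if g.number_of_nodes() == 0:
        raise ValueError("empty network")
    out: dict[str, float] = {}
    n_isolated = 0
    for comp in nx.connected_components(g):
        sub = g.subgraph(comp)
        if len(comp) == 1:
            out[next(iter(comp))] = 0.0
            n_isolated += 1
            continue
        out.update(nx.closeness_centrality(sub))
    if n_isolated:
        logger.info("closeness: %d isolated nodes assigned 0", n_isolated)
    return out


def betweenness(network: GeneNetwork) -> dict[str, float]:
    """Betweenness centrality normalized by (n-1)(n-2)/2 per component."""
    g = network.graph
    if g.number_of_nodes() < 3:
        raise ValueError("betweenness requires at least 3 nodes")
    out: dict[str, float] = {}
    for comp in nx.connected_components(g):
        sub = g.subgraph(comp)
        if len(comp) < 3:
            out.update({v: 0.0 for v in comp})
        else:
            out.update(nx.betweenness_centrality(sub, normalized=True))
    return out


def degree(network: GeneNetwork) -> tuple[dict[str, float], dict[str, int]]:
    """Normalized degree centrality and the raw degree per node."""
    g = network.graph
    if g.number_of_nodes() == 0:
        raise ValueError("empty network")
    n = g.number_of_nodes()
    raw = {v: int(d) for v, d in g.degree()}
    if n == 1:
        return {v: 0.0 for v in raw}, raw
    return {v: d / (n - 1) for v, d in raw.items()}, raw


def eigenvector(
    network: GeneNetwork, tol: float = 1e-10, max_iter: int = 1000
) -> dict[str, float]:
    """Eigenvector centrality by power iteration, unit-maximum normalized.

    Computed per connected component; edge weights (attribute ``weight``)
    default to 1.  Raises on non-convergence, carrying the final residual.
    """
    g = network.graph
    if g.number_of_nodes() == 0:
        raise ValueError("empty network")
    out: dict[str, float] = {}
    for comp in nx.connected_components(g):
        nodes = sorted(comp)
        if len(nodes) == 1:
            out[nodes[0]] = 0.0
            continue
        A = nx.to_numpy_array(g, nodelist=nodes, weight="weight")
        # shift by the identity: same eigenvectors, but the iteration cannot
        # oscillate on bipartite components (e.g. stars)
        A = A + np.eye(len(nodes)) * A.max()
        x = np.ones(len(nodes)) / len(nodes)
        residual = np.inf
        for _ in range(max_iter):
            x_new = A @ x
            x_new /= np.linalg.norm(x_new)
            residual = float(np.abs(x_new - x).max())
            x = x_new
            if residual < tol:
                break
        else:
            raise RuntimeError(
                f"eigenvector power iteration did not converge "
                f"(residual {residual:.3e} after {max_iter} iterations)"
            )
        x /= x.max()
        out.update(dict(zip(nodes, x)))
    return out


def centrality_table(network: GeneNetwork) -> pd.DataFrame:
    """All four centralities plus raw degree, indexed by gene."""
    cd, raw = degree(network)
    data = {
        "closeness": closeness(network),
        "betweenness": betweenness(network)
        if network.graph.number_of_nodes() >= 3
        else {v: 0.0 for v in network.graph},
        "degree_norm": cd,
        "degree": raw,
        "eigenvector": eigenvector(network),
    }
    df = pd.DataFrame(data).sort_index()
    df.index.name = "gene"
    return df


# ---------------------------------------------------------------------------
# ranking and benchmark scoring


def rank_genes(
    table: pd.DataFrame,
    measure: str,
    top_k: int | None = None,
) -> list[str]:
    """Genes sorted by a centrality measure, descending.

    Ties break by raw degree descending, then gene label ascending.  Seed
    genes are not excluded: known disease genes legitimately dominate the
    top of the ranking.
    """
    col = {"degree": "degree_norm"}.get(measure, measure)
    if col not in table.columns:
        raise KeyError(f"measure {measure!r} not in table")
    order = sorted(
        table.index,
        key=lambda g: (-table.at[g, col], -table.at[g, "degree"], g),
    )
    if top_k is None:
        return order
    if top_k > len(order):
        logger.warning("top_k=%d exceeds %d genes; returning all", top_k, len(order))
        return order
    return order[:top_k]


def precision_at_k(
    ranked_genes: Sequence[str], benchmark: Iterable[str], k: int
) -> float:
    """Percentage of the top-k ranked genes found in the benchmark set."""
    if not ranked_genes:
        raise ValueError("empty ranking")
    if k > len(ranked_genes):
        raise ValueError(f"k={k} exceeds the {len(ranked_genes)} ranked genes")
    bench = set(benchmark)
    hits = sum(1 for g in ranked_genes[:k] if g in bench)
    return 100.0 * hits / k


def pr_curve(
    ranked_genes: Sequence[str],
    benchmark: Iterable[str],
    step: int = 10,
    denominator_mode: str = "benchmark_in_network",
) -> pd.DataFrame:
    """Precision and recall at n = step, 2*step, ...

    Recall divides benchmark hits by either the full benchmark size
    (``full_benchmark``) or the number of benchmark genes present among the
    ranked genes (``benchmark_in_network``, the default, which matches how
    printed precision/recall pairs reconcile).
    """
    if step < 1:
        raise ValueError("step must be >= 1")
    bench = set(benchmark)
    if denominator_mode == "full_benchmark":
        denom = len(bench)
    elif denominator_mode == "benchmark_in_network":
        denom = len(bench & set(ranked_genes))
    else:
        raise ValueError(f"unknown denominator mode {denominator_mode!r}")
    rows = []
    for n in range(step, len(ranked_genes) + 1, step):
        hits = sum(1 for g in ranked_genes[:n] if g in bench)
        rows.append(
            {
                "n": n,
                "precision": 100.0 * hits / n,
                "recall": 100.0 * hits / denom if denom else 0.0,
            }
        )
    return pd.DataFrame(rows)


def average_precision_over_cuts(table: pd.DataFrame) -> pd.Series:
    """Unweighted per-column mean of a (cut N) x (measure) precision table,
    rounded half-up to 1 decimal."""
    if table.isna().any().any():
        raise ValueError("ragged precision table")
    return table.mean(axis=0).map(lambda v: round_half_up(v, 1))


def subsample_seeds(
    seeds: Sequence[str], sn: int, repeats: int, seed: int
) -> list[list[str]]:
    """``repeats`` random seed-gene subsets of size ``sn``, deterministic."""
    seeds = sorted(seeds)
    if sn > len(seeds):
        raise ValueError(f"sn={sn} exceeds the {len(seeds)} seed genes")
    rng = np.random.default_rng(seed)
    return [
        sorted(np.asarray(seeds)[rng.choice(len(seeds), size=sn, replace=False)])
        for _ in range(repeats)
    ]


# ---------------------------------------------------------------------------
# export


def write_edges_tsv(edges: Sequence[ScoredEdge], path) -> None:
    with open(Path(path), "w", encoding="utf-8") as fh:
        for e in edges:
            fh.write(f"{e.gene_a}\t{e.gene_b}\t{e.score:.6g}\t{e.rank}\n")


def write_sif(network: GeneNetwork, path, interaction: str = "gg") -> None:
    """Simple interaction format: ``a<TAB>interaction<TAB>b`` per edge."""
    with open(Path(path), "w", encoding="utf-8") as fh:
        for a, b in sorted(network.graph.edges):
            fh.write(f"{a}\t{interaction}\t{b}\n")
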