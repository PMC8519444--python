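"""Synthetic typed knowledge graphs with planted, learnable structure.

The generator emulates the shape of a curated biomedical KB -- four entity
types (chemical, gene, disease, symptom) and the five relation signatures
(chemical-gene, chemical-disease, disease-gene, gene-gene, disease-symptom)
-- using a latent block model: every entity belongs to one of ``n_blocks``
latent modules, triples between aligned blocks are sampled with probability
``p_within`` and all other type-compatible pairs with a small background
probability ``p_noise``.  A fraction of the within-block positives is
withheld from the emitted graph as ground-truth material for link-prediction
tests, and the genes of one designated block double as a planted
"disease-associated" gene set from which seed and benchmark lists are drawn.

Descriptions embed a block-revealing token, so a lexical encoder's vectors
correlate with the latent structure -- the synthetic analogue of real
entity descriptions carrying relational semantics.

Everything is deterministic given ``spec.seed`` and emits the exact same
file formats as curated data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .kg import (
    EntityRecord,
    KnowledgeGraph,
    RELATION_SIGNATURES,
    Triple,
    TYPE_PREFIX,
    build_graph,
    default_relations,
)
from .networks import BenchmarkGeneSet

DEFAULT_TEMPLATES: dict[str, str] = {
    etype: (
        "{name} is a synthetic {etype} belonging to module {block}; "
        "{block} {block} activity characterizes this {etype}."
    )
    for etype in TYPE_PREFIX
}


@dataclass(frozen=True)
class SyntheticKGSpec:
    """Generator controls.  Defaults give the desk-scale study conditions:
    ~200 entities in 4 blocks, a strong within-block signal (0.5) over a
    weak background (0.005), 10% of within-block positives held out."""

    n_chemicals: int = 40
    n_genes: int = 80
    n_diseases: int = 40
    n_symptoms: int = 40
    n_blocks: int = 4
    p_within: float = 0.5
    p_noise: float = 0.005
    holdout_fraction: float = 0.1
    disease_block: int = 0
    seed_fraction: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        for p in (self.p_within, self.p_noise, self.holdout_fraction,
                  self.seed_fraction):
            if not (0.0 <= p <= 1.0):
                raise ValueError("probabilities and fractions must lie in [0, 1]")
        if not (0 <= self.disease_block < self.n_blocks):
            raise ValueError("disease_block out of range")

    @property
    def counts(self) -> dict[str, int]:
        return {
            "chemical": self.n_chemicals,
            "gene": self.n_genes,
            "disease": self.n_diseases,
            "symptom": self.n_symptoms,
        }


@dataclass
class GroundTruth:
    blocks: dict[str, int]
    heldout_positives: frozenset[Triple]
    disease_genes: frozenset[str]
    symbols: dict[str, str] = field(default_factory=dict)  # entity id -> name
    spec: SyntheticKGSpec = field(repr=False, default=None)


def _entity_name(etype: str, i: int) -> str:
    return f"{etype.upper()}{i:03d}"


def generate_kg(spec: SyntheticKGSpec) -> tuple[KnowledgeGraph, GroundTruth]:
    """Sample a typed block-model KG; see module docstring.

    Entities get deterministic type-prefixed ids; blocks are assigned
    round-robin by entity index.  Gene-gene pairs are sampled once per
    unordered pair (one direction emitted).  Raises if any relation ends up
    with no emitted triples.
    """
    rng = np.random.default_rng(spec.seed)
    entities: list[EntityRecord] = []
    blocks: dict[str, int] = {}
    ids_by_type: dict[str, list[str]] = {}
    for etype, count in spec.counts.items():
        prefix = TYPE_PREFIX[etype]
        ids = []
        for i in range(1, count + 1):
            eid = f"/{prefix}/{i:05d}"
            entities.append(
                EntityRecord(eid, etype, _entity_name(etype, i))
            )
            blocks[eid] = (i - 1) % spec.n_blocks
            ids.append(eid)
        ids_by_type[etype] = ids

    emitted: list[Triple] = []
    heldout: set[Triple] = set()
    for rel, (head_type, tail_type) in RELATION_SIGNATURES.items():
        heads = ids_by_type[head_type]
        tails = ids_by_type[tail_type]
        within: list[Triple] = []
        noise: list[Triple] = []
        for h in heads:
            for t in tails:
                if h == t:
                    continue
                if head_type == tail_type and h > t:
                    continue  # one direction per unordered gene pair
                p = spec.p_within if blocks[h] == blocks[t] else spec.p_noise
                if rng.random() < p:
                    (within if blocks[h] == blocks[t] else noise).append(
                        Triple(h, rel, t)
                    )
        n_hold = int(round(spec.holdout_fraction * len(within)))
        if n_hold:
            idx = rng.choice(len(within), size=n_hold, replace=False)
            hold = {within[i] for i in idx}
            heldout.update(hold)
            within = [t for t in within if t not in hold]
        if not within and not noise:
            raise ValueError(f"spec produced zero triples for relation {rel!r}")
        emitted.extend(within)
        emitted.extend(noise)

    kg = build_graph(emitted, entities, default_relations())
    disease_genes = frozenset(
        eid for eid in ids_by_type["gene"] if blocks[eid] == spec.disease_block
    )
    return kg, GroundTruth(
        blocks=blocks,
        heldout_positives=frozenset(heldout),
        disease_genes=disease_genes,
        symbols={e.entity_id: e.canonical_name for e in entities},
        spec=spec,
    )


def generate_descriptions(
    kg: KnowledgeGraph,
    ground_truth: GroundTruth,
    templates: Mapping[str, str] | None = None,
) -> dict[str, tuple[str, str]]:
    """Templated descriptions embedding each entity's block token ("blk3")."""
    templates = dict(templates) if templates is not None else DEFAULT_TEMPLATES
    out: dict[str, tuple[str, str]] = {}
    for eid, rec in kg.entities.items():
        if rec.entity_type not in templates:
            raise KeyError(f"no description template for type {rec.entity_type!r}")
        text = templates[rec.entity_type].format(
            name=rec.canonical_name,
            etype=rec.entity_type,
            block=f"blk{ground_truth.blocks[eid]}",
        )
        out[eid] = (rec.canonical_name, text)
    return out


def make_benchmark(
    ground_truth: GroundTruth, seed: int | None = None
) -> tuple[list[str], BenchmarkGeneSet]:
    """Seed-gene list and benchmark set from the planted disease genes.

    Seeds are a random ``seed_fraction`` subset of the planted genes (at
    least one); the benchmark is the full planted set, expressed as gene
    symbols (canonical names are the symbols here).  Deterministic given
    the seed (defaults to the generator spec's seed).
    """
    planted = sorted(ground_truth.disease_genes)
    if not planted:
        raise ValueError("no planted disease-associated genes")
    spec = ground_truth.spec
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    n_seeds = max(1, int(round(spec.seed_fraction * len(planted))))
    idx = rng.choice(len(planted), size=n_seeds, replace=False)
    seeds = sorted(planted[i] for i in idx)
    benchmark = BenchmarkGeneSet(
        name="planted",
        symbols=frozenset(ground_truth.symbols[g] for g in planted),
    )
    return seeds, benchmark
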