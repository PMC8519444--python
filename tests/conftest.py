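"""Shared fixtures: a tiny hand-built KG and desk-scale trained models.

Training fixtures are session-scoped because a single desk-scale KGED run
takes tens of seconds; tests share them rather than retrain.
"""

from __future__ import annotations

import dataclasses
from types import SimpleNamespace

import numpy as np
import pytest

import kged
from kged import (
    DESK_CONFIG,
    EntityRecord,
    HashingTextEncoder,
    SyntheticKGSpec,
    Triple,
    build_graph,
    default_relations,
    generate_descriptions,
    generate_kg,
    initialize_kged,
    split_triples,
)
from kged.models import KGEDModel, _train_conv_model


def make_tiny_kg():
    """Six entities, five valid triples over three relations."""
    entities = [
        EntityRecord("/c/00001", "chemical", "aspirin"),
        EntityRecord("/c/00002", "chemical", "cisplatin"),
        EntityRecord("/g/00001", "gene", "BRCA2", synonyms=frozenset({"FANCD1"})),
        EntityRecord("/g/00002", "gene", "TP53"),
        EntityRecord("/d/00001", "disease", "breast cancer",
                     synonyms=frozenset({"mammary carcinoma"})),
        EntityRecord("/s/00001", "symptom", "fatigue"),
    ]
    triples = [
        Triple("/c/00001", "c_relate_g", "/g/00001"),
        Triple("/c/00002", "c_relate_g", "/g/00002"),
        Triple("/c/00001", "c_relate_d", "/d/00001"),
        Triple("/d/00001", "d_relate_g", "/g/00001"),
        Triple("/d/00001", "d_have_s", "/s/00001"),
    ]
    return build_graph(triples, entities, default_relations())


@pytest.fixture
def tiny_kg():
    return make_tiny_kg()


def desk_problem(seed: int) -> SimpleNamespace:
    """Synthetic desk-scale study conditions for one generator seed."""
    spec = SyntheticKGSpec(seed=seed)
    kg, truth = generate_kg(spec)
    split = split_triples(kg, 25, 25, seed=seed)
    descriptions = generate_descriptions(kg, truth)
    encoder = HashingTextEncoder(DESK_CONFIG.l)
    config = dataclasses.replace(DESK_CONFIG, seed=seed)
    return SimpleNamespace(
        spec=spec, kg=kg, truth=truth, split=split,
        descriptions=descriptions, encoder=encoder, config=config,
    )


def train_desk_model(problem: SimpleNamespace) -> tuple[KGEDModel, KGEDModel]:
    """Return (initial snapshot, trained model) for a desk problem."""
    init = initialize_kged(
        problem.kg, problem.descriptions, problem.encoder, problem.config,
        problem.split,
    )
    snapshot = KGEDModel(
        problem.config,
        init.entities.copy(),
        init.relations.copy(),
        init.conv_params.copy(),
        init.entity_descriptions.copy(),
        init.relation_descriptions.copy(),
    )
    trained = _train_conv_model(init, problem.kg, problem.split, problem.config)
    return snapshot, trained


@pytest.fixture(scope="session")
def desk_run(ten_seed_runs):
    """One desk-scale problem (seed 3) with its initial and trained models."""
    return ten_seed_runs[3]


@pytest.fixture(scope="session")
def ten_seed_runs():
    """Ten generator seeds with initial and trained models each (the
    repeat-experiment study conditions); shared by the recovery and
    monotone-training checks."""
    runs = []
    for seed in range(10):
        problem = desk_problem(seed)
        snapshot, trained = train_desk_model(problem)
        problem.initial_model = snapshot
        problem.model = trained
        runs.append(problem)
    return runs
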