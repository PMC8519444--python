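"""Score functions, loss, negative sampling, initialization, training."""

import dataclasses
import math

import numpy as np
import pytest

from kged import (
    EntityRecord,
    HashingTextEncoder,
    ModelConfig,
    Triple,
    build_graph,
    build_input_matrices,
    convkb_score,
    corrupt_triples,
    cosine_distance_profile,
    default_relations,
    generate_descriptions,
    generate_kg,
    initialize_kged,
    kged_feature_maps,
    kged_loss,
    kged_score,
    split_triples,
    train_kged,
    train_transe,
    transe_energy,
    SyntheticKGSpec,
)
from kged.models import (
    ConvParams,
    EmbeddingTable,
    ScoringModeError,
    _backward_branch,
    _forward_branch,
    _sample_negatives_batch,
)

SMALL = ModelConfig(k=6, l=8, delta=2, epochs=5, transe_epochs=5, seed=0)


def conv_features_oracle(M, bank, bias, activation="relu"):
    """Nested-loop reimplementation of the branch feature maps."""
    feats = []
    for n in sorted(bank):
        for d in range(bank[n].shape[0]):
            for i in range(M.shape[0] - n + 1):
                v = bias[n][d]
                for a in range(n):
                    for b in range(3):
                        v += bank[n][d, a, b] * M[i + a, b]
                feats.append(max(v, 0.0) if activation == "relu" else math.tanh(v))
    return np.array(feats)


def random_tables(config, rng, n_ent=5, n_rel=2):
    ents = [f"/g/{i:05d}" for i in range(1, n_ent + 1)]
    rels = [f"r{i}" for i in range(n_rel)]
    return (
        EmbeddingTable.random(ents, config.k, rng),
        EmbeddingTable.random(rels, config.k, rng),
        EmbeddingTable.random(ents, config.l, rng),
        EmbeddingTable.random(rels, config.l, rng),
    )


# ---------------------------------------------------------------------------
# TransE energy


def test_transe_energy_identity_and_hand_sum():
    h = np.array([1.0, 0.0])
    assert transe_energy(h, np.zeros(2), h) == 0.0
    assert transe_energy(h, np.array([0.0, 1.0]), np.zeros(2), "L1") == 2.0


def test_transe_energy_matches_elementwise_recomputation():
    rng = np.random.default_rng(0)
    h, r, t = rng.normal(size=(3, 50))
    manual = math.sqrt(sum((h[i] + r[i] - t[i]) ** 2 for i in range(50)))
    assert transe_energy(h, r, t, "L2") == pytest.approx(manual, rel=1e-12)
    with pytest.raises(ValueError):
        transe_energy(h, r, t[:10])


# ---------------------------------------------------------------------------
# convolution feature maps and scores


def test_feature_maps_length_formula():
    cfg = ModelConfig(k=10, l=12, delta=4)
    rng = np.random.default_rng(0)
    params = ConvParams.init(cfg, rng)
    M = rng.normal(size=(10, 3))
    out = kged_feature_maps(M, params.theta1, params.b1)
    assert out.shape[0] == 3 * 4 * (10 - 3) == cfg.feature_length(10)


def test_feature_maps_zero_bank_and_all_ones_window():
    bank = {3: np.zeros((2, 3, 3))}
    bias = {3: np.zeros(2)}
    M = np.ones((7, 3))
    assert np.all(kged_feature_maps(M, bank, bias) == 0.0)
    bank = {3: np.ones((1, 3, 3))}
    bias = {3: np.zeros(1)}
    out = kged_feature_maps(M, bank, bias)
    assert np.all(out == 9.0) and out.shape == (5,)


def test_feature_maps_error_when_matrix_too_short():
    bank = {5: np.ones((1, 5, 3))}
    with pytest.raises(ValueError):
        kged_feature_maps(np.ones((4, 3)), bank, {5: np.zeros(1)})


def test_convkb_score_hand_case_zero_filters_and_linearity():
    cfg = ModelConfig(k=6, l=8, delta=2)
    rng = np.random.default_rng(1)
    ents, rels, *_ = random_tables(cfg, rng)
    t = Triple("/g/00001", "r0", "/g/00002")
    zero = ConvParams(
        theta1={n: np.zeros((2, n, 3)) for n in (3, 4, 5)},
        b1={n: np.zeros(2) for n in (3, 4, 5)},
        theta2=None, b2=None,
        w=rng.normal(size=cfg.feature_length(6)),
    )
    assert convkb_score(t, ents, rels, zero, cfg) == 0.0
    params = ConvParams.init(cfg, rng, with_descriptions=False)
    s1 = convkb_score(t, ents, rels, params, cfg)
    doubled = ConvParams(params.theta1, params.b1, None, None, 2 * params.w)
    assert convkb_score(t, ents, rels, doubled, cfg) == pytest.approx(2 * s1)


def test_convkb_identity_like_hand_computation():
    # k=3, single 3x3 all-ones filter, bias 0, w=(1): score = relu(sum(A))
    cfg = ModelConfig(k=4, l=8, delta=1, filter_sizes=(3,))
    A = np.eye(4, 3)
    bank = {3: np.ones((1, 3, 3))}
    out = kged_feature_maps(A, bank, {3: np.zeros(1)})
    assert out.tolist() == [3.0, 2.0]  # window sums of the two 3-row windows


@pytest.mark.parametrize("instance", range(50))
def test_kged_score_matches_nested_loop_oracle(instance):
    cfg = SMALL
    rng = np.random.default_rng(100 + instance)
    ents, rels, ed, rd = random_tables(cfg, rng)
    params = ConvParams.init(cfg, rng)
    t = Triple("/g/00001", "r0", "/g/00003")
    got = kged_score(t, ents, rels, ed, rd, params, cfg)
    A, B = build_input_matrices(t, ents, rels, ed, rd)
    x = conv_features_oracle(A, params.theta1, params.b1)
    y = conv_features_oracle(B, params.theta2, params.b2)
    expected = float(np.concatenate([x, y]) @ params.w)
    assert got == pytest.approx(expected, rel=1e-6)


def test_kged_score_zero_banks_give_zero_and_dropout_contract():
    cfg = SMALL
    rng = np.random.default_rng(2)
    ents, rels, ed, rd = random_tables(cfg, rng)
    params = ConvParams.init(cfg, rng)
    for n in cfg.filter_sizes:
        params.theta1[n][:] = 0.0
        params.theta2[n][:] = 0.0
    t = Triple("/g/00002", "r1", "/g/00004")
    assert kged_score(t, ents, rels, ed, rd, params, cfg) == 0.0
    with pytest.raises(ScoringModeError):
        kged_score(t, ents, rels, ed, rd, params, cfg,
                   training=False, rng=np.random.default_rng(0))


def test_kged_degenerates_to_convkb_with_zeroed_description_branch():
    cfg = SMALL
    rng = np.random.default_rng(3)
    ents, rels, ed, rd = random_tables(cfg, rng)
    params = ConvParams.init(cfg, rng)
    for n in cfg.filter_sizes:
        params.theta2[n][:] = 0.0
        params.b2[n][:] = 0.0
    dx = cfg.feature_length(cfg.k)
    convkb_params = ConvParams(params.theta1, params.b1, None, None,
                               params.w[:dx])
    for i in range(1, 6):
        t = Triple(f"/g/{i:05d}", "r0", f"/g/{(i % 5) + 1:05d}")
        assert kged_score(t, ents, rels, ed, rd, params, cfg) == convkb_score(
            t, ents, rels, convkb_params, cfg
        )


def test_build_input_matrices_columns_and_order():
    cfg = SMALL
    rng = np.random.default_rng(4)
    ents, rels, ed, rd = random_tables(cfg, rng)
    t = Triple("/g/00001", "r0", "/g/00002")
    A, B = build_input_matrices(t, ents, rels, ed, rd)
    assert np.array_equal(A[:, 0], ents["/g/00001"])
    assert np.array_equal(A[:, 1], rels["r0"])
    assert np.array_equal(A[:, 2], ents["/g/00002"])
    assert B.shape == (cfg.l, 3)
    A_swapped, _ = build_input_matrices(
        Triple(t.tail, t.relation, t.head), ents, rels, ed, rd
    )
    assert not np.array_equal(A, A_swapped)
    with pytest.raises(KeyError, match="/g/99999"):
        build_input_matrices(Triple("/g/99999", "r0", "/g/00002"),
                             ents, rels, ed, rd)


# ---------------------------------------------------------------------------
# loss


def test_kged_loss_worked_values():
    w = np.zeros(4)
    assert kged_loss([0.0], [1.0], w, 0.0) == pytest.approx(math.log(2))
    assert kged_loss([-10.0], [1.0], w, 0.0) == pytest.approx(
        math.log1p(math.exp(-10)), rel=1e-9
    )
    m = 7
    assert kged_loss([0.0] * m, [1.0] * m, w, 0.0) == pytest.approx(m * math.log(2))
    # regularizer: (lambda/2) ||w||^2
    w = np.array([3.0, 4.0])
    assert kged_loss([0.0], [-1.0], w, 0.1) == pytest.approx(
        math.log(2) + 0.05 * 25.0
    )
    with pytest.raises(ValueError):
        kged_loss([0.0], [0.5], w, 0.0)


def test_loss_gradient_matches_finite_differences():
    """Analytic gradients of the softplus ranking loss w.r.t. w and a filter."""
    cfg = dataclasses.replace(SMALL, dropout_rate=0.0, l2_lambda=1e-3)
    rng = np.random.default_rng(5)
    ents, rels, ed, rd = random_tables(cfg, rng)
    params = ConvParams.init(cfg, rng)
    t = Triple("/g/00001", "r0", "/g/00002")
    label = np.array([1.0])

    def loss_fn(p):
        s = kged_score(t, ents, rels, ed, rd, p, cfg)
        return kged_loss([s], label, p.w, cfg.l2_lambda)

    # analytic, via the training-path forward/backward
    A, B = build_input_matrices(t, ents, rels, ed, rd)
    X, cx = _forward_branch(A[None], params.theta1, params.b1, cfg.activation)
    Y, _cy = _forward_branch(B[None], params.theta2, params.b2, cfg.activation)
    Z = np.concatenate([X, Y], axis=1)
    s = float(Z[0] @ params.w)
    ds = label * (1.0 / (1.0 + np.exp(-label * s)))
    dw = Z[0] * ds[0] + cfg.l2_lambda * params.w
    dx = cfg.feature_length(cfg.k)
    dZ = ds[:, None] * params.w[None, :]
    d_theta1, _db1, _ = _backward_branch(
        dZ[:, :dx], cx, params.theta1, cfg.activation, cfg.k, False
    )

    eps = 1e-6
    # w gradient
    num = np.zeros_like(params.w)
    for i in range(len(params.w)):
        p_hi = ConvParams(params.theta1, params.b1, params.theta2, params.b2,
                          params.w.copy())
        p_hi.w[i] += eps
        p_lo = ConvParams(params.theta1, params.b1, params.theta2, params.b2,
                          params.w.copy())
        p_lo.w[i] -= eps
        num[i] = (loss_fn(p_hi) - loss_fn(p_lo)) / (2 * eps)
    assert np.max(np.abs(num - dw)) / max(np.max(np.abs(num)), 1e-12) < 1e-4

    # one filter's gradient (size 3, filter 0)
    th = params.theta1[3]
    num_f = np.zeros_like(th[0])
    for a in range(3):
        for b in range(3):
            for sign in (1, -1):
                th[0, a, b] += sign * eps
                val = loss_fn(params)
                th[0, a, b] -= sign * eps
                num_f[a, b] += sign * val / (2 * eps)
    rel_err = np.max(np.abs(num_f - d_theta1[3][0])) / max(
        np.max(np.abs(num_f)), 1e-12
    )
    assert rel_err < 1e-4


# ---------------------------------------------------------------------------
# negative sampling


def _gene_chain_kg(n=8):
    ents = [EntityRecord(f"/g/{i:05d}", "gene", f"G{i}") for i in range(1, n + 1)]
    triples = [
        Triple(f"/g/{i:05d}", "g_relate_g", f"/g/{i + 1:05d}")
        for i in range(1, n)
    ] + [Triple(f"/g/{n:05d}", "g_relate_g", "/g/00001")]
    return build_graph(triples, ents, default_relations())


def test_corrupt_triples_properties():
    kg, _ = generate_kg(SyntheticKGSpec(seed=2))
    t = sorted(kg.triples)[0]
    negs = corrupt_triples(t, kg, 10, seed=0)
    assert len(negs) == 10
    rel = kg.relations[t.relation]
    for n in negs:
        assert n not in kg
        changed_head = n.head != t.head
        changed_tail = n.tail != t.tail
        assert changed_head != changed_tail  # exactly one slot changed
        assert kg.entities[n.head].entity_type == rel.head_type
        assert kg.entities[n.tail].entity_type == rel.tail_type
    assert corrupt_triples(t, kg, 10, seed=0) == negs  # deterministic


def test_corrupt_triples_exhaustion_error():
    ents = [
        EntityRecord("/c/00001", "chemical", "c1"),
        EntityRecord("/c/00002", "chemical", "c2"),
        EntityRecord("/g/00001", "gene", "g1"),
    ]
    triples = [
        Triple("/c/00001", "c_relate_g", "/g/00001"),
        Triple("/c/00002", "c_relate_g", "/g/00001"),
    ]
    kg = build_graph(triples, ents, default_relations())
    with pytest.raises(ValueError, match="no valid corruption"):
        corrupt_triples(triples[0], kg, 1, seed=0)


# ---------------------------------------------------------------------------
# training


def test_transe_training_separates_facts_from_corruptions():
    kg = _gene_chain_kg()
    from kged import TripleSplit

    split = TripleSplit(frozenset(kg.triples), frozenset(), frozenset(), 0)
    cfg = ModelConfig(k=8, l=16, epochs=0, transe_epochs=200,
                      transe_learning_rate=0.05, seed=0)
    model = train_transe(kg, split, cfg)
    rng = np.random.default_rng(0)
    pos = [model.energy(t) for t in kg.triples]
    negs = _sample_negatives_batch(sorted(kg.triples), kg, 3, rng)
    neg = [model.energy(t) for t in negs]
    assert np.mean(pos) < np.mean(neg)


def test_transe_zero_epochs_returns_initialization_deterministically():
    kg = _gene_chain_kg()
    from kged import TripleSplit

    split = TripleSplit(frozenset(kg.triples), frozenset(), frozenset(), 0)
    cfg = ModelConfig(k=8, l=16, transe_epochs=0, seed=42)
    m1 = train_transe(kg, split, cfg)
    m2 = train_transe(kg, split, cfg)
    assert np.array_equal(m1.entities.vectors, m2.entities.vectors)
    assert np.array_equal(m1.relations.vectors, m2.relations.vectors)


@pytest.fixture(scope="module")
def small_problem():
    spec = SyntheticKGSpec(n_chemicals=10, n_genes=20, n_diseases=10,
                           n_symptoms=10, n_blocks=2, seed=0)
    kg, truth = generate_kg(spec)
    split = split_triples(kg, 2, 2, seed=0)
    descriptions = generate_descriptions(kg, truth)
    return kg, split, descriptions


def test_kged_training_is_deterministic_given_seed(small_problem):
    kg, split, descriptions = small_problem
    cfg = dataclasses.replace(SMALL, epochs=3, transe_epochs=3, seed=11)
    enc = HashingTextEncoder(cfg.l)
    m1 = train_kged(kg, split, descriptions, enc, cfg)
    m2 = train_kged(kg, split, descriptions, enc, cfg)
    assert m1.loss_history == m2.loss_history
    assert np.array_equal(m1.conv_params.w, m2.conv_params.w)
    assert np.array_equal(m1.entities.vectors, m2.entities.vectors)


def test_kged_zero_epochs_equals_initialization(small_problem):
    kg, split, descriptions = small_problem
    cfg = dataclasses.replace(SMALL, epochs=0, transe_epochs=2, seed=7)
    enc = HashingTextEncoder(cfg.l)
    init = initialize_kged(kg, descriptions, enc, cfg, split)
    trained = train_kged(kg, split, descriptions, enc, cfg)
    assert np.array_equal(init.conv_params.w, trained.conv_params.w)
    assert np.array_equal(init.entities.vectors, trained.entities.vectors)


def test_kged_frozen_descriptions_are_bit_stable(small_problem):
    kg, split, descriptions = small_problem
    cfg = dataclasses.replace(SMALL, epochs=2, transe_epochs=2, seed=9)
    enc = HashingTextEncoder(cfg.l)
    init = initialize_kged(kg, split=split, descriptions=descriptions,
                           encoder=enc, config=cfg)
    before = init.entity_descriptions.vectors.copy()
    trained = train_kged(kg, split, descriptions, enc, cfg)
    assert np.array_equal(trained.entity_descriptions.vectors, before)


def test_relation_descriptions_are_the_canonical_sentences(small_problem):
    kg, split, descriptions = small_problem
    from kged import RELATION_DESCRIPTIONS

    assert kg.relations["c_relate_g"].description_text == (
        "a chemical is related to a gene"
    )
    assert kg.relations["d_have_s"].description_text == (
        "a disease contains a symptom"
    )
    assert set(RELATION_DESCRIPTIONS) == set(kg.relations)


def test_checkpoint_round_trip(small_problem, tmp_path):
    kg, split, descriptions = small_problem
    cfg = dataclasses.replace(SMALL, epochs=1, transe_epochs=1, seed=3)
    enc = HashingTextEncoder(cfg.l)
    from kged.models import KGEDModel

    model = train_kged(kg, split, descriptions, enc, cfg)
    model.save(tmp_path / "ckpt.npz")
    loaded = KGEDModel.load(tmp_path / "ckpt.npz")
    t = sorted(split.train)[0]
    assert loaded.score(t) == pytest.approx(model.score(t), rel=1e-12)
    assert loaded.config == model.config


def test_training_loss_decreases_across_seeds(ten_seed_runs):
    """Final training loss beats the first epoch's on >= 9 of 10 seeds."""
    wins = sum(
        run.model.loss_history[-1] < run.model.loss_history[0]
        for run in ten_seed_runs
    )
    assert wins >= 9


# ---------------------------------------------------------------------------
# cosine distance profile


def test_cosine_profile_degenerate_cases():
    table = EmbeddingTable(["/g/00001", "/g/00002"],
                           np.array([[1.0, 0.0], [0.0, 1.0]]))
    same = [Triple("/g/00001", "g_relate_g", "/g/00001")]
    hist = cosine_distance_profile(table, same, window_n=2)
    assert hist[0] == 1.0
    orth = [Triple("/g/00001", "g_relate_g", "/g/00002")]
    hist = cosine_distance_profile(table, orth, window_n=2)
    assert hist[9] == 1.0


def test_cosine_profile_matches_brute_force():
    rng = np.random.default_rng(6)
    ids = [f"/g/{i:05d}" for i in range(1, 7)]
    table = EmbeddingTable(ids, rng.normal(size=(6, 10)))
    triples = [Triple(ids[i], "g_relate_g", ids[(i + 1) % 6]) for i in range(6)]
    hist = cosine_distance_profile(table, triples, window_n=3)
    assert hist.sum() == pytest.approx(1.0)
    counts = np.zeros(10)
    for t in triples:
        h, tt = table[t.head], table[t.tail]
        for i in range(8):
            a, b = h[i:i + 3], tt[i:i + 3]
            d = 1 - (a @ b) / (np.linalg.norm(a) * np.linalg.norm(b))
            counts[min(int(np.clip(d, 0, 1) * 10), 9)] += 1
    assert np.allclose(hist, counts / counts.sum())
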