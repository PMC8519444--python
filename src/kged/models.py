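"""Triple-scoring models: TransE, ConvKB, and the description-aware KGED.

TransE scores a triple (h, r, t) by the translation energy
``E_r(h, t) = ||h + r - t||`` (L1 or L2); low energy means plausible.

ConvKB stacks the three k-dimensional embeddings into a k x 3 matrix
``A = [h, r, t]`` and convolves it with a bank of n x 3 filters (window
heights n in {3, 4, 5} here); the activated feature maps are concatenated
and projected with a weight vector ``w`` to a scalar score.

KGED adds a second branch: an l x 3 matrix ``B = [h_d, r_d, t_d]`` of
*description* embeddings (from a sentence encoder, frozen during training)
convolved with its own filter bank.  The score is

    f(h, r, t) = concat(X, Y) . w

where X and Y are the concatenated feature maps of the triple branch and the
description branch.  Training minimizes the softplus ranking loss

    L = sum softplus(l * f) + (lambda/2) ||w||^2

over facts and sampled corrupted triples, with Adam.  Throughout the public
API, HIGHER score = more plausible; internally facts carry the label -1 so
that minimizing the loss above drives fact scores up (with the printed
convention l=+1 for facts the same loss drives fact scores down; only the
orientation differs, not the optimum).

No autodiff framework is used: gradients of the convolutional score are
short closed forms and are computed analytically (and checked against finite
differences in the test suite).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .encoders import TextEncoder
from .kg import KnowledgeGraph, Triple, TripleSplit

logger = logging.getLogger(__name__)


class TrainingDivergenceError(RuntimeError):
    """Raised when the training loss becomes non-finite."""


class ScoringModeError(RuntimeError):
    """Raised when dropout is requested outside training mode."""


def _activation(name: str) -> Callable[[np.ndarray], np.ndarray]:
    if name == "relu":
        return lambda x: np.maximum(x, 0.0)
    if name == "tanh":
        return np.tanh
    raise ValueError(f"unknown activation {name!r}")


@dataclass(frozen=True)
class ModelConfig:
    """Hyperparameters. Defaults are the optimal full-scale configuration
    (k=50, lr=1e-4, 500 filters per size, dropout 0.7, batch 128,
    lambda=1e-4, 200 epochs, ReLU, description dimension 512; TransE:
    lr=0.01, L1, margin 2, batch 100, 3000 pre-training epochs)."""

    k: int = 50
    l: int = 512
    filter_sizes: tuple[int, ...] = (3, 4, 5)
    delta: int = 500
    dropout_rate: float = 0.7
    learning_rate: float = 1e-4
    batch_size: int = 128
    l2_lambda: float = 1e-4
    epochs: int = 200
    margin: float = 2.0
    norm: str = "L1"
    activation: str = "relu"
    neg_per_pos: int = 1
    seed: int = 0
    transe_epochs: int = 3000
    transe_learning_rate: float = 0.01
    transe_batch_size: int = 100
    train_entity_embeddings: bool = True
    freeze_descriptions: bool = True

    def __post_init__(self) -> None:
        mx = max(self.filter_sizes)
        if self.k <= mx or self.l <= mx:
            raise ValueError("embedding dimensions must exceed the largest filter")
        if not (0.0 <= self.dropout_rate < 1.0):
            raise ValueError("dropout_rate must lie in [0, 1)")
        if self.norm not in ("L1", "L2"):
            raise ValueError("norm must be 'L1' or 'L2'")
        for name in ("delta", "batch_size", "neg_per_pos"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        for name in ("epochs", "transe_epochs"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        _activation(self.activation)

    def feature_length(self, height: int) -> int:
        """Length of one branch's concatenated feature vector."""
        return self.delta * sum(height - n + 1 for n in self.filter_sizes)


#: Desk-scale configuration used for synthetic experiments and tests: small
#: enough for a single CPU, large enough for the block structure to be
#: learnable.  Paper-scale defaults stay in ModelConfig.
DESK_CONFIG = ModelConfig(
    k=16,
    l=32,
    delta=8,
    dropout_rate=0.2,
    learning_rate=3e-3,
    epochs=100,
    neg_per_pos=2,
    transe_epochs=50,
)


class EmbeddingTable:
    """One fixed-length vector per id, with O(1) id lookup."""

    def __init__(self, ids: Sequence[str], vectors: np.ndarray):
        if len(ids) != len(vectors):
            raise ValueError("ids and vectors disagree in length")
        self.ids = tuple(ids)
        self.index = {eid: i for i, eid in enumerate(self.ids)}
        self.vectors = np.asarray(vectors, dtype=float)

    @property
    def dim(self) -> int:
        return self.vectors.shape[1]

    def get(self, eid: str) -> np.ndarray:
        if eid not in self.index:
            raise KeyError(f"no embedding for {eid!r}")
        return self.vectors[self.index[eid]]

    __getitem__ = get

    def rows(self, eids: Sequence[str]) -> np.ndarray:
        return self.vectors[[self.index[e] for e in eids]]

    def copy(self) -> "EmbeddingTable":
        return EmbeddingTable(self.ids, self.vectors.copy())

    @classmethod
    def random(
        cls, ids: Sequence[str], dim: int, rng: np.random.Generator, scale: float = 1.0
    ) -> "EmbeddingTable":
        return cls(ids, rng.normal(0.0, scale, size=(len(ids), dim)))


@dataclass
class ConvParams:
    """Filter banks, biases, and the scoring weight vector.

    ``theta1``/``b1`` act on the triple matrix, ``theta2``/``b2`` on the
    description matrix; both banks hold ``delta`` filters of shape (n, 3)
    for each window height n.  ``w`` spans the concatenated feature vector
    (triple features first, then description features)."""

    theta1: dict[int, np.ndarray]
    b1: dict[int, np.ndarray]
    theta2: dict[int, np.ndarray] | None
    b2: dict[int, np.ndarray] | None
    w: np.ndarray

    @property
    def with_descriptions(self) -> bool:
        return self.theta2 is not None

    @classmethod
    def init(
        cls,
        config: ModelConfig,
        rng: np.random.Generator,
        with_descriptions: bool = True,
        filter_scale: float = 0.1,
    ) -> "ConvParams":
        """Zero-mean normal filters (scale 0.1), zero biases, and a weight
        vector scaled by 1/sqrt(len(w))."""
        theta1 = {
            n: rng.normal(0.0, filter_scale, size=(config.delta, n, 3))
            for n in config.filter_sizes
        }
        b1 = {n: np.zeros(config.delta) for n in config.filter_sizes}
        d = config.feature_length(config.k)
        theta2 = b2 = None
        if with_descriptions:
            theta2 = {
                n: rng.normal(0.0, filter_scale, size=(config.delta, n, 3))
                for n in config.filter_sizes
            }
            b2 = {n: np.zeros(config.delta) for n in config.filter_sizes}
            d += config.feature_length(config.l)
        w = rng.normal(0.0, 1.0 / np.sqrt(d), size=d)
        return cls(theta1=theta1, b1=b1, theta2=theta2, b2=b2, w=w)

    def copy(self) -> "ConvParams":
        return ConvParams(
            theta1={n: v.copy() for n, v in self.theta1.items()},
            b1={n: v.copy() for n, v in self.b1.items()},
            theta2=None
            if self.theta2 is None
            else {n: v.copy() for n, v in self.theta2.items()},
            b2=None if self.b2 is None else {n: v.copy() for n, v in self.b2.items()},
            w=self.w.copy(),
        )


# ---------------------------------------------------------------------------
# score functions


def transe_energy(
    h_vec: np.ndarray, r_vec: np.ndarray, t_vec: np.ndarray, norm: str = "L1"
) -> float:
    """Translation energy ||h + r - t|| (lower = more plausible)."""
    h_vec, r_vec, t_vec = (np.asarray(v, dtype=float) for v in (h_vec, r_vec, t_vec))
    if not (h_vec.shape == r_vec.shape == t_vec.shape):
        raise ValueError("h, r, t must share a dimension")
    d = h_vec + r_vec - t_vec
    if norm == "L1":
        return float(np.abs(d).sum())
    if norm == "L2":
        return float(np.sqrt((d * d).sum()))
    raise ValueError(f"unknown norm {norm!r}")


def kged_feature_maps(
    matrix: np.ndarray,
    filter_bank: Mapping[int, np.ndarray],
    bias: Mapping[int, np.ndarray],
    activation: str = "relu",
) -> np.ndarray:
    """Convolve a (height x 3) matrix with a bank of (n x 3) filters.

    For each window height n (ascending) and each filter, the filter slides
    over the ``height - n + 1`` row windows; features are concatenated in the
    fixed order (size ascending, then filter index, then window position).
    """
    g = _activation(activation)
    matrix = np.asarray(matrix, dtype=float)
    height = matrix.shape[0]
    parts = []
    for n in sorted(filter_bank):
        if height < n:
            raise ValueError(f"matrix height {height} below filter size {n}")
        windows = sliding_window_view(matrix, (n, 3)).reshape(height - n + 1, n, 3)
        pre = np.einsum("pnc,dnc->dp", windows, filter_bank[n]) + np.asarray(
            bias[n]
        ).reshape(-1, 1)
        parts.append(g(pre).ravel())
    return np.concatenate(parts)


def build_input_matrices(
    triple: Triple,
    entities: EmbeddingTable,
    relations: EmbeddingTable,
    entity_descriptions: EmbeddingTable,
    relation_descriptions: EmbeddingTable,
) -> tuple[np.ndarray, np.ndarray]:
    """Assemble A = [h, r, t] (k x 3) and B = [h_d, r_d, t_d] (l x 3)."""
    A = np.column_stack(
        [entities[triple.head], relations[triple.relation], entities[triple.tail]]
    )
    B = np.column_stack(
        [
            entity_descriptions[triple.head],
            relation_descriptions[triple.relation],
            entity_descriptions[triple.tail],
        ]
    )
    return A, B


def convkb_score(
    triple: Triple,
    entities: EmbeddingTable,
    relations: EmbeddingTable,
    conv_params: ConvParams,
    config: ModelConfig,
) -> float:
    """ConvKB score: feature maps of [h, r, t] dotted with w."""
    A = np.column_stack(
        [entities[triple.head], relations[triple.relation], entities[triple.tail]]
    )
    x = kged_feature_maps(A, conv_params.theta1, conv_params.b1, config.activation)
    if conv_params.w.shape[0] != x.shape[0]:
        raise ValueError(
            f"w has length {conv_params.w.shape[0]}, features have {x.shape[0]}"
        )
    return float(x @ conv_params.w)


def kged_score(
    triple: Triple,
    entities: EmbeddingTable,
    relations: EmbeddingTable,
    entity_descriptions: EmbeddingTable,
    relation_descriptions: EmbeddingTable,
    conv_params: ConvParams,
    config: ModelConfig,
    training: bool = False,
    rng: np.random.Generator | None = None,
) -> float:
    """KGED score: concat(X, Y) . w with X/Y from the two branches.

    Dropout applies to the concatenated feature vector, and only in training
    mode (pass ``training=True`` with an rng); requesting dropout at
    evaluation time is a contract violation.
    """
    if rng is not None and not training:
        raise ScoringModeError("dropout rng supplied outside training mode")
    A, B = build_input_matrices(
        triple, entities, relations, entity_descriptions, relation_descriptions
    )
    x = kged_feature_maps(A, conv_params.theta1, conv_params.b1, config.activation)
    y = kged_feature_maps(B, conv_params.theta2, conv_params.b2, config.activation)
    if conv_params.w.shape[0] != x.shape[0] + y.shape[0]:
        raise ValueError(
            f"w has length {conv_params.w.shape[0]}, features have "
            f"{x.shape[0] + y.shape[0]}"
        )
    if training and config.dropout_rate > 0.0:
        if rng is None:
            raise ScoringModeError("training-mode dropout requires an rng")
        keep = 1.0 - config.dropout_rate
        z = np.concatenate([x, y])
        z = z * (rng.random(z.shape) < keep) / keep
        return float(z @ conv_params.w)
    # per-branch partial dots: with a zeroed description branch this is
    # bit-identical to the triple-branch-only (ConvKB) score
    dx = x.shape[0]
    return float(x @ conv_params.w[:dx] + y @ conv_params.w[dx:])


def kged_loss(
    scores: np.ndarray,
    labels: np.ndarray,
    w: np.ndarray,
    l2_lambda: float,
) -> float:
    """Softplus ranking loss: sum log(1 + exp(label * score)) + (lambda/2)||w||^2.

    Labels must be +1 or -1.  With the printed orientation (+1 for facts) the
    minimum pushes fact scores negative; the training loop therefore feeds
    facts with label -1 so that public scores are higher = more plausible.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=float)
    if scores.shape != labels.shape:
        raise ValueError("one label per score required")
    if not np.all(np.isin(labels, (-1.0, 1.0))):
        raise ValueError("labels must be +1 or -1")
    return float(
        np.logaddexp(0.0, labels * scores).sum()
        + 0.5 * l2_lambda * float(w @ w)
    )


# ---------------------------------------------------------------------------
# negative sampling


def corrupt_triples(
    triple: Triple,
    kg: KnowledgeGraph,
    count: int,
    side_policy: str = "both",
    seed: int | np.random.Generator = 0,
) -> list[Triple]:
    """Sample ``count`` type-respecting corruptions of one triple.

    Exactly one slot (head or tail) is replaced per corruption with another
    entity of that slot's type; corruptions that are themselves known facts
    anywhere in the KG are rejected and resampled.  Deterministic given the
    seed.  ``side_policy`` is 'head', 'tail', or 'both' (equal probability).
    """
    if count < 1:
        raise ValueError("count must be >= 1")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    rel = kg.relations[triple.relation]
    sides = {"head": ("head",), "tail": ("tail",), "both": ("head", "tail")}[
        side_policy
    ]
    valid: list[Triple] = []
    for side in sides:
        etype = rel.head_type if side == "head" else rel.tail_type
        keep = triple.head if side == "head" else triple.tail
        for cand in kg.entities_by_type[etype]:
            if cand == keep:
                continue
            c = (
                Triple(cand, triple.relation, triple.tail)
                if side == "head"
                else Triple(triple.head, triple.relation, cand)
            )
            if c not in kg:
                valid.append(c)
    if not valid:
        raise ValueError(f"no valid corruption exists for {triple}")
    idx = rng.integers(0, len(valid), size=count)
    return [valid[i] for i in idx]


def _sample_negatives_batch(
    triples: Sequence[Triple],
    kg: KnowledgeGraph,
    neg_per_pos: int,
    rng: np.random.Generator,
) -> list[Triple]:
    """Fast rejection sampler used inside training loops (one draw at a time,
    falling back to exhaustive enumeration only on repeated rejection)."""
    negatives: list[Triple] = []
    for t in triples:
        rel = kg.relations[t.relation]
        for _ in range(neg_per_pos):
            for attempt in range(50):
                side = "head" if rng.random() < 0.5 else "tail"
                etype = rel.head_type if side == "head" else rel.tail_type
                pool = kg.entities_by_type[etype]
                cand = pool[int(rng.integers(0, len(pool)))]
                c = (
                    Triple(cand, t.relation, t.tail)
                    if side == "head"
                    else Triple(t.head, t.relation, cand)
                )
                if c not in kg and (c.head != c.tail or t.head == t.tail):
                    negatives.append(c)
                    break
            else:
                negatives.extend(corrupt_triples(t, kg, 1, "both", rng))
    return negatives


# ---------------------------------------------------------------------------
# TransE training


class TransEModel:
    """Trained translation embeddings with the public higher-is-plausible
    scoring convention (score = -energy)."""

    def __init__(
        self, config: ModelConfig, entities: EmbeddingTable, relations: EmbeddingTable
    ):
        self.config = config
        self.entities = entities
        self.relations = relations

    def energy(self, triple: Triple) -> float:
        return transe_energy(
            self.entities[triple.head],
            self.relations[triple.relation],
            self.entities[triple.tail],
            self.config.norm,
        )

    def score_batch(
        self, heads: Sequence[str], relation: str, tails: Sequence[str]
    ) -> np.ndarray:
        H = self.entities.rows(heads)
        T = self.entities.rows(tails)
        r = self.relations[relation]
        d = H + r[None, :] - T
        if self.config.norm == "L1":
            e = np.abs(d).sum(axis=1)
        else:
            e = np.sqrt((d * d).sum(axis=1))
        return -e

    def score(self, triple: Triple) -> float:
        return -self.energy(triple)

    def save(self, path) -> None:
        meta = {
            "config": asdict(self.config),
            "entity_ids": list(self.entities.ids),
            "relation_ids": list(self.relations.ids),
        }
        np.savez_compressed(
            Path(path),
            entity_vectors=self.entities.vectors,
            relation_vectors=self.relations.vectors,
            meta_json=np.frombuffer(json.dumps(meta).encode("utf-8"), dtype=np.uint8),
        )

    @classmethod
    def load(cls, path) -> "TransEModel":
        with np.load(Path(path)) as data:
            meta = json.loads(bytes(data["meta_json"]).decode("utf-8"))
            cfg = meta["config"]
            cfg["filter_sizes"] = tuple(cfg["filter_sizes"])
            return cls(
                ModelConfig(**cfg),
                EmbeddingTable(meta["entity_ids"], data["entity_vectors"]),
                EmbeddingTable(meta["relation_ids"], data["relation_vectors"]),
            )


def train_transe(
    kg: KnowledgeGraph, split: TripleSplit, config: ModelConfig
) -> TransEModel:
    """Margin-based ranking SGD over (fact, corruption) pairs.

    Entity vectors are renormalized to unit L2 at the start of every epoch;
    relation vectors are normalized once at initialization.  Deterministic
    given ``config.seed``.
    """
    train = sorted(split.train)
    if not train:
        raise ValueError("empty training set")
    rng = np.random.default_rng(config.seed)
    k = config.k
    bound = 6.0 / np.sqrt(k)
    ent_ids = kg.entity_ids
    rel_ids = kg.relation_ids
    E = rng.uniform(-bound, bound, size=(len(ent_ids), k))
    R = rng.uniform(-bound, bound, size=(len(rel_ids), k))
    R /= np.linalg.norm(R, axis=1, keepdims=True)
    ent_index = {e: i for i, e in enumerate(ent_ids)}
    rel_index = {r: i for i, r in enumerate(rel_ids)}

    lr = config.transe_learning_rate
    for _epoch in range(config.transe_epochs):
        E /= np.maximum(np.linalg.norm(E, axis=1, keepdims=True), 1e-12)
        order = rng.permutation(len(train))
        for start in range(0, len(train), config.transe_batch_size):
            batch = [train[i] for i in order[start : start + config.transe_batch_size]]
            negs = _sample_negatives_batch(batch, kg, 1, rng)
            hp = np.array([ent_index[t.head] for t in batch])
            tp = np.array([ent_index[t.tail] for t in batch])
            rr = np.array([rel_index[t.relation] for t in batch])
            hn = np.array([ent_index[t.head] for t in negs])
            tn = np.array([ent_index[t.tail] for t in negs])
            dp = E[hp] + R[rr] - E[tp]
            dn = E[hn] + R[rr] - E[tn]
            if config.norm == "L1":
                ep, en = np.abs(dp).sum(1), np.abs(dn).sum(1)
                gp, gn = np.sign(dp), np.sign(dn)
            else:
                ep = np.sqrt((dp * dp).sum(1))
                en = np.sqrt((dn * dn).sum(1))
                gp = dp / np.maximum(ep, 1e-12)[:, None]
                gn = dn / np.maximum(en, 1e-12)[:, None]
            active = (config.margin + ep - en) > 0
            if not active.any():
                continue
            gp = gp[active] * lr
            gn = gn[active] * lr
            np.add.at(E, hp[active], -gp)
            np.add.at(E, tp[active], gp)
            np.add.at(E, hn[active], gn)
            np.add.at(E, tn[active], -gn)
            np.add.at(R, rr[active], -(gp - gn))
    return TransEModel(
        config, EmbeddingTable(ent_ids, E), EmbeddingTable(rel_ids, R)
    )


# ---------------------------------------------------------------------------
# batched convolutional forward/backward


def _forward_branch(
    M: np.ndarray,
    theta: Mapping[int, np.ndarray],
    b: Mapping[int, np.ndarray],
    activation: str,
) -> tuple[np.ndarray, dict]:
    """Batched feature maps for a (batch, height, 3) stack of matrices."""
    g = _activation(activation)
    cache: dict = {"windows": {}, "pre": {}}
    parts = []
    for n in sorted(theta):
        win = sliding_window_view(M, (n, 3), axis=(1, 2))
        win = win.reshape(M.shape[0], M.shape[1] - n + 1, n, 3)
        pre = np.einsum("bpnc,dnc->bdp", win, theta[n]) + b[n][None, :, None]
        cache["windows"][n] = win
        cache["pre"][n] = pre
        parts.append(g(pre).reshape(M.shape[0], -1))
    return np.concatenate(parts, axis=1), cache


def _backward_branch(
    dF: np.ndarray,
    cache: dict,
    theta: Mapping[int, np.ndarray],
    activation: str,
    height: int,
    need_input_grad: bool,
) -> tuple[dict, dict, np.ndarray | None]:
    """Gradients of a branch w.r.t. its filters, biases, and (optionally) its
    input matrices.  ``dF`` is the gradient on the branch's concatenated
    feature block, shape (batch, branch_length)."""
    if activation != "relu":
        raise NotImplementedError("training supports the ReLU activation")
    B = dF.shape[0]
    d_theta: dict[int, np.ndarray] = {}
    d_b: dict[int, np.ndarray] = {}
    dM = np.zeros((B, height, 3)) if need_input_grad else None
    offset = 0
    for n in sorted(theta):
        delta = theta[n].shape[0]
        pos = height - n + 1
        block = dF[:, offset : offset + delta * pos].reshape(B, delta, pos)
        offset += delta * pos
        dpre = block * (cache["pre"][n] > 0)
        d_theta[n] = np.einsum("bdp,bpnc->dnc", dpre, cache["windows"][n])
        d_b[n] = dpre.sum(axis=(0, 2))
        if need_input_grad:
            dwin = np.einsum("bdp,dnc->bpnc", dpre, theta[n])
            for i in range(pos):
                dM[:, i : i + n, :] += dwin[:, i]
    return d_theta, d_b, dM


class _Adam:
    """Plain Adam over a named collection of arrays."""

    def __init__(self, lr: float, beta1: float = 0.9, beta2: float = 0.999,
                 eps: float = 1e-8):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m: dict[str, np.ndarray] = {}
        self.v: dict[str, np.ndarray] = {}
        self.t: dict[str, int] = {}

    def step(self, name: str, param: np.ndarray, grad: np.ndarray) -> None:
        if name not in self.m:
            self.m[name] = np.zeros_like(param)
            self.v[name] = np.zeros_like(param)
            self.t[name] = 0
        self.t[name] += 1
        t = self.t[name]
        self.m[name] = self.beta1 * self.m[name] + (1 - self.beta1) * grad
        self.v[name] = self.beta2 * self.v[name] + (1 - self.beta2) * grad * grad
        mhat = self.m[name] / (1 - self.beta1**t)
        vhat = self.v[name] / (1 - self.beta2**t)
        param -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


# ---------------------------------------------------------------------------
# the KGED model object


class KGEDModel:
    """Trained (or initialized) convolutional scoring model.

    ``entity_descriptions``/``relation_descriptions`` are None for the
    plain-ConvKB variant.  ``score``/``score_batch`` are evaluation-mode
    (no dropout); higher = more plausible.
    """

    def __init__(
        self,
        config: ModelConfig,
        entities: EmbeddingTable,
        relations: EmbeddingTable,
        conv_params: ConvParams,
        entity_descriptions: EmbeddingTable | None = None,
        relation_descriptions: EmbeddingTable | None = None,
        loss_history: list[float] | None = None,
    ):
        self.config = config
        self.entities = entities
        self.relations = relations
        self.conv_params = conv_params
        self.entity_descriptions = entity_descriptions
        self.relation_descriptions = relation_descriptions
        self.loss_history = loss_history or []

    @property
    def uses_descriptions(self) -> bool:
        return self.conv_params.with_descriptions

    def _stack(
        self, heads: Sequence[str], relation: str, tails: Sequence[str],
        table: EmbeddingTable, rel_table: EmbeddingTable,
    ) -> np.ndarray:
        H = table.rows(heads)
        T = table.rows(tails)
        r = np.broadcast_to(rel_table[relation], H.shape)
        return np.stack([H, r, T], axis=2)

    def score_batch(
        self, heads: Sequence[str], relation: str, tails: Sequence[str]
    ) -> np.ndarray:
        A = self._stack(heads, relation, tails, self.entities, self.relations)
        X, _ = _forward_branch(
            A, self.conv_params.theta1, self.conv_params.b1, self.config.activation
        )
        dx = X.shape[1]
        scores = X @ self.conv_params.w[:dx]
        if self.uses_descriptions:
            B = self._stack(
                heads, relation, tails,
                self.entity_descriptions, self.relation_descriptions,
            )
            Y, _ = _forward_branch(
                B, self.conv_params.theta2, self.conv_params.b2,
                self.config.activation,
            )
            scores = scores + Y @ self.conv_params.w[dx:]
        return scores

    def score(self, triple: Triple) -> float:
        return float(
            self.score_batch([triple.head], triple.relation, [triple.tail])[0]
        )

    # -- checkpointing ------------------------------------------------------

    def save(self, path) -> None:
        arrays: dict[str, np.ndarray] = {
            "entity_vectors": self.entities.vectors,
            "relation_vectors": self.relations.vectors,
            "w": self.conv_params.w,
        }
        for n, v in self.conv_params.theta1.items():
            arrays[f"theta1_{n}"] = v
            arrays[f"b1_{n}"] = self.conv_params.b1[n]
        if self.uses_descriptions:
            arrays["entity_desc_vectors"] = self.entity_descriptions.vectors
            arrays["relation_desc_vectors"] = self.relation_descriptions.vectors
            for n, v in self.conv_params.theta2.items():
                arrays[f"theta2_{n}"] = v
                arrays[f"b2_{n}"] = self.conv_params.b2[n]
        meta = {
            "config": asdict(self.config),
            "entity_ids": list(self.entities.ids),
            "relation_ids": list(self.relations.ids),
            "uses_descriptions": self.uses_descriptions,
            "loss_history": self.loss_history,
        }
        arrays["meta_json"] = np.frombuffer(
            json.dumps(meta).encode("utf-8"), dtype=np.uint8
        )
        np.savez_compressed(Path(path), **arrays)

    @classmethod
    def load(cls, path) -> "KGEDModel":
        with np.load(Path(path)) as data:
            meta = json.loads(bytes(data["meta_json"]).decode("utf-8"))
            cfg = meta["config"]
            cfg["filter_sizes"] = tuple(cfg["filter_sizes"])
            config = ModelConfig(**cfg)
            ents = EmbeddingTable(meta["entity_ids"], data["entity_vectors"])
            rels = EmbeddingTable(meta["relation_ids"], data["relation_vectors"])
            theta1 = {n: data[f"theta1_{n}"] for n in config.filter_sizes}
            b1 = {n: data[f"b1_{n}"] for n in config.filter_sizes}
            theta2 = b2 = None
            ent_desc = rel_desc = None
            if meta["uses_descriptions"]:
                theta2 = {n: data[f"theta2_{n}"] for n in config.filter_sizes}
                b2 = {n: data[f"b2_{n}"] for n in config.filter_sizes}
                ent_desc = EmbeddingTable(
                    meta["entity_ids"], data["entity_desc_vectors"]
                )
                rel_desc = EmbeddingTable(
                    meta["relation_ids"], data["relation_desc_vectors"]
                )
            params = ConvParams(theta1, b1, theta2, b2, data["w"])
        return cls(
            config, ents, rels, params, ent_desc, rel_desc,
            loss_history=meta["loss_history"],
        )


# ---------------------------------------------------------------------------
# initialization and training


def initialize_kged(
    kg: KnowledgeGraph,
    descriptions: Mapping[str, tuple[str, str]],
    encoder: TextEncoder,
    config: ModelConfig,
    split: TripleSplit | None = None,
) -> KGEDModel:
    """Build the initial KGED state.

    Entity/relation vectors come from a TransE pre-training run
    (``config.transe_epochs``; 0 returns TransE's own random initialization);
    description vectors come from the encoder applied to each entity's
    description text (falling back to its canonical name when no description
    is on file, logged) and to the relation description sentences.
    """
    if encoder.dim != config.l:
        raise ValueError(
            f"encoder dimension {encoder.dim} != configured l={config.l}"
        )
    if split is None:
        split = TripleSplit(frozenset(kg.triples), frozenset(), frozenset(), config.seed)
    transe = train_transe(kg, split, config)

    ent_rows = []
    n_fallback = 0
    for eid in transe.entities.ids:
        if eid in descriptions:
            _name, text = descriptions[eid]
        else:
            rec = kg.entities[eid]
            if not rec.canonical_name:
                raise ValueError(f"entity {eid!r} has no description and no name")
            text = rec.canonical_name
            n_fallback += 1
        ent_rows.append(encoder.encode(text))
    if n_fallback:
        logger.info("encoded canonical names for %d description-less entities",
                    n_fallback)
    ent_desc = EmbeddingTable(transe.entities.ids, np.array(ent_rows))
    rel_desc = EmbeddingTable(
        transe.relations.ids,
        np.array(
            [
                encoder.encode(kg.relations[rid].description_text)
                for rid in transe.relations.ids
            ]
        ),
    )
    rng = np.random.default_rng(config.seed + 1)
    params = ConvParams.init(config, rng, with_descriptions=True)
    return KGEDModel(config, transe.entities, transe.relations, params,
                     ent_desc, rel_desc)


def initialize_convkb(
    kg: KnowledgeGraph, config: ModelConfig, split: TripleSplit | None = None
) -> KGEDModel:
    """ConvKB initial state: TransE-pretrained embeddings, no description branch."""
    if split is None:
        split = TripleSplit(frozenset(kg.triples), frozenset(), frozenset(), config.seed)
    transe = train_transe(kg, split, config)
    rng = np.random.default_rng(config.seed + 1)
    params = ConvParams.init(config, rng, with_descriptions=False)
    return KGEDModel(config, transe.entities, transe.relations, params)


def _train_conv_model(
    model: KGEDModel, kg: KnowledgeGraph, split: TripleSplit, config: ModelConfig
) -> KGEDModel:
    train = sorted(split.train)
    if not train:
        raise ValueError("empty training set")
    rng = np.random.default_rng(config.seed + 2)
    opt = _Adam(config.learning_rate)
    ent = model.entities
    rel = model.relations
    params = model.conv_params
    use_desc = model.uses_descriptions
    keep = 1.0 - config.dropout_rate
    dx = config.feature_length(config.k)
    frozen_desc_snapshot = (
        model.entity_descriptions.vectors.copy() if use_desc else None
    )

    for epoch in range(config.epochs):
        order = rng.permutation(len(train))
        epoch_losses = []
        for start in range(0, len(train), config.batch_size):
            pos = [train[i] for i in order[start : start + config.batch_size]]
            neg = _sample_negatives_batch(pos, kg, config.neg_per_pos, rng)
            batch = pos + neg
            # facts get the internal label -1: minimizing softplus(l * f)
            # then drives fact scores up (public: higher = plausible)
            labels = np.concatenate(
                [-np.ones(len(pos)), np.ones(len(neg))]
            )
            h_idx = np.array([ent.index[t.head] for t in batch])
            t_idx = np.array([ent.index[t.tail] for t in batch])
            r_idx = np.array([rel.index[t.relation] for t in batch])
            A = np.stack(
                [ent.vectors[h_idx], rel.vectors[r_idx], ent.vectors[t_idx]], axis=2
            )
            X, cache_x = _forward_branch(A, params.theta1, params.b1,
                                         config.activation)
            if use_desc:
                ed = model.entity_descriptions.vectors
                rd = model.relation_descriptions.vectors
                Bm = np.stack([ed[h_idx], rd[r_idx], ed[t_idx]], axis=2)
                Y, cache_y = _forward_branch(Bm, params.theta2, params.b2,
                                             config.activation)
                Z = np.concatenate([X, Y], axis=1)
            else:
                Z = X
            if config.dropout_rate > 0.0:
                mask = (rng.random(Z.shape) < keep) / keep
            else:
                mask = np.ones_like(Z)
            Zd = Z * mask
            scores = Zd @ params.w
            m = len(batch)
            loss = (
                np.logaddexp(0.0, labels * scores).sum() / m
                + 0.5 * config.l2_lambda * float(params.w @ params.w)
            )
            if not np.isfinite(loss):
                raise TrainingDivergenceError(
                    f"non-finite loss at epoch {epoch}"
                )
            epoch_losses.append(loss)

            ds = labels / (1.0 + np.exp(-labels * scores)) / m
            dw = Zd.T @ ds + config.l2_lambda * params.w
            dZ = ds[:, None] * params.w[None, :] * mask
            d_theta1, d_b1, dA = _backward_branch(
                dZ[:, :dx], cache_x, params.theta1, config.activation,
                config.k, config.train_entity_embeddings,
            )
            for n in config.filter_sizes:
                opt.step(f"theta1_{n}", params.theta1[n], d_theta1[n])
                opt.step(f"b1_{n}", params.b1[n], d_b1[n])
            if use_desc:
                d_theta2, d_b2, dB = _backward_branch(
                    dZ[:, dx:], cache_y, params.theta2, config.activation,
                    config.l, not config.freeze_descriptions,
                )
                for n in config.filter_sizes:
                    opt.step(f"theta2_{n}", params.theta2[n], d_theta2[n])
                    opt.step(f"b2_{n}", params.b2[n], d_b2[n])
                if dB is not None:
                    ge = np.zeros_like(model.entity_descriptions.vectors)
                    gr = np.zeros_like(model.relation_descriptions.vectors)
                    np.add.at(ge, h_idx, dB[:, :, 0])
                    np.add.at(gr, r_idx, dB[:, :, 1])
                    np.add.at(ge, t_idx, dB[:, :, 2])
                    opt.step("ent_desc", model.entity_descriptions.vectors, ge)
                    opt.step("rel_desc", model.relation_descriptions.vectors, gr)
            opt.step("w", params.w, dw)
            if config.train_entity_embeddings and dA is not None:
                gE = np.zeros_like(ent.vectors)
                gR = np.zeros_like(rel.vectors)
                np.add.at(gE, h_idx, dA[:, :, 0])
                np.add.at(gR, r_idx, dA[:, :, 1])
                np.add.at(gE, t_idx, dA[:, :, 2])
                opt.step("entities", ent.vectors, gE)
                opt.step("relations", rel.vectors, gR)
        model.loss_history.append(float(np.mean(epoch_losses)))

    if use_desc and config.freeze_descriptions:
        assert np.array_equal(
            frozen_desc_snapshot, model.entity_descriptions.vectors
        ), "frozen description embeddings were mutated"
    return model


def train_kged(
    kg: KnowledgeGraph,
    split: TripleSplit,
    descriptions: Mapping[str, tuple[str, str]],
    encoder: TextEncoder,
    config: ModelConfig,
) -> KGEDModel:
    """Initialize and train KGED with minibatch Adam (see module docstring)."""
    model = initialize_kged(kg, descriptions, encoder, config, split)
    return _train_conv_model(model, kg, split, config)


def train_convkb(
    kg: KnowledgeGraph, split: TripleSplit, config: ModelConfig
) -> KGEDModel:
    """Train the description-free ConvKB baseline."""
    model = initialize_convkb(kg, config, split)
    return _train_conv_model(model, kg, split, config)


# ---------------------------------------------------------------------------
# diagnostics


def cosine_distance_profile(
    embeddings: EmbeddingTable,
    triples: Iterable[Triple],
    window_n: int,
) -> np.ndarray:
    """Histogram of head-tail cosine distances over sliding sub-windows.

    For each triple, a window of ``window_n`` rows slides over the head and
    tail vectors in parallel; cosine distance (1 - cosine similarity,
    clipped to [0, 1]) is computed per aligned window pair and binned into
    10 equal bins on [0, 1] (distance 1 falls in the top bin).
    ``window_n == k`` degenerates to whole-vector comparison.  Zero-norm
    windows are skipped with a logged count.  Returns normalized frequencies.
    """
    k = embeddings.dim
    if window_n > k or window_n < 1:
        raise ValueError("window_n must lie in [1, embedding dimension]")
    counts = np.zeros(10)
    skipped = 0
    for t in triples:
        h = embeddings[t.head]
        tt = embeddings[t.tail]
        for i in range(k - window_n + 1):
            a = h[i : i + window_n]
            b = tt[i : i + window_n]
            na, nb = np.linalg.norm(a), np.linalg.norm(b)
            if na == 0.0 or nb == 0.0:
                skipped += 1
                continue
            d = np.clip(1.0 - float(a @ b) / (na * nb), 0.0, 1.0)
            counts[min(int(d * 10), 9)] += 1
    if skipped:
        logger.info("cosine_distance_profile: skipped %d zero-norm windows", skipped)
    total = counts.sum()
    return counts / total if total else counts
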