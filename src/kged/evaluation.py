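"""Filtered link-prediction evaluation: mean rank, Hits@10, comparisons.

For each test triple the head (then the tail) is replaced by every candidate
entity of the slot's type; candidates that are themselves known facts are
removed ("filtered" setting), the remaining corruptions plus the true triple
are scored, and the true entity's rank is recorded.  Mean rank (MR) averages
ranks over test triples (lower better); Hits@10 is the percentage of test
triples whose true entity ranks in the top 10.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from ._util import round_half_up
from .kg import KnowledgeGraph, Triple

logger = logging.getLogger(__name__)

MR_METRICS = ("mr_head", "mr_tail", "mr_both")
HITS_METRICS = ("hits_head", "hits_tail", "hits_both")


@dataclass(frozen=True)
class RankRecord:
    triple: Triple
    head_rank: float
    tail_rank: float
    head_candidates: int
    tail_candidates: int
    filtered: bool

    def __post_init__(self) -> None:
        if not (1 <= self.head_rank <= self.head_candidates):
            raise ValueError("head rank outside [1, candidate count]")
        if not (1 <= self.tail_rank <= self.tail_candidates):
            raise ValueError("tail rank outside [1, candidate count]")


@dataclass
class EvalReport:
    """Per-relation MR rows plus overall ('ALL') aggregates and Hits@10.

    The ALL mean rank is the unweighted mean of the per-relation mean ranks;
    Hits@10 is computed over the pooled test triples.  ``top_pct`` columns
    convert mean ranks to a percentage of the slot's candidate pool.
    """

    rows: dict[str, dict[str, float]]  # relation -> metric -> value
    hits_head: float
    hits_tail: float
    hits_both: float
    repeat: int = 0

    @property
    def all_row(self) -> dict[str, float]:
        rels = sorted(self.rows)
        return {
            m: float(np.mean([self.rows[r][m] for r in rels])) for m in MR_METRICS
        }

    def cells(self) -> dict[tuple[str, str], float]:
        """Flat (row, metric) -> value view used for comparisons."""
        out: dict[tuple[str, str], float] = {}
        for rel, metrics in self.rows.items():
            for m in MR_METRICS:
                out[(rel, m)] = metrics[m]
        for m, v in zip(MR_METRICS, [self.all_row[m] for m in MR_METRICS]):
            out[("ALL", m)] = v
        out[("ALL", "hits_head")] = self.hits_head
        out[("ALL", "hits_tail")] = self.hits_tail
        out[("ALL", "hits_both")] = self.hits_both
        return out

    def to_frame(self) -> pd.DataFrame:
        recs = []
        for rel in sorted(self.rows):
            recs.append({"relation": rel, **self.rows[rel]})
        all_row = {"relation": "ALL", **self.all_row}
        all_row.update(
            hits_head=self.hits_head, hits_tail=self.hits_tail,
            hits_both=self.hits_both,
        )
        recs.append(all_row)
        return pd.DataFrame(recs)

    def to_tsv(self) -> str:
        return self.to_frame().to_csv(sep="\t", index=False, float_format="%.2f")


def candidate_entities(
    slot: str, relation: str, kg: KnowledgeGraph, mode: str = "typed"
) -> list[str]:
    """All candidate entities for a slot of a relation.

    ``typed`` restricts to entities of the slot's signature type (the
    protocol used here: a chemical head is replaced only by chemicals);
    ``all`` returns every entity.  The true entity is *not* excluded here.
    """
    if relation not in kg.relations:
        raise KeyError(f"unknown relation {relation!r}")
    if slot not in ("head", "tail"):
        raise ValueError("slot must be 'head' or 'tail'")
    if mode == "all":
        return kg.entity_ids
    if mode != "typed":
        raise ValueError("mode must be 'typed' or 'all'")
    rel = kg.relations[relation]
    etype = rel.head_type if slot == "head" else rel.tail_type
    return list(kg.entities_by_type[etype])


def _slot_rank(
    model,
    triple: Triple,
    kg: KnowledgeGraph,
    slot: str,
    mode: str,
    tie_policy: str,
    filter_set: set[Triple] | frozenset[Triple] | None,
) -> tuple[float, int]:
    true_ent = triple.head if slot == "head" else triple.tail
    pool = candidate_entities(slot, triple.relation, kg, mode)
    corruptions = []
    for cand in pool:
        if cand == true_ent:
            continue
        c = (
            Triple(cand, triple.relation, triple.tail)
            if slot == "head"
            else Triple(triple.head, triple.relation, cand)
        )
        if filter_set is not None and c in filter_set:
            continue
        corruptions.append(cand)
    if slot == "head":
        scores = model.score_batch(
            corruptions + [true_ent], triple.relation, [triple.tail] * (len(corruptions) + 1)
        )
    else:
        scores = model.score_batch(
            [triple.head] * (len(corruptions) + 1), triple.relation,
            corruptions + [true_ent],
        )
    true_score = scores[-1]
    cand_scores = scores[:-1]
    n_greater = int(np.sum(cand_scores > true_score))
    n_ties = int(np.sum(cand_scores == true_score))
    if tie_policy == "mid":
        rank = 1.0 + n_greater + n_ties / 2.0
    elif tie_policy == "optimistic":
        rank = 1.0 + n_greater
    elif tie_policy == "pessimistic":
        rank = 1.0 + n_greater + n_ties
    else:
        raise ValueError(f"unknown tie policy {tie_policy!r}")
    return rank, len(corruptions) + 1


def rank_triple(
    model,
    triple: Triple,
    kg: KnowledgeGraph,
    mode: str = "typed",
    tie_policy: str = "mid",
    filtered: bool = True,
    filter_set: Iterable[Triple] | None = None,
) -> RankRecord:
    """Filtered (or raw) rank of a triple's head and tail entities.

    ``model`` needs a ``score_batch(heads, relation, tails) -> array`` method
    with higher = more plausible.  The filter set defaults to every triple in
    the KG (train + valid + test).  Rank = 1 + number of strictly
    higher-scoring candidates, ties handled per ``tie_policy``
    (default mid-rank: each tie contributes one half).
    """
    fs: set[Triple] | frozenset[Triple] | None = None
    if filtered:
        fs = set(filter_set) if filter_set is not None else kg.triples
    head_rank, n_head = _slot_rank(model, triple, kg, "head", mode, tie_policy, fs)
    tail_rank, n_tail = _slot_rank(model, triple, kg, "tail", mode, tie_policy, fs)
    return RankRecord(
        triple=triple,
        head_rank=head_rank,
        tail_rank=tail_rank,
        head_candidates=n_head,
        tail_candidates=n_tail,
        filtered=filtered,
    )


def evaluate(
    model,
    test_triples: Iterable[Triple],
    kg: KnowledgeGraph,
    mode: str = "typed",
    tie_policy: str = "mid",
    filtered: bool = True,
    filter_set: Iterable[Triple] | None = None,
    repeat: int = 0,
) -> EvalReport:
    """Full filtered-ranking evaluation over a test set."""
    test = list(test_triples)
    if not test:
        raise ValueError("empty test set")
    fs = None
    if filtered:
        fs = set(filter_set) if filter_set is not None else set(kg.triples)
    by_rel: dict[str, list[RankRecord]] = {}
    for t in test:
        rec = rank_triple(model, t, kg, mode, tie_policy, filtered, fs)
        by_rel.setdefault(t.relation, []).append(rec)

    rows: dict[str, dict[str, float]] = {}
    for rel, recs in by_rel.items():
        mr_h = float(np.mean([r.head_rank for r in recs]))
        mr_t = float(np.mean([r.tail_rank for r in recs]))
        n_head_pool = len(candidate_entities("head", rel, kg, mode))
        n_tail_pool = len(candidate_entities("tail", rel, kg, mode))
        rows[rel] = {
            "mr_head": mr_h,
            "mr_tail": mr_t,
            "mr_both": (mr_h + mr_t) / 2.0,
            "top_pct_head": rank_to_top_percent(mr_h, n_head_pool),
            "top_pct_tail": rank_to_top_percent(mr_t, n_tail_pool),
        }
    for rel in kg.relation_ids:
        if rel not in rows and any(True for _ in kg.by_relation[rel]):
            logger.warning("relation %s has no test triples; omitted", rel)

    all_recs = [r for recs in by_rel.values() for r in recs]
    hits_h = 100.0 * np.mean([r.head_rank <= 10 for r in all_recs])
    hits_t = 100.0 * np.mean([r.tail_rank <= 10 for r in all_recs])
    return EvalReport(
        rows=rows,
        hits_head=float(hits_h),
        hits_tail=float(hits_t),
        hits_both=(float(hits_h) + float(hits_t)) / 2.0,
        repeat=repeat,
    )


def rank_to_top_percent(mean_rank: float, candidate_count: int) -> float:
    """Express a mean rank as the top percentage of its candidate pool.

    100 * mean_rank / candidate_count, rounded half-up to 2 decimals
    (e.g. a mean rank of 444.1 among 68,364 candidates is the top 0.65%).
    """
    if candidate_count < 1:
        raise ValueError("candidate_count must be >= 1")
    if mean_rank > candidate_count:
        raise ValueError("mean rank exceeds the candidate count")
    return round_half_up(100.0 * mean_rank / candidate_count, 2)


@dataclass
class ComparisonReport:
    """Cell-wise deltas of a candidate model against a baseline.

    For mean ranks (lower better): delta = baseline - candidate and
    relative = 100 * delta / baseline.  For Hits@10 (higher better):
    delta = candidate - baseline.  ``grades`` (when built from repeated
    experiments) map win counts to '-' (<=7 of 10), '*' (8), '**' (9),
    '***' (10).
    """

    delta: dict[tuple[str, str], float]
    relative: dict[tuple[str, str], float]
    wins: dict[tuple[str, str], int] = field(default_factory=dict)
    grades: dict[tuple[str, str], str] = field(default_factory=dict)


def compare_models(candidate: EvalReport, baseline: EvalReport) -> ComparisonReport:
    cc, bc = candidate.cells(), baseline.cells()
    if set(cc) != set(bc):
        raise ValueError("reports have mismatched rows")
    delta: dict[tuple[str, str], float] = {}
    relative: dict[tuple[str, str], float] = {}
    for cell in cc:
        _row, metric = cell
        if metric.startswith("mr"):
            delta[cell] = bc[cell] - cc[cell]
            relative[cell] = 100.0 * delta[cell] / bc[cell] if bc[cell] else 0.0
        else:
            delta[cell] = cc[cell] - bc[cell]
            relative[cell] = delta[cell]
    return ComparisonReport(delta=delta, relative=relative)


def _grade(wins: int, n: int) -> str:
    # thresholds fixed at the 10-repeat protocol: 8 -> *, 9 -> **, 10 -> ***
    if wins >= n:
        return "***"
    if wins == n - 1:
        return "**"
    if wins == n - 2:
        return "*"
    return "-"


def win_count(
    candidate_reports: Sequence[EvalReport],
    baseline_reports: Sequence[EvalReport],
) -> ComparisonReport:
    """Count per-cell wins over paired repeats and grade them.

    A win is a strictly lower MR (or strictly higher Hits@10) in the repeat
    paired by repeat index.
    """
    if len(candidate_reports) != len(baseline_reports):
        raise ValueError("unpaired repeats")
    cand = sorted(candidate_reports, key=lambda r: r.repeat)
    base = sorted(baseline_reports, key=lambda r: r.repeat)
    if [r.repeat for r in cand] != [r.repeat for r in base]:
        raise ValueError("repeat indices do not pair up")
    n = len(cand)
    wins: dict[tuple[str, str], int] = {}
    for c, b in zip(cand, base):
        cc, bc = c.cells(), b.cells()
        if set(cc) != set(bc):
            raise ValueError("reports have mismatched rows")
        for cell in cc:
            _row, metric = cell
            better = cc[cell] < bc[cell] if metric.startswith("mr") else cc[cell] > bc[cell]
            wins[cell] = wins.get(cell, 0) + int(better)
    report = ComparisonReport(delta={}, relative={}, wins=wins)
    report.grades = {cell: _grade(w, n) for cell, w in wins.items()}
    return report
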