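"""Typed biomedical knowledge-graph data model and file I/O.

A knowledge base is a set of triples (head entity, relation, tail entity)
over four entity types -- chemical, gene, disease, symptom -- with each
relation carrying a fixed type signature (e.g. the disease-gene relation
links a disease head to a gene tail).  Entities carry type-prefixed
identifiers such as ``/d/13364`` or ``/g/28644``; a separate description
file maps identifiers to names and free-text descriptions.

All on-disk formats are UTF-8, tab-separated and headerless:

* triple files: ``head_id<TAB>relation_id<TAB>tail_id``
* description files: ``entity_id<TAB>name<TAB>description text``
* dictionary files: ``canonical name<TAB>entity_id<TAB>syn1|syn2<TAB>id1|id2``
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np

from ._util import round_half_up

logger = logging.getLogger(__name__)

ENTITY_TYPES = ("chemical", "gene", "disease", "symptom")

TYPE_PREFIX = {"chemical": "c", "gene": "g", "disease": "d", "symptom": "s"}
PREFIX_TYPE = {v: k for k, v in TYPE_PREFIX.items()}

_ID_RE = re.compile(r"^/([cgds])/(\d+)$")

#: The five canonical relations with their type signatures and the fixed
#: one-sentence descriptions used to embed each relation's meaning.
RELATION_SIGNATURES: dict[str, tuple[str, str]] = {
    "c_relate_g": ("chemical", "gene"),
    "c_relate_d": ("chemical", "disease"),
    "d_relate_g": ("disease", "gene"),
    "g_relate_g": ("gene", "gene"),
    "d_have_s": ("disease", "symptom"),
}

RELATION_DESCRIPTIONS: dict[str, str] = {
    "c_relate_g": "a chemical is related to a gene",
    "c_relate_d": "a chemical is related to a disease",
    "d_relate_g": "a disease is related to a gene",
    "g_relate_g": "a gene is related to a gene",
    "d_have_s": "a disease contains a symptom",
}


class ParseError(ValueError):
    """A malformed line in a tab-separated input file."""

    def __init__(self, message: str, line_number: int | None = None):
        super().__init__(message)
        self.line_number = line_number


class ValidationError(ValueError):
    """A record violating a structural invariant (ID scheme, type signature)."""


class NormalizationError(ValueError):
    """Strict name normalization met names absent from the dictionary."""

    def __init__(self, unresolved: Sequence[str]):
        super().__init__(
            "unresolved names in strict mode: " + ", ".join(sorted(unresolved))
        )
        self.unresolved = tuple(unresolved)


class Triple(NamedTuple):
    head: str
    relation: str
    tail: str


def entity_type_of(entity_id: str) -> str:
    """Return the entity type encoded in a type-prefixed identifier."""
    m = _ID_RE.match(entity_id)
    if not m:
        raise ValidationError(f"malformed entity id: {entity_id!r}")
    return PREFIX_TYPE[m.group(1)]


@dataclass(frozen=True)
class EntityRecord:
    entity_id: str
    entity_type: str
    canonical_name: str
    synonyms: frozenset[str] = frozenset()
    concept_ids: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.entity_type not in ENTITY_TYPES:
            raise ValidationError(f"unknown entity type: {self.entity_type!r}")
        if entity_type_of(self.entity_id) != self.entity_type:
            raise ValidationError(
                f"id {self.entity_id!r} does not agree with type {self.entity_type!r}"
            )
        if not self.canonical_name:
            raise ValidationError(f"entity {self.entity_id!r} has an empty name")


@dataclass(frozen=True)
class RelationRecord:
    relation_id: str
    head_type: str
    tail_type: str
    description_text: str = ""

    def __post_init__(self) -> None:
        for t in (self.head_type, self.tail_type):
            if t not in ENTITY_TYPES:
                raise ValidationError(f"unknown entity type: {t!r}")
        if not self.description_text:
            # The five canonical relations default to their fixed sentences.
            text = RELATION_DESCRIPTIONS.get(self.relation_id, "")
            object.__setattr__(self, "description_text", text)


def default_relations() -> list[RelationRecord]:
    """The five canonical relations with their signatures and descriptions."""
    return [
        RelationRecord(rid, head, tail)
        for rid, (head, tail) in RELATION_SIGNATURES.items()
    ]


class KnowledgeGraph:
    """Deduplicated triple set with entity/relation tables and lookup indices.

    Membership queries (``triple in kg``) are O(1); per-relation and
    per-entity-type slices are precomputed.  Self-interactions (head == tail,
    as occur in protein-interaction data) are retained but flagged.
    """

    def __init__(
        self,
        entities: Iterable[EntityRecord],
        relations: Iterable[RelationRecord],
        triples: Iterable[Triple],
    ):
        self.entities: dict[str, EntityRecord] = {}
        for e in entities:
            if e.entity_id in self.entities:
                raise ValidationError(f"duplicate entity id {e.entity_id!r}")
            self.entities[e.entity_id] = e
        self.relations: dict[str, RelationRecord] = {}
        for r in relations:
            if r.relation_id in self.relations:
                raise ValidationError(f"duplicate relation id {r.relation_id!r}")
            self.relations[r.relation_id] = r

        self.triples: set[Triple] = set()
        self.by_relation: dict[str, list[Triple]] = {r: [] for r in self.relations}
        self.by_head_relation: dict[tuple[str, str], list[Triple]] = {}
        self.by_relation_tail: dict[tuple[str, str], list[Triple]] = {}
        self.self_loops: set[Triple] = set()
        n_dup = 0
        for t in triples:
            if t in self.triples:
                n_dup += 1
                continue
            self._validate_triple(t)
            self.triples.add(t)
            self.by_relation[t.relation].append(t)
            self.by_head_relation.setdefault((t.head, t.relation), []).append(t)
            self.by_relation_tail.setdefault((t.relation, t.tail), []).append(t)
            if t.head == t.tail:
                self.self_loops.add(t)
        if n_dup:
            logger.info("collapsed %d duplicate triples", n_dup)
        self.duplicates_collapsed = n_dup

        self.entities_by_type: dict[str, list[str]] = {t: [] for t in ENTITY_TYPES}
        for eid in sorted(self.entities):
            self.entities_by_type[self.entities[eid].entity_type].append(eid)

    def _validate_triple(self, t: Triple) -> None:
        if t.relation not in self.relations:
            raise ValidationError(f"triple {t} uses undeclared relation")
        for eid in (t.head, t.tail):
            if eid not in self.entities:
                raise ValidationError(f"triple {t} references unknown entity {eid!r}")
        rel = self.relations[t.relation]
        if self.entities[t.head].entity_type != rel.head_type:
            raise ValidationError(
                f"triple {t}: head type {self.entities[t.head].entity_type!r} "
                f"violates signature {rel.head_type!r}->{rel.tail_type!r}"
            )
        if self.entities[t.tail].entity_type != rel.tail_type:
            raise ValidationError(
                f"triple {t}: tail type {self.entities[t.tail].entity_type!r} "
                f"violates signature {rel.head_type!r}->{rel.tail_type!r}"
            )

    def __contains__(self, triple: Triple) -> bool:
        return triple in self.triples

    def __len__(self) -> int:
        return len(self.triples)

    @property
    def entity_ids(self) -> list[str]:
        return sorted(self.entities)

    @property
    def relation_ids(self) -> list[str]:
        return sorted(self.relations)


@dataclass(frozen=True)
class TripleSplit:
    train: frozenset[Triple]
    valid: frozenset[Triple]
    test: frozenset[Triple]
    seed: int

    def __post_init__(self) -> None:
        if (self.train & self.valid) or (self.train & self.test) or (
            self.valid & self.test
        ):
            raise ValidationError("split parts are not pairwise disjoint")

    @property
    def all(self) -> frozenset[Triple]:
        return self.train | self.valid | self.test


@dataclass
class DatasetStats:
    """Per-relation head/tail/triple counts plus totals and ATPE.

    ATPE (average triples per entity) = |triples| / |entities| is a proxy for
    the diversity/complexity of a knowledge base.
    """

    per_relation: dict[str, tuple[int, int, int]]  # (heads, tails, triples)
    total_entities: int
    total_triples: int

    @property
    def atpe(self) -> float:
        return self.total_triples / self.total_entities

    def to_tsv(self) -> str:
        lines = ["relation\theads\ttails\ttriples"]
        for rel in sorted(self.per_relation):
            h, t, n = self.per_relation[rel]
            lines.append(f"{rel}\t{h}\t{t}\t{n}")
        lines.append(f"TOTAL\t{self.total_entities} entities\t\t{self.total_triples}")
        lines.append(f"ATPE\t{round_half_up(self.atpe, 2):.2f}")
        return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# file I/O


def _data_lines(path: Path) -> Iterable[tuple[int, str]]:
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            yield lineno, line


def read_triples(path, *, return_duplicates: bool = False):
    """Read a headerless tab-separated triple file.

    Duplicate lines are collapsed (first occurrence kept, in input order) and
    their count logged.  With ``return_duplicates=True`` returns
    ``(triples, n_duplicates)``.
    """
    path = Path(path)
    seen: dict[Triple, None] = {}
    n_dup = 0
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if len(fields) != 3:
            raise ParseError(
                f"{path}:{lineno}: expected 3 tab-separated fields, got {len(fields)}",
                line_number=lineno,
            )
        t = Triple(*fields)
        if t in seen:
            n_dup += 1
        else:
            seen[t] = None
    if n_dup:
        logger.info("read_triples(%s): collapsed %d duplicate lines", path, n_dup)
    triples = list(seen)
    return (triples, n_dup) if return_duplicates else triples


def write_triples(triples: Iterable[Triple], path) -> None:
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        for t in triples:
            fh.write(f"{t.head}\t{t.relation}\t{t.tail}\n")


def read_descriptions(path) -> dict[str, tuple[str, str]]:
    """Read an ``id<TAB>name<TAB>description`` file into a mapping.

    Exact duplicate lines are idempotent; the same ID with conflicting text
    is an error (the file no longer identifies a single description).
    """
    path = Path(path)
    out: dict[str, tuple[str, str]] = {}
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if len(fields) != 3:
            raise ParseError(
                f"{path}:{lineno}: expected 3 tab-separated fields, got {len(fields)}",
                line_number=lineno,
            )
        eid, name, text = fields
        if eid in out and out[eid] != (name, text):
            raise ParseError(
                f"{path}:{lineno}: conflicting description for {eid!r}",
                line_number=lineno,
            )
        out[eid] = (name, text)
    return out


def write_descriptions(descriptions: Mapping[str, tuple[str, str]], path) -> None:
    with open(Path(path), "w", encoding="utf-8") as fh:
        for eid in sorted(descriptions):
            name, text = descriptions[eid]
            fh.write(f"{eid}\t{name}\t{text}\n")


# ---------------------------------------------------------------------------
# name normalization


@dataclass
class NameDictionary:
    """Case-insensitive mapping from names and synonyms to entity IDs.

    One dictionary per entity type (its *scope*), mirroring how curated
    disease and gene dictionaries are assembled from name + synonym +
    concept-identifier columns.
    """

    scope: str
    mapping: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.scope not in ENTITY_TYPES:
            raise ValidationError(f"unknown scope {self.scope!r}")
        for name, eid in self.mapping.items():
            if entity_type_of(eid) != self.scope:
                raise ValidationError(
                    f"dictionary entry {name!r} -> {eid!r} is not a {self.scope} id"
                )
        self.mapping = {k.lower(): v for k, v in self.mapping.items()}

    def lookup(self, name: str) -> str | None:
        return self.mapping.get(name.lower())

    def add(self, name: str, entity_id: str) -> None:
        if entity_type_of(entity_id) != self.scope:
            raise ValidationError(f"{entity_id!r} is not a {self.scope} id")
        self.mapping[name.lower()] = entity_id

    def mint_id(self) -> str:
        """Return a fresh id of the scope type, one past the largest in use."""
        prefix = TYPE_PREFIX[self.scope]
        used = [
            int(_ID_RE.match(v).group(2)) for v in self.mapping.values()
        ]
        nxt = max(used, default=0) + 1
        return f"/{prefix}/{nxt:05d}"

    @classmethod
    def from_entities(
        cls, entities: Iterable[EntityRecord], scope: str
    ) -> "NameDictionary":
        d = cls(scope)
        for e in entities:
            if e.entity_type != scope:
                continue
            d.add(e.canonical_name, e.entity_id)
            for s in e.synonyms:
                d.add(s, e.entity_id)
        return d

    @classmethod
    def read(cls, path, scope: str) -> "NameDictionary":
        """Read ``canonical<TAB>id<TAB>syn|syn<TAB>concept|concept`` lines."""
        d = cls(scope)
        for lineno, line in _data_lines(Path(path)):
            fields = line.split("\t")
            if len(fields) != 4:
                raise ParseError(
                    f"{path}:{lineno}: expected 4 tab-separated fields",
                    line_number=lineno,
                )
            canonical, eid, syns, _concepts = fields
            d.add(canonical, eid)
            for s in syns.split("|"):
                if s:
                    d.add(s, eid)
        return d


def normalize_names(
    raw_names: Sequence[str],
    dictionary: NameDictionary,
    strict: bool = False,
) -> dict[str, str]:
    """Resolve raw names to entity IDs through a dictionary.

    Lookup is case-insensitive over canonical names and synonyms.  Unresolved
    names raise in strict mode; otherwise a fresh id of the dictionary's
    scope type is minted (and added to the dictionary) so pipelines never
    silently drop records.
    """
    if not dictionary.mapping:
        raise NormalizationError(list(raw_names))
    out: dict[str, str] = {}
    unresolved: list[str] = []
    for name in raw_names:
        eid = dictionary.lookup(name)
        if eid is None:
            unresolved.append(name)
        else:
            out[name] = eid
    if unresolved:
        if strict:
            raise NormalizationError(unresolved)
        for name in unresolved:
            eid = dictionary.mint_id()
            dictionary.add(name, eid)
            out[name] = eid
            logger.info("minted %s for unresolved name %r", eid, name)
    return out


def assign_entity_ids(names_by_type: Mapping[str, Sequence[str]]) -> dict[str, str]:
    """Assign type-prefixed, zero-padded ids deterministically.

    Names are sorted within each type; ids are ``/<prefix>/<00001...>``.
    """
    out: dict[str, str] = {}
    for etype, names in names_by_type.items():
        prefix = TYPE_PREFIX[etype]
        for i, name in enumerate(sorted(set(names)), start=1):
            out[name] = f"/{prefix}/{i:05d}"
    return out


# ---------------------------------------------------------------------------
# graph construction, splitting, statistics


def build_graph(
    triples: Iterable[Triple],
    entities: Iterable[EntityRecord],
    relations: Iterable[RelationRecord],
) -> KnowledgeGraph:
    """Assemble and validate a KnowledgeGraph (see class docstring)."""
    return KnowledgeGraph(entities, relations, triples)


def split_triples(
    kg: KnowledgeGraph,
    n_test_per_relation: int,
    n_valid_per_relation: int,
    seed: int,
) -> TripleSplit:
    """Sample per-relation test/valid triples without replacement.

    Deterministic given ``seed``; the remainder of each relation's triples is
    the training set.
    """
    rng = np.random.default_rng(seed)
    test: set[Triple] = set()
    valid: set[Triple] = set()
    train: set[Triple] = set()
    n_held = n_test_per_relation + n_valid_per_relation
    for rel in kg.relation_ids:
        pool = sorted(kg.by_relation[rel])
        if not pool:
            continue  # declared relation with no triples: nothing to split
        if len(pool) <= n_held:
            raise ValidationError(
                f"relation {rel!r} has {len(pool)} triples, "
                f"not enough for {n_held} held out"
            )
        idx = rng.permutation(len(pool))
        test.update(pool[i] for i in idx[:n_test_per_relation])
        valid.update(pool[i] for i in idx[n_test_per_relation:n_held])
        train.update(pool[i] for i in idx[n_held:])
    return TripleSplit(frozenset(train), frozenset(valid), frozenset(test), seed)


def compute_stats(kg: KnowledgeGraph) -> DatasetStats:
    if not kg.triples:
        raise ValidationError("cannot compute statistics of an empty graph")
    per_relation: dict[str, tuple[int, int, int]] = {}
    for rel in kg.relation_ids:
        ts = kg.by_relation[rel]
        heads = {t.head for t in ts}
        tails = {t.tail for t in ts}
        per_relation[rel] = (len(heads), len(tails), len(ts))
    return DatasetStats(
        per_relation=per_relation,
        total_entities=len(kg.entities),
        total_triples=len(kg.triples),
    )
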