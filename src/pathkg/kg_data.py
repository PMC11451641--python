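"""Data model and I/O for heterogeneous directed knowledge graphs.

A knowledge graph here is a set of directed, relation-labelled triplets
``(head, relation, tail)`` over typed entities.  Two edge sets play different
roles: *supervision* edges (G1) carry the relations the model is trained and
evaluated on, while *propagation* edges (G1-train plus an optional background
regulatory graph, G2) are the edges messages travel along.  Background edges
never enter any supervision split — they inform reasoning without ever being
a positive or negative example.

File conventions
----------------
Triplet TSV: ``head<TAB>relation<TAB>tail[<TAB>confidence]``; lines starting
with ``#`` are ignored.  Entity-type TSV: ``entity<TAB>type``.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, NamedTuple


class Triplet(NamedTuple):
    """A directed fact (head, relation, tail), all dense integer ids."""

    head: int
    relation: int
    tail: int


class ParseError(ValueError):
    """Malformed triplet or type file line."""


class VocabularyError(KeyError):
    """Name not present in a vocabulary with extension disabled."""


class LeakageError(ValueError):
    """A held-out supervision edge also appears among propagation edges."""


class StateError(RuntimeError):
    """Operation applied in the wrong order (e.g. double reverse-augmentation)."""


UNKNOWN_TYPE = "UNKNOWN"


@dataclass
class TypedEntityVocab:
    """Bijection entity-name <-> dense id, plus an entity-type label per id.

    Ids are assigned densely, 0-based, in first-seen order so that encodings
    are reproducible across runs independent of hash order.
    """

    name_to_id: dict[str, int] = field(default_factory=dict)
    id_to_name: list[str] = field(default_factory=list)
    id_to_type: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.id_to_name)

    @property
    def types(self) -> set[str]:
        return set(self.id_to_type)

    def add(self, name: str, type_label: str = UNKNOWN_TYPE) -> int:
        if name in self.name_to_id:
            return self.name_to_id[name]
        idx = len(self.id_to_name)
        self.name_to_id[name] = idx
        self.id_to_name.append(name)
        self.id_to_type.append(type_label)
        return idx

    def encode(self, name: str, extend: bool = False) -> int:
        if name in self.name_to_id:
            return self.name_to_id[name]
        if not extend:
            raise VocabularyError(f"unknown entity {name!r} (extend disabled)")
        return self.add(name)

    def type_of(self, entity_id: int) -> str:
        return self.id_to_type[entity_id]

    def ids_of_type(self, type_label: str) -> list[int]:
        return [i for i, t in enumerate(self.id_to_type) if t == type_label]

    @classmethod
    def from_type_table(cls, path: str | Path) -> "TypedEntityVocab":
        """Load an entity->type TSV; entities first seen later default to UNKNOWN."""
        vocab = cls()
        with open(path, encoding="utf-8") as fh:
            for lineno, raw in enumerate(fh, start=1):
                line = raw.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if len(parts) != 2:
                    raise ParseError(f"{path}:{lineno}: expected 2 columns, got {len(parts)}")
                vocab.add(parts[0], parts[1])
        return vocab

    def warn_untyped(self) -> int:
        """Warn (once) about entities carrying the UNKNOWN type; return their count."""
        n = sum(1 for t in self.id_to_type if t == UNKNOWN_TYPE)
        if n:
            warnings.warn(f"{n} entities have no type label; using {UNKNOWN_TYPE!r}")
        return n


@dataclass
class RelationVocab:
    """Relation-name <-> id map with reverse-relation augmentation.

    The first R ids are the original relations; after :meth:`augment`, relation
    ``r + R`` is the inverse of ``r`` and ``inverse_of`` is an involution over
    all ``2R`` ids.
    """

    name_to_id: dict[str, int] = field(default_factory=dict)
    id_to_name: list[str] = field(default_factory=list)
    num_base: int | None = None  # R, frozen at augmentation time

    def __len__(self) -> int:
        return len(self.id_to_name)

    @property
    def augmented(self) -> bool:
        return self.num_base is not None

    def encode(self, name: str, extend: bool = False) -> int:
        if name in self.name_to_id:
            return self.name_to_id[name]
        if not extend:
            raise VocabularyError(f"unknown relation {name!r} (extend disabled)")
        if self.augmented:
            raise StateError("cannot extend a reverse-augmented relation vocabulary")
        idx = len(self.id_to_name)
        self.name_to_id[name] = idx
        self.id_to_name.append(name)
        return idx

    def augment(self) -> None:
        """Add a reverse relation ``<name>^-1`` with id r+R for every base id r."""
        if self.augmented:
            raise StateError("relation vocabulary already reverse-augmented")
        self.num_base = len(self.id_to_name)
        for name in list(self.id_to_name[: self.num_base]):
            rev = f"{name}^-1"
            self.name_to_id[rev] = len(self.id_to_name)
            self.id_to_name.append(rev)

    def inverse_of(self, rel: int) -> int:
        if not self.augmented:
            raise StateError("inverse_of requires an augmented vocabulary")
        R = self.num_base
        return rel + R if rel < R else rel - R


def read_triplets(
    path: str | Path,
    vocab: TypedEntityVocab,
    relations: RelationVocab,
    extend: bool = False,
    min_confidence: float | None = None,
) -> list[Triplet]:
    """Read a triplet TSV into integer-encoded triplets, in file order.

    Duplicates are preserved (deduplication is a separate, explicit step).  An
    optional fourth numeric column is a confidence score; rows below
    `min_confidence` are dropped when a threshold is given.
    """
    out: list[Triplet] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) not in (3, 4):
                raise ParseError(f"{path}:{lineno}: expected 3 columns, got {len(parts)}")
            if len(parts) == 4 and min_confidence is not None:
                try:
                    conf = float(parts[3])
                except ValueError as exc:
                    raise ParseError(f"{path}:{lineno}: bad confidence {parts[3]!r}") from exc
                if conf < min_confidence:
                    continue
            h = vocab.encode(parts[0], extend=extend)
            r = relations.encode(parts[1], extend=extend)
            t = vocab.encode(parts[2], extend=extend)
            out.append(Triplet(h, r, t))
    return out


def write_triplets(
    path: str | Path,
    triplets: Iterable[Triplet],
    vocab: TypedEntityVocab,
    relations: RelationVocab,
) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for h, r, t in triplets:
            fh.write(f"{vocab.id_to_name[h]}\t{relations.id_to_name[r]}\t{vocab.id_to_name[t]}\n")


def dedupe(triplets: Iterable[Triplet]) -> list[Triplet]:
    """Remove duplicate triplets, keeping first-seen order."""
    seen: set[Triplet] = set()
    out = []
    for t in triplets:
        if t not in seen:
            seen.add(t)
            out.append(t)
    return out


def strip_preexisting_reverse(triplets: list[Triplet]) -> list[Triplet]:
    """Drop (v, r, u) when (u, r, v) with the same relation appears earlier.

    Some source datasets ship both directions of a symmetric relation; reverse
    augmentation would then double them, so they can be stripped first.
    """
    kept: list[Triplet] = []
    seen: set[Triplet] = set()
    for t in triplets:
        if Triplet(t.tail, t.relation, t.head) in seen:
            continue
        seen.add(t)
        kept.append(t)
    return kept


def add_reverse_edges(triplets: list[Triplet], relations: RelationVocab) -> list[Triplet]:
    """Append the reverse triplet (v, r+R, u) for every (u, r, v).

    Must be applied exactly once, right after :meth:`RelationVocab.augment`;
    triplets already containing augmented relation ids are rejected.
    """
    if not relations.augmented:
        relations.augment()
    R = relations.num_base
    if any(t.relation >= R for t in triplets):
        raise StateError("triplets already contain reverse (augmented) relation ids")
    return list(triplets) + [Triplet(t, relations.inverse_of(r), h) for h, r, t in triplets]


@dataclass
class KnowledgeGraph:
    """Assembled graph: supervision splits plus the message-passing edge set.

    ``propagation_edges`` = train ∪ background; held-out (valid/test) edges are
    never propagated, and background edges never supervised.  ``adjacency``
    maps each node to its list of incoming propagation edges.
    """

    vocab: TypedEntityVocab
    relations: RelationVocab
    train: list[Triplet]
    valid: list[Triplet]
    test: list[Triplet]
    background: list[Triplet] = field(default_factory=list)

    propagation_edges: list[Triplet] = field(init=False)
    adjacency: dict[int, list[Triplet]] = field(init=False)

    def __post_init__(self):
        held_out = set(self.valid) | set(self.test)
        leaked = held_out & set(self.background)
        if leaked:
            raise LeakageError(
                f"{len(leaked)} held-out supervision edges appear in the background "
                f"graph, e.g. {next(iter(leaked))}"
            )
        leaked = held_out & set(self.train)
        if leaked:
            raise LeakageError(f"{len(leaked)} held-out edges also in train, e.g. {next(iter(leaked))}")
        self.propagation_edges = dedupe(list(self.train) + list(self.background))
        self.adjacency = {}
        for e in self.propagation_edges:
            self.adjacency.setdefault(e.tail, []).append(e)

    @property
    def num_nodes(self) -> int:
        return len(self.vocab)

    @property
    def num_relations(self) -> int:
        """Size of the augmented relation vocabulary (2R)."""
        return len(self.relations)

    def supervision_edges(self) -> list[Triplet]:
        return list(self.train) + list(self.valid) + list(self.test)

    def incoming(self, node: int) -> list[Triplet]:
        return self.adjacency.get(node, [])

    def edge_arrays(self):
        """Propagation edges as (heads, relations, tails) int arrays."""
        import numpy as np

        if not self.propagation_edges:
            z = np.zeros(0, dtype=np.int64)
            return z, z.copy(), z.copy()
        arr = np.asarray(self.propagation_edges, dtype=np.int64)
        return arr[:, 0], arr[:, 1], arr[:, 2]

    def known_tails(self, split: str = "train") -> dict[tuple[int, int], set[int]]:
        """Map (head, relation) -> set of known tails in the given split(s).

        ``split`` is one of train/valid/test/all.
        """
        edges: list[Triplet] = []
        if split in ("train", "all"):
            edges += self.train
        if split in ("valid", "all"):
            edges += self.valid
        if split in ("test", "all"):
            edges += self.test
        out: dict[tuple[int, int], set[int]] = {}
        for h, r, t in edges:
            out.setdefault((h, r), set()).add(t)
        return out


def assemble_graph(
    train: list[Triplet],
    valid: list[Triplet],
    test: list[Triplet],
    brg: list[Triplet],
    vocab: TypedEntityVocab,
    relations: RelationVocab,
) -> KnowledgeGraph:
    """Build a :class:`KnowledgeGraph` from already reverse-augmented train/brg lists."""
    return KnowledgeGraph(vocab, relations, train, valid, test, brg)


def dump_vocab(path: str | Path, vocab: TypedEntityVocab, relations: RelationVocab) -> None:
    payload = {
        "entities": vocab.name_to_id,
        "entity_types": {name: vocab.id_to_type[i] for name, i in vocab.name_to_id.items()},
        "relations": relations.name_to_id,
        "num_base_relations": relations.num_base,
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def load_bundle(
    directory: str | Path,
    strip_reverse: bool = False,
    min_confidence: float | None = None,
    augment_brg: bool = True,
) -> KnowledgeGraph:
    """Load a train/valid/test(/brg) TSV bundle plus a type table into a graph.

    Expects ``train.tsv``, ``valid.tsv``, ``test.tsv``, optionally ``brg.tsv``
    and ``types.tsv`` in `directory`.  Reverse relations are added to train and
    (by default) background edges before assembly.
    """
    directory = Path(directory)
    types_path = directory / "types.tsv"
    vocab = TypedEntityVocab.from_type_table(types_path) if types_path.exists() else TypedEntityVocab()
    relations = RelationVocab()

    def _read(name):
        p = directory / name
        if not p.exists():
            return []
        tr = read_triplets(p, vocab, relations, extend=True, min_confidence=min_confidence)
        return dedupe(tr)

    train = _read("train.tsv")
    brg = _read("brg.tsv")
    valid = _read("valid.tsv")
    test = _read("test.tsv")
    vocab.warn_untyped()
    if strip_reverse:
        train = strip_preexisting_reverse(train)
        brg = strip_preexisting_reverse(brg)
    relations.augment()
    train = add_reverse_edges_unchecked(train, relations)
    if augment_brg:
        brg = add_reverse_edges_unchecked(brg, relations)
    return assemble_graph(train, valid, test, brg, vocab, relations)


def add_reverse_edges_unchecked(triplets: list[Triplet], relations: RelationVocab) -> list[Triplet]:
    """Reverse-augment when the vocabulary is already augmented (internal)."""
    R = relations.num_base
    if any(t.relation >= R for t in triplets):
        raise StateError("triplets already contain reverse relation ids")
    return list(triplets) + [Triplet(t, r + R, h) for h, r, t in triplets]
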