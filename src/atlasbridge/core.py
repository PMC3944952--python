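"""In-memory anatomical ontology with taxonomic and partonomic reasoning.

The store keeps named anatomical classes (gyri, Brodmann areas, tracts,
sulci, ...) together with three kinds of structural assertions:

* ``is_a`` — taxonomic subsumption (e.g. *Right superior frontal gyrus*
  is_a *Superior frontal gyrus*);
* ``part_of`` — generic transitive parthood;
* ``regional_part_of`` — spatially delimited regional parthood, a
  transitive sub-relation of ``part_of`` (its edges count toward the
  ``part_of`` closure). The inverse reading, *has_regional_part*, is a
  query direction, not a stored relation.

Both hierarchies are maintained acyclic at insertion time; irreflexive,
antisymmetric parthood is enforced because downstream machine reasoning
(closure queries, correlation paths) breaks on cycles.
"""

from __future__ import annotations

import re
from collections import deque
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Optional

import networkx as nx

__all__ = [
    "Laterality",
    "EntityCategory",
    "RelationKind",
    "OntologyClass",
    "StructuralAssertion",
    "Violation",
    "Ontology",
    "OntologyError",
    "DuplicateClassError",
    "UnknownClassError",
    "CycleError",
    "slugify",
]

#: namespace prefix for generated class identifiers
NAMESPACE = "na"


class OntologyError(ValueError):
    """Base class for ontology content errors."""


class DuplicateClassError(OntologyError):
    pass


class UnknownClassError(KeyError, OntologyError):
    pass


class CycleError(OntologyError):
    """Raised when an assertion would create a cycle; carries the path."""

    def __init__(self, relation: "RelationKind", path: list[str]):
        self.relation = relation
        self.path = path
        super().__init__(
            f"asserting this {relation.value} edge would create a cycle: "
            + " -> ".join(path)
        )


class Laterality(str, Enum):
    LEFT = "left"
    RIGHT = "right"
    UNPAIRED = "unpaired"


class EntityCategory(str, Enum):
    """Material structures can carry connectivity; spaces (sulci,
    ventricles) cannot."""

    MATERIAL = "material_structure"
    SPACE = "anatomical_space"


class RelationKind(str, Enum):
    IS_A = "is_a"
    PART_OF = "part_of"
    REGIONAL_PART_OF = "regional_part_of"


def _normkey(name: str) -> str:
    """Case-insensitive lookup key with internal whitespace collapsed."""
    return re.sub(r"\s+", " ", name.strip()).lower()


def slugify(name: str) -> str:
    """Namespace-prefixed lowercase slug used as a ClassId."""
    slug = re.sub(r"[^a-z0-9]+", "-", name.lower()).strip("-")
    return f"{NAMESPACE}:{slug}"


@dataclass(frozen=True)
class OntologyClass:
    """A named anatomical entity.

    ``synonyms`` never contain the preferred name; ``laterality`` is
    ``unpaired`` for structures without a left/right attribute (the
    NeuroLex convention).
    """

    id: str
    preferred_name: str
    synonyms: frozenset[str] = frozenset()
    laterality: Laterality = Laterality.UNPAIRED
    category: EntityCategory = EntityCategory.MATERIAL
    definition: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.id:
            raise OntologyError("class id must be non-empty")
        if not self.preferred_name or not self.preferred_name.strip():
            raise OntologyError("preferred_name must be non-empty")
        if _normkey(self.preferred_name) in {_normkey(s) for s in self.synonyms}:
            raise OntologyError(
                f"preferred name {self.preferred_name!r} repeated in synonyms"
            )


@dataclass(frozen=True, order=True)
class StructuralAssertion:
    subject: str
    relation: RelationKind
    object: str


@dataclass(frozen=True)
class Violation:
    """A content problem found by :meth:`Ontology.validate`."""

    kind: str  # cycle | dangling | duplicate_name | space_connectivity | non_exclusive_term
    message: str
    involved: tuple[str, ...] = ()


# part_of closure traverses both plain part_of edges and regional_part_of
# edges (sub-relation containment); the other two kinds traverse only
# their own edges.
_CLOSURE_KINDS: dict[RelationKind, tuple[RelationKind, ...]] = {
    RelationKind.IS_A: (RelationKind.IS_A,),
    RelationKind.PART_OF: (RelationKind.PART_OF, RelationKind.REGIONAL_PART_OF),
    RelationKind.REGIONAL_PART_OF: (RelationKind.REGIONAL_PART_OF,),
}


@dataclass
class Ontology:
    """Mutable ontology store.

    ``bindings`` maps ``(scheme, external_label)`` to a terminology
    binding (see :mod:`atlasbridge.mapping`); ``connectivity`` holds
    asserted tract/region relations and ``connectivity_inferred`` the
    pathway derivations (see :mod:`atlasbridge.connectivity`);
    ``sulcus_links`` records which sulcal segments adjoin a sulcus space.
    """

    classes: dict[str, OntologyClass] = field(default_factory=dict)
    structural: set[StructuralAssertion] = field(default_factory=set)
    bindings: dict = field(default_factory=dict)
    connectivity: list = field(default_factory=list)
    connectivity_inferred: list = field(default_factory=list)
    sulcus_links: dict[str, set[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self._name_index: dict[str, str] = {}
        for cls in self.classes.values():
            self._index_class(cls)

    # ------------------------------------------------------------------ classes

    def _index_class(self, cls: OntologyClass) -> None:
        self._name_index[_normkey(cls.preferred_name)] = cls.id
        for syn in cls.synonyms:
            self._name_index.setdefault(_normkey(syn), cls.id)

    def add_class(self, cls: OntologyClass) -> str:
        """Add a class; id and preferred name must be unique.

        Returns the class id. Lookup afterwards works by id, preferred
        name or any synonym, case-insensitively.
        """
        if cls.id in self.classes:
            raise DuplicateClassError(
                f"id {cls.id!r} already used by "
                f"{self.classes[cls.id].preferred_name!r}"
            )
        key = _normkey(cls.preferred_name)
        if key in self._name_index:
            other = self.classes[self._name_index[key]]
            raise DuplicateClassError(
                f"preferred name {cls.preferred_name!r} conflicts with "
                f"existing class {other.id} ({other.preferred_name!r})"
            )
        self.classes[cls.id] = cls
        self._index_class(cls)
        return cls.id

    def new_class(self, preferred_name: str, **kwargs) -> str:
        """Convenience: create and add a class with a slug id."""
        kwargs.setdefault("synonyms", frozenset())
        cls = OntologyClass(
            id=slugify(preferred_name), preferred_name=preferred_name,
            synonyms=frozenset(kwargs.pop("synonyms")), **kwargs,
        )
        return self.add_class(cls)

    def __contains__(self, class_id: str) -> bool:
        return class_id in self.classes

    def get(self, class_id: str) -> OntologyClass:
        try:
            return self.classes[class_id]
        except KeyError:
            raise UnknownClassError(f"unknown class id {class_id!r}") from None

    def resolve_name(self, name: str) -> Optional[str]:
        """Class id for a preferred name or synonym, or None."""
        return self._name_index.get(_normkey(name))

    def name_of(self, class_id: str) -> str:
        return self.get(class_id).preferred_name

    def add_synonym(self, class_id: str, synonym: str) -> None:
        cls = self.get(class_id)
        if _normkey(synonym) == _normkey(cls.preferred_name):
            raise OntologyError("synonym equals preferred name")
        updated = replace(cls, synonyms=cls.synonyms | {synonym})
        self.classes[class_id] = updated
        self._name_index.setdefault(_normkey(synonym), class_id)

    # --------------------------------------------------------------- structural

    def _edges(self, kinds: Iterable[RelationKind]) -> dict[str, set[str]]:
        kinds = tuple(kinds)
        adj: dict[str, set[str]] = {}
        for a in self.structural:
            if a.relation in kinds:
                adj.setdefault(a.subject, set()).add(a.object)
        return adj

    def _find_path(self, start: str, goal: str,
                   kinds: tuple[RelationKind, ...]) -> Optional[list[str]]:
        """Shortest edge path start -> goal over the given kinds, or None."""
        if start == goal:
            return [start]
        adj = self._edges(kinds)
        prev: dict[str, str] = {}
        queue = deque([start])
        seen = {start}
        while queue:
            node = queue.popleft()
            for nxt in adj.get(node, ()):  # order irrelevant: path existence only
                if nxt in seen:
                    continue
                prev[nxt] = node
                if nxt == goal:
                    path = [goal]
                    while path[-1] != start:
                        path.append(prev[path[-1]])
                    return path[::-1]
                seen.add(nxt)
                queue.append(nxt)
        return None

    def assert_structural(self, subject: str, relation: RelationKind,
                          object: str) -> StructuralAssertion:
        """Add a structural edge; idempotent; rejects cycles and
        dangling endpoints."""
        relation = RelationKind(relation)
        if subject not in self.classes:
            raise UnknownClassError(f"unknown subject {subject!r}")
        if object not in self.classes:
            raise UnknownClassError(f"unknown object {object!r}")
        if subject == object:
            raise CycleError(relation, [subject, subject])
        edge = StructuralAssertion(subject, relation, object)
        if edge in self.structural:
            return edge
        # a subject->object edge closes a cycle iff subject is already
        # reachable from object in the relation's closure graph
        back = self._find_path(object, subject, _CLOSURE_KINDS[relation])
        if back is not None:
            # back runs object -> ... -> subject; prepending subject closes it
            raise CycleError(relation, [subject] + back)
        self.structural.add(edge)
        return edge

    def _closure(self, class_id: str, relation: RelationKind,
                 forward: bool) -> list[str]:
        if class_id not in self.classes:
            raise UnknownClassError(f"unknown class id {class_id!r}")
        kinds = _CLOSURE_KINDS[RelationKind(relation)]
        adj: dict[str, set[str]] = {}
        for a in self.structural:
            if a.relation in kinds:
                if forward:
                    adj.setdefault(a.subject, set()).add(a.object)
                else:
                    adj.setdefault(a.object, set()).add(a.subject)
        out: list[str] = []
        seen = {class_id}
        frontier = [class_id]
        while frontier:
            nxt: set[str] = set()
            for node in frontier:
                nxt |= adj.get(node, set()) - seen
            layer = sorted(nxt, key=lambda c: (self.classes[c].preferred_name, c))
            out.extend(layer)
            seen |= nxt
            frontier = layer
        return out

    def ancestors(self, class_id: str, relation: RelationKind) -> list[str]:
        """Transitive closure above a class (reflexive-free).

        ``part_of`` ancestors include those reached through
        ``regional_part_of`` edges. Order is breadth-first by depth,
        ties broken by preferred name.
        """
        return self._closure(class_id, relation, forward=True)

    def descendants(self, class_id: str, relation: RelationKind) -> list[str]:
        """Inverse of :meth:`ancestors` (e.g. has_regional_part listing)."""
        return self._closure(class_id, relation, forward=False)

    # ---------------------------------------------------------------- validation

    def validate(self) -> list[Violation]:
        """Report all content problems; never raises on content.

        Checks: relation cycles, dangling assertion endpoints, duplicate
        preferred names, connectivity on anatomical spaces, and
        non-exclusive whole/part term reuse (a part sharing its whole's
        preferred name).
        """
        out: list[Violation] = []

        for a in sorted(self.structural):
            for end in (a.subject, a.object):
                if end not in self.classes:
                    out.append(Violation(
                        "dangling",
                        f"assertion {a.subject} {a.relation.value} {a.object} "
                        f"references unknown class {end!r}",
                        (a.subject, a.object)))

        # cycles per closure graph (is_a; part_of incl. regional)
        for rel in (RelationKind.IS_A, RelationKind.PART_OF):
            adj = self._edges(_CLOSURE_KINDS[rel])
            graph = nx.DiGraph()
            for subject, objects in adj.items():
                for obj in objects:
                    graph.add_edge(subject, obj)
            try:
                cyc_edges = nx.find_cycle(graph, orientation="original")
            except nx.NetworkXNoCycle:
                continue
            cyc = [e[0] for e in cyc_edges] + [cyc_edges[0][0]]
            out.append(Violation(
                "cycle",
                f"{rel.value} cycle: " + " -> ".join(cyc),
                tuple(cyc)))

        seen_names: dict[str, str] = {}
        for cid in sorted(self.classes):
            key = _normkey(self.classes[cid].preferred_name)
            if key in seen_names:
                out.append(Violation(
                    "duplicate_name",
                    f"classes {seen_names[key]} and {cid} share preferred "
                    f"name {self.classes[cid].preferred_name!r}",
                    (seen_names[key], cid)))
            else:
                seen_names[key] = cid

        for a in list(self.connectivity) + list(self.connectivity_inferred):
            for end in (a.subject, a.object) + ((a.via,) if a.via else ()):
                cls = self.classes.get(end)
                if cls is not None and cls.category is EntityCategory.SPACE:
                    out.append(Violation(
                        "space_connectivity",
                        f"connectivity assertion {a.kind.value} touches "
                        f"anatomical space {cls.preferred_name!r}",
                        (a.subject, a.object)))

        # non-exclusive term: a regional part reusing its whole's name
        for a in sorted(self.structural):
            if a.relation is not RelationKind.REGIONAL_PART_OF:
                continue
            sub = self.classes.get(a.subject)
            obj = self.classes.get(a.object)
            if sub and obj and _normkey(sub.preferred_name) == _normkey(obj.preferred_name):
                out.append(Violation(
                    "non_exclusive_term",
                    f"part {a.subject} reuses the whole's term "
                    f"{obj.preferred_name!r}; parts need exclusive names",
                    (a.subject, a.object)))
        return out
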