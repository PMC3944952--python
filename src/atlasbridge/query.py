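"""Cross-atlas correlation queries.

A label from one scheme resolves (through its terminology binding) to an
ontology class; walking the part hierarchy — and, for non-lateralized
target vocabularies, the taxonomy — reaches classes bound in the target
scheme. The explanatory path of relation hops is reported alongside the
target labels, making the correspondence auditable rather than a bare
lookup. One coarse label can legitimately correlate to many finer ones
(the atlas concordance problem: label sets are not one-to-one), so
downward queries return every bound descendant.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass
from enum import Enum
from typing import Sequence

import pandas as pd

from .core import Ontology, RelationKind, _CLOSURE_KINDS
from .labels import SchemeId
from .mapping import UnmappedLabelError, lookup_by_binding

__all__ = [
    "GranularityLevel",
    "CorrelationResult",
    "correlate_label",
    "granularity_level",
    "overlap_query",
    "annotate_table",
]


class GranularityLevel(str, Enum):
    CYTOARCHITECTURAL_AREA = "cytoarchitectural_area"
    CORTICAL_GRAY_MATTER = "cortical_gray_matter"
    GYRUS = "gyrus"
    LOBE = "lobe"
    HEMISPHERE = "hemisphere"
    OTHER = "other"


class Direction(str, Enum):
    UP = "up"
    DOWN = "down"
    LATERAL_IS_A = "lateral_is_a"
    IDENTITY = "identity"


@dataclass(frozen=True)
class CorrelationResult:
    source_scheme: SchemeId
    source_label: str
    target_scheme: SchemeId
    target_label: str
    target_class: str
    path: tuple[tuple[str, RelationKind], ...]  # hops from the source class
    direction: Direction


def granularity_level(ontology: Ontology, class_id: str) -> GranularityLevel:
    """Granularity of a class from its naming pattern.

    Brodmann-by-gyrus intersections are the finest (cytoarchitectural)
    level; "Gray matter of ... gyrus" sits between area and gyrus; then
    gyrus, lobe, hemisphere/cerebrum; anything else is ``other``.
    """
    name = ontology.name_of(class_id).lower()
    if name.startswith("brodmann area") and " of " in name:
        return GranularityLevel.CYTOARCHITECTURAL_AREA
    if name.startswith("gray matter of") and name.endswith("gyrus"):
        return GranularityLevel.CORTICAL_GRAY_MATTER
    if name.endswith("gyrus"):
        return GranularityLevel.GYRUS
    if name.endswith("lobe"):
        return GranularityLevel.LOBE
    if name.endswith("hemisphere") or name.endswith("cerebrum"):
        return GranularityLevel.HEMISPHERE
    return GranularityLevel.OTHER


def _bound_labels(ontology: Ontology, scheme: SchemeId) -> dict[str, list[str]]:
    """class id -> bound labels in the scheme (sorted)."""
    out: dict[str, list[str]] = {}
    for (s, label), binding in ontology.bindings.items():
        if s is scheme:
            out.setdefault(binding.class_id, []).append(label)
    return {cid: sorted(labels) for cid, labels in out.items()}


def _bfs_paths(
    ontology: Ontology,
    start: str,
    adjacency,
    targets: set[str],
) -> dict[str, tuple[tuple[str, RelationKind], ...]]:
    """Shortest hop-path from start to each reachable target class.

    ``adjacency(node)`` yields (next_class, relation) pairs; ties are
    broken by visiting neighbors in preferred-name order.
    """
    found: dict[str, tuple[tuple[str, RelationKind], ...]] = {}
    paths: dict[str, tuple[tuple[str, RelationKind], ...]] = {start: ()}
    queue = deque([start])
    while queue:
        node = queue.popleft()
        neighbors = sorted(adjacency(node),
                           key=lambda nr: (ontology.name_of(nr[0]), nr[1].value))
        for nxt, rel in neighbors:
            if nxt in paths:
                continue
            paths[nxt] = paths[node] + ((nxt, rel),)
            if nxt in targets:
                found[nxt] = paths[nxt]
            queue.append(nxt)
    return found


def _directed_adjacency(ontology: Ontology, kinds, forward: bool):
    adj: dict[str, list[tuple[str, RelationKind]]] = {}
    for a in ontology.structural:
        if a.relation in kinds:
            if forward:
                adj.setdefault(a.subject, []).append((a.object, a.relation))
            else:
                adj.setdefault(a.object, []).append((a.subject, a.relation))
    return lambda node: adj.get(node, [])


def correlate_label(
    ontology: Ontology,
    raw: str,
    source: SchemeId,
    target: SchemeId,
) -> list[CorrelationResult]:
    """Correlate one source-scheme label into the target scheme.

    Search order: identity (the source class itself bound in the
    target), then part_of ancestors (direction ``up``), then part_of
    descendants (``down``); taxonomic ``is_a`` hops participate only
    when the part search yields nothing or the target vocabulary is
    non-lateralized (NeuroLex). Shortest path per target label,
    deterministic order (path length, then target label).
    """
    source = SchemeId(source)
    target = SchemeId(target)
    src_class = lookup_by_binding(ontology, source, raw)
    bound = _bound_labels(ontology, target)
    results: list[CorrelationResult] = []

    def emit(cid: str, path, direction: Direction) -> None:
        for label in bound.get(cid, []):
            results.append(CorrelationResult(
                source, raw, target, label, cid, tuple(path), direction))

    if src_class in bound:
        emit(src_class, (), Direction.IDENTITY)

    part_kinds = _CLOSURE_KINDS[RelationKind.PART_OF]
    targets = set(bound) - {src_class}

    up = _bfs_paths(ontology, src_class,
                    _directed_adjacency(ontology, part_kinds, True), targets)
    for cid in sorted(up, key=lambda c: (len(up[c]), ontology.name_of(c))):
        emit(cid, up[cid], Direction.UP)

    down = _bfs_paths(ontology, src_class,
                      _directed_adjacency(ontology, part_kinds, False),
                      targets - set(up))
    for cid in sorted(down, key=lambda c: (len(down[c]), ontology.name_of(c))):
        emit(cid, down[cid], Direction.DOWN)

    use_is_a = not results or target is SchemeId.NEUROLEX
    if use_is_a:
        mixed_kinds = part_kinds + (RelationKind.IS_A,)
        reached = set(up) | set(down) | ({src_class} if src_class in bound else set())

        def mixed_adjacency(node):
            yield from _directed_adjacency(ontology, mixed_kinds, True)(node)
            # downward taxonomy matters for delateralization in reverse
            yield from _directed_adjacency(
                ontology, (RelationKind.IS_A,), False)(node)

        lateral = _bfs_paths(ontology, src_class, mixed_adjacency,
                             targets - reached)
        for cid in sorted(lateral,
                          key=lambda c: (len(lateral[c]), ontology.name_of(c))):
            if any(rel is RelationKind.IS_A for _, rel in lateral[cid]):
                emit(cid, lateral[cid], Direction.LATERAL_IS_A)

    results.sort(key=lambda r: (len(r.path), r.target_label))
    return results


def overlap_query(ontology: Ontology, class_a: str, class_b: str) -> dict:
    """Partonomic overlap of two structures.

    ``shared_parts`` — classes in the part_of closure below both;
    ``a_only_exists`` — A has a part not under B (so part of A lies
    outside B), and symmetrically for B.
    """
    ontology.get(class_a)
    ontology.get(class_b)
    below_a = set(ontology.descendants(class_a, RelationKind.PART_OF))
    below_b = set(ontology.descendants(class_b, RelationKind.PART_OF))
    if class_a == class_b:
        return {"shared_parts": sorted(below_a, key=ontology.name_of),
                "a_only_exists": False, "b_only_exists": False}
    shared = below_a & below_b
    a_only = bool(below_a - below_b - {class_b})
    b_only = bool(below_b - below_a - {class_a})
    return {"shared_parts": sorted(shared, key=ontology.name_of),
            "a_only_exists": a_only, "b_only_exists": b_only}


def annotate_table(
    ontology: Ontology,
    rows: Sequence[tuple[str, str]],
    expand: RelationKind = RelationKind.PART_OF,
) -> pd.DataFrame:
    """Annotate (scheme, label) rows with their ontology context.

    Adds class id/name, granularity level and the ``expand``-relation
    ancestor names. Unmapped rows are flagged, never dropped.
    """
    records = []
    for scheme_name, label in rows:
        rec = {"scheme": scheme_name, "label": label, "mapped": False,
               "class_id": None, "class_name": None, "granularity": None,
               "ancestors": None}
        try:
            cid = lookup_by_binding(ontology, SchemeId(scheme_name), label)
        except (UnmappedLabelError, ValueError):
            records.append(rec)
            continue
        ancestors = ontology.ancestors(cid, expand)
        rec.update(
            mapped=True, class_id=cid, class_name=ontology.name_of(cid),
            granularity=granularity_level(ontology, cid).value,
            ancestors="|".join(ontology.name_of(a) for a in ancestors))
        records.append(rec)
    return pd.DataFrame.from_records(
        records,
        columns=["scheme", "label", "mapped", "class_id", "class_name",
                 "granularity", "ancestors"])
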