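"""Reusable ontology-modeling patterns for cortical parcellation.

Four constructors capture the modeling idioms needed to reconcile
morphological (gyral) and cytoarchitectural (Brodmann) parcellations in
one partonomy:

* ``create_intersection_class`` — the overlap of a gyral gray-matter
  region with a Brodmann area becomes its own class, a regional part of
  both parents and a taxonomic child of "Segment of Brodmann area N";
* ``lateralize`` — split an unpaired structure into Left/Right
  subclasses;
* ``create_sulcal_segment`` — the buried cortex of a gyrus inside a
  sulcus, modeled as a material segment of the gyrus while the sulcus
  itself stays an anatomical space;
* ``partition_tract`` — name the segments of a white-matter tract with
  terms exclusive of the whole-tract term, so annotations can never
  confuse a segment with the entire tract.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from .core import (
    EntityCategory,
    Laterality,
    Ontology,
    OntologyError,
    RelationKind,
    _normkey,
)

__all__ = [
    "IntersectionSpec",
    "TractPartition",
    "NonExclusiveTermError",
    "create_intersection_class",
    "lateralize",
    "create_sulcal_segment",
    "partition_tract",
]


class NonExclusiveTermError(OntologyError):
    """A part was given the same term as its whole."""


@dataclass(frozen=True)
class IntersectionSpec:
    """Parents of one Brodmann-by-gyrus intersection."""

    gyral_gm_class: str  # e.g. "Gray matter of right superior frontal gyrus"
    brodmann_class: str  # e.g. "Right Brodmann area 6"
    laterality: Laterality = Laterality.UNPAIRED


@dataclass(frozen=True)
class TractPartition:
    tract: str
    segment_names: tuple[str, ...] = field(default=())


_BRODMANN_RE = re.compile(r"brodmann area (\w+)", re.IGNORECASE)
_GM_RE = re.compile(r"^gray matter of (?:the )?(left |right )?(.+)$",
                    re.IGNORECASE)


def _brodmann_number(name: str) -> str:
    m = _BRODMANN_RE.search(name)
    if not m:
        raise OntologyError(
            f"{name!r} does not name a Brodmann area; cannot derive the "
            "intersection-class name")
    return m.group(1)


def _gyrus_phrase(name: str) -> str:
    """'Gray matter of right superior frontal gyrus' -> 'superior frontal
    gyrus' (the side is supplied by the spec's laterality)."""
    m = _GM_RE.match(_normkey(name))
    if m:
        return m.group(2)
    return _normkey(name)


def intersection_name(ontology: Ontology, spec: IntersectionSpec) -> str:
    number = _brodmann_number(ontology.name_of(spec.brodmann_class))
    gyrus = _gyrus_phrase(ontology.name_of(spec.gyral_gm_class))
    side = "" if spec.laterality is Laterality.UNPAIRED else f"{spec.laterality.value} "
    return f"Brodmann area {number} of {side}{gyrus}"


def create_intersection_class(ontology: Ontology, spec: IntersectionSpec) -> str:
    """Create (or return) the class for a gyral-GM x Brodmann overlap.

    The new class is asserted ``regional_part_of`` both parents and
    ``is_a`` the (auto-created) "Segment of Brodmann area N" class.
    Idempotent: re-running the same spec returns the existing id without
    duplicating edges.
    """
    gm = ontology.get(spec.gyral_gm_class)
    ba = ontology.get(spec.brodmann_class)
    name = intersection_name(ontology, spec)
    number = _brodmann_number(ba.preferred_name)

    existing = ontology.resolve_name(name)
    if existing is not None:
        return existing

    segment_parent_name = f"Segment of Brodmann area {number}"
    segment_parent = ontology.resolve_name(segment_parent_name)
    if segment_parent is None:
        segment_parent = ontology.new_class(
            segment_parent_name, category=EntityCategory.MATERIAL)

    cid = ontology.new_class(
        name, laterality=spec.laterality, category=EntityCategory.MATERIAL)
    ontology.assert_structural(cid, RelationKind.IS_A, segment_parent)
    ontology.assert_structural(cid, RelationKind.REGIONAL_PART_OF, ba.id)
    ontology.assert_structural(cid, RelationKind.REGIONAL_PART_OF, gm.id)
    return cid


def lateralize(ontology: Ontology, unpaired_class: str) -> tuple[str, str]:
    """Create Left/Right subclasses of an unpaired structure.

    Structural context is inherited through ``is_a`` queries, never
    copied onto the sided children. Errors if the input is already
    lateralized or was lateralized before.
    """
    cls = ontology.get(unpaired_class)
    if cls.laterality is not Laterality.UNPAIRED:
        raise OntologyError(
            f"{cls.preferred_name!r} is already lateralized "
            f"({cls.laterality.value})")
    base = cls.preferred_name[0].lower() + cls.preferred_name[1:]
    left_name = f"Left {base}"
    right_name = f"Right {base}"
    if ontology.resolve_name(left_name) or ontology.resolve_name(right_name):
        raise OntologyError(f"{cls.preferred_name!r} was already lateralized")
    left = ontology.new_class(left_name, laterality=Laterality.LEFT,
                              category=cls.category)
    right = ontology.new_class(right_name, laterality=Laterality.RIGHT,
                               category=cls.category)
    ontology.assert_structural(left, RelationKind.IS_A, cls.id)
    ontology.assert_structural(right, RelationKind.IS_A, cls.id)
    return left, right


SEGMENT_OF_GYRUS = "Segment of gyrus of brain"


def create_sulcal_segment(ontology: Ontology, gyrus: str, sulcus_space: str) -> str:
    """Model the buried cortex of ``gyrus`` inside ``sulcus_space``.

    The segment (material) is a regional part of the gyrus and a
    taxonomic child of "Segment of gyrus of brain"; the sulcus <->
    segment adjacency is a dedicated association record, not parthood,
    since a space is not a part of a material gyrus. A sulcus flanked by
    two gyri thus links to two sulcal segments.
    """
    g = ontology.get(gyrus)
    s = ontology.get(sulcus_space)
    if g.category is not EntityCategory.MATERIAL:
        raise OntologyError(
            f"gyrus {g.preferred_name!r} must be a material structure")
    if s.category is not EntityCategory.SPACE:
        raise OntologyError(
            f"sulcus {s.preferred_name!r} must be an anatomical space")

    base = g.preferred_name[0].lower() + g.preferred_name[1:]
    name = f"Sulcal segment of {base}"
    cid = ontology.resolve_name(name)
    if cid is None:
        parent = ontology.resolve_name(SEGMENT_OF_GYRUS)
        if parent is None:
            parent = ontology.new_class(SEGMENT_OF_GYRUS)
        cid = ontology.new_class(name, laterality=g.laterality)
        ontology.assert_structural(cid, RelationKind.IS_A, parent)
        ontology.assert_structural(cid, RelationKind.REGIONAL_PART_OF, g.id)
    ontology.sulcus_links.setdefault(s.id, set()).add(cid)
    return cid


def partition_tract(ontology: Ontology, partition: TractPartition) -> list[str]:
    """Declare the named segments of a white-matter tract.

    Every segment becomes a regional part of the whole tract. Reusing
    the whole-tract term for a segment is rejected: annotation with a
    non-exclusive term is exactly the inconsistency this pattern exists
    to prevent.
    """
    tract = ontology.get(partition.tract)
    names = list(partition.segment_names)
    lowered = [_normkey(n) for n in names]
    if len(set(lowered)) != len(lowered):
        raise OntologyError("segment names must be pairwise distinct")
    for n in names:
        if _normkey(n) == _normkey(tract.preferred_name):
            raise NonExclusiveTermError(
                f"segment may not reuse the whole-tract term "
                f"{tract.preferred_name!r}")
    out: list[str] = []
    for n in names:
        cid = ontology.resolve_name(n)
        if cid is None:
            cid = ontology.new_class(n, laterality=tract.laterality)
        ontology.assert_structural(cid, RelationKind.REGIONAL_PART_OF, tract.id)
        out.append(cid)
    return out
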