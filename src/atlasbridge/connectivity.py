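"""White-matter connectivity relations and pathway derivation.

Relation vocabulary, by anatomical granularity:

* neuron level — ``innervates``, ``synapses_with`` (symmetric);
* tract level — ``projects_to`` / ``projects_from``: the axons of a
  fiber tract terminate in / originate from a brain region
  (``terminate_in`` / ``originate_in`` are accepted input aliases);
* region level — ``sends_output_to`` / ``receives_input_from``,
  declared subproperties of projects_to / projects_from;
* ``has_pathway`` — the only ternary kind: region A sends output to
  region B *via* a named tract.

The derivation rule reads the ternary definition literally: whenever a
tract projects_from one or more origins and projects_to one or more
terminations, every origin-termination pair gains an inferred
``sends_output_to`` (plus its ``receives_input_from`` dual) and a
``has_pathway`` triple through that tract. Inferred edges are flagged
and recomputed from the asserted set, so derivation is idempotent and
never overwrites an asserted fact.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Optional

from .core import EntityCategory, Ontology, OntologyError

__all__ = [
    "ConnectivityKind",
    "ConnectivityAssertion",
    "assert_connectivity",
    "derive_pathways",
    "inputs_of",
    "outputs_of",
]


class ConnectivityKind(str, Enum):
    INNERVATES = "innervates"
    SYNAPSES_WITH = "synapses_with"
    PROJECTS_TO = "projects_to"
    PROJECTS_FROM = "projects_from"
    SENDS_OUTPUT_TO = "sends_output_to"
    RECEIVES_INPUT_FROM = "receives_input_from"
    HAS_PATHWAY = "has_pathway"


#: input aliases canonicalized on load
KIND_ALIASES = {
    "terminate_in": ConnectivityKind.PROJECTS_TO,
    "terminates_in": ConnectivityKind.PROJECTS_TO,
    "originate_in": ConnectivityKind.PROJECTS_FROM,
    "originates_in": ConnectivityKind.PROJECTS_FROM,
}

#: subproperty -> parent property
SUBPROPERTY_OF = {
    ConnectivityKind.SENDS_OUTPUT_TO: ConnectivityKind.PROJECTS_TO,
    ConnectivityKind.RECEIVES_INPUT_FROM: ConnectivityKind.PROJECTS_FROM,
}

SYMMETRIC_KINDS = frozenset({ConnectivityKind.SYNAPSES_WITH})


def coerce_kind(value: str) -> ConnectivityKind:
    """Canonical kind for a relation name, resolving aliases."""
    try:
        return ConnectivityKind(value)
    except ValueError:
        if value in KIND_ALIASES:
            return KIND_ALIASES[value]
        accepted = sorted(k.value for k in ConnectivityKind) + sorted(KIND_ALIASES)
        raise OntologyError(
            f"unknown connectivity relation {value!r}; accepted: "
            + ", ".join(accepted)) from None


@dataclass(frozen=True, order=True)
class ConnectivityAssertion:
    subject: str
    kind: ConnectivityKind
    object: str
    via: Optional[str] = None
    inferred: bool = False


def _check_material(ontology: Ontology, class_id: str, role: str) -> None:
    cls = ontology.get(class_id)
    if cls.category is not EntityCategory.MATERIAL:
        raise OntologyError(
            f"connectivity {role} {cls.preferred_name!r} must be a material "
            "structure, not an anatomical space")


def assert_connectivity(ontology: Ontology,
                        assertion: ConnectivityAssertion) -> ConnectivityAssertion:
    """Store an asserted connectivity fact after category checks.

    Symmetric kinds are stored once in canonical (sorted-id) order and
    answered in both directions by the query functions.
    """
    kind = coerce_kind(assertion.kind)
    subject, object_, via = assertion.subject, assertion.object, assertion.via
    _check_material(ontology, subject, "subject")
    _check_material(ontology, object_, "object")
    if kind is ConnectivityKind.HAS_PATHWAY:
        if via is None:
            raise OntologyError("has_pathway requires a via tract")
        _check_material(ontology, via, "via tract")
    elif via is not None:
        raise OntologyError(f"{kind.value} does not take a via tract")
    if kind in SYMMETRIC_KINDS and object_ < subject:
        subject, object_ = object_, subject
    stored = ConnectivityAssertion(subject, kind, object_, via, inferred=False)
    if stored not in ontology.connectivity:
        ontology.connectivity.append(stored)
    return stored


def _asserted(ontology: Ontology) -> list[ConnectivityAssertion]:
    return list(ontology.connectivity)


def derive_pathways(ontology: Ontology) -> list[ConnectivityAssertion]:
    """Recompute all inferred region-level edges from asserted facts.

    Per tract T with projects_from(T, A...) and projects_to(T, B...):
    emit sends_output_to(A, B) and has_pathway(A, B, via=T) for every
    (A, B) pair. Additionally every sends_output_to(A, B), asserted or
    derived, gets its receives_input_from(B, A) dual and vice versa.
    Results are deterministic (sorted by class name) and replace any
    previous inferred set; asserted facts are never duplicated.
    """
    asserted = _asserted(ontology)
    asserted_keys = {(a.subject, a.kind, a.object, a.via) for a in asserted}

    origins: dict[str, set[str]] = {}
    terminations: dict[str, set[str]] = {}
    for a in asserted:
        if a.kind is ConnectivityKind.PROJECTS_FROM:
            origins.setdefault(a.subject, set()).add(a.object)
        elif a.kind is ConnectivityKind.PROJECTS_TO:
            terminations.setdefault(a.subject, set()).add(a.object)

    derived: set[tuple[str, ConnectivityKind, str, Optional[str]]] = set()
    for tract in origins.keys() & terminations.keys():
        for a in origins[tract]:
            for b in terminations[tract]:
                derived.add((a, ConnectivityKind.SENDS_OUTPUT_TO, b, None))
                derived.add((a, ConnectivityKind.HAS_PATHWAY, b, tract))

    # duality closure over sends/receives (asserted facts included)
    pairs = {(k[0], k[2]) for k in derived
             if k[1] is ConnectivityKind.SENDS_OUTPUT_TO}
    for a in asserted:
        if a.kind is ConnectivityKind.SENDS_OUTPUT_TO:
            pairs.add((a.subject, a.object))
        elif a.kind is ConnectivityKind.RECEIVES_INPUT_FROM:
            pairs.add((a.object, a.subject))
        elif a.kind is ConnectivityKind.HAS_PATHWAY:
            pairs.add((a.subject, a.object))
    for src, dst in pairs:
        derived.add((src, ConnectivityKind.SENDS_OUTPUT_TO, dst, None))
        derived.add((dst, ConnectivityKind.RECEIVES_INPUT_FROM, src, None))

    derived -= asserted_keys

    def sort_key(key):
        s, kind, o, via = key
        return (ontology.name_of(s), kind.value, ontology.name_of(o),
                ontology.name_of(via) if via else "")

    inferred = [ConnectivityAssertion(s, k, o, v, inferred=True)
                for s, k, o, v in sorted(derived, key=sort_key)]
    ontology.connectivity_inferred = inferred
    return inferred


def _all_edges(ontology: Ontology) -> list[ConnectivityAssertion]:
    return list(ontology.connectivity) + list(ontology.connectivity_inferred)


def _via_index(ontology: Ontology) -> dict[tuple[str, str], str]:
    via: dict[tuple[str, str], str] = {}
    for a in _all_edges(ontology):
        if a.kind is ConnectivityKind.HAS_PATHWAY and a.via is not None:
            via.setdefault((a.subject, a.object), a.via)
    return via


def outputs_of(ontology: Ontology, region: str) -> list[tuple[str, Optional[str]]]:
    """(target, via-tract-or-None) pairs the region sends output to,
    over asserted plus derived edges."""
    ontology.get(region)
    via = _via_index(ontology)
    out: set[tuple[str, Optional[str]]] = set()
    for a in _all_edges(ontology):
        if a.kind is ConnectivityKind.SENDS_OUTPUT_TO and a.subject == region:
            out.add((a.object, via.get((region, a.object))))
        elif a.kind is ConnectivityKind.RECEIVES_INPUT_FROM and a.object == region:
            out.add((a.subject, via.get((region, a.subject))))
        elif a.kind is ConnectivityKind.HAS_PATHWAY and a.subject == region:
            out.add((a.object, a.via))
    return sorted(out, key=lambda t: (ontology.name_of(t[0]), t[1] or ""))


def inputs_of(ontology: Ontology, region: str) -> list[tuple[str, Optional[str]]]:
    """(source, via-tract-or-None) pairs the region receives input from."""
    ontology.get(region)
    via = _via_index(ontology)
    out: set[tuple[str, Optional[str]]] = set()
    for a in _all_edges(ontology):
        if a.kind is ConnectivityKind.RECEIVES_INPUT_FROM and a.subject == region:
            out.add((a.object, via.get((a.object, region))))
        elif a.kind is ConnectivityKind.SENDS_OUTPUT_TO and a.object == region:
            out.add((a.subject, via.get((a.subject, region))))
        elif a.kind is ConnectivityKind.HAS_PATHWAY and a.object == region:
            out.add((a.subject, a.via))
    return sorted(out, key=lambda t: (ontology.name_of(t[0]), t[1] or ""))
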