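"""Serialization: a Turtle ontology file plus TSV side tables.

A saved bundle is a directory::

    ontology.ttl       classes, structural edges, sulcus adjacency,
                       reified has_pathway triples (RDF/Turtle)
    bindings.tsv       scheme, label, class_id, external_id
    connectivity.tsv   subject, kind, object, via, provenance

The Turtle file is written by a small canonical serializer (fixed
prefixes, triples emitted in sorted order) so that saving the same
ontology twice produces byte-identical files; rdflib does the parsing on
load. Bindings and connectivity are loaded from the TSVs (curators edit
those by hand); the reified pathway triples in the Turtle are a
convenience for RDF consumers.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
import rdflib
from rdflib import Namespace, RDF, RDFS, URIRef

from . import __version__
from .connectivity import ConnectivityAssertion, ConnectivityKind, coerce_kind
from .core import (
    EntityCategory,
    Laterality,
    Ontology,
    OntologyClass,
    OntologyError,
    RelationKind,
)
from .labels import SchemeId
from .mapping import TerminologyBinding

__all__ = ["save", "load", "BundleError"]

CLASS_NS = Namespace("urn:atlasbridge:class:")
REL_NS = Namespace("urn:atlasbridge:relation:")
PATHWAY_NS = Namespace("urn:atlasbridge:pathway:")

ANATOMICAL_CLASS = REL_NS["AnatomicalClass"]
PATHWAY_STATEMENT = REL_NS["PathwayStatement"]

_STRUCTURAL_IRIS = {kind.value: kind for kind in RelationKind}


class BundleError(OntologyError):
    pass


def _iri(class_id: str) -> URIRef:
    # class ids are "na:slug"; the slug becomes the local name
    return CLASS_NS[class_id.split(":", 1)[-1]]


def _id_from_iri(iri: URIRef) -> str:
    return "na:" + str(iri)[len(str(CLASS_NS)):]


def _ttl_escape(text: str) -> str:
    return text.replace("\\", "\\\\").replace('"', '\\"').replace("\n", "\\n")


def _write_turtle(ontology: Ontology) -> str:
    """Canonical Turtle text: sorted subjects, predicates and objects."""
    lines = [
        f"# atlasbridge ontology bundle (tool version {__version__})",
        f"@prefix cls: <{CLASS_NS}> .",
        f"@prefix rel: <{REL_NS}> .",
        f"@prefix pw: <{PATHWAY_NS}> .",
        "@prefix rdf: <http://www.w3.org/1999/02/22-rdf-syntax-ns#> .",
        "@prefix rdfs: <http://www.w3.org/2000/01/rdf-schema#> .",
        "",
    ]

    def local(class_id: str) -> str:
        return "cls:" + class_id.split(":", 1)[-1]

    for cid in sorted(ontology.classes):
        cls = ontology.classes[cid]
        lines.append(f"{local(cid)} rdf:type rel:AnatomicalClass ;")
        lines.append(f'    rdfs:label "{_ttl_escape(cls.preferred_name)}" ;')
        for syn in sorted(cls.synonyms):
            lines.append(f'    rel:synonym "{_ttl_escape(syn)}" ;')
        if cls.definition:
            lines.append(f'    rel:definition "{_ttl_escape(cls.definition)}" ;')
        lines.append(f'    rel:laterality "{cls.laterality.value}" ;')
        lines.append(f'    rel:category "{cls.category.value}" .')
        lines.append("")

    edges = sorted((a.subject, a.relation.value, a.object)
                   for a in ontology.structural)
    for s, rel, o in edges:
        lines.append(f"{local(s)} rel:{rel} {local(o)} .")
    if edges:
        lines.append("")

    links = sorted((sulcus, seg) for sulcus, segs in ontology.sulcus_links.items()
                   for seg in segs)
    for sulcus, seg in links:
        lines.append(f"{local(sulcus)} rel:has_adjacent_sulcal_segment {local(seg)} .")
    if links:
        lines.append("")

    # reified ternary pathway statements with deterministic node names
    pathways = sorted(
        (a.subject, a.object, a.via, a.inferred)
        for a in list(ontology.connectivity) + list(ontology.connectivity_inferred)
        if a.kind is ConnectivityKind.HAS_PATHWAY and a.via)
    for s, o, via, inferred in pathways:
        node = "pw:" + "--".join(x.split(":", 1)[-1] for x in (s, o, via))
        lines.append(f"{node} rdf:type rel:PathwayStatement ;")
        lines.append(f"    rel:pathway_origin {local(s)} ;")
        lines.append(f"    rel:pathway_termination {local(o)} ;")
        lines.append(f"    rel:pathway_via {local(via)} ;")
        lines.append(f'    rel:provenance "{"inferred" if inferred else "asserted"}" .')
        lines.append("")

    return "\n".join(lines).rstrip() + "\n"


def _bindings_frame(ontology: Ontology) -> pd.DataFrame:
    rows = [
        {"scheme": b.scheme.value, "label": b.external_label,
         "class_id": b.class_id, "external_id": b.external_id or ""}
        for b in ontology.bindings.values()
    ]
    frame = pd.DataFrame(rows, columns=["scheme", "label", "class_id",
                                        "external_id"])
    return frame.sort_values(["scheme", "label"]).reset_index(drop=True)


def _connectivity_frame(ontology: Ontology) -> pd.DataFrame:
    rows = [
        {"subject": a.subject, "kind": a.kind.value, "object": a.object,
         "via": a.via or "",
         "provenance": "inferred" if a.inferred else "asserted"}
        for a in list(ontology.connectivity) + list(ontology.connectivity_inferred)
    ]
    frame = pd.DataFrame(rows, columns=["subject", "kind", "object", "via",
                                        "provenance"])
    return frame.sort_values(["provenance", "subject", "kind", "object",
                              "via"]).reset_index(drop=True)


def save(ontology: Ontology, path: str | Path) -> Path:
    """Write the bundle directory; returns its path.

    Output is deterministic: no timestamps, canonical ordering
    everywhere, so identical ontologies give byte-identical files.
    """
    root = Path(path)
    root.mkdir(parents=True, exist_ok=True)
    (root / "ontology.ttl").write_text(_write_turtle(ontology))
    _bindings_frame(ontology).to_csv(root / "bindings.tsv", sep="\t",
                                     index=False)
    _connectivity_frame(ontology).to_csv(root / "connectivity.tsv", sep="\t",
                                         index=False)
    return root


def load(path: str | Path) -> Ontology:
    """Parse a bundle directory back into an Ontology.

    Referential integrity is enforced: a triple or table row naming an
    undeclared class is an error, as is an unknown relation IRI.
    """
    root = Path(path)
    ttl = root / "ontology.ttl"
    if not ttl.exists():
        raise BundleError(f"{root}: no ontology.ttl")
    graph = rdflib.Graph()
    try:
        graph.parse(ttl, format="turtle")
    except Exception as exc:  # rdflib raises several parse error types
        raise BundleError(f"{ttl}: malformed Turtle: {exc}") from exc

    onto = Ontology()

    declared = sorted(graph.subjects(RDF.type, ANATOMICAL_CLASS))
    meta: dict[URIRef, dict] = {}
    for node in declared:
        labels = list(graph.objects(node, RDFS.label))
        if len(labels) != 1:
            raise BundleError(f"{node}: expected exactly one rdfs:label")
        lat = graph.value(node, REL_NS["laterality"])
        cat = graph.value(node, REL_NS["category"])
        definition = graph.value(node, REL_NS["definition"])
        meta[node] = dict(
            id=_id_from_iri(node),
            preferred_name=str(labels[0]),
            synonyms=frozenset(str(s) for s in graph.objects(node, REL_NS["synonym"])),
            laterality=Laterality(str(lat)) if lat else Laterality.UNPAIRED,
            category=EntityCategory(str(cat)) if cat else EntityCategory.MATERIAL,
            definition=str(definition) if definition else None,
        )
    for node in declared:
        onto.add_class(OntologyClass(**meta[node]))

    known_rel = {REL_NS[k] for k in _STRUCTURAL_IRIS}
    skip_pred = {RDF.type, RDFS.label, REL_NS["synonym"], REL_NS["definition"],
                 REL_NS["laterality"], REL_NS["category"],
                 REL_NS["has_adjacent_sulcal_segment"],
                 REL_NS["pathway_origin"], REL_NS["pathway_termination"],
                 REL_NS["pathway_via"], REL_NS["provenance"]}

    def require_class(iri: URIRef, context: str) -> str:
        cid = _id_from_iri(iri)
        if cid not in onto.classes:
            raise BundleError(f"{context}: references undeclared class {iri}")
        return cid

    for s, p, o in graph:
        if p in skip_pred or not str(p).startswith(str(REL_NS)):
            continue
        if p not in known_rel:
            accepted = ", ".join(sorted(_STRUCTURAL_IRIS))
            raise BundleError(
                f"unknown relation IRI {p}; accepted structural relations: "
                f"{accepted}")
        kind = _STRUCTURAL_IRIS[str(p)[len(str(REL_NS)):]]
        onto.assert_structural(require_class(s, str(p)), kind,
                               require_class(o, str(p)))

    for s, o in graph.subject_objects(REL_NS["has_adjacent_sulcal_segment"]):
        onto.sulcus_links.setdefault(
            require_class(s, "sulcus link"), set()).add(
            require_class(o, "sulcus link"))

    btsv = root / "bindings.tsv"
    if btsv.exists():
        frame = pd.read_csv(btsv, sep="\t", dtype=str).fillna("")
        for row in frame.itertuples(index=False):
            if row.class_id not in onto.classes:
                raise BundleError(
                    f"bindings.tsv: unknown class {row.class_id!r}")
            binding = TerminologyBinding(
                class_id=row.class_id, scheme=SchemeId(row.scheme),
                external_label=row.label,
                external_id=row.external_id or None)
            onto.bindings[(binding.scheme, binding.external_label)] = binding

    ctsv = root / "connectivity.tsv"
    if ctsv.exists():
        frame = pd.read_csv(ctsv, sep="\t", dtype=str).fillna("")
        for row in frame.itertuples(index=False):
            for cid in (row.subject, row.object) + ((row.via,) if row.via else ()):
                if cid not in onto.classes:
                    raise BundleError(
                        f"connectivity.tsv: unknown class {cid!r}")
            assertion = ConnectivityAssertion(
                subject=row.subject, kind=coerce_kind(row.kind),
                object=row.object, via=row.via or None,
                inferred=row.provenance == "inferred")
            if assertion.inferred:
                onto.connectivity_inferred.append(assertion)
            else:
                onto.connectivity.append(assertion)

    return onto
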