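"""Semi-automatic atlas-label -> ontology-class mapping with curation.

Candidate mappings are generated by four methods, in decreasing order of
confidence:

* **exact** — the label text equals a class's preferred name;
* **synonym** — it equals a recorded synonym;
* **abbreviation** — after abbreviation expansion and side extraction,
  the token multiset equals the class name's (or a synonym's) tokens;
* **lexical** — one token set (stopwords removed) contains the other;
  scored by Jaccard overlap.

A human curation pass turns accepted candidates into terminology
bindings — the slot linking a class to one scheme's label/identifier.
Bindings are unique per (scheme, label) and are not inherited down the
taxonomy: each class carries its own.
"""

from __future__ import annotations

import warnings as _warnings
from collections import Counter
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Optional, Sequence

from .core import Laterality, Ontology, OntologyError, _normkey
from .labels import STOPWORDS, NormalizedLabel, SchemeId, normalize_label

__all__ = [
    "MappingMethod",
    "MappingCandidate",
    "TerminologyBinding",
    "CurationDecision",
    "CurationError",
    "UnmappedLabelError",
    "generate_candidates",
    "apply_curation",
    "lookup_by_binding",
]

#: minimum lexical Jaccard score worth reporting
LEXICAL_THRESHOLD = 0.5


class MappingMethod(str, Enum):
    EXACT = "exact"
    SYNONYM = "synonym"
    ABBREVIATION = "abbreviation"
    LEXICAL = "lexical"


#: candidate sort order: higher-confidence methods first
_PRECEDENCE = {
    MappingMethod.EXACT: 0,
    MappingMethod.SYNONYM: 1,
    MappingMethod.ABBREVIATION: 2,
    MappingMethod.LEXICAL: 3,
}


@dataclass(frozen=True)
class MappingCandidate:
    label: NormalizedLabel
    class_id: str
    method: MappingMethod
    score: float

    def sort_key(self, ontology: Ontology):
        return (_PRECEDENCE[self.method], -self.score,
                ontology.name_of(self.class_id))


@dataclass(frozen=True)
class TerminologyBinding:
    class_id: str
    scheme: SchemeId
    external_label: str
    external_id: Optional[str] = None


@dataclass(frozen=True)
class CurationDecision:
    """One curator verdict for a (scheme, label) pair.

    ``accepted_class`` of None records an explicit rejection.
    """

    scheme: SchemeId
    label: str
    accepted_class: Optional[str]
    note: str = ""


class CurationError(OntologyError):
    pass


class UnmappedLabelError(KeyError):
    """Label has no binding; carries nearest candidates for diagnosis."""

    def __init__(self, scheme: SchemeId, label: str,
                 nearest: Sequence[MappingCandidate] = ()):
        self.scheme = scheme
        self.label = label
        self.nearest = tuple(nearest)
        hint = ""
        if nearest:
            hint = "; nearest candidates: " + ", ".join(
                f"{c.class_id} ({c.method.value}, {c.score:.2f})"
                for c in nearest[:3])
        super().__init__(f"no {scheme.value} binding for label {label!r}{hint}")


def _content_tokens(tokens: Iterable[str]) -> frozenset[str]:
    return frozenset(t for t in tokens if t not in STOPWORDS)


def _label_multiset(label: NormalizedLabel) -> Counter:
    toks = Counter(label.tokens)
    if label.laterality is not Laterality.UNPAIRED:
        toks[label.laterality.value] += 1
    return toks


def candidates_for(label: NormalizedLabel, ontology: Ontology) -> list[MappingCandidate]:
    """All candidate classes for one normalized label, best first."""
    raw_key = _normkey(label.raw)
    expanded = _label_multiset(label)
    label_content = _content_tokens(expanded)

    found: dict[str, MappingCandidate] = {}

    def offer(class_id: str, method: MappingMethod, score: float) -> None:
        prev = found.get(class_id)
        if prev is None or _PRECEDENCE[method] < _PRECEDENCE[prev.method]:
            found[class_id] = MappingCandidate(label, class_id, method, score)

    for cid in ontology.classes:
        cls = ontology.classes[cid]
        name_key = _normkey(cls.preferred_name)
        syn_keys = {_normkey(s) for s in cls.synonyms}

        if raw_key == name_key:
            offer(cid, MappingMethod.EXACT, 1.0)
            continue
        if raw_key in syn_keys:
            offer(cid, MappingMethod.SYNONYM, 1.0)
            continue
        # expanded-token comparison (abbreviation method)
        name_ms = Counter(name_key.split())
        if expanded == name_ms or any(
                expanded == Counter(k.split()) for k in syn_keys):
            offer(cid, MappingMethod.ABBREVIATION, 1.0)
            continue
        # lexical containment either way, Jaccard-scored
        name_content = _content_tokens(name_key.split())
        if not label_content or not name_content:
            continue
        if label_content <= name_content or name_content <= label_content:
            inter = len(label_content & name_content)
            union = len(label_content | name_content)
            score = inter / union
            if score >= LEXICAL_THRESHOLD:
                offer(cid, MappingMethod.LEXICAL, score)

    return sorted(found.values(), key=lambda c: c.sort_key(ontology))


def generate_candidates(
    labels: Sequence[NormalizedLabel], ontology: Ontology
) -> dict[str, list[MappingCandidate]]:
    """Candidate groups keyed by raw label text, each sorted by method
    precedence, then score, then class name. Labels with no candidates
    map to an empty ("unmapped") group.
    """
    return {lab.raw: candidates_for(lab, ontology) for lab in labels}


def apply_curation(
    candidates: dict[str, list[MappingCandidate]],
    decisions: Sequence[CurationDecision],
    ontology: Ontology,
    auto_accept_exact: bool = False,
) -> list[TerminologyBinding]:
    """Turn curation decisions (plus optional auto-accepted unambiguous
    exact matches) into bindings stored on the ontology.

    Accepting a class that was never proposed is honored with a warning
    (curator override); two decisions accepting different classes for
    one (scheme, label) is an error.
    """
    accepted: dict[tuple[SchemeId, str], CurationDecision] = {}
    for d in decisions:
        key = (d.scheme, d.label)
        if d.accepted_class is None:
            accepted.setdefault(key, d)
            continue
        if key in accepted and accepted[key].accepted_class not in (
                None, d.accepted_class):
            raise CurationError(
                f"conflicting curation for {d.scheme.value} label "
                f"{d.label!r}: {accepted[key].accepted_class} vs "
                f"{d.accepted_class}")
        accepted[key] = d

    created: list[TerminologyBinding] = []

    def bind(scheme: SchemeId, label: str, class_id: str,
             external_id: Optional[str] = None) -> None:
        if class_id not in ontology.classes:
            raise CurationError(f"accepted class {class_id!r} does not exist")
        key = (scheme, label)
        existing = ontology.bindings.get(key)
        if existing is not None:
            if existing.class_id != class_id:
                raise CurationError(
                    f"{scheme.value} label {label!r} already bound to "
                    f"{existing.class_id}")
            return
        binding = TerminologyBinding(class_id, scheme, label, external_id)
        ontology.bindings[key] = binding
        created.append(binding)

    for d in accepted.values():
        if d.accepted_class is None:
            continue
        group = candidates.get(d.label, [])
        if d.accepted_class not in {c.class_id for c in group}:
            _warnings.warn(
                f"curator override: {d.scheme.value} label {d.label!r} "
                f"accepted for {d.accepted_class}, which was not among the "
                "generated candidates", stacklevel=2)
        bind(d.scheme, d.label, d.accepted_class)

    if auto_accept_exact:
        decided = set(accepted)
        for raw, group in candidates.items():
            exact = [c for c in group if c.method is MappingMethod.EXACT]
            if len(exact) != 1:
                continue
            key = (exact[0].label.scheme, raw)
            if key in decided or key in ontology.bindings:
                continue
            bind(exact[0].label.scheme, raw, exact[0].class_id)

    return created


def lookup_by_binding(ontology: Ontology, scheme: SchemeId,
                      external_label: str) -> str:
    """Class id bound to (scheme, label); exact match first, then
    case-insensitive. Raises :class:`UnmappedLabelError` with nearest
    candidates otherwise.
    """
    scheme = SchemeId(scheme)
    key = (scheme, external_label)
    if key in ontology.bindings:
        return ontology.bindings[key].class_id
    for (s, lab), b in ontology.bindings.items():
        if s is scheme and _normkey(lab) == _normkey(external_label):
            return b.class_id
    try:
        normalized = normalize_label(scheme, external_label)
        nearest = candidates_for(normalized, ontology)
    except Exception:
        nearest = []
    raise UnmappedLabelError(scheme, external_label, nearest)


def add_binding(ontology: Ontology, class_id: str, scheme: SchemeId,
                external_label: str, external_id: Optional[str] = None
                ) -> TerminologyBinding:
    """Directly record a curated binding (used by fixture builders and
    bundle loading); enforces (scheme, label) uniqueness."""
    scheme = SchemeId(scheme)
    if class_id not in ontology.classes:
        raise CurationError(f"cannot bind unknown class {class_id!r}")
    key = (scheme, external_label)
    existing = ontology.bindings.get(key)
    if existing is not None and existing.class_id != class_id:
        raise CurationError(
            f"{scheme.value} label {external_label!r} already bound to "
            f"{existing.class_id}")
    binding = TerminologyBinding(class_id, scheme, external_label, external_id)
    ontology.bindings[key] = binding
    return binding
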