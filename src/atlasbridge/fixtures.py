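"""Deterministic fixture builders.

``build_reference_fixture`` assembles the worked mini-ontology every
example in this package's documentation and test suite runs against: the
frontal-lobe partonomy with Brodmann-by-gyrus intersections, the
lateralized superior-frontal chain with its four terminology bindings
(Talairach, DK/FreeSurfer, AAL, NeuroLex), the corticospinal-tract
partition, SLF I connectivity, sulcal segments of the middle frontal
sulcus, and a small basal-ganglia connectivity neighborhood.

``random_ontology`` generates seeded layered DAGs with ground-truth
closure tables and perturbed labels for property and recovery tests.
Everything is rebuilt programmatically; no download or bundled data file
is ever needed.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, replace

from .connectivity import ConnectivityAssertion, ConnectivityKind, assert_connectivity
from .core import EntityCategory, Laterality, Ontology, RelationKind
from .labels import SchemeId
from .mapping import add_binding
from .patterns import (
    IntersectionSpec,
    TractPartition,
    create_intersection_class,
    create_sulcal_segment,
    lateralize,
    partition_tract,
)

__all__ = ["build_reference_fixture", "FixtureSpec", "random_ontology"]

SYNTHETIC_NOTE = ("synthetic fixture content: plausible placeholder, not a "
                  "published assertion")

#: the five frontal gyri whose gray matter overlaps Brodmann area 6
BA6_GYRI = ("precentral gyrus", "superior frontal gyrus", "middle frontal gyrus",
            "inferior frontal gyrus", "medial frontal gyrus")

#: Brodmann areas overlapping the gray matter of the superior frontal gyrus
SFG_AREAS = ("6", "8", "9", "10", "11")

TALAIRACH_BA6 = ("Right Cerebrum.Frontal Lobe.Superior Frontal Gyrus."
                 "Gray Matter.Brodmann area 6")
TALAIRACH_BA20 = ("Right Cerebrum.Temporal Lobe.Inferior Temporal Gyrus."
                  "Gray Matter.Brodmann area 20")

#: corticospinal segment names, brain to spinal cord (synthetic naming)
CORTICOSPINAL_SEGMENTS = (
    "Corona radiata segment of corticospinal tract",
    "Internal capsule segment of corticospinal tract",
    "Cerebral peduncle segment of corticospinal tract",
    "Pontine segment of corticospinal tract",
    "Pyramidal segment of corticospinal tract",
    "Spinal segment of corticospinal tract",
)


def _title(phrase: str) -> str:
    return phrase[0].upper() + phrase[1:]


def build_reference_fixture() -> Ontology:
    """Build the reference mini-ontology; validates clean by design."""
    onto = Ontology()

    # ---- hemisphere / lobe scaffolding, unpaired plus lateralized ----
    hemi = onto.new_class("Cerebral hemisphere")
    _, right_hemi = lateralize(onto, hemi)
    left_hemi = onto.resolve_name("Left cerebral hemisphere")

    frontal = onto.new_class("Frontal lobe")
    left_frontal, right_frontal = lateralize(onto, frontal)
    onto.assert_structural(frontal, RelationKind.REGIONAL_PART_OF, hemi)
    onto.assert_structural(right_frontal, RelationKind.REGIONAL_PART_OF, right_hemi)
    onto.assert_structural(left_frontal, RelationKind.REGIONAL_PART_OF, left_hemi)

    temporal = onto.new_class("Temporal lobe")
    _, right_temporal = lateralize(onto, temporal)
    onto.assert_structural(temporal, RelationKind.REGIONAL_PART_OF, hemi)
    onto.assert_structural(right_temporal, RelationKind.REGIONAL_PART_OF, right_hemi)

    parietal = onto.new_class("Parietal lobe")
    onto.assert_structural(parietal, RelationKind.REGIONAL_PART_OF, hemi)
    occipital = onto.new_class("Occipital lobe")
    onto.assert_structural(occipital, RelationKind.REGIONAL_PART_OF, hemi)

    # ---- frontal gyri and their gray matter ----
    gm_classes: dict[str, str] = {}
    for gyrus_phrase in BA6_GYRI:
        gid = onto.new_class(_title(gyrus_phrase))
        onto.assert_structural(gid, RelationKind.REGIONAL_PART_OF, frontal)
        gm = onto.new_class(f"Gray matter of {gyrus_phrase}")
        onto.assert_structural(gm, RelationKind.REGIONAL_PART_OF, gid)
        gm_classes[gyrus_phrase] = gm

    # ---- Brodmann areas (unpaired) ----
    ba_classes: dict[str, str] = {}
    for n in SFG_AREAS:
        ba_classes[n] = onto.new_class(f"Brodmann area {n}")

    # GM of superior frontal gyrus overlaps Brodmann areas 6, 8, 9, 10, 11
    gm_sfg = gm_classes["superior frontal gyrus"]
    for n in SFG_AREAS:
        create_intersection_class(onto, IntersectionSpec(
            gyral_gm_class=gm_sfg, brodmann_class=ba_classes[n]))

    # Brodmann area 6 overlaps the gray matter of the five frontal gyri
    for gyrus_phrase in BA6_GYRI:
        create_intersection_class(onto, IntersectionSpec(
            gyral_gm_class=gm_classes[gyrus_phrase],
            brodmann_class=ba_classes["6"]))

    # ---- lateralized superior-frontal chain (the correlation star) ----
    sfg = onto.resolve_name("Superior frontal gyrus")
    _, right_sfg = lateralize(onto, sfg)
    onto.assert_structural(right_sfg, RelationKind.REGIONAL_PART_OF, right_frontal)
    gm_right_sfg = onto.new_class("Gray matter of right superior frontal gyrus",
                                  laterality=Laterality.RIGHT)
    onto.assert_structural(gm_right_sfg, RelationKind.REGIONAL_PART_OF, right_sfg)
    onto.assert_structural(gm_right_sfg, RelationKind.IS_A, gm_sfg)
    right_ba6 = onto.new_class("Right Brodmann area 6", laterality=Laterality.RIGHT)
    onto.assert_structural(right_ba6, RelationKind.IS_A, ba_classes["6"])
    ba6_right_sfg = create_intersection_class(onto, IntersectionSpec(
        gyral_gm_class=gm_right_sfg, brodmann_class=right_ba6,
        laterality=Laterality.RIGHT))

    # ---- postcentral (for the DK left-hemisphere example) ----
    postcentral = onto.new_class("Postcentral gyrus")
    left_postcentral, _ = lateralize(onto, postcentral)
    onto.assert_structural(postcentral, RelationKind.REGIONAL_PART_OF, parietal)
    gm_left_postcentral = onto.new_class(
        "Gray matter of left postcentral gyrus", laterality=Laterality.LEFT)
    onto.assert_structural(gm_left_postcentral, RelationKind.REGIONAL_PART_OF,
                           left_postcentral)

    # ---- temporal chain (Talairach BA20 annotation example) ----
    itg = onto.new_class("Inferior temporal gyrus")
    _, right_itg = lateralize(onto, itg)
    onto.assert_structural(itg, RelationKind.REGIONAL_PART_OF, temporal)
    onto.assert_structural(right_itg, RelationKind.REGIONAL_PART_OF, right_temporal)
    gm_itg = onto.new_class("Gray matter of inferior temporal gyrus")
    onto.assert_structural(gm_itg, RelationKind.REGIONAL_PART_OF, itg)
    ba20 = onto.new_class("Brodmann area 20")
    create_intersection_class(onto, IntersectionSpec(
        gyral_gm_class=gm_itg, brodmann_class=ba20))
    gm_right_itg = onto.new_class("Gray matter of right inferior temporal gyrus",
                                  laterality=Laterality.RIGHT)
    onto.assert_structural(gm_right_itg, RelationKind.REGIONAL_PART_OF, right_itg)
    onto.assert_structural(gm_right_itg, RelationKind.IS_A, gm_itg)
    right_ba20 = onto.new_class("Right Brodmann area 20",
                                laterality=Laterality.RIGHT)
    onto.assert_structural(right_ba20, RelationKind.IS_A, ba20)
    ba20_right_itg = create_intersection_class(onto, IntersectionSpec(
        gyral_gm_class=gm_right_itg, brodmann_class=right_ba20,
        laterality=Laterality.RIGHT))

    # ---- parietal target of SLF I ----
    spl = onto.new_class("Superior parietal lobule")
    onto.assert_structural(spl, RelationKind.REGIONAL_PART_OF, parietal)
    gm_spl = onto.new_class("Gray matter of superior parietal lobule")
    onto.assert_structural(gm_spl, RelationKind.REGIONAL_PART_OF, spl)
    ba5 = onto.new_class("Brodmann area 5")
    ba5_spl = create_intersection_class(onto, IntersectionSpec(
        gyral_gm_class=gm_spl, brodmann_class=ba5))
    ba6_sfg = onto.resolve_name("Brodmann area 6 of superior frontal gyrus")

    # ---- white matter: SLF partition and its projections ----
    slf = onto.new_class("Superior longitudinal fasciculus")
    slf_segments = partition_tract(onto, TractPartition(
        tract=slf,
        segment_names=(
            "Dorsal segment of superior longitudinal fasciculus",
            "Middle segment of superior longitudinal fasciculus",
            "Ventral segment of superior longitudinal fasciculus",
        )))
    slf1 = slf_segments[0]
    onto.add_synonym(slf1, "SLF I")
    assert_connectivity(onto, ConnectivityAssertion(
        slf1, ConnectivityKind.PROJECTS_FROM, ba6_sfg))
    assert_connectivity(onto, ConnectivityAssertion(
        slf1, ConnectivityKind.PROJECTS_TO, ba5_spl))

    # ---- corticospinal tract partition ----
    cst = onto.new_class("Corticospinal tract")
    partition_tract(onto, TractPartition(
        tract=cst, segment_names=CORTICOSPINAL_SEGMENTS))
    for seg_name in CORTICOSPINAL_SEGMENTS:
        seg = onto.resolve_name(seg_name)
        onto.classes[seg] = replace(onto.classes[seg], definition=SYNTHETIC_NOTE)

    # ---- sulci ----
    mfs = onto.new_class("Middle frontal sulcus", category=EntityCategory.SPACE)
    mfg = onto.resolve_name("Middle frontal gyrus")
    ifg = onto.resolve_name("Inferior frontal gyrus")
    create_sulcal_segment(onto, mfg, mfs)
    create_sulcal_segment(onto, ifg, mfs)

    # ---- basal ganglia connectivity neighborhood (synthetic edges) ----
    putamen = onto.new_class("Putamen", definition=SYNTHETIC_NOTE)
    gpe = onto.new_class("Globus pallidus", definition=SYNTHETIC_NOTE)
    thalamus = onto.new_class("Thalamus", definition=SYNTHETIC_NOTE)
    assert_connectivity(onto, ConnectivityAssertion(
        ba6_sfg, ConnectivityKind.SENDS_OUTPUT_TO, putamen))
    assert_connectivity(onto, ConnectivityAssertion(
        putamen, ConnectivityKind.SENDS_OUTPUT_TO, gpe))
    assert_connectivity(onto, ConnectivityAssertion(
        putamen, ConnectivityKind.RECEIVES_INPUT_FROM, thalamus))

    # ---- NeuroLex mapping material ----
    thlv = onto.new_class("Temporal horn of lateral ventricle",
                          synonyms={"Inferior horn of the lateral ventricle"},
                          category=EntityCategory.SPACE)
    log = onto.new_class("Lateral occipital gyrus")
    onto.assert_structural(log, RelationKind.REGIONAL_PART_OF, occipital)
    clog = onto.new_class("Cortex of lateral occipital gyrus")
    onto.assert_structural(clog, RelationKind.REGIONAL_PART_OF, log)

    # ---- terminology bindings (curated) ----
    add_binding(onto, ba6_right_sfg, SchemeId.TALAIRACH, TALAIRACH_BA6)
    add_binding(onto, ba20_right_itg, SchemeId.TALAIRACH, TALAIRACH_BA20)
    add_binding(onto, gm_right_sfg, SchemeId.DK, "ctx-rh-superiorfrontal")
    add_binding(onto, gm_left_postcentral, SchemeId.DK, "ctx-lh-postcentral")
    add_binding(onto, right_sfg, SchemeId.AAL, "Frontal_superior_right")
    add_binding(onto, sfg, SchemeId.NEUROLEX, "Superior frontal gyrus",
                external_id="nlx_fixture_0001")
    add_binding(onto, right_frontal, SchemeId.NEUROLEX, "Right frontal lobe",
                external_id="nlx_fixture_0002")
    add_binding(onto, thlv, SchemeId.NEUROLEX,
                "Inferior horn of the lateral ventricle",
                external_id="nlx_fixture_0003")
    add_binding(onto, clog, SchemeId.NEUROLEX, "Lateral occipital cortex",
                external_id="nlx_fixture_0004")
    add_binding(onto, itg, SchemeId.NEUROLEX, "Inferior temporal gyrus",
                external_id="nlx_fixture_0005")

    return onto


# --------------------------------------------------------------- random DAGs


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of one seeded random ontology.

    Layered generation keeps every relation graph acyclic by
    construction: edges only point from a layer to strictly earlier
    layers.
    """

    seed: int
    n_classes: int = 50
    n_layers: int = 5
    part_density: float = 1.5       # mean part_of out-edges per class
    regional_density: float = 0.5   # mean regional_part_of out-edges
    is_a_density: float = 0.5       # mean is_a out-edges
    n_labels: int = 20
    perturbations: tuple[str, ...] = ("exact", "case", "abbreviation", "synonym")


_WORD_REVERSE = {  # expansion -> abbreviation, mirrors the default tables
    "superior": "sup", "inferior": "inf", "middle": "mid", "medial": "med",
    "lateral": "lat", "anterior": "ant", "posterior": "post",
    "cortex": "ctx", "white matter": "wm", "gray matter": "gm",
}

_ADJ1 = ("superior", "inferior", "middle", "medial", "lateral", "anterior",
         "posterior")
_ADJ2 = ("frontal", "parietal", "temporal", "occipital", "central", "limbic")
_NOUN = ("gyrus", "lobe", "region", "cortex", "segment", "zone")


def random_ontology(spec: FixtureSpec):
    """Seeded random layered ontology plus ground truth.

    Returns ``(ontology, truth)`` where ``truth`` carries, per relation
    kind, the generator-side transitive-closure sets, and a list of
    ``(scheme, raw_label, class_id, perturbation)`` records whose true
    class the mapping engine should recover.
    """
    if spec.n_classes < spec.n_layers:
        raise ValueError("need at least one class per layer")
    rng = random.Random(spec.seed)

    onto = Ontology()
    layers: list[list[str]] = [[] for _ in range(spec.n_layers)]
    for i in range(spec.n_classes):
        phrase = (f"{rng.choice(_ADJ1)} {rng.choice(_ADJ2)} "
                  f"{rng.choice(_NOUN)} {i}")
        cid = onto.new_class(_title(phrase))
        layers[i * spec.n_layers // spec.n_classes].append(cid)

    def add_edges(kind: RelationKind, density: float) -> None:
        for li in range(1, spec.n_layers):
            for cid in layers[li]:
                pool = [c for lj in range(li) for c in layers[lj]]
                k = min(len(pool), _poisson(rng, density))
                for target in rng.sample(pool, k):
                    try:
                        onto.assert_structural(cid, kind, target)
                    except Exception:  # duplicate edge attempt is fine
                        pass

    add_edges(RelationKind.PART_OF, spec.part_density)
    add_edges(RelationKind.REGIONAL_PART_OF, spec.regional_density)
    add_edges(RelationKind.IS_A, spec.is_a_density)

    closures = {kind: _brute_force_closure(onto, kind)
                for kind in RelationKind}

    # ground-truth labels: perturb class names per perturbation kind
    label_truth: list[tuple[SchemeId, str, str, str]] = []
    ids = sorted(onto.classes)
    for _ in range(spec.n_labels):
        cid = rng.choice(ids)
        name = onto.classes[cid].preferred_name
        kind = rng.choice(spec.perturbations)
        if kind == "exact":
            raw = name
        elif kind == "case":
            raw = "".join(ch.upper() if rng.random() < 0.5 else ch.lower()
                          for ch in name)
        elif kind == "abbreviation":
            words = name.lower().split()
            raw = " ".join(_WORD_REVERSE.get(w, w) for w in words)
        elif kind == "synonym":
            syn = f"{name} (alt {rng.randrange(10**6)})"
            onto.add_synonym(cid, syn)
            raw = syn
        else:
            raise ValueError(f"unknown perturbation {kind!r}")
        label_truth.append((SchemeId.NEUROLEX, raw, cid, kind))

    truth = {"closures": closures, "labels": label_truth}
    return onto, truth


def _poisson(rng: random.Random, lam: float) -> int:
    # inverse-CDF sampling; lambdas here are tiny
    import math
    u = rng.random()
    p = math.exp(-lam)
    cdf = p
    k = 0
    while u > cdf and k < 100:
        k += 1
        p *= lam / k
        cdf += p
    return k


def _brute_force_closure(onto: Ontology, kind: RelationKind) -> dict[str, set[str]]:
    """Naive per-node DFS reachability, independent of Ontology.ancestors."""
    from .core import _CLOSURE_KINDS
    kinds = _CLOSURE_KINDS[kind]
    adj: dict[str, list[str]] = {}
    for a in onto.structural:
        if a.relation in kinds:
            adj.setdefault(a.subject, []).append(a.object)
    out: dict[str, set[str]] = {}
    for cid in onto.classes:
        seen: set[str] = set()
        stack = list(adj.get(cid, []))
        while stack:
            node = stack.pop()
            if node in seen:
                continue
            seen.add(node)
            stack.extend(adj.get(node, []))
        out[cid] = seen
    return out
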