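"""Candidate generation, curation and binding lookup."""

import pytest

from atlasbridge import (
    CurationDecision,
    MappingMethod,
    SchemeId,
    apply_curation,
    generate_candidates,
    lookup_by_binding,
    normalize_label,
)
from atlasbridge.fixtures import FixtureSpec, random_ontology
from atlasbridge.mapping import (
    CurationError,
    UnmappedLabelError,
    candidates_for,
    LEXICAL_THRESHOLD,
)
from atlasbridge.labels import STOPWORDS


def nl(raw, scheme=SchemeId.NEUROLEX):
    return normalize_label(scheme, raw)


class TestGenerateCandidates:
    @pytest.mark.parametrize("raw,target,method", [
        ("Right frontal lobe", "Right frontal lobe", MappingMethod.EXACT),
        ("Inferior horn of the lateral ventricle",
         "Temporal horn of lateral ventricle", MappingMethod.SYNONYM),
        ("Lateral occipital cortex", "Cortex of lateral occipital gyrus",
         MappingMethod.LEXICAL),
    ])
    def test_documented_mapping_examples(self, onto, raw, target, method):
        group = generate_candidates([nl(raw)], onto)[raw]
        best = group[0]
        assert onto.name_of(best.class_id) == target
        assert best.method is method

    def test_exact_match_scores_one(self, onto):
        best = candidates_for(nl("Putamen"), onto)[0]
        assert best.method is MappingMethod.EXACT
        assert best.score == 1.0

    def test_abbreviation_match_after_expansion(self, onto):
        label = nl("Gray_matter_of_left_postcentral_gyrus".replace("_", " "))
        # AAL-style abbreviated rendition of the same class name
        abbrev = nl("gm of left postcentral gyrus")
        best = candidates_for(abbrev, onto)[0]
        assert onto.name_of(best.class_id) == "Gray matter of left postcentral gyrus"
        assert best.method is MappingMethod.ABBREVIATION

    def test_unmapped_label_yields_empty_group(self, onto):
        groups = generate_candidates([nl("Flux capacitor housing")], onto)
        assert groups["Flux capacitor housing"] == []

    def test_candidates_sorted_by_method_precedence(self, onto):
        group = candidates_for(nl("Frontal lobe"), onto)
        precedence = [c.method for c in group]
        order = [MappingMethod.EXACT, MappingMethod.SYNONYM,
                 MappingMethod.ABBREVIATION, MappingMethod.LEXICAL]
        assert precedence == sorted(precedence, key=order.index)
        assert onto.name_of(group[0].class_id) == "Frontal lobe"

    def test_exact_candidates_are_lexical_matches_too(self, onto):
        """Method soundness: exact implies token-set containment."""
        for raw in ("Right frontal lobe", "Putamen", "Corticospinal tract"):
            label = nl(raw)
            best = candidates_for(label, onto)[0]
            assert best.method is MappingMethod.EXACT
            name_tokens = {t for t in onto.name_of(best.class_id).lower().split()
                           if t not in STOPWORDS}
            label_tokens = {t for t in label.render().split()
                            if t not in STOPWORDS}
            assert label_tokens <= name_tokens or name_tokens <= label_tokens
            assert len(label_tokens & name_tokens) / len(
                label_tokens | name_tokens) >= LEXICAL_THRESHOLD


class TestCuration:
    def test_accept_creates_binding(self, onto):
        raw = "Cortex of lateral occipital gyrus test-label"
        target = onto.resolve_name("Cortex of lateral occipital gyrus")
        decisions = [CurationDecision(SchemeId.DK, raw, target)]
        created = apply_curation({}, decisions, onto)
        assert len(created) == 1
        assert lookup_by_binding(onto, SchemeId.DK, raw) == target

    def test_conflicting_acceptances_error(self, onto):
        a = onto.resolve_name("Putamen")
        b = onto.resolve_name("Thalamus")
        decisions = [CurationDecision(SchemeId.DK, "x", a),
                     CurationDecision(SchemeId.DK, "x", b)]
        with pytest.raises(CurationError, match="conflicting"):
            apply_curation({}, decisions, onto)

    def test_override_outside_candidates_warns_but_binds(self, onto):
        target = onto.resolve_name("Putamen")
        label = nl("Completely unrelated label")
        cands = generate_candidates([label], onto)
        decisions = [CurationDecision(SchemeId.NEUROLEX,
                                      "Completely unrelated label", target)]
        with pytest.warns(UserWarning, match="override"):
            apply_curation(cands, decisions, onto)
        assert lookup_by_binding(
            onto, SchemeId.NEUROLEX, "Completely unrelated label") == target

    def test_auto_accept_unambiguous_exact(self, onto):
        label = nl("Putamen")
        cands = generate_candidates([label], onto)
        created = apply_curation(cands, [], onto, auto_accept_exact=True)
        assert any(b.class_id == onto.resolve_name("Putamen") for b in created)

    def test_rebinding_same_class_is_idempotent(self, onto):
        target = onto.resolve_name("Putamen")
        d = [CurationDecision(SchemeId.DK, "put", target)]
        apply_curation({}, d, onto)
        created = apply_curation({}, d, onto)
        assert created == []


class TestLookup:
    @pytest.mark.parametrize("scheme,label,target", [
        (SchemeId.AAL, "Frontal_superior_right", "Right superior frontal gyrus"),
        (SchemeId.NEUROLEX, "Right frontal lobe", "Right frontal lobe"),
        (SchemeId.DK, "ctx-rh-superiorfrontal",
         "Gray matter of right superior frontal gyrus"),
    ])
    def test_reference_bindings_resolve(self, onto, scheme, label, target):
        assert onto.name_of(lookup_by_binding(onto, scheme, label)) == target

    def test_unbound_label_raises_with_nearest(self, onto):
        with pytest.raises(UnmappedLabelError) as err:
            lookup_by_binding(onto, SchemeId.NEUROLEX, "Frontal lobe")
        assert err.value.nearest  # diagnostic candidates attached

    def test_binding_uniqueness_invariant(self, onto):
        seen = {}
        for (scheme, label), binding in onto.bindings.items():
            assert (scheme, label) not in seen
            seen[(scheme, label)] = binding.class_id


class TestRecoveryOracle:
    @pytest.mark.parametrize("seed", [7, 11])
    def test_top1_recovers_ground_truth_for_reliable_perturbations(self, seed):
        """Labels perturbed by casing/abbreviation/synonym only must be
        recovered perfectly by the top candidate."""
        o, truth = random_ontology(FixtureSpec(
            seed=seed, n_classes=60, n_labels=40,
            perturbations=("exact", "case", "abbreviation", "synonym")))
        hits = total = 0
        for scheme, raw, cid, kind in truth["labels"]:
            total += 1
            group = candidates_for(normalize_label(scheme, raw), o)
            if group and group[0].class_id == cid:
                hits += 1
        assert total == 40
        assert hits == total

    def test_method_tags_match_perturbation_kind(self):
        o, truth = random_ontology(FixtureSpec(
            seed=3, n_classes=40, n_labels=30,
            perturbations=("exact", "synonym")))
        expected = {"exact": MappingMethod.EXACT,
                    "synonym": MappingMethod.SYNONYM}
        for scheme, raw, cid, kind in truth["labels"]:
            best = candidates_for(normalize_label(scheme, raw), o)[0]
            assert best.method is expected[kind]
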