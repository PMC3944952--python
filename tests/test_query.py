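"""Cross-atlas correlation, granularity, overlap and annotation."""

import pytest

from atlasbridge import (
    GranularityLevel,
    RelationKind,
    SchemeId,
    annotate_table,
    correlate_label,
    granularity_level,
    overlap_query,
)
from atlasbridge.fixtures import (
    FixtureSpec,
    TALAIRACH_BA6,
    TALAIRACH_BA20,
    random_ontology,
)
from atlasbridge.mapping import UnmappedLabelError
from atlasbridge.query import Direction


def result_for(results, label):
    matches = [r for r in results if r.target_label == label]
    assert matches, f"no correlation to {label!r}"
    return matches[0]


class TestCorrelateLabel:
    def test_talairach_to_dk_one_part_hop(self, onto):
        results = correlate_label(onto, TALAIRACH_BA6, SchemeId.TALAIRACH,
                                  SchemeId.DK)
        r = result_for(results, "ctx-rh-superiorfrontal")
        assert len(r.path) == 1
        assert r.path[0][1] in (RelationKind.PART_OF,
                                RelationKind.REGIONAL_PART_OF)
        assert r.direction is Direction.UP

    def test_talairach_to_aal_two_part_hops(self, onto):
        results = correlate_label(onto, TALAIRACH_BA6, SchemeId.TALAIRACH,
                                  SchemeId.AAL)
        r = result_for(results, "Frontal_superior_right")
        assert len(r.path) == 2
        assert all(rel in (RelationKind.PART_OF, RelationKind.REGIONAL_PART_OF)
                   for _, rel in r.path)

    def test_talairach_to_neurolex_uses_is_a(self, onto):
        results = correlate_label(onto, TALAIRACH_BA6, SchemeId.TALAIRACH,
                                  SchemeId.NEUROLEX)
        r = result_for(results, "Superior frontal gyrus")
        assert r.direction is Direction.LATERAL_IS_A
        assert any(rel is RelationKind.IS_A for _, rel in r.path)

    def test_aal_to_neurolex_single_is_a_hop(self, onto):
        results = correlate_label(onto, "Frontal_superior_right", SchemeId.AAL,
                                  SchemeId.NEUROLEX)
        r = result_for(results, "Superior frontal gyrus")
        assert len(r.path) == 1
        assert r.path[0][1] is RelationKind.IS_A

    def test_identity_same_scheme_empty_path(self, onto):
        results = correlate_label(onto, "Frontal_superior_right", SchemeId.AAL,
                                  SchemeId.AAL)
        r = result_for(results, "Frontal_superior_right")
        assert r.path == ()
        assert r.direction is Direction.IDENTITY

    def test_downward_correlation_returns_bound_descendants(self, onto):
        results = correlate_label(onto, "Frontal_superior_right", SchemeId.AAL,
                                  SchemeId.DK)
        r = result_for(results, "ctx-rh-superiorfrontal")
        assert r.direction is Direction.DOWN

    def test_every_hop_replayable_against_closure(self, onto):
        for target in (SchemeId.DK, SchemeId.AAL, SchemeId.NEUROLEX):
            for r in correlate_label(onto, TALAIRACH_BA6, SchemeId.TALAIRACH,
                                     target):
                prev = onto.resolve_name(
                    "Brodmann area 6 of right superior frontal gyrus")
                for cid, rel in r.path:
                    ok = (cid in onto.ancestors(prev, rel)
                          or cid in onto.descendants(prev, rel))
                    assert ok, (onto.name_of(prev), rel, onto.name_of(cid))
                    prev = cid
                assert prev == r.target_class

    def test_unmapped_source_raises(self, onto):
        with pytest.raises(UnmappedLabelError):
            correlate_label(onto, "no-such-label", SchemeId.DK, SchemeId.AAL)


class TestGranularity:
    @pytest.mark.parametrize("name,level", [
        ("Brodmann area 6 of right superior frontal gyrus",
         GranularityLevel.CYTOARCHITECTURAL_AREA),
        ("Gray matter of right superior frontal gyrus",
         GranularityLevel.CORTICAL_GRAY_MATTER),
        ("Right superior frontal gyrus", GranularityLevel.GYRUS),
        ("Right frontal lobe", GranularityLevel.LOBE),
        ("Right cerebral hemisphere", GranularityLevel.HEMISPHERE),
        ("Putamen", GranularityLevel.OTHER),
    ])
    def test_levels_from_naming_patterns(self, onto, name, level):
        assert granularity_level(onto, onto.resolve_name(name)) is level

    def test_monotone_coarsening_along_upward_part_paths(self, onto):
        """Granularity never moves back toward finer levels going up."""
        order = [GranularityLevel.CYTOARCHITECTURAL_AREA,
                 GranularityLevel.CORTICAL_GRAY_MATTER, GranularityLevel.GYRUS,
                 GranularityLevel.LOBE, GranularityLevel.HEMISPHERE]
        start = onto.resolve_name(
            "Brodmann area 6 of right superior frontal gyrus")
        adj = {}
        for a in onto.structural:
            if a.relation in (RelationKind.PART_OF,
                              RelationKind.REGIONAL_PART_OF):
                adj.setdefault(a.subject, []).append(a.object)

        def walk(node, floor):
            level = granularity_level(onto, node)
            if level in order:
                assert order.index(level) >= floor
                floor = order.index(level)
            for nxt in adj.get(node, []):
                walk(nxt, floor)

        walk(start, 0)


class TestOverlapQuery:
    def test_gm_sfg_vs_ba6(self, onto):
        gm = onto.resolve_name("Gray matter of superior frontal gyrus")
        ba6 = onto.resolve_name("Brodmann area 6")
        out = overlap_query(onto, gm, ba6)
        shared = {onto.name_of(c) for c in out["shared_parts"]}
        assert "Brodmann area 6 of superior frontal gyrus" in shared
        assert out["a_only_exists"] and out["b_only_exists"]

    def test_self_overlap(self, onto):
        ba6 = onto.resolve_name("Brodmann area 6")
        out = overlap_query(onto, ba6, ba6)
        assert set(out["shared_parts"]) == set(
            onto.descendants(ba6, RelationKind.PART_OF))
        assert not out["a_only_exists"] and not out["b_only_exists"]

    @pytest.mark.parametrize("seed", [5])
    def test_matches_brute_force_closure_sets(self, seed):
        o, truth = random_ontology(FixtureSpec(seed=seed, n_classes=80,
                                               n_labels=0))
        down = {}
        for cid, ups in truth["closures"][RelationKind.PART_OF].items():
            for up in ups:
                down.setdefault(up, set()).add(cid)
        ids = sorted(o.classes)
        for a in ids[::7]:
            for b in ids[::11]:
                out = overlap_query(o, a, b)
                da, db = down.get(a, set()), down.get(b, set())
                assert set(out["shared_parts"]) == (da & db)
                if a != b:
                    assert out["a_only_exists"] == bool(da - db - {b})
                    assert out["b_only_exists"] == bool(db - da - {a})


class TestAnnotateTable:
    def test_ba20_row_gains_temporal_chain(self, onto):
        frame = annotate_table(onto, [("talairach", TALAIRACH_BA20)])
        row = frame.iloc[0]
        assert row["mapped"]
        assert row["granularity"] == "cytoarchitectural_area"
        assert "Right inferior temporal gyrus" in row["ancestors"]
        assert "Right temporal lobe" in row["ancestors"]

    def test_empty_table(self, onto):
        frame = annotate_table(onto, [])
        assert len(frame) == 0

    def test_unmapped_row_flagged_not_dropped(self, onto):
        frame = annotate_table(onto, [("dk", "ctx-rh-superiorfrontal"),
                                      ("dk", "ctx-rh-nonexistent")])
        assert len(frame) == 2
        assert frame["mapped"].tolist() == [True, False]
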