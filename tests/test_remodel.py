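"""Remodeling actions: shrink, remove, extend, branch, scale, pipelines."""

import warnings

import numpy as np
import pytest

import remodkit as rk
from remodkit.errors import RemodWarning
from remodkit.remodel import ActionSpec, GrowthParams
from remodkit.selection import SelectionSpec


def _terminals(m):
    return [s for s in m.sections() if s.is_terminal]


def _stem(m):
    return [s for s in m.sections() if s.branch_order == 0][0]


def _untouched_positions_identical(before, after, touched_ids):
    for nid, node in before.nodes.items():
        if nid in touched_ids or nid not in after.nodes:
            continue
        assert np.array_equal(node.pos, after.nodes[nid].pos)
        assert node.radius == after.nodes[nid].radius


# ----------------------------------------------------------------------
# shrink


def test_shrink_zero_is_identity(toy_y):
    m, log = rk.shrink(toy_y, _terminals(toy_y), 0.0)
    assert m.to_swc() == toy_y.to_swc()
    assert all(e.achieved == 0.0 for e in log)


def test_shrink_negative_magnitude_rejected(toy_y):
    with pytest.raises(ValueError):
        rk.shrink(toy_y, _terminals(toy_y), -5.0)
    with pytest.raises(ValueError):
        rk.shrink(toy_y, _terminals(toy_y), 120.0, "percent")


def test_shrink_toy_terminal_by_half(toy_y):
    target = _terminals(toy_y)[:1]
    m, log = rk.shrink(toy_y, target, 50.0)
    assert rk.total_length(m) == pytest.approx(25.0, abs=1e-9)
    lengths = sorted(m.section_length(s) for s in _terminals(m))
    assert lengths == pytest.approx([5.0, 10.0], abs=1e-9)
    assert log.entries[0].achieved == pytest.approx(5.0, abs=1e-9)
    _untouched_positions_identical(toy_y, m, set(target[0].node_path[1:]))


def test_shrink_60_percent_of_apical_terminals(small_tree):
    m = small_tree(5, terminals=4, basal=1, apical=2)
    targets = [s for s in _terminals(m) if s.region == "apical"]
    before = sum(m.section_length(s) for s in targets)
    edited, log = rk.shrink(m, targets, 60.0)
    for e in log:
        assert e.achieved == pytest.approx(e.requested, abs=1e-6)
    remaining = sum(
        edited.section_length(s)
        for s in _terminals(edited)
        if s.region == "apical"
    )
    assert remaining == pytest.approx(0.4 * before, abs=1e-6)


def test_shrink_micrometer_mode_exact(toy_y):
    target = _terminals(toy_y)[:1]
    m, log = rk.shrink(toy_y, target, 3.25, mode="micrometers")
    assert log.entries[0].achieved == pytest.approx(3.25, abs=1e-9)


def test_shrink_whole_section_skipped_with_warning(toy_y):
    target = _terminals(toy_y)[:1]
    with pytest.warns(RemodWarning, match="skipped"):
        m, log = rk.shrink(toy_y, target, 100.0)
    assert rk.total_length(m) == pytest.approx(30.0)
    assert log.entries[0].achieved == 0.0 and log.entries[0].warnings


def test_shrink_nonterminal_translates_subtree_rigidly(toy_y):
    stem = _stem(toy_y)
    tip_positions = {nid: toy_y.nodes[nid].pos.copy() for nid in (4, 5)}
    with pytest.warns(RemodWarning, match="translated"):
        m, log = rk.shrink(toy_y, [stem], 40.0)  # stem 10 -> 6 um
    assert rk.total_length(m) == pytest.approx(26.0, abs=1e-9)
    # both daughters still attached, same lengths, rigid shift
    terms = _terminals(m)
    assert sorted(m.section_length(s) for s in terms) == pytest.approx(
        [10.0, 10.0], abs=1e-9
    )
    shifts = [m.nodes[nid].pos - tip_positions[nid] for nid in (4, 5)]
    assert np.allclose(shifts[0], shifts[1])
    assert np.allclose(shifts[0], [0, -4.0, 0])


# ----------------------------------------------------------------------
# remove


def test_remove_both_toy_terminals_merges_stem(toy_y):
    m, _ = rk.remove(toy_y, _terminals(toy_y))
    secs = m.sections()
    assert len(secs) == 1 and secs[0].is_terminal
    assert rk.total_length(m) == pytest.approx(10.0)
    assert len(m.branch_point_ids()) == 0


def test_remove_stem_leaves_soma_with_warning(toy_y):
    with pytest.warns(RemodWarning, match="degenerate"):
        m, _ = rk.remove(toy_y, [_stem(toy_y)])
    assert len(m) == 1 and m.root.type_code == 1
    assert rk.total_length(m) == 0.0


def test_remove_nonsibling_terminals_drops_one_branch_point_each(small_tree):
    m = small_tree(2, terminals=4, basal=1, apical=1)
    terminals = _terminals(m)
    # pick non-sibling terminals: distinct parent sections
    chosen, seen_parents = [], set()
    for t in terminals:
        if t.parent_section not in seen_parents:
            chosen.append(t)
            seen_parents.add(t.parent_section)
    k = len(chosen)
    before = len(m.branch_point_ids())
    edited, _ = rk.remove(m, chosen)
    assert len(edited.branch_point_ids()) == before - k


def test_remove_logs_removed_length(toy_y):
    target = _terminals(toy_y)[:1]
    _, log = rk.remove(toy_y, target)
    assert log.entries[0].achieved == pytest.approx(10.0)


# ----------------------------------------------------------------------
# extend


def test_extend_zero_is_identity(toy_y):
    m, _ = rk.extend(toy_y, _terminals(toy_y), 0.0, seed=1)
    assert m.to_swc() == toy_y.to_swc()


def test_extend_requires_seed(toy_y):
    with pytest.raises(ValueError, match="seed"):
        rk.extend(toy_y, _terminals(toy_y), 50.0)


def test_extend_terminal_by_half_is_exact_for_any_seed(toy_y):
    target = _terminals(toy_y)[:1]
    for seed in (0, 1, 99):
        m, log = rk.extend(toy_y, target, 50.0, seed=seed)
        grown = [
            s for s in _terminals(m)
            if s.node_path[:2] == target[0].node_path[:2]
        ]
        assert m.section_length(grown[0]) == pytest.approx(15.0, abs=1e-6)
        assert log.entries[0].achieved == pytest.approx(5.0, abs=1e-6)
        _untouched_positions_identical(toy_y, m, set())


def test_extend_growth_radiates_away_from_soma(toy_y):
    """Across many seeds every appended sample lies on the far side of
    the original tip, and the added length is exact."""
    target = _terminals(toy_y)[:1]
    tip = toy_y.nodes[target[0].node_path[-1]].pos
    radial = tip - toy_y.soma_center
    old_ids = set(toy_y.nodes)
    for seed in range(1000):
        m, log = rk.extend(toy_y, target, 50.0, seed=seed)
        assert abs(log.entries[0].achieved - 5.0) <= 1e-6
        for nid in set(m.nodes) - old_ids:
            assert float((m.nodes[nid].pos - tip) @ radial) >= -1e-9


def test_extend_appended_radii_taper_with_floor(toy_y):
    target = _terminals(toy_y)[:1]  # taper 0.1 um diameter per um
    m, _ = rk.extend(toy_y, target, 400.0, mode="micrometers",
                     seed=3, growth=GrowthParams(cone_half_angle=5.0))
    new_ids = sorted(set(m.nodes) - set(toy_y.nodes))
    radii = [m.nodes[nid].radius for nid in new_ids]
    assert all(r >= 0.1 - 1e-12 for r in radii)
    assert radii[-1] == pytest.approx(0.1)  # floor reached on a long cable
    assert radii[0] <= 0.5  # continues the tip radius downward


def test_extend_nonterminal_translates_subtree(toy_y):
    stem = _stem(toy_y)
    with pytest.warns(RemodWarning, match="translated"):
        m, log = rk.extend(toy_y, [stem], 30.0, seed=7)
    assert log.entries[0].achieved == pytest.approx(3.0, abs=1e-6)
    # daughters intact
    assert sorted(m.section_length(s) for s in _terminals(m)) == pytest.approx(
        [10.0, 10.0], abs=1e-9
    )
    assert rk.total_length(m) == pytest.approx(33.0, abs=1e-6)


# ----------------------------------------------------------------------
# branch


def test_branch_toy_terminal_adds_two_daughters(toy_y):
    target = _terminals(toy_y)[:1]
    m, log = rk.branch(toy_y, target, 0.8, seed=5)
    assert rk.total_length(m) == pytest.approx(46.0, abs=1e-6)
    assert len(m.branch_point_ids()) == 2
    new_terms = _terminals(m)
    assert len(new_terms) == 3
    daughters = [s for s in new_terms if s.branch_order == 2]
    assert sorted(m.section_length(s) for s in daughters) == pytest.approx(
        [8.0, 8.0], abs=1e-6
    )
    for e in log:
        assert e.achieved == pytest.approx(8.0, abs=1e-6)


def test_branch_increases_terminal_count_by_targets(small_tree):
    m = small_tree(4, terminals=3)
    targets = _terminals(m)[:3]
    edited, _ = rk.branch(m, targets, 0.5, seed=2)
    assert len(_terminals(edited)) == len(_terminals(m)) + len(targets)


def test_branch_daughters_open_by_twice_the_divergence_angle(toy_y):
    target = _terminals(toy_y)[:1]
    tip_id = target[0].node_path[-1]
    divergence = 40.0
    for seed in range(100):
        m, _ = rk.branch(
            toy_y, target, 0.8,
            growth=GrowthParams(branch_divergence_angle=divergence), seed=seed,
        )
        first_steps = [
            m.nodes[c].pos - m.nodes[tip_id].pos for c in m.children[tip_id]
        ]
        assert len(first_steps) == 2
        u = [v / np.linalg.norm(v) for v in first_steps]
        angle = np.arccos(np.clip(u[0] @ u[1], -1, 1))
        assert angle == pytest.approx(np.radians(2 * divergence), abs=1e-6)


def test_branch_attach_at_mid_section(toy_y):
    target = _terminals(toy_y)[:1]
    m, log = rk.branch(toy_y, target, 0.5, seed=8, attach_at=0.5)
    # attachment inserts a sample at the terminal's midpoint: the parent
    # terminal is split 5 + 5 and two 5 um daughters sprout there
    assert rk.total_length(m) == pytest.approx(40.0, abs=1e-6)
    assert len(m.branch_point_ids()) == 2


def test_branch_requires_positive_fraction_and_seed(toy_y):
    with pytest.raises(ValueError):
        rk.branch(toy_y, _terminals(toy_y), 0.0, seed=1)
    with pytest.raises(ValueError, match="seed"):
        rk.branch(toy_y, _terminals(toy_y), 0.8)


# ----------------------------------------------------------------------
# scale


def test_scale_identity(toy_y):
    m, _ = rk.scale(toy_y, "all", 1.0, scale_radii=True)
    assert m.to_swc() == toy_y.to_swc()


def test_scale_rejects_nonpositive_factor(toy_y):
    with pytest.raises(ValueError):
        rk.scale(toy_y, "all", 0.0)


def test_scale_apical_only_leaves_basal_bit_identical(small_tree):
    m = small_tree(11, terminals=3, basal=2, apical=1)
    scaled, _ = rk.scale(m, "apical", 0.5, scale_radii=True)
    for nid, node in m.nodes.items():
        other = scaled.nodes[nid]
        if rk.region_of_type(node.type_code) == "apical":
            continue
        assert np.array_equal(node.pos, other.pos)
        assert node.radius == other.radius
    assert rk.total_length(scaled, "basal") == rk.total_length(m, "basal")
    assert rk.total_length(scaled, "apical") == pytest.approx(
        0.5 * rk.total_length(m, "apical"), rel=1e-9
    )


# ----------------------------------------------------------------------
# pipelines and global invariants


def test_empty_pipeline_is_reindexed_identity(toy_y):
    m, log = rk.apply_pipeline(toy_y, [])
    assert m.to_swc() == toy_y.to_swc()  # toy is already canonically indexed
    assert len(log) == 0


def test_extend_then_shrink_restores_length_exactly(small_tree):
    m = small_tree(13, terminals=3)
    target = [s for s in m.sections() if s.is_terminal][2]
    before = m.section_length(target)
    grown, _ = rk.extend(m, [target], 12.5, mode="micrometers", seed=4)
    regrown_target = [
        s for s in grown.sections()
        if s.is_terminal and s.node_path[:2] == target.node_path[:2]
    ][0]
    shrunk, _ = rk.shrink(grown, [regrown_target], 12.5, mode="micrometers")
    final = [
        s for s in shrunk.sections()
        if s.is_terminal and s.node_path[:2] == target.node_path[:2]
    ][0]
    assert shrunk.section_length(final) == pytest.approx(before, abs=1e-6)


def test_every_action_preserves_validity(small_tree):
    m = small_tree(19, terminals=3)
    terminals = [s for s in m.sections() if s.is_terminal]
    results = [
        rk.shrink(m, terminals[:2], 30.0)[0],
        rk.remove(m, terminals[:2])[0],
        rk.extend(m, terminals[:2], 40.0, seed=0)[0],
        rk.branch(m, terminals[:2], 0.6, seed=0)[0],
        rk.scale(m, "all", 1.3)[0],
    ]
    for edited in results:
        edited.validate()
        reparsed, _ = rk.loads(edited.to_swc())  # full SWC validity
        assert len(reparsed) == len(edited)


def test_pipeline_seed_determinism_byte_identical(small_tree):
    m = small_tree(23, terminals=4)
    steps = rk.bla_stress_pipeline()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        a, _ = rk.apply_pipeline(m, steps, seed=99)
        b, _ = rk.apply_pipeline(m, steps, seed=99)
        c, _ = rk.apply_pipeline(m, steps, seed=100)
    assert a.to_swc() == b.to_swc()
    assert c.to_swc() != a.to_swc()


def test_pipeline_requires_seed_for_stochastic_steps(toy_y):
    steps = [(
        SelectionSpec(mode="random_fraction", fraction=0.5, terminal_only=True),
        ActionSpec("remove"),
    )]
    with pytest.raises(ValueError, match="seed"):
        rk.apply_pipeline(toy_y, steps)


def test_sequential_selection_resolves_against_edited_tree(small_tree):
    """Removing then shrinking "the remaining" terminals never touches a
    section that no longer exists."""
    m = small_tree(29, terminals=5, basal=2, apical=2)
    steps = [
        (SelectionSpec(mode="random_fraction", fraction=0.3,
                       terminal_only=True, seed=1), ActionSpec("remove")),
        (SelectionSpec(mode="random_fraction", fraction=0.5,
                       terminal_only=True, seed=2),
         ActionSpec("shrink", "percent", 18.0)),
    ]
    edited, log = rk.apply_pipeline(m, steps, seed=0)
    edited.validate()
    shrink_entries = [e for e in log if e.action == "shrink"]
    assert shrink_entries
    for e in shrink_entries:
        assert e.achieved == pytest.approx(e.requested, abs=1e-6)
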