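"""Single-cell statistics: lengths, frusta, Sholl, taper, reports."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import remodkit as rk
from remodkit.morphometry import (
    frustum_lateral_surface,
    frustum_volume,
    section_taper_rate,
    sholl,
)
from conftest import perfect_binary_records


def _brute_total_length(m, region="all"):
    """Independent per-edge summation straight off the node table."""
    total = 0.0
    soma = m.soma_ids
    region_by_type = {2: "axon", 3: "basal", 4: "apical"}
    for nid, node in m.nodes.items():
        if node.parent == -1:
            continue
        if nid in soma and node.parent in soma:
            continue
        if region != "all" and region_by_type.get(node.type_code, "other") != region:
            continue
        total += math.dist(tuple(node.pos), tuple(m.nodes[node.parent].pos))
    return total


def test_total_length_toy(toy_y):
    assert rk.total_length(toy_y, "all") == pytest.approx(30.0)
    assert rk.total_length(toy_y, "basal") == pytest.approx(30.0)
    assert rk.total_length(toy_y, "apical") == 0.0
    assert rk.total_length(toy_y, "axon") == 0.0


def test_total_length_unknown_region(toy_y):
    with pytest.raises(ValueError, match="region"):
        rk.total_length(toy_y, "dendritic")


def test_total_length_matches_brute_force_oracle(small_tree):
    m = small_tree(12, terminals=6, basal=2, apical=2,
                   mean_section_length=30.0)  # a few hundred edges
    assert sum(1 for _ in m.edges()) > 200
    for region in ("all", "basal", "apical"):
        assert rk.total_length(m, region) == pytest.approx(
            _brute_total_length(m, region), abs=1e-9
        )


def test_cylinder_surface_and_volume_closed_form():
    surface, volume = frustum_lateral_surface(1, 1, 10), frustum_volume(1, 1, 10)
    assert surface == pytest.approx(20 * math.pi)
    assert volume == pytest.approx(10 * math.pi)


def test_zero_length_edge_contributes_nothing():
    assert frustum_lateral_surface(2, 1, 0) == 0.0
    assert frustum_volume(2, 1, 0) == 0.0


def test_frustum_closed_form():
    assert frustum_lateral_surface(2, 1, 4) == pytest.approx(3 * math.pi * math.sqrt(17))
    assert frustum_volume(2, 1, 4) == pytest.approx(4 * math.pi / 3 * 7)


@settings(derandomize=True, max_examples=25, deadline=None)
@given(
    r1=st.floats(0.1, 5.0),
    r2=st.floats(0.1, 5.0),
    length=st.floats(0.5, 50.0),
)
def test_frustum_matches_solid_of_revolution_quadrature(r1, r2, length):
    from scipy.integrate import quad

    slope = (r2 - r1) / length
    surface, _ = quad(
        lambda x: 2 * math.pi * (r1 + slope * x) * math.sqrt(1 + slope**2),
        0, length,
    )
    volume, _ = quad(lambda x: math.pi * (r1 + slope * x) ** 2, 0, length)
    assert frustum_lateral_surface(r1, r2, length) == pytest.approx(surface, rel=1e-9)
    assert frustum_volume(r1, r2, length) == pytest.approx(volume, rel=1e-9)


def test_morphology_surface_volume_sums_edges(toy_y):
    surface, volume = rk.surface_volume(toy_y, "all")
    expected_s = (
        frustum_lateral_surface(5, 1, 5)
        + frustum_lateral_surface(1, 1, 5)
        + 2 * frustum_lateral_surface(1, 0.5, 10)
    )
    expected_v = (
        frustum_volume(5, 1, 5)
        + frustum_volume(1, 1, 5)
        + 2 * frustum_volume(1, 0.5, 10)
    )
    assert surface == pytest.approx(expected_s)
    assert volume == pytest.approx(expected_v)


# ----------------------------------------------------------------------
# Sholl


def test_sholl_toy_intersections(toy_y):
    profile = sholl(toy_y, radius_step=5.0, variant="intersections")
    # spheres at 5, 10, 15, 20 um: stem crosses 5 and (exactly at the
    # branch point) 10; both daughters cross 15; tips stop short of 20
    assert profile.shell_edges.tolist() == [0, 5, 10, 15, 20]
    assert profile.values.tolist() == [1, 1, 2, 0]


def test_sholl_toy_branch_points(toy_y):
    profile = sholl(toy_y, radius_step=5.0, variant="branch_points")
    assert profile.values.tolist() == [0, 0, 1, 0]  # branch point at r=10


def test_sholl_rejects_bad_arguments(toy_y):
    with pytest.raises(ValueError):
        sholl(toy_y, radius_step=0.0)
    with pytest.raises(ValueError):
        sholl(toy_y, variant="surface")


def test_sholl_length_conserves_total_length(toy_y, small_tree):
    cells = [toy_y] + [small_tree(s, terminals=3) for s in range(5)]
    for m in cells:
        for step in (5.0, 13.0, 20.0):
            profile = sholl(m, radius_step=step, variant="length")
            assert profile.values.sum() == pytest.approx(
                rk.total_length(m, "all"), rel=1e-9
            )


def test_sholl_length_matches_subdivision_oracle(small_tree):
    m = small_tree(21, terminals=3)
    step = 10.0
    profile = sholl(m, radius_step=step, variant="length")
    # brute force: chop every edge into 10^4 pieces, bin midpoints
    values = np.zeros_like(profile.values)
    center = m.soma_center
    n_sub = 10_000
    t = (np.arange(n_sub) + 0.5) / n_sub
    for parent, child in m.edges():
        if m.is_soma_edge(parent.id, child.id):
            continue
        pts = parent.pos[None, :] + t[:, None] * (child.pos - parent.pos)[None, :]
        dists = np.linalg.norm(pts - center, axis=1)
        seg = float(np.linalg.norm(child.pos - parent.pos)) / n_sub
        idx = np.minimum((dists / step).astype(int), len(values) - 1)
        np.add.at(values, idx, seg)
    assert profile.values == pytest.approx(values, rel=1e-3)


def test_sholl_region_profiles_partition_the_full_profile(small_tree):
    m = small_tree(2, terminals=3)
    full = sholl(m, radius_step=15.0, variant="length").values
    partial = np.zeros_like(full)  # regional profiles may span fewer shells
    for region in ("basal", "apical", "axon"):
        values = sholl(m, radius_step=15.0, variant="length", region=region).values
        partial[: len(values)] += values
    assert partial == pytest.approx(full, abs=1e-9)


# ----------------------------------------------------------------------
# taper


def test_taper_constant_radius_is_zero(toy_y):
    stem = [s for s in toy_y.sections() if not s.is_terminal][0]
    assert section_taper_rate(toy_y, stem) == pytest.approx(0.0)


def test_taper_arithmetic(toy_y):
    # terminal: diameter 2 -> 1 over 10 um of path
    terminal = [s for s in toy_y.sections() if s.is_terminal][0]
    assert section_taper_rate(toy_y, terminal) == pytest.approx(0.1)


def test_taper_mean_matches_recomputation(small_tree):
    m = small_tree(8, terminals=3, taper_per_um=0.004)
    rates = rk.taper_rates(m, "all")
    expected = []
    origin = m.origin_ids
    for sec in m.sections():
        path = [n for n in sec.node_path if n not in origin] \
            if sec.node_path[0] in origin else list(sec.node_path)
        if len(path) < 2:
            continue
        length = sum(
            float(np.linalg.norm(m.nodes[a].pos - m.nodes[b].pos))
            for a, b in zip(path[:-1], path[1:])
        )
        expected.append(
            (2 * m.nodes[path[0]].radius - 2 * m.nodes[path[-1]].radius) / length
        )
    assert np.mean(rates) == pytest.approx(np.mean(expected), rel=1e-9)
    assert all(r > 0 for r in rates)  # generator tapers distally


# ----------------------------------------------------------------------
# aggregate report


def test_report_toy(toy_y):
    rep = rk.report(toy_y)
    assert rep["all"].n_branch_points == 1
    assert rep["all"].n_terminals == 2
    assert rep["all"].total_length == pytest.approx(30.0)
    assert rep["all"].max_branch_order == 1
    assert rep["all"].terminal_path_lengths == pytest.approx((20.0, 20.0))


def test_report_cable():
    records, _ = rk.parse_swc(
        "1 1 0 0 0 4 -1\n" + "\n".join(
            f"{i} 3 0 {2 * (i - 1)} 0 1 {i - 1}" for i in range(2, 11)
        )
    )
    rep = rk.report(rk.build(records))
    assert rep["all"].n_branch_points == 0
    assert rep["all"].n_terminals == 1


def test_report_perfect_binary_depth4_counts():
    m = rk.build(perfect_binary_records(4))
    rep = rk.report(m)
    assert rep["all"].n_terminals == 16
    assert rep["all"].n_branch_points == 15


def test_region_scalars_sum_to_all(small_tree):
    m = small_tree(17, terminals=4, basal=2, apical=1)
    rep = rk.report(m)
    for metric in ("total_length", "total_surface", "total_volume"):
        parts = sum(
            getattr(rep[r], metric) for r in ("basal", "apical", "axon", "other")
        )
        assert parts == pytest.approx(getattr(rep["all"], metric), rel=1e-9)
    for metric in ("n_branch_points", "n_terminals"):
        parts = sum(
            getattr(rep[r], metric) for r in ("basal", "apical", "axon", "other")
        )
        assert parts == getattr(rep["all"], metric)


def test_scaling_covariance_of_length_surface_volume(small_tree):
    m = small_tree(6, terminals=3)
    s = 2.0
    scaled, _ = rk.scale(m, "all", s, scale_radii=True)
    assert rk.total_length(scaled) == pytest.approx(s * rk.total_length(m), rel=1e-9)
    surf0, vol0 = rk.surface_volume(m)
    surf1, vol1 = rk.surface_volume(scaled)
    assert surf1 == pytest.approx(s**2 * surf0, rel=1e-9)
    assert vol1 == pytest.approx(s**3 * vol0, rel=1e-9)
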