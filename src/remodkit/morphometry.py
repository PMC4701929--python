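"""Single-cell morphometric statistics.

All metrics are computed on the edges *outside* the soma cluster so
that multi-point soma contours never contaminate dendritic totals.  An
edge belongs to the region (basal / apical / axon / other) of its child
sample's SWC type code; ``region="all"`` means every non-soma edge.

Each inter-sample edge is modeled as a conical frustum between the
parent radius ``r1`` and child radius ``r2`` over its Euclidean length
``L``:

    lateral surface = pi * (r1 + r2) * sqrt(L**2 + (r1 - r2)**2)
    volume          = (pi / 3) * L * (r1**2 + r1 * r2 + r2**2)

Sholl profiles use Euclidean (radial) distance from the soma centroid,
in half-open shells ``[k*dr, (k+1)*dr)``.  Three variants are offered:
``intersections`` (crossings of the sphere at each shell's outer
boundary, counted once per crossing — an edge that enters and leaves a
sphere counts twice; tangencies are ignored and a node lying exactly on
a boundary is attributed to the inner shell), ``branch_points`` (branch
points binned by radial distance), and ``length`` (each edge's length
apportioned to shells by exact segment–sphere clipping, so the shell
values sum to the total dendritic length to machine precision).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .morphology import Morphology, Section, region_of_type

__all__ = [
    "RegionStats",
    "MorphometryReport",
    "ShollProfile",
    "total_length",
    "surface_volume",
    "frustum_lateral_surface",
    "frustum_volume",
    "sholl",
    "taper_rates",
    "section_taper_rate",
    "report",
]

REPORT_REGIONS = ("all", "basal", "apical", "axon", "other")


def _edge_in_region(m: Morphology, parent_id: int, child_id: int, region: str) -> bool:
    if m.is_soma_edge(parent_id, child_id):
        return False
    if region == "all":
        return True
    return region_of_type(m.nodes[child_id].type_code) == region


def _check_region(region: str) -> None:
    if region not in REPORT_REGIONS:
        raise ValueError(
            f"unknown region {region!r}; expected one of {REPORT_REGIONS}"
        )


def total_length(m: Morphology, region: str = "all") -> float:
    """Sum of Euclidean edge lengths over the region's non-soma edges (μm)."""
    _check_region(region)
    total = 0.0
    for parent, child in m.edges():
        if _edge_in_region(m, parent.id, child.id, region):
            total += float(np.linalg.norm(child.pos - parent.pos))
    return total


def frustum_lateral_surface(r1: float, r2: float, length: float) -> float:
    if length <= 0:
        return 0.0
    return math.pi * (r1 + r2) * math.sqrt(length**2 + (r1 - r2) ** 2)


def frustum_volume(r1: float, r2: float, length: float) -> float:
    if length <= 0:
        return 0.0
    return (math.pi / 3.0) * length * (r1 * r1 + r1 * r2 + r2 * r2)


def surface_volume(m: Morphology, region: str = "all") -> tuple[float, float]:
    """Total lateral surface (μm²) and volume (μm³) of the region's edges,
    each edge modeled as a conical frustum between its sample radii."""
    _check_region(region)
    surface = 0.0
    volume = 0.0
    for parent, child in m.edges():
        if not _edge_in_region(m, parent.id, child.id, region):
            continue
        length = float(np.linalg.norm(child.pos - parent.pos))
        surface += frustum_lateral_surface(parent.radius, child.radius, length)
        volume += frustum_volume(parent.radius, child.radius, length)
    return surface, volume


# ----------------------------------------------------------------------
# Sholl analysis


@dataclass
class ShollProfile:
    """Radial profile of a single cell around the soma centroid."""

    center: np.ndarray
    radius_step: float
    shell_edges: np.ndarray  # length n_shells + 1, starting at 0
    variant: str  # intersections | branch_points | length
    region: str
    values: np.ndarray  # counts, or μm for variant="length"

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "shell_low": self.shell_edges[:-1],
                "shell_high": self.shell_edges[1:],
                "value": self.values,
            }
        )


_TIE_EPS = 1e-9


def _segment_sphere_roots(a: np.ndarray, d: np.ndarray, radius: float) -> list[float]:
    """Parameters t where |a + t*d| == radius, tangencies excluded."""
    A = float(d @ d)
    if A < 1e-30:
        return []
    B = 2.0 * float(a @ d)
    C = float(a @ a) - radius * radius
    disc = B * B - 4.0 * A * C
    if disc <= 0:  # no crossing, or tangency (ignored)
        return []
    sq = math.sqrt(disc)
    return [(-B - sq) / (2.0 * A), (-B + sq) / (2.0 * A)]


def sholl(
    m: Morphology,
    radius_step: float = 20.0,
    variant: str = "intersections",
    region: str = "all",
) -> ShollProfile:
    """Compute a Sholl profile.  See the module docstring for shell and
    crossing conventions."""
    if radius_step <= 0:
        raise ValueError("radius_step must be > 0")
    if variant not in ("intersections", "branch_points", "length"):
        raise ValueError(f"unknown Sholl variant {variant!r}")
    _check_region(region)

    center = m.soma_center
    edges = [
        (parent, child)
        for parent, child in m.edges()
        if _edge_in_region(m, parent.id, child.id, region)
    ]
    max_dist = 0.0
    for parent, child in edges:
        max_dist = max(
            max_dist,
            float(np.linalg.norm(parent.pos - center)),
            float(np.linalg.norm(child.pos - center)),
        )
    n_shells = max(1, int(math.ceil(max_dist / radius_step - _TIE_EPS)))
    shell_edges = np.arange(n_shells + 1, dtype=float) * radius_step
    values = np.zeros(n_shells)

    if variant == "branch_points":
        for nid in m.branch_point_ids():
            node = m.nodes[nid]
            if region != "all" and region_of_type(node.type_code) != region:
                continue
            dist = float(np.linalg.norm(node.pos - center))
            k = min(int(dist / radius_step), n_shells - 1)
            values[k] += 1
        return ShollProfile(center, radius_step, shell_edges, variant, region, values)

    if variant == "intersections":
        for k in range(n_shells):
            radius = shell_edges[k + 1]
            count = 0
            for parent, child in edges:
                a = parent.pos - center
                d = child.pos - parent.pos
                for t in _segment_sphere_roots(a, d, radius):
                    # a crossing exactly at a node is attributed to the
                    # proximal edge (t == 1 counts, t == 0 does not)
                    if _TIE_EPS < t <= 1.0 + _TIE_EPS:
                        count += 1
            values[k] = count
        return ShollProfile(center, radius_step, shell_edges, variant, region, values)

    # variant == "length": exact clipping of each straight segment at the
    # shell boundaries it straddles
    for parent, child in edges:
        a = parent.pos - center
        b = child.pos - center
        d = b - a
        length = float(np.linalg.norm(d))
        if length == 0.0:
            continue
        da, db = float(np.linalg.norm(a)), float(np.linalg.norm(b))
        # minimum distance to the center along the (clamped) segment
        t_star = min(1.0, max(0.0, -float(a @ d) / float(d @ d)))
        d_min = float(np.linalg.norm(a + t_star * d))
        d_max = max(da, db)
        lo = int(math.floor(d_min / radius_step))
        hi = int(math.ceil(d_max / radius_step))
        cuts = [0.0, 1.0]
        for j in range(lo, hi + 1):
            radius = j * radius_step
            if radius <= 0:
                continue
            for t in _segment_sphere_roots(a, d, radius):
                if 0.0 < t < 1.0:
                    cuts.append(t)
        cuts = sorted(set(cuts))
        for t0, t1 in zip(cuts[:-1], cuts[1:]):
            mid = a + 0.5 * (t0 + t1) * d
            k = min(int(float(np.linalg.norm(mid)) / radius_step), n_shells - 1)
            values[k] += (t1 - t0) * length
    return ShollProfile(center, radius_step, shell_edges, variant, region, values)


# ----------------------------------------------------------------------
# diameter taper


def section_taper_rate(m: Morphology, section: Section) -> Optional[float]:
    """End-to-end diameter taper of one section (μm diameter per μm path).

    Defined as (proximal diameter - distal diameter) / section path
    length.  For soma-attached stems the proximal sample is taken as the
    first dendritic node, so the soma's large radius never inflates the
    rate.  Returns None for degenerate (zero-length) measurements.
    """
    path = list(section.node_path)
    origin = m.origin_ids
    while len(path) > 1 and path[0] in origin:
        path = path[1:]
    if len(path) < 2:
        return None
    pts = np.array([m.nodes[i].pos for i in path])
    length = float(np.sum(np.linalg.norm(np.diff(pts, axis=0), axis=1)))
    if length <= 0:
        return None
    d_prox = 2.0 * m.nodes[path[0]].radius
    d_dist = 2.0 * m.nodes[path[-1]].radius
    return (d_prox - d_dist) / length


def taper_rates(m: Morphology, region: str = "all") -> list[float]:
    """Per-section diameter taper rates for a region (μm/μm)."""
    _check_region(region)
    out = []
    for sec in m.sections():
        if region != "all" and sec.region != region:
            continue
        rate = section_taper_rate(m, sec)
        if rate is not None:
            out.append(rate)
    return out


# ----------------------------------------------------------------------
# aggregate report


@dataclass
class RegionStats:
    total_length: float = 0.0  # μm
    total_surface: float = 0.0  # μm²
    total_volume: float = 0.0  # μm³
    n_branch_points: int = 0
    n_terminals: int = 0
    max_branch_order: int = 0
    mean_taper_rate: float = float("nan")  # μm diameter per μm path
    terminal_path_lengths: tuple[float, ...] = ()


@dataclass
class MorphometryReport:
    """Per-region scalar statistics of a single cell.

    The basal/apical/axon/other entries sum to the ``all`` entry for
    length, surface, volume, branch points and terminals.
    """

    per_region: dict[str, RegionStats] = field(default_factory=dict)

    def __getitem__(self, region: str) -> RegionStats:
        return self.per_region[region]

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for region, stats in self.per_region.items():
            for metric in (
                "total_length",
                "total_surface",
                "total_volume",
                "n_branch_points",
                "n_terminals",
                "max_branch_order",
                "mean_taper_rate",
            ):
                rows.append(
                    {"region": region, "metric": metric,
                     "value": getattr(stats, metric)}
                )
            rows.append(
                {
                    "region": region,
                    "metric": "mean_terminal_path_length",
                    "value": float(np.mean(stats.terminal_path_lengths))
                    if stats.terminal_path_lengths
                    else float("nan"),
                }
            )
        return pd.DataFrame(rows)


def report(m: Morphology) -> MorphometryReport:
    """Aggregate every statistic into one per-region report."""
    sections = m.sections()
    out = MorphometryReport()
    for region in REPORT_REGIONS:
        surface, volume = surface_volume(m, region)
        region_secs = [
            s for s in sections if region == "all" or s.region == region
        ]
        terminals = [s for s in region_secs if s.is_terminal]
        rates = [
            r
            for r in (section_taper_rate(m, s) for s in region_secs)
            if r is not None
        ]
        n_bp = 0
        for nid in m.branch_point_ids():
            node_region = region_of_type(m.nodes[nid].type_code)
            if region == "all" or node_region == region:
                n_bp += 1
        out.per_region[region] = RegionStats(
            total_length=total_length(m, region),
            total_surface=surface,
            total_volume=volume,
            n_branch_points=n_bp,
            n_terminals=len(terminals),
            max_branch_order=max((s.branch_order for s in region_secs), default=0),
            mean_taper_rate=float(np.mean(rates)) if rates else float("nan"),
            terminal_path_lengths=tuple(
                m.path_length_to_soma(s.node_path[-1]) for s in terminals
            ),
        )
    return out
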