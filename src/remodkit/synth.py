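"""Seeded generation of synthetic NeuroMorpho-style morphologies.

The generator emulates the gross architecture of reconstructed
pyramidal neurons so that every analysis and remodeling operation can be
exercised on populations of valid SWC trees without downloads: a single
soma sample at the origin; basal stems (type 3) radiating into the z<0
hemisphere and apical stems (type 4) into z>0; per stem a strictly
bifurcating random topology grown until the requested number of
terminal sections exists; section lengths drawn from a gamma
distribution with a chosen mean and coefficient of variation; each
section polylined in steps of a few μm with bounded per-step angular
jitter; diameters tapering linearly with path distance and floored.

Because every section's length is an independent gamma draw with the
same mean, population expectations are available in closed form: a cell
with S sections has expected total dendritic length S times the mean
section length, which is what the statistical tests check against.

Strict bifurcation keeps the tree-combinatorial invariants exact: a
stem with T terminals has T - 1 branch points and 2T - 1 sections.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass
from typing import Optional

import numpy as np

from ._geom import perpendicular_unit, rotate_towards, sample_cone, unit
from .morphology import Morphology, Node

__all__ = [
    "SyntheticSpec",
    "generate",
    "generate_population",
    "ca3_like_spec",
    "bla_like_spec",
    "expected_total_length",
    "expected_section_count",
]

#: half-angle (degrees) between daughter directions at generated branch points
_BRANCH_HALF_ANGLE = 35.0


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one synthetic cell.

    ``apical_terminals_per_stem`` defaults to ``terminals_per_stem``;
    pyramidal-like cells typically concentrate many more terminals on
    their single apical trunk than on each basal stem, so the presets
    set it separately.
    """

    n_basal_stems: int = 5
    n_apical_stems: int = 1
    terminals_per_stem: int = 6
    apical_terminals_per_stem: Optional[int] = None
    mean_section_length: float = 60.0  # μm
    section_length_cv: float = 0.5
    mean_step_length: float = 4.0  # μm per sample point
    initial_diameter: float = 2.5  # μm at the stem base
    taper_per_um: float = 0.003  # μm diameter lost per μm of path
    tortuosity_angle: float = 12.0  # degrees of per-step jitter
    soma_radius: float = 6.0  # μm
    seed: int = 0

    def __post_init__(self):
        if self.n_basal_stems < 1:
            raise ValueError("n_basal_stems must be >= 1")
        if self.n_apical_stems < 0:
            raise ValueError("n_apical_stems must be >= 0")
        if self.terminals_per_stem < 1:
            raise ValueError("terminals_per_stem must be >= 1")
        if (
            self.apical_terminals_per_stem is not None
            and self.apical_terminals_per_stem < 1
        ):
            raise ValueError("apical_terminals_per_stem must be >= 1")
        for name in (
            "mean_section_length",
            "mean_step_length",
            "initial_diameter",
            "soma_radius",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.section_length_cv <= 0:
            raise ValueError("section_length_cv must be > 0")
        if not 0.0 <= self.tortuosity_angle < 90.0:
            raise ValueError("tortuosity_angle must be in [0, 90) degrees")
        if self.taper_per_um < 0:
            raise ValueError("taper_per_um must be >= 0")

    @property
    def apical_terminals(self) -> int:
        return (
            self.apical_terminals_per_stem
            if self.apical_terminals_per_stem is not None
            else self.terminals_per_stem
        )


def ca3_like_spec(seed: int = 0) -> SyntheticSpec:
    """Hippocampal-CA3-pyramidal-like cell: a few bushy basal stems and
    one terminal-rich apical trunk."""
    return SyntheticSpec(
        n_basal_stems=5,
        n_apical_stems=1,
        terminals_per_stem=6,
        apical_terminals_per_stem=30,
        mean_section_length=75.0,
        seed=seed,
    )


def bla_like_spec(seed: int = 0) -> SyntheticSpec:
    """Basolateral-amygdala-pyramidal-like cell: smaller arbor, less
    pronounced apical dominance."""
    return SyntheticSpec(
        n_basal_stems=4,
        n_apical_stems=1,
        terminals_per_stem=5,
        apical_terminals_per_stem=8,
        mean_section_length=55.0,
        seed=seed,
    )


def expected_section_count(spec: SyntheticSpec) -> int:
    """Exact section count of any cell from this spec (strict
    bifurcation: 2T - 1 sections per stem with T terminals)."""
    basal = spec.n_basal_stems * (2 * spec.terminals_per_stem - 1)
    apical = spec.n_apical_stems * (2 * spec.apical_terminals - 1)
    return basal + apical


def expected_total_length(spec: SyntheticSpec) -> float:
    """Expected total dendritic length (μm): section count times the
    gamma mean section length."""
    return expected_section_count(spec) * spec.mean_section_length


def _hemisphere_direction(rng: np.random.Generator, z_sign: float) -> np.ndarray:
    while True:
        v = rng.normal(size=3)
        if np.linalg.norm(v) > 1e-6 and abs(v[2]) > 1e-3:
            break
    v[2] = z_sign * abs(v[2])
    return unit(v)


def generate(spec: SyntheticSpec) -> Morphology:
    """Generate one seeded synthetic cell.

    Deterministic: the same spec (including its seed) always yields a
    byte-identical SWC serialization.
    """
    rng = np.random.default_rng(spec.seed)
    shape = 1.0 / spec.section_length_cv**2
    scale = spec.mean_section_length * spec.section_length_cv**2
    tort_rad = math.radians(spec.tortuosity_angle)
    branch_rad = math.radians(_BRANCH_HALF_ANGLE)

    nodes = {
        1: Node(1, 1, np.zeros(3), spec.soma_radius, -1)
    }
    children: dict[int, list[int]] = {1: []}
    next_id = [2]

    def add(type_code, pos, radius, parent) -> int:
        nid = next_id[0]
        next_id[0] += 1
        nodes[nid] = Node(nid, type_code, np.asarray(pos, float), radius, parent)
        children[nid] = []
        children[parent].append(nid)
        return nid

    def grow_section(parent_id, direction, type_code, path_s):
        """One unbranched section; returns (tip id, end direction, new s)."""
        length = float(rng.gamma(shape, scale))
        length = max(length, 1.0)  # μm; avoid degenerate sections
        n_steps = max(1, int(round(length / spec.mean_step_length)))
        step = length / n_steps
        pos = nodes[parent_id].pos.copy()
        end_dir = direction
        pid = parent_id
        for i in range(1, n_steps + 1):
            if spec.tortuosity_angle > 0:
                end_dir = sample_cone(direction, tort_rad, rng)
            pos = pos + step * end_dir
            s = path_s + i * step
            diameter = max(spec.initial_diameter - spec.taper_per_um * s, 0.2)
            pid = add(type_code, pos, diameter / 2.0, pid)
        return pid, end_dir, path_s + length

    def grow_subtree(parent_id, direction, n_terminals, type_code, path_s):
        tip, end_dir, s = grow_section(parent_id, direction, type_code, path_s)
        if n_terminals == 1:
            return
        left = int(rng.integers(1, n_terminals))
        right = n_terminals - left
        perp = perpendicular_unit(end_dir, rng)
        d_left = rotate_towards(end_dir, perp, +branch_rad)
        d_right = rotate_towards(end_dir, perp, -branch_rad)
        grow_subtree(tip, d_left, left, type_code, s)
        grow_subtree(tip, d_right, right, type_code, s)

    for _ in range(spec.n_basal_stems):
        grow_subtree(1, _hemisphere_direction(rng, -1.0),
                     spec.terminals_per_stem, 3, 0.0)
    for _ in range(spec.n_apical_stems):
        grow_subtree(1, _hemisphere_direction(rng, +1.0),
                     spec.apical_terminals, 4, 0.0)

    m = Morphology(nodes, 1, provenance={"source": "synthetic",
                                         "spec_seed": spec.seed})
    return m


def generate_population(
    spec: SyntheticSpec, n_cells: int, seed: Optional[int] = None
) -> list[Morphology]:
    """Generate ``n_cells`` independent cells with per-cell seeds derived
    deterministically from ``seed`` (defaults to the spec's own seed)."""
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    cell_seeds = rng.integers(0, 2**31 - 1, size=n_cells)
    return [
        generate(dataclasses.replace(spec, seed=int(s))) for s in cell_seeds
    ]
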