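"""Structural remodeling actions on selected dendritic sections.

Five actions cover the remodeling repertoire: ``shrink`` and ``remove``
simulate the end state of dendritic retraction by deleting sample
points; ``extend`` and ``branch`` simulate growth by appending chains of
short, somewhat randomly directed segments that radiate away from the
parent dendrite and the soma; ``scale`` enlarges or reduces a whole
region about the soma centroid.  None of these implement a biophysical
growth or retraction rule — they reshape an already-grown reconstruction
to a prescribed end result, which is the point: the experimenter, not a
growth model, decides what changed.

Exactness contract: the achieved length change of every targeted section
equals the request to within 1e-6 μm.  Shrink deletes whole samples
tip-inward and places the new tip by linear interpolation along the last
crossed edge; extend and branch truncate their final growth step.  When
an action cannot honor a request (e.g. shrinking by at least the whole
section length) the section is skipped and a warning is logged instead.

All stochastic kernels are driven by an explicit integer seed; identical
inputs and seed reproduce byte-identical SWC output.
"""

from __future__ import annotations

import dataclasses
import json
import math
import warnings as _warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from ._geom import perpendicular_unit, rotate_towards, sample_cone, unit
from .errors import RemodWarning
from .morphology import Morphology, Section
from .morphometry import section_taper_rate
from .selection import SelectionSpec, resolve

__all__ = [
    "GrowthParams",
    "ActionSpec",
    "LogEntry",
    "EditLog",
    "shrink",
    "remove",
    "extend",
    "branch",
    "scale",
    "apply_action",
    "apply_pipeline",
]

#: gamma(shape, scale μm) used when a host cell has no usable edge-length
#: statistics to fit (e.g. a minimal synthetic fixture).
FALLBACK_STEP_GAMMA = (2.0, 1.5)

_EXACT = 1e-9  # internal snapping tolerance, well below the 1e-6 contract
_MIN_RADIUS = 0.1  # μm floor for appended samples


@dataclass(frozen=True)
class GrowthParams:
    """Parameters of the stochastic growth kernel.

    step_length_distribution
        ``"fitted"`` — gamma distribution moment-matched to the host
        cell's existing inter-sample edge lengths (its "realistic
        distribution" of sampling steps) — or an explicit
        ``(shape, scale_um)`` pair.
    cone_half_angle
        Maximum deviation (degrees) of each new step from the current
        growth axis.
    branch_divergence_angle
        Half-angle (degrees) between the two daughters created by the
        branch action; the daughters open up by twice this angle.
    min_steps
        Lower bound on the number of segments used to realize a given
        added length.
    """

    step_length_distribution: object = "fitted"
    cone_half_angle: float = 30.0
    branch_divergence_angle: float = 40.0
    min_steps: int = 1

    def __post_init__(self):
        if not 0.0 < self.cone_half_angle < 90.0:
            raise ValueError("cone_half_angle must be in (0, 90) degrees")
        if not 0.0 < self.branch_divergence_angle < 90.0:
            raise ValueError("branch_divergence_angle must be in (0, 90) degrees")
        if self.min_steps < 1:
            raise ValueError("min_steps must be >= 1")


@dataclass(frozen=True)
class ActionSpec:
    """Declarative description of one remodeling action.

    ``magnitude`` is interpreted per ``magnitude_mode``: a percentage of
    each target section's current length (``percent``), an absolute
    length in μm (``micrometers``), or a multiplicative ``factor``
    (scale action only).
    """

    action: str  # shrink | remove | extend | branch | scale
    magnitude_mode: str = "percent"
    magnitude: Optional[float] = None
    branch_daughter_fraction: Optional[float] = None
    scale_radii: bool = False
    seed: Optional[int] = None
    growth_params: GrowthParams = field(default_factory=GrowthParams)

    def __post_init__(self):
        if self.action not in ("shrink", "remove", "extend", "branch", "scale"):
            raise ValueError(f"unknown action {self.action!r}")
        if self.magnitude_mode not in ("percent", "micrometers", "factor"):
            raise ValueError(f"unknown magnitude_mode {self.magnitude_mode!r}")


@dataclass(frozen=True)
class LogEntry:
    action: str
    section_id: Optional[int]
    requested: Optional[float]  # μm (or factor for scale)
    achieved: Optional[float]
    warnings: tuple[str, ...] = ()


class EditLog:
    """Ordered record of what each action did to each target section."""

    def __init__(self, entries: Optional[list[LogEntry]] = None):
        self.entries: list[LogEntry] = list(entries or [])

    def append(self, entry: LogEntry) -> None:
        self.entries.append(entry)

    def extend(self, other: "EditLog") -> None:
        self.entries.extend(other.entries)

    @property
    def warnings(self) -> list[str]:
        return [w for e in self.entries for w in e.warnings]

    def to_dicts(self) -> list[dict]:
        return [dataclasses.asdict(e) for e in self.entries]

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dicts(), **kwargs)

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)


def _warn(log_warnings: list[str], message: str) -> None:
    log_warnings.append(message)
    _warnings.warn(message, RemodWarning, stacklevel=3)


def _live_path_length(m: Morphology, path: Sequence[int]) -> float:
    pts = np.array([m.nodes[i].pos for i in path])
    return float(np.sum(np.linalg.norm(np.diff(pts, axis=0), axis=1)))


def _resolve_delta(
    mode: str, magnitude: float, current_length: float, action: str
) -> float:
    if magnitude < 0:
        raise ValueError(f"{action}: magnitude must be >= 0, got {magnitude}")
    if mode == "percent":
        if action == "shrink" and magnitude > 100.0:
            raise ValueError("shrink: percent magnitude must be in [0, 100]")
        return magnitude / 100.0 * current_length
    if mode == "micrometers":
        return magnitude
    raise ValueError(f"{action}: magnitude_mode must be percent or micrometers")


# ----------------------------------------------------------------------
# retraction actions


def _cut_section_to(m: Morphology, path: Sequence[int], new_length: float) -> None:
    """Shorten the cable along ``path`` to ``new_length`` measured from its
    proximal landmark, deleting samples tip-inward and interpolating the
    new tip.  Any subtree hanging off the old tip is re-attached to the
    new tip and rigidly translated by the tip displacement."""
    pts = [m.nodes[i].pos for i in path]
    seg = [float(np.linalg.norm(pts[i + 1] - pts[i])) for i in range(len(pts) - 1)]
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    old_tip = path[-1]
    old_tip_pos = pts[-1].copy()
    tip_children = list(m.children[old_tip])

    j = int(np.searchsorted(cum, new_length + _EXACT) - 1)
    j = max(0, min(j, len(path) - 2))
    if abs(new_length - cum[j]) <= _EXACT:
        new_tip = path[j]
        first_deleted = j + 1
    else:
        t = (new_length - cum[j]) / seg[j]
        keep = path[j + 1]
        node = m.nodes[keep]
        node.pos = pts[j] + t * (pts[j + 1] - pts[j])
        node.radius = m.nodes[path[j]].radius + t * (
            m.nodes[keep].radius - m.nodes[path[j]].radius
        )
        new_tip = keep
        first_deleted = j + 2

    shift = m.nodes[new_tip].pos - old_tip_pos
    for child in tip_children:
        if new_tip != old_tip:
            m.reparent(child, new_tip)
        m.translate_subtree(child, shift)
    if new_tip != old_tip and first_deleted < len(path):
        m.delete_subtree(path[first_deleted])


def shrink(
    morphology: Morphology,
    sections: Sequence[Section],
    magnitude: float,
    mode: str = "percent",
) -> tuple[Morphology, EditLog]:
    """Shorten each target section from its distal end.

    ``magnitude`` is a percentage of each section's current length
    (``mode="percent"``) or an absolute length in μm.  A request equal to
    or exceeding a section's length skips that section with a warning
    (use :func:`remove` for full deletion).  Magnitude 0 is the identity.
    Non-terminal targets keep their distal subtree attached: it is
    rigidly translated by the tip displacement.
    """
    m = morphology.copy()
    log = EditLog()
    for sec in sections:
        entry_warnings: list[str] = []
        length = _live_path_length(m, sec.node_path)
        delta = _resolve_delta(mode, magnitude, length, "shrink")
        if delta == 0.0:
            log.append(LogEntry("shrink", sec.section_id, 0.0, 0.0))
            continue
        if delta >= length - _EXACT:
            _warn(
                entry_warnings,
                f"shrink: requested removal {delta:.3f} μm >= section "
                f"{sec.section_id} length {length:.3f} μm; section skipped "
                "(use the remove action instead)",
            )
            log.append(
                LogEntry("shrink", sec.section_id, delta, 0.0, tuple(entry_warnings))
            )
            continue
        if not sec.is_terminal:
            _warn(
                entry_warnings,
                f"shrink: section {sec.section_id} is not terminal; its "
                "distal subtree was rigidly translated with the new tip",
            )
        _cut_section_to(m, sec.node_path, length - delta)
        achieved = length - _live_path_length(
            m, _current_section_path(m, sec)
        )
        log.append(
            LogEntry("shrink", sec.section_id, delta, achieved, tuple(entry_warnings))
        )
    return m, log


def _current_section_path(m: Morphology, sec: Section) -> list[int]:
    """Re-walk a section's cable in the edited morphology: from its
    proximal landmark along surviving nodes to the next landmark."""
    path = [sec.node_path[0]]
    for nid in sec.node_path[1:]:
        if nid in m.nodes:
            path.append(nid)
    return path


def remove(
    morphology: Morphology, sections: Sequence[Section]
) -> tuple[Morphology, EditLog]:
    """Delete each target section and, for non-terminal targets, its
    entire distal subtree.  A parent branch point left with a single
    child becomes a continuation node, so the flanking sections merge on
    the next decomposition."""
    m = morphology.copy()
    log = EditLog()
    for sec in sections:
        entry_warnings: list[str] = []
        first = sec.node_path[1]
        if first not in m.nodes:
            _warn(
                entry_warnings,
                f"remove: section {sec.section_id} already deleted by an "
                "earlier target; skipped",
            )
            log.append(
                LogEntry("remove", sec.section_id, None, 0.0, tuple(entry_warnings))
            )
            continue
        removed_length = sum(
            m.edge_length(m.nodes[nid].parent, nid)
            for nid in m.subtree_ids(first)
        )
        m.delete_subtree(first)
        log.append(
            LogEntry(
                "remove", sec.section_id, None, removed_length, tuple(entry_warnings)
            )
        )
    if not any(
        not m.is_soma_edge(node.parent, node.id)
        for node in m.nodes.values()
        if node.parent != -1
    ):
        _warnings.warn(
            "remove: no dendritic edges remain (degenerate cell)",
            RemodWarning,
            stacklevel=2,
        )
    return m, log


# ----------------------------------------------------------------------
# growth actions


def _resolve_step_gamma(
    m: Morphology, growth: GrowthParams
) -> tuple[float, float]:
    dist = growth.step_length_distribution
    if dist != "fitted":
        shape, scale_um = dist  # type: ignore[misc]
        if shape <= 0 or scale_um <= 0:
            raise ValueError("gamma step distribution needs positive shape/scale")
        return float(shape), float(scale_um)
    lengths = [
        float(np.linalg.norm(child.pos - parent.pos))
        for parent, child in m.edges()
        if not m.is_soma_edge(parent.id, child.id)
    ]
    lengths = [x for x in lengths if x > 0]
    if len(lengths) < 2:
        return FALLBACK_STEP_GAMMA
    mean = float(np.mean(lengths))
    var = float(np.var(lengths))
    if var <= 0 or mean <= 0:
        return FALLBACK_STEP_GAMMA
    return mean * mean / var, var / mean


def _grow_cable(
    m: Morphology,
    tip_id: int,
    total: float,
    init_axis: np.ndarray,
    radial_unit: np.ndarray,
    taper_rate: float,
    growth: GrowthParams,
    rng: np.random.Generator,
    step_gamma: tuple[float, float],
    first_step_exact: bool = False,
) -> tuple[int, float]:
    """Append a chain of samples of total length ``total`` distal to
    ``tip_id``; returns (new tip id, achieved length).

    Each step direction is drawn uniformly in a cone around the current
    growth axis and redrawn while it points back towards the soma
    (negative dot product with the radial unit vector at the original
    tip); the final step is truncated so the added length is exact.
    """
    tip = m.nodes[tip_id]
    r0, tcode = tip.radius, tip.type_code
    pos = tip.pos.copy()
    axis = unit(np.asarray(init_axis, float))
    cone_rad = math.radians(growth.cone_half_angle)
    shape, scale_um = step_gamma
    max_step = total / growth.min_steps
    parent = tip_id
    added = 0.0
    first = True
    while total - added > _EXACT:
        step = float(rng.gamma(shape, scale_um))
        step = min(max(step, 1e-3), max_step)
        if added + step >= total - _EXACT:
            step = total - added
        if first and first_step_exact:
            direction = axis
        else:
            direction = sample_cone(axis, cone_rad, rng)
            tries = 0
            while float(direction @ radial_unit) < 0.0 and tries < 1000:
                direction = sample_cone(axis, cone_rad, rng)
                tries += 1
            if float(direction @ radial_unit) < 0.0:
                direction = radial_unit
        pos = pos + step * direction
        added += step
        axis = direction
        radius = max(r0 - 0.5 * taper_rate * added, _MIN_RADIUS)
        parent = m.add_node(tcode, pos.copy(), radius, parent)
        first = False
    return parent, added


def _tip_frame(
    m: Morphology, sec: Section
) -> tuple[int, np.ndarray, np.ndarray]:
    """Tip id, last-edge direction and soma-to-tip radial unit vector."""
    tip_id = sec.node_path[-1]
    prev_id = sec.node_path[-2]
    tip_pos = m.nodes[tip_id].pos
    axis = unit(tip_pos - m.nodes[prev_id].pos)
    radial = tip_pos - m.soma_center
    norm = float(np.linalg.norm(radial))
    radial_unit = radial / norm if norm > 1e-12 else axis
    return tip_id, axis, radial_unit


def extend(
    morphology: Morphology,
    sections: Sequence[Section],
    magnitude: float,
    mode: str = "percent",
    growth: Optional[GrowthParams] = None,
    seed: Optional[int] = None,
) -> tuple[Morphology, EditLog]:
    """Lengthen each target section by appending new samples at its tip.

    ``magnitude`` is a percentage of the section's current length or an
    absolute μm value.  Appended samples take the tip's type code and
    continue the section's linear diameter taper (radius floored at
    0.1 μm).  For a non-terminal target the new cable is inserted at the
    tip and the distal subtree is translated to its far end (warned).
    """
    growth = growth or GrowthParams()
    if seed is None:
        raise ValueError("extend is stochastic and requires a seed")
    rng = np.random.default_rng(seed)
    m = morphology.copy()
    log = EditLog()
    step_gamma = _resolve_step_gamma(m, growth)
    for sec in sections:
        entry_warnings: list[str] = []
        length = _live_path_length(m, sec.node_path)
        add = _resolve_delta(mode, magnitude, length, "extend")
        if add == 0.0:
            log.append(LogEntry("extend", sec.section_id, 0.0, 0.0))
            continue
        tip_id, axis, radial_unit = _tip_frame(m, sec)
        taper = section_taper_rate(m, sec) or 0.0
        tip_children = list(m.children[tip_id])
        old_tip_pos = m.nodes[tip_id].pos.copy()
        new_tip, achieved = _grow_cable(
            m, tip_id, add, axis, radial_unit, taper, growth, rng, step_gamma
        )
        if tip_children:
            _warn(
                entry_warnings,
                f"extend: section {sec.section_id} is not terminal; the new "
                "cable was inserted at its tip and the distal subtree "
                "translated by the added displacement",
            )
            shift = m.nodes[new_tip].pos - old_tip_pos
            for child in tip_children:
                m.reparent(child, new_tip)
                m.translate_subtree(child, shift)
        log.append(
            LogEntry("extend", sec.section_id, add, achieved, tuple(entry_warnings))
        )
    return m, log


def branch(
    morphology: Morphology,
    sections: Sequence[Section],
    daughter_fraction: float,
    growth: Optional[GrowthParams] = None,
    seed: Optional[int] = None,
    attach_at: Optional[float] = None,
) -> tuple[Morphology, EditLog]:
    """Add two new terminal dendrites stemming from each target section.

    Each daughter is grown with the stochastic kernel to a total length
    of ``daughter_fraction`` times the parent section's length, exact by
    final-step truncation.  Initial daughter directions are the local
    dendrite direction rotated by +/- the divergence half-angle within a
    uniformly random plane containing it, so the daughters open up by
    twice that angle.

    By default the daughters stem from the parent's distal tip, which
    becomes a branch point.  ``attach_at`` in (0, 1] instead attaches
    them at that fraction of the parent's arc length (an interpolated
    sample is inserted if the position falls inside an edge).
    """
    growth = growth or GrowthParams()
    if seed is None:
        raise ValueError("branch is stochastic and requires a seed")
    if daughter_fraction is None or daughter_fraction <= 0:
        raise ValueError("branch requires daughter_fraction > 0")
    if attach_at is not None and not 0.0 < attach_at <= 1.0:
        raise ValueError("attach_at must be in (0, 1]")
    rng = np.random.default_rng(seed)
    m = morphology.copy()
    log = EditLog()
    step_gamma = _resolve_step_gamma(m, growth)
    alpha = math.radians(growth.branch_divergence_angle)
    for sec in sections:
        entry_warnings: list[str] = []
        parent_length = _live_path_length(m, sec.node_path)
        daughter_length = daughter_fraction * parent_length
        if attach_at is None:
            attach_id, axis, radial_unit = _tip_frame(m, sec)
            if m.children[attach_id]:
                _warn(
                    entry_warnings,
                    f"branch: tip of section {sec.section_id} already has "
                    "children; creating a higher-order branch point",
                )
        else:
            attach_id, axis = _attachment_node(m, sec, attach_at)
            radial = m.nodes[attach_id].pos - m.soma_center
            norm = float(np.linalg.norm(radial))
            radial_unit = radial / norm if norm > 1e-12 else axis
        taper = section_taper_rate(m, sec) or 0.0
        perp = perpendicular_unit(axis, rng)
        for sign in (+1.0, -1.0):
            init = rotate_towards(axis, perp, sign * alpha)
            _, achieved = _grow_cable(
                m,
                attach_id,
                daughter_length,
                init,
                radial_unit,
                taper,
                growth,
                rng,
                step_gamma,
                first_step_exact=True,
            )
            log.append(
                LogEntry(
                    "branch",
                    sec.section_id,
                    daughter_length,
                    achieved,
                    tuple(entry_warnings),
                )
            )
            entry_warnings = []
    return m, log


def _attachment_node(
    m: Morphology, sec: Section, attach_at: float
) -> tuple[int, np.ndarray]:
    """Node at fraction ``attach_at`` of a section's arc length, inserting
    an interpolated sample inside an edge when necessary."""
    path = list(sec.node_path)
    pts = [m.nodes[i].pos for i in path]
    seg = [float(np.linalg.norm(pts[i + 1] - pts[i])) for i in range(len(pts) - 1)]
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    target = attach_at * cum[-1]
    j = int(np.searchsorted(cum, target + _EXACT) - 1)
    j = max(0, min(j, len(path) - 2))
    if abs(target - cum[j]) <= _EXACT and j > 0:
        nid = path[j]
        axis = unit(pts[j] - pts[j - 1])
        return nid, axis
    if abs(target - cum[j + 1]) <= _EXACT:
        nid = path[j + 1]
        axis = unit(pts[j + 1] - pts[j])
        return nid, axis
    t = (target - cum[j]) / seg[j]
    pos = pts[j] + t * (pts[j + 1] - pts[j])
    r = m.nodes[path[j]].radius + t * (
        m.nodes[path[j + 1]].radius - m.nodes[path[j]].radius
    )
    nid = m.add_node(m.nodes[path[j + 1]].type_code, pos, r, path[j])
    m.reparent(path[j + 1], nid)
    return nid, unit(pts[j + 1] - pts[j])


# ----------------------------------------------------------------------
# scaling


def scale(
    morphology: Morphology,
    region: str = "all",
    factor: float = 1.0,
    scale_radii: bool = False,
) -> tuple[Morphology, EditLog]:
    """Enlarge or reduce a region about the soma centroid.

    Coordinates transform as ``center + factor * (p - center)``; radii
    are multiplied by ``factor`` iff ``scale_radii``.  With a regional
    selection only samples of that type code move, so the untouched
    regions are bit-identical; stems stay attached because the scaling
    is centered on the soma they emanate from.
    """
    if factor <= 0:
        raise ValueError("scale factor must be > 0")
    if region not in ("all", "basal", "apical", "axon"):
        raise ValueError(f"unknown region {region!r}")
    m = morphology.copy()
    center = m.soma_center
    from .morphology import region_of_type

    for node in m.nodes.values():
        if region != "all" and region_of_type(node.type_code) != region:
            continue
        node.pos = center + factor * (node.pos - center)
        if scale_radii:
            node.radius *= factor
    log = EditLog([LogEntry("scale", None, factor, factor)])
    return m, log


# ----------------------------------------------------------------------
# pipelines


def apply_action(
    morphology: Morphology,
    selection: SelectionSpec,
    action: ActionSpec,
) -> tuple[Morphology, EditLog]:
    """Resolve one selection against the morphology and apply one action."""
    if action.action == "scale":
        return scale(
            morphology,
            region=selection.region,
            factor=action.magnitude if action.magnitude is not None else 1.0,
            scale_radii=action.scale_radii,
        )
    sections = resolve(selection, morphology)
    if not sections:
        return morphology.copy(), EditLog(
            [LogEntry(action.action, None, None, None,
                      ("empty selection; action skipped",))]
        )
    if action.action == "shrink":
        return shrink(morphology, sections, action.magnitude, action.magnitude_mode)
    if action.action == "remove":
        return remove(morphology, sections)
    if action.action == "extend":
        return extend(
            morphology,
            sections,
            action.magnitude,
            action.magnitude_mode,
            growth=action.growth_params,
            seed=action.seed,
        )
    if action.action == "branch":
        return branch(
            morphology,
            sections,
            action.branch_daughter_fraction,
            growth=action.growth_params,
            seed=action.seed,
        )
    raise ValueError(f"unknown action {action.action!r}")


def apply_pipeline(
    morphology: Morphology,
    steps: Sequence[tuple[SelectionSpec, ActionSpec]],
    seed: Optional[int] = None,
    reindex: bool = True,
) -> tuple[Morphology, EditLog]:
    """Apply an ordered list of (selection, action) steps.

    Each selection is re-resolved against the *current*, already-edited
    morphology — "an additional 10% of the remaining terminal dendrites"
    means exactly that.  Steps whose specs carry no seed of their own
    draw per-step seeds deterministically from the pipeline ``seed``.
    The final morphology is re-indexed, ready for SWC export.
    """
    master = np.random.default_rng(seed) if seed is not None else None

    def _derived() -> int:
        if master is None:
            raise ValueError(
                "a stochastic step has no seed and no pipeline seed was given"
            )
        return int(master.integers(0, 2**31 - 1))

    m = morphology
    full = EditLog()
    for sel, act in steps:
        if sel.mode == "random_fraction" and sel.seed is None:
            sel = dataclasses.replace(sel, seed=_derived())
        if act.action in ("extend", "branch") and act.seed is None:
            act = dataclasses.replace(act, seed=_derived())
        m, log = apply_action(m, sel, act)
        full.extend(log)
    if reindex:
        m = m.reindex()
    return m, full
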