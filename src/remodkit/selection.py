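"""Resolve declarative dendrite selections into concrete sections.

Three modes mirror how users pick targets in practice: naming specific
sections (``manual``), taking a whole region such as the entire apical
tree (``region``), or drawing a random portion of a region
(``random_fraction``).  Random draws are uniform over sections, without
replacement, and always require a seed so that every stochastic edit is
reproducible.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .errors import RemodWarning
from .morphology import Morphology, Section

__all__ = ["SelectionSpec", "resolve", "round_half_away"]


def round_half_away(x: float) -> int:
    """Round to the nearest integer, halves away from zero.

    This is the rule used to turn "17% of the terminal dendrites" into a
    count: round(0.5) == 1, unlike Python's banker's rounding.
    """
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


@dataclass(frozen=True)
class SelectionSpec:
    """Declarative description of which sections an action targets.

    mode
        ``manual`` (explicit ``section_ids``), ``region`` (every section
        of ``region``), or ``random_fraction`` (a seeded uniform draw of
        ``round(fraction * N)`` sections from the region).
    region
        ``all``, ``basal``, ``apical`` or ``axon``.
    terminal_only
        Restrict candidates to terminal sections before sampling.
    """

    mode: str = "region"
    region: str = "all"
    section_ids: tuple[int, ...] = field(default_factory=tuple)
    fraction: Optional[float] = None
    terminal_only: bool = False
    seed: Optional[int] = None


def resolve(spec: SelectionSpec, morphology: Morphology) -> list[Section]:
    """Resolve a selection against the *current* morphology.

    Returns sections ordered by section id.  An empty result is not an
    error: a :class:`RemodWarning` is emitted and downstream actions
    simply have nothing to do.
    """
    sections = morphology.sections()
    if spec.mode == "manual":
        by_id = {s.section_id: s for s in sections}
        chosen = []
        for sid in spec.section_ids:
            if sid not in by_id:
                raise ValueError(f"selection names unknown section id {sid}")
            chosen.append(by_id[sid])
    elif spec.mode in ("region", "random_fraction"):
        if spec.region not in ("all", "basal", "apical", "axon"):
            raise ValueError(f"unknown region {spec.region!r}")
        candidates = [
            s
            for s in sections
            if (spec.region == "all" or s.region == spec.region)
            and (not spec.terminal_only or s.is_terminal)
        ]
        if spec.mode == "region":
            chosen = candidates
        else:
            if spec.fraction is None or not 0.0 <= spec.fraction <= 1.0:
                raise ValueError("random_fraction requires fraction in [0, 1]")
            if spec.seed is None:
                raise ValueError("random_fraction selection requires a seed")
            k = round_half_away(spec.fraction * len(candidates))
            rng = np.random.default_rng(spec.seed)
            if k > 0:
                idx = rng.choice(len(candidates), size=k, replace=False)
                chosen = [candidates[int(i)] for i in idx]
            else:
                chosen = []
    else:
        raise ValueError(f"unknown selection mode {spec.mode!r}")

    chosen = sorted(chosen, key=lambda s: s.section_id)
    if not chosen:
        warnings.warn(
            f"selection ({spec.mode}, region={spec.region}) matched no "
            "sections",
            RemodWarning,
            stacklevel=2,
        )
    return chosen
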