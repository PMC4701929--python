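"""Ready-made remodeling pipelines for the two classic chronic-stress
phenotypes.

Chronic immobilization stress (CIS) atrophies hippocampal CA3 pyramidal
dendrites while hypertrophying basolateral amygdala (BLA) pyramidal
dendrites.  These pipelines express each end state as an ordered list of
(selection, action) steps; selections are re-resolved against the
current, already-edited morphology, so "an additional 10% of the
remaining terminal dendrites" is taken after the removals.

Per-step seeds are left unset here and derived from the pipeline seed at
:func:`remodkit.remodel.apply_pipeline` time.
"""

from __future__ import annotations

from .remodel import ActionSpec
from .selection import SelectionSpec

__all__ = ["ca3_stress_pipeline", "bla_stress_pipeline"]


def ca3_stress_pipeline() -> list[tuple[SelectionSpec, ActionSpec]]:
    """CA3 atrophy: remove 17% of apical terminal dendrites, shrink a
    further 10% of the remaining ones by 18%; remove 15% of basal
    terminal dendrites, shrink a further 5% of the remaining ones by 5%."""
    apical = dict(mode="random_fraction", region="apical", terminal_only=True)
    basal = dict(mode="random_fraction", region="basal", terminal_only=True)
    return [
        (SelectionSpec(**apical, fraction=0.17), ActionSpec("remove")),
        (SelectionSpec(**apical, fraction=0.10),
         ActionSpec("shrink", "percent", 18.0)),
        (SelectionSpec(**basal, fraction=0.15), ActionSpec("remove")),
        (SelectionSpec(**basal, fraction=0.05),
         ActionSpec("shrink", "percent", 5.0)),
    ]


def bla_stress_pipeline() -> list[tuple[SelectionSpec, ActionSpec]]:
    """BLA hypertrophy: branch 10% of terminal dendrites with daughters
    80% of the parent length, then extend 20% of the (now more numerous)
    terminal dendrites by 70% of their length."""
    terminals = dict(mode="random_fraction", region="all", terminal_only=True)
    return [
        (SelectionSpec(**terminals, fraction=0.10),
         ActionSpec("branch", branch_daughter_fraction=0.8)),
        (SelectionSpec(**terminals, fraction=0.20),
         ActionSpec("extend", "percent", 70.0)),
    ]
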