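import numpy as np
import pytest

import remodkit as rk
from remodkit.synth import SyntheticSpec, generate

# Toy Y cell: one soma point, a 10 um stem sampled at its midpoint, and
# two 10 um terminal daughters whose tips sit 18.97 um from the soma.
# Hand-checkable: total dendritic length 30, one branch point, two
# terminals, terminal path length 20.
TOY_Y_TEXT = """\
# toy Y: 10 um stem + two 10 um terminal daughters
1 1 0 0 0 5 -1
2 3 0 5 0 1 1
3 3 0 10 0 1 2
4 3 6 18 0 0.5 3
5 3 -6 18 0 0.5 3
"""


@pytest.fixture
def toy_y_text() -> str:
    return TOY_Y_TEXT


@pytest.fixture
def toy_y() -> rk.Morphology:
    m, _ = rk.loads(TOY_Y_TEXT)
    return m


@pytest.fixture
def small_tree():
    """Factory for small (< 50 sample) seeded bifurcating cells."""

    def make(seed: int, terminals: int = 2, basal: int = 1, apical: int = 1,
             **overrides) -> rk.Morphology:
        kwargs = dict(
            n_basal_stems=basal,
            n_apical_stems=apical,
            terminals_per_stem=terminals,
            mean_section_length=18.0,
            section_length_cv=0.4,
            mean_step_length=5.0,
            seed=seed,
        )
        kwargs.update(overrides)
        return generate(SyntheticSpec(**kwargs))

    return make


def perfect_binary_records(depth: int, edge: float = 10.0):
    """Soma + one stem carrying a perfect binary tree of the given depth.

    Terminal sections have centrifugal order ``depth``; the stem has
    2**depth terminals and 2**depth - 1 branch points.
    """
    records = [rk.SWCRecord(1, 1, 0.0, 0.0, 0.0, 4.0, -1)]
    next_id = [2]

    def grow(parent_id, x, y, level):
        nid = next_id[0]
        next_id[0] += 1
        records.append(rk.SWCRecord(nid, 3, x, y, 0.0, 1.0, parent_id))
        if level < depth:
            dx = edge / (2.0 ** (level + 1))
            grow(nid, x - dx, y + edge, level + 1)
            grow(nid, x + dx, y + edge, level + 1)

    grow(1, 0.0, edge, 0)
    return records
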