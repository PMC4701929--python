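"""Two-group comparison of morphology populations.

Compares a control and a treated/remodeled group of cells metric by
metric, reporting group means, SEMs and the percent change of the
means::

    percent change = 100 * (mean_treated - mean_control) / mean_control

computed on group means (not the mean of per-cell changes) and rounded
to two decimals (half-even).  Radial profiles track dendritic length or
branch-point counts per radial-distance bin (Sholl shells) with group
means and SEMs on common bins.  No inferential statistics are attached.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd

from .morphology import Morphology
from .morphometry import MorphometryReport, report, sholl

__all__ = [
    "percent_change",
    "GroupComparison",
    "compare_groups",
    "comparisons_to_dataframe",
    "RadialProfile",
    "radial_profiles",
    "plot_radial_profile",
    "DEFAULT_METRICS",
]


def percent_change(
    mean_control: float, mean_treated: float, ndigits: Optional[int] = 2
) -> float:
    """100 * (treated - control) / control, rounded half-even.

    Pass ``ndigits=None`` for the unrounded value; ``ndigits=0`` returns
    a float rounded to integer precision.
    """
    if mean_control == 0:
        raise ValueError("percent change is undefined for a zero control mean")
    value = 100.0 * (mean_treated - mean_control) / mean_control
    return value if ndigits is None else float(round(value, ndigits))


def _sem(values: np.ndarray) -> float:
    if len(values) < 2:
        return 0.0
    return float(np.std(values, ddof=1) / np.sqrt(len(values)))


#: metric name -> extractor from a per-region MorphometryReport
_EXTRACTORS: dict[str, Callable[[MorphometryReport, str], float]] = {
    "total_length": lambda r, reg: r[reg].total_length,
    "total_surface": lambda r, reg: r[reg].total_surface,
    "total_volume": lambda r, reg: r[reg].total_volume,
    "n_branch_points": lambda r, reg: float(r[reg].n_branch_points),
    "n_terminals": lambda r, reg: float(r[reg].n_terminals),
    "max_branch_order": lambda r, reg: float(r[reg].max_branch_order),
    "mean_taper_rate": lambda r, reg: r[reg].mean_taper_rate,
    "mean_terminal_path_length": lambda r, reg: (
        float(np.mean(r[reg].terminal_path_lengths))
        if r[reg].terminal_path_lengths
        else float("nan")
    ),
}

DEFAULT_METRICS: tuple[tuple[str, str], ...] = (
    ("total_length", "all"),
    ("total_length", "basal"),
    ("total_length", "apical"),
    ("n_branch_points", "all"),
    ("n_branch_points", "basal"),
    ("n_branch_points", "apical"),
    ("n_terminals", "all"),
)


@dataclass(frozen=True)
class GroupComparison:
    metric: str
    region: str
    mean_a: float
    sem_a: float
    n_a: int
    mean_b: float
    sem_b: float
    n_b: int
    percent_change: float  # % , rounded to 2 decimals


def compare_groups(
    cells_a: Sequence[Morphology],
    cells_b: Sequence[Morphology],
    metrics: Sequence[tuple[str, str]] = DEFAULT_METRICS,
) -> list[GroupComparison]:
    """Per-metric group means, SEMs and percent change of the means.

    ``metrics`` is a sequence of (metric_name, region) pairs; group A is
    the control.  Raises on an empty group.
    """
    if not cells_a or not cells_b:
        raise ValueError("both groups must be non-empty")
    reports_a = [report(c) for c in cells_a]
    reports_b = [report(c) for c in cells_b]
    out = []
    for metric, region in metrics:
        try:
            extract = _EXTRACTORS[metric]
        except KeyError:
            raise ValueError(f"unknown metric {metric!r}") from None
        va = np.array([extract(r, region) for r in reports_a], float)
        vb = np.array([extract(r, region) for r in reports_b], float)
        mean_a, mean_b = float(np.mean(va)), float(np.mean(vb))
        out.append(
            GroupComparison(
                metric=metric,
                region=region,
                mean_a=mean_a,
                sem_a=_sem(va),
                n_a=len(va),
                mean_b=mean_b,
                sem_b=_sem(vb),
                n_b=len(vb),
                percent_change=percent_change(mean_a, mean_b),
            )
        )
    return out


def comparisons_to_dataframe(comparisons: Sequence[GroupComparison]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "metric": c.metric,
                "region": c.region,
                "control_mean": c.mean_a,
                "control_sem": c.sem_a,
                "control_n": c.n_a,
                "treated_mean": c.mean_b,
                "treated_sem": c.sem_b,
                "treated_n": c.n_b,
                "percent_change": c.percent_change,
            }
            for c in comparisons
        ]
    )


@dataclass
class RadialProfile:
    """Group mean ± SEM of a quantity per radial-distance bin."""

    quantity: str  # length | branch_points
    region: str
    bin_edges: np.ndarray  # μm
    mean_a: np.ndarray
    sem_a: np.ndarray
    mean_b: np.ndarray
    sem_b: np.ndarray

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_low": self.bin_edges[:-1],
                "bin_high": self.bin_edges[1:],
                "control_mean": self.mean_a,
                "control_sem": self.sem_a,
                "treated_mean": self.mean_b,
                "treated_sem": self.sem_b,
            }
        )


def _cell_profiles(
    cells: Sequence[Morphology], bin_width: float, variant: str, region: str
) -> list[np.ndarray]:
    return [
        sholl(c, radius_step=bin_width, variant=variant, region=region).values
        for c in cells
    ]


def radial_profiles(
    cells_a: Sequence[Morphology],
    cells_b: Sequence[Morphology],
    bin_width: float = 20.0,
    quantity: str = "length",
    region: str = "all",
) -> RadialProfile:
    """Group-level radial profiles on common bins.

    ``quantity="length"`` sums dendritic length per Sholl shell (so each
    cell's bins sum to its total dendritic length); ``"branch_points"``
    counts branch points per shell.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be > 0")
    if quantity not in ("length", "branch_points"):
        raise ValueError(f"unknown quantity {quantity!r}")
    profiles_a = _cell_profiles(cells_a, bin_width, quantity, region)
    profiles_b = _cell_profiles(cells_b, bin_width, quantity, region)
    n_bins = max(len(p) for p in profiles_a + profiles_b)

    def _stack(profiles: list[np.ndarray]) -> np.ndarray:
        return np.array(
            [np.pad(p, (0, n_bins - len(p))) for p in profiles], float
        )

    stacked_a, stacked_b = _stack(profiles_a), _stack(profiles_b)
    return RadialProfile(
        quantity=quantity,
        region=region,
        bin_edges=np.arange(n_bins + 1, dtype=float) * bin_width,
        mean_a=stacked_a.mean(axis=0),
        sem_a=np.apply_along_axis(_sem, 0, stacked_a),
        mean_b=stacked_b.mean(axis=0),
        sem_b=np.apply_along_axis(_sem, 0, stacked_b),
    )


def plot_radial_profile(profile: RadialProfile, path) -> None:
    """Save a simple mean ± SEM radial-profile figure as an image."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    centers = 0.5 * (profile.bin_edges[:-1] + profile.bin_edges[1:])
    fig, ax = plt.subplots(figsize=(5, 3.5))
    ax.errorbar(centers, profile.mean_a, yerr=profile.sem_a, label="control",
                capsize=2)
    ax.errorbar(centers, profile.mean_b, yerr=profile.sem_b, label="treated",
                capsize=2)
    unit = "μm" if profile.quantity == "length" else "count"
    ax.set_xlabel("radial distance from soma (μm)")
    ax.set_ylabel(f"{profile.quantity} per bin ({unit})")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
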