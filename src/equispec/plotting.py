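"""Convenience plots: species-distribution diagrams and competition curves.

Plots are a presentation aid only; every quantitative surface of the package
is the CSV/YAML output.
"""

from __future__ import annotations

from typing import Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .model import EquilibriumModel
from .speciation import CompetitionProfile, SpeciationPoint


def plot_speciation(
    points: Sequence[SpeciationPoint],
    model: EquilibriumModel,
    ax: plt.Axes | None = None,
    min_fraction: float = 0.01,
) -> plt.Axes:
    """Species-distribution diagram: fraction of the reference vs pH."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    ph = [pt.pH for pt in points]
    keys: list = []
    for pt in points:
        if pt.fractions is None:
            continue
        for key in pt.fractions:
            if key not in keys:
                keys.append(key)
    by_key = {sp.key: sp for sp in model.species}
    for key in keys:
        curve = [0.0 if pt.fractions is None else pt.fractions.get(key, 0.0) for pt in points]
        if max(curve) < min_fraction:
            continue
        label = "free" if key == "free" else model.species_name(by_key[key])
        ax.plot(ph, [100 * c for c in curve], label=label)
    ax.set_xlabel("pH")
    reference = points[0].reference if points else None
    ax.set_ylabel(f"% of total {reference}" if reference else "% of total")
    ax.set_ylim(0, 105)
    ax.legend(fontsize=8, ncol=2)
    ax.set_title(model.label)
    return ax


def plot_competition(profile: CompetitionProfile, ax: plt.Axes | None = None) -> plt.Axes:
    """Bound-metal fraction per competing ligand vs pH."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    for ligand, curve in profile.bound.items():
        ax.plot(profile.ph, 100 * curve, label=ligand)
    ax.plot(profile.ph, 100 * profile.unbound, "k--", label=f"free {profile.metal}")
    ax.set_xlabel("pH")
    ax.set_ylabel(f"% of total {profile.metal}")
    ax.set_ylim(0, 105)
    ax.legend(fontsize=8)
    return ax
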