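"""Diagnostic figures: normalized-fluorescence densities and trajectories."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .io import EventTable
from .quantify import CNVTrajectory, normalize_concentration

__all__ = ["plot_concentration_density", "plot_trajectory"]


def plot_concentration_density(
    samples: list[EventTable],
    path: str | Path,
    log: bool = True,
) -> None:
    """Overlaid density (histogram) of FLUOR/FSC-A per sample."""
    fig, ax = plt.subplots(figsize=(6, 4))
    for table in samples:
        conc, _ = normalize_concentration(table)
        conc = conc[conc > 0] if log else conc
        if len(conc) == 0:
            continue
        values = np.log10(conc) if log else conc
        label = f"{table.role or 'sample'} g{table.generation}"
        ax.hist(values, bins=100, density=True, histtype="step", label=label)
    ax.set_xlabel("log10 normalized fluorescence" if log else "normalized fluorescence")
    ax.set_ylabel("density")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def plot_trajectory(
    traj: CNVTrajectory,
    path: str | Path,
    theta: float | None = 0.05,
) -> None:
    """CNV proportion over generations, with the control series if present."""
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(traj.generations, traj.p, "o-", label=f"{traj.population} CNV proportion")
    if traj.control_p is not None:
        ax.plot(traj.generations, traj.control_p, "s--", color="grey",
                label="one-copy control (false positives)")
    if theta is not None:
        ax.axhline(theta, color="red", lw=0.8, ls=":", label=f"theta = {theta}")
    ax.set_xlabel("generation")
    ax.set_ylabel("proportion of population")
    ax.set_ylim(-0.02, 1.02)
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
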