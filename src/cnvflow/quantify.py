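"""Per-cell copy-number estimates, per-sample summaries and trajectories.

Fluorescent protein abundance scales with cell size, so the per-cell
signal is normalized by forward scatter area: ``concentration =
FLUOR / FSC-A`` on the raw (linear) scale. The concentration is
proportional to the ploidy-normalized reporter copy number, so dividing
by the one-copy control's median concentration and multiplying by ploidy
yields a continuous per-cell copy-number estimate.

Per-sample summaries carry the gated copy-class proportions and the
median normalized fluorescence over all singlets — a convenient summary
that deliberately convolves CNV frequency with per-cell copy number and
should be read with that caveat. Trajectories order summaries by
generation and attach the one-copy control's CNV-gate proportion, which
downstream dynamics estimation uses as an empirical false-positive series.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .gating import GateCounts
from .io import EventTable

__all__ = [
    "SampleSummary",
    "CNVTrajectory",
    "normalize_concentration",
    "estimate_copy_number",
    "summarize_sample",
    "assemble_trajectory",
]


def normalize_concentration(
    events: EventTable,
    floor: float = 0.0,
) -> tuple[np.ndarray, int]:
    """Per-event concentration FLUOR / FSC-A on the raw scale.

    Events with FSC-A <= *floor* are excluded; returns ``(values,
    n_excluded)``. All events excluded is an error.
    """
    fsc = events["FSC-A"]
    fluor = events["FLUOR"]
    keep = fsc > floor
    n_excluded = int(len(fsc) - keep.sum())
    if len(fsc) and not keep.any():
        raise ValueError("all events have non-positive FSC-A; cannot normalize")
    return fluor[keep] / fsc[keep], n_excluded


def estimate_copy_number(
    concentrations: np.ndarray,
    reference_median: float,
    ploidy: int = 1,
) -> np.ndarray:
    """Continuous per-event copy estimate: ploidy × concentration / reference.

    *reference_median* is the median concentration of a one-copy control
    grown and measured in parallel; estimates are not rounded.
    """
    if not reference_median > 0:
        raise ValueError(f"reference median must be positive, got {reference_median}")
    return ploidy * np.asarray(concentrations, dtype=float) / reference_median


@dataclass
class SampleSummary:
    """Gated proportions and normalized-fluorescence summary for one sample."""

    population: str
    generation: int
    n_singlets: int
    p0: float
    p1: float
    p2plus: float
    median_norm_fluor: float
    flags: tuple[str, ...] = ()

    def as_row(self) -> dict:
        return {
            "population": self.population, "generation": self.generation,
            "n_singlets": self.n_singlets, "p0": self.p0, "p1": self.p1,
            "p2plus": self.p2plus, "median_norm_fluor": self.median_norm_fluor,
            "flags": ";".join(self.flags),
        }


def summarize_sample(
    counts: GateCounts,
    events: EventTable,
    low_count_min: int = 1000,
) -> SampleSummary:
    """Combine gate counts with the median normalized fluorescence.

    The median is the midpoint-of-central-order-statistics convention
    (numpy's default), computed over all events with positive FSC-A.
    Problems are flagged (``empty``, ``low_count``) rather than raised.
    """
    flags: list[str] = []
    if counts.undefined or counts.n_singlets == 0:
        flags.append("empty")
        median = float("nan")
    else:
        scope = (events.subset(counts.singlet_mask)
                 if counts.singlet_mask is not None else events)
        conc, _ = normalize_concentration(scope)
        median = float(np.median(conc)) if len(conc) else float("nan")
        if counts.n_singlets < low_count_min:
            flags.append("low_count")
    return SampleSummary(
        population=events.population or "unknown",
        generation=int(events.generation) if events.generation is not None else -1,
        n_singlets=counts.n_singlets,
        p0=counts.proportions["Copy0"],
        p1=counts.proportions["Copy1"],
        p2plus=counts.proportions["Copy2plus"],
        median_norm_fluor=median,
        flags=tuple(flags),
    )


@dataclass
class CNVTrajectory:
    """Per-generation variant-class proportions for one population.

    ``p`` is the Copy2plus proportion by default; set ``variant_class`` to
    ``"copy0"`` for deletion selections, where the zero-copy class is the
    variant of interest. ``control_p`` is the one-copy control's proportion
    inside the same variant gate per timepoint (the false-positive series).
    """

    population: str
    generations: np.ndarray
    p: np.ndarray
    control_p: np.ndarray | None = None
    n_singlets: np.ndarray | None = None
    variant_class: str = "copy2plus"

    def __post_init__(self) -> None:
        self.generations = np.asarray(self.generations, dtype=int)
        self.p = np.asarray(self.p, dtype=float)
        if len(self.generations) != len(self.p):
            raise ValueError("generations and p must have equal length")
        if np.any(np.diff(self.generations) <= 0):
            raise ValueError("generations must be strictly increasing")
        with np.errstate(invalid="ignore"):
            if np.any((self.p < 0) | (self.p > 1)):
                raise ValueError("proportions must lie in [0, 1]")
        if self.control_p is not None:
            self.control_p = np.asarray(self.control_p, dtype=float)
            if len(self.control_p) != len(self.generations):
                raise ValueError("control_p must align with generations")

    def __len__(self) -> int:
        return len(self.generations)

    def to_frame(self) -> pd.DataFrame:
        out = pd.DataFrame({"generation": self.generations, "p_cnv": self.p})
        if self.control_p is not None:
            out["control_p"] = self.control_p
        if self.n_singlets is not None:
            out["n_singlets"] = self.n_singlets
        out.insert(0, "population", self.population)
        return out


def assemble_trajectory(
    summaries: list[SampleSummary],
    control_summaries: list[SampleSummary] | None = None,
    variant_class: str = "copy2plus",
) -> CNVTrajectory:
    """Order experimental summaries by generation into a trajectory.

    *control_summaries* are one-copy control samples; their proportion in
    the variant gate is attached per timepoint (missing timepoints are
    gaps — never interpolated). Duplicate (population, generation) pairs
    are an error.
    """
    if len(summaries) < 2:
        raise ValueError("a trajectory requires at least two timepoints")
    if variant_class not in ("copy2plus", "copy0"):
        raise ValueError("variant_class must be 'copy2plus' or 'copy0'")
    pops = {s.population for s in summaries}
    if len(pops) > 1:
        raise ValueError(f"summaries mix populations: {sorted(pops)}")
    keys = [(s.population, s.generation) for s in summaries]
    if len(set(keys)) != len(keys):
        dupes = sorted({k for k in keys if keys.count(k) > 1})
        raise ValueError(f"duplicate (population, generation) pairs: {dupes}")

    ordered = sorted(summaries, key=lambda s: s.generation)
    gens = np.array([s.generation for s in ordered])
    value = (lambda s: s.p2plus) if variant_class == "copy2plus" else (lambda s: s.p0)
    p = np.array([value(s) for s in ordered])
    n = np.array([s.n_singlets for s in ordered])

    control_p = None
    if control_summaries:
        by_gen = {}
        for s in control_summaries:
            if s.generation in by_gen:
                raise ValueError(f"duplicate control generation {s.generation}")
            by_gen[s.generation] = value(s)
        control_p = np.array([by_gen.get(int(g), np.nan) for g in gens])

    return CNVTrajectory(
        population=ordered[0].population, generations=gens, p=p,
        control_p=control_p, n_singlets=n, variant_class=variant_class,
    )
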