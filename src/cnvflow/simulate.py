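"""Ground-truthed simulation of CNV-reporter evolution experiments.

Two layers:

* **Population genetics.** A discrete-generation mutation–selection
  recurrence over copy-number classes. Each generation, the one-copy
  (ancestral) class loses probability mass ``delta_amp`` to amplified
  classes and ``delta_del`` to the zero-copy class, then classes are
  reweighted by relative fitness ``1 + s_i`` and renormalized. In
  ``wright_fisher`` mode class counts are additionally resampled
  multinomially at the effective population size, adding genetic drift.

* **Observation.** Sampled generations are rendered as flow-cytometry
  events. Cell size is lognormal; forward scatter area and height both
  report size (singlets sit on the FSC-A ≈ FSC-H diagonal); fluorescence
  is size-proportional with multiplicative lognormal noise, scaled by the
  ploidy-normalized reporter copy number raised to ``copy_scaling_exponent``
  (β < 1 emulates the sub-linear scaling seen with multi-copy reporters),
  plus additive autofluorescence. Doublets sum the areas of two cells but
  keep the larger height, putting them off the diagonal; debris is rendered
  ~100× smaller than cells with autofluorescence only.

Control-strain samples (pure zero-, one- and two-copy populations with a
stable reporter signal) are emitted alongside every experimental sample,
mirroring how engineered control strains are propagated in parallel and
measured at each timepoint.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .io import DEBRIS_LABEL, DOUBLET_LABEL, EventTable, write_events, write_manifest

__all__ = [
    "SimulationConfig",
    "TrueTrajectory",
    "simulate_evolution",
    "sample_events",
    "sample_seed",
    "sample_timecourse",
    "simulate_timecourse",
]

_DEBRIS_SIZE_FACTOR = 100.0  # debris is ~100x smaller than cells
_SSC_SIGMA = 0.25            # lognormal spread of SSC-A around cell size


def _lognormal_sigma(cv: float) -> float:
    """Log-scale sigma of a lognormal with coefficient of variation *cv*."""
    return math.sqrt(math.log1p(cv * cv))


@dataclass(frozen=True)
class SimulationConfig:
    """Evolution-model and observation-model parameters.

    Defaults emulate the design scale of a chemostat reporter experiment:
    ~250 generations sampled every 10 (26 timepoints), 10,000 events per
    sample, 25% cell-size CV, 15% multiplicative fluorescence CV, 5%
    doublets and 5% debris. The amplified class carries three reporter
    copies (amplifications are "two or more" copies; three is a typical
    multi-copy allele) with selection coefficient 0.1 per generation and a
    formation rate of 1e-4 per cell per generation.
    """

    copy_numbers: tuple[int, ...] = (0, 1, 3)
    initial_freqs: tuple[float, ...] = (0.0, 1.0, 0.0)
    s: tuple[float, ...] = (0.0, 0.0, 0.1)
    delta_amp: float = 1e-4
    delta_del: float = 1e-5
    pop_size: int = 100_000
    mode: str = "deterministic"
    generations: int = 250
    sample_every: int = 10
    events_per_sample: int = 10_000
    size_mu: float = math.log(5.0e4)
    size_cv: float = 0.25
    fluor_per_copy: float = 0.2
    fluor_cv: float = 0.15
    autofluor_mu: float = 200.0
    autofluor_cv: float = 0.5
    doublet_frac: float = 0.05
    debris_frac: float = 0.05
    copy_scaling_exponent: float = 1.0
    ploidy: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        k = len(self.copy_numbers)
        if len(self.initial_freqs) != k or len(self.s) != k:
            raise ValueError("copy_numbers, initial_freqs and s must have equal length")
        if any((not float(c).is_integer()) or c < 0 for c in self.copy_numbers):
            raise ValueError("copy numbers must be non-negative integers")
        if sum(1 for c in self.copy_numbers if c == 1) != 1:
            raise ValueError("exactly one class must be the one-copy ancestral class")
        if abs(sum(self.initial_freqs) - 1.0) > 1e-9:
            raise ValueError("initial_freqs must sum to 1 (tolerance 1e-9)")
        if any(f < 0 or f > 1 for f in self.initial_freqs):
            raise ValueError("initial_freqs must lie in [0, 1]")
        if any(si <= -1.0 for si in self.s):
            raise ValueError("selection coefficients must exceed -1")
        for name in ("delta_amp", "delta_del", "doublet_frac", "debris_frac"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.delta_amp + self.delta_del > 1.0:
            raise ValueError("delta_amp + delta_del must not exceed 1")
        if self.doublet_frac + self.debris_frac > 1.0:
            raise ValueError("doublet_frac + debris_frac must not exceed 1")
        if self.mode not in ("deterministic", "wright_fisher"):
            raise ValueError(f"mode must be deterministic|wright_fisher, got {self.mode!r}")
        if self.pop_size < 1:
            raise ValueError("pop_size must be at least 1")
        if self.generations < 0:
            raise ValueError("generations must be non-negative")
        if self.sample_every < 1:
            raise ValueError("sample_every must be at least 1")
        if self.events_per_sample < 0:
            raise ValueError("events_per_sample must be non-negative")
        if self.size_cv < 0 or self.fluor_cv < 0 or self.autofluor_cv < 0:
            raise ValueError("coefficients of variation must be non-negative")
        if self.fluor_per_copy <= 0:
            raise ValueError("fluor_per_copy must be positive")
        if self.copy_scaling_exponent <= 0:
            raise ValueError("copy_scaling_exponent must be positive")
        if self.ploidy not in (1, 2):
            raise ValueError("ploidy must be 1 or 2")

    @property
    def ancestral_index(self) -> int:
        return next(i for i, c in enumerate(self.copy_numbers) if c == 1)

    @property
    def sampled_generations(self) -> np.ndarray:
        return np.arange(0, self.generations + 1, self.sample_every)


@dataclass
class TrueTrajectory:
    """Per-generation class frequencies of one simulated population."""

    generations: np.ndarray
    class_freqs: np.ndarray  # shape (n_generations, n_classes)
    copy_numbers: tuple[int, ...]
    seed: int

    def __post_init__(self) -> None:
        self.generations = np.asarray(self.generations, dtype=int)
        self.class_freqs = np.asarray(self.class_freqs, dtype=float)
        if np.any(np.diff(self.generations) <= 0):
            raise ValueError("generations must be strictly increasing")
        sums = self.class_freqs.sum(axis=1)
        if np.any(np.abs(sums - 1.0) > 1e-9):
            raise ValueError("class frequencies must sum to 1 at every generation")

    def freqs_at(self, generation: int) -> np.ndarray:
        idx = np.searchsorted(self.generations, generation)
        if idx >= len(self.generations) or self.generations[idx] != generation:
            raise KeyError(f"generation {generation} not in trajectory")
        return self.class_freqs[idx]

    def cnv_freq(self, generation: int | None = None) -> np.ndarray | float:
        """Summed frequency of classes with two or more copies."""
        cnv = np.asarray(self.copy_numbers) >= 2
        series = self.class_freqs[:, cnv].sum(axis=1)
        if generation is None:
            return series
        return float(series[np.searchsorted(self.generations, generation)])


def _evolution_rng(config: SimulationConfig) -> np.random.Generator:
    # child 0 of the master seed; samples use children 1, 2, ... (see
    # simulate_timecourse) so every output is independently regenerable.
    return np.random.default_rng(np.random.SeedSequence((config.seed, 0)))


def simulate_evolution(config: SimulationConfig) -> TrueTrajectory:
    """Run the mutation–selection(–drift) recurrence for all generations."""
    copy = np.asarray(config.copy_numbers)
    k = len(copy)
    anc = config.ancestral_index
    amplified = np.flatnonzero(copy >= 2)
    deleted = np.flatnonzero(copy == 0)
    if config.delta_amp > 0 and amplified.size == 0:
        raise ValueError("delta_amp > 0 requires an amplified (copy >= 2) class")
    if config.delta_del > 0 and deleted.size == 0:
        raise ValueError("delta_del > 0 requires a zero-copy class")
    fitness = 1.0 + np.asarray(config.s, dtype=float)
    rng = _evolution_rng(config)

    freqs = np.empty((config.generations + 1, k))
    f = np.asarray(config.initial_freqs, dtype=float)
    f = f / f.sum()
    freqs[0] = f
    for t in range(1, config.generations + 1):
        prev_anc = f[anc]
        f = f.copy()
        f[anc] -= prev_anc * (config.delta_amp + config.delta_del)
        if amplified.size and config.delta_amp > 0:
            f[amplified] += prev_anc * config.delta_amp / amplified.size
        if deleted.size and config.delta_del > 0:
            f[deleted] += prev_anc * config.delta_del / deleted.size
        f = f * fitness
        f = f / f.sum()
        if config.mode == "wright_fisher":
            counts = rng.multinomial(config.pop_size, f / f.sum())
            f = counts / config.pop_size
        freqs[t] = f
    return TrueTrajectory(
        generations=np.arange(config.generations + 1),
        class_freqs=freqs,
        copy_numbers=tuple(config.copy_numbers),
        seed=config.seed,
    )


def _render_cells(
    classes: np.ndarray,
    copy_numbers: np.ndarray,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Draw (size, ssc, fluorescence) for cells with the given class indices."""
    n = len(classes)
    sigma_size = _lognormal_sigma(config.size_cv)
    size = np.exp(rng.normal(config.size_mu, sigma_size, size=n))
    ssc = size * np.exp(rng.normal(0.0, _SSC_SIGMA, size=n))
    c = copy_numbers[classes].astype(float)
    beta = config.copy_scaling_exponent
    signal = np.where(
        c > 0,
        config.fluor_per_copy * (c / config.ploidy) ** beta * size,
        0.0,
    )
    if config.fluor_cv > 0:
        signal = signal * np.exp(rng.normal(0.0, _lognormal_sigma(config.fluor_cv), n))
    fluor = signal + _draw_autofluor(n, config, rng)
    return size, ssc, fluor


def _draw_autofluor(n: int, config: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    if config.autofluor_mu <= 0:
        return np.zeros(n)
    sigma = _lognormal_sigma(config.autofluor_cv)
    return np.exp(rng.normal(math.log(config.autofluor_mu), sigma, size=n))


def sample_events(
    freqs: np.ndarray,
    config: SimulationConfig,
    seed: int | np.random.SeedSequence,
    copy_numbers: tuple[int, ...] | None = None,
    role: str | None = None,
    generation: int | None = None,
    population: str | None = None,
) -> EventTable:
    """Render one flow-cytometry sample from per-class frequencies.

    *copy_numbers* overrides the config's classes, which is how control
    strains (a single pure class of known copy number) are rendered.
    True class labels are kept in a ``true_class`` column for testing.
    """
    copy = np.asarray(copy_numbers if copy_numbers is not None else config.copy_numbers)
    freqs = np.asarray(freqs, dtype=float)
    if len(freqs) != len(copy):
        raise ValueError("freqs and copy_numbers must have equal length")
    if abs(freqs.sum() - 1.0) > 1e-9:
        raise ValueError("class frequencies must sum to 1")
    freqs = freqs / freqs.sum()
    rng = np.random.default_rng(seed)
    n = config.events_per_sample

    columns = ("FSC-A", "FSC-H", "SSC-A", "FLUOR", "true_class")
    if n == 0:
        data = pd.DataFrame({c: np.array([]) for c in columns})
        return EventTable(data=data, role=role, generation=generation,
                          population=population)

    n_debris, n_doublet, n_singlet = rng.multinomial(
        n, [config.debris_frac, config.doublet_frac,
            1.0 - config.debris_frac - config.doublet_frac]
    )

    fsc_a = np.empty(n)
    fsc_h = np.empty(n)
    ssc_a = np.empty(n)
    fluor = np.empty(n)
    label = np.empty(n, dtype=int)

    # singlets
    sl = slice(0, n_singlet)
    cls = rng.choice(len(copy), size=n_singlet, p=freqs)
    size, ssc, flr = _render_cells(cls, copy, config, rng)
    fsc_a[sl], fsc_h[sl], ssc_a[sl], fluor[sl] = size, size, ssc, flr
    label[sl] = cls

    # doublets: areas add, height keeps the larger cell
    dl = slice(n_singlet, n_singlet + n_doublet)
    cls2 = rng.choice(len(copy), size=2 * n_doublet, p=freqs)
    size2, ssc2, flr2 = _render_cells(cls2, copy, config, rng)
    s1, s2 = size2[:n_doublet], size2[n_doublet:]
    fsc_a[dl] = s1 + s2
    fsc_h[dl] = np.maximum(s1, s2)
    ssc_a[dl] = ssc2[:n_doublet] + ssc2[n_doublet:]
    fluor[dl] = flr2[:n_doublet] + flr2[n_doublet:]
    label[dl] = DOUBLET_LABEL

    # debris: far smaller than cells, autofluorescence only
    db = slice(n_singlet + n_doublet, n)
    dsize = np.exp(rng.normal(
        config.size_mu - math.log(_DEBRIS_SIZE_FACTOR),
        _lognormal_sigma(config.size_cv), size=n_debris,
    ))
    fsc_a[db] = dsize
    fsc_h[db] = dsize
    ssc_a[db] = dsize * np.exp(rng.normal(0.0, _SSC_SIGMA, size=n_debris))
    fluor[db] = _draw_autofluor(n_debris, config, rng)
    label[db] = DEBRIS_LABEL

    order = rng.permutation(n)
    data = pd.DataFrame({
        "FSC-A": fsc_a[order],
        "FSC-H": fsc_h[order],
        "SSC-A": ssc_a[order],
        "FLUOR": fluor[order],
        "true_class": label[order],
    })
    return EventTable(data=data, role=role, generation=generation,
                      population=population)


_CONTROL_COPIES = {"control_0": 0, "control_1": 1, "control_2": 2}


def sample_seed(config: SimulationConfig, timepoint_index: int, role: str) -> np.random.SeedSequence:
    """Deterministic per-sample seed: child ``1 + 4*timepoint + role`` of the
    master seed (role order: experimental, control_0, control_1, control_2)."""
    roles = ("experimental", "control_0", "control_1", "control_2")
    counter = 1 + 4 * timepoint_index + roles.index(role)
    return np.random.SeedSequence((config.seed, counter))


def sample_timecourse(
    config: SimulationConfig,
    trajectory: TrueTrajectory | None = None,
    population: str = "pop1",
) -> tuple[list[EventTable], TrueTrajectory]:
    """In-memory timecourse: per sampled generation, one experimental sample
    plus the three control samples."""
    trajectory = trajectory or simulate_evolution(config)
    tables: list[EventTable] = []
    for i, gen in enumerate(config.sampled_generations):
        gen = int(gen)
        tables.append(sample_events(
            trajectory.freqs_at(gen), config, sample_seed(config, i, "experimental"),
            role="experimental", generation=gen, population=population,
        ))
        for role, copies in _CONTROL_COPIES.items():
            tables.append(sample_events(
                np.array([1.0]), config, sample_seed(config, i, role),
                copy_numbers=(copies,), role=role, generation=gen,
                population=population,
            ))
    return tables, trajectory


def simulate_timecourse(
    config: SimulationConfig,
    out_dir: str | Path,
    fmt: str = "fcs",
    population: str = "pop1",
) -> pd.DataFrame:
    """Simulate and write a full timecourse to *out_dir*.

    Writes one file per sample, a ``manifest.tsv`` (file, role, generation,
    population) and a ``truth.tsv`` of ground-truth class frequencies at the
    sampled generations. Returns the manifest.
    """
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise OSError(f"cannot create output directory {out_dir}: {exc}") from exc
    tables, trajectory = sample_timecourse(config, population=population)

    rows = []
    for table in tables:
        fname = f"{population}_g{table.generation:04d}_{table.role}.{fmt}"
        try:
            write_events(table, out_dir / fname, fmt=fmt)
        except OSError as exc:
            raise OSError(f"failed writing {out_dir / fname}: {exc}") from exc
        rows.append({"file": fname, "role": table.role,
                     "generation": table.generation, "population": population})
    manifest = pd.DataFrame(rows)
    write_manifest(manifest, out_dir / "manifest.tsv")

    grid = config.sampled_generations
    idx = np.searchsorted(trajectory.generations, grid)
    truth = pd.DataFrame(
        trajectory.class_freqs[idx],
        columns=[f"freq_copy{c}" for c in config.copy_numbers],
    )
    truth.insert(0, "generation", grid)
    truth.to_csv(out_dir / "truth.tsv", sep="\t", index=False)
    return manifest
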