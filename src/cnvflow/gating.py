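"""Hierarchical gating calibrated from copy-number control strains.

The gate hierarchy is a chain: **Cells** (FSC-A × SSC-A, excludes small
debris) → **Singlets** (FSC-A × FSC-H, keeps events on the area≈height
diagonal) → three adjacent, non-overlapping copy-number gates
(**Copy0 / Copy1 / Copy2plus**) drawn in transformed FSC-A × fluorescence
space, their boundaries calibrated from the zero-, one- and two-copy
control strains by a quantile/midpoint construction.

Because fluorescence scales with cell size, the automatic copy-number
boundaries are drawn along the size diagonal rather than as horizontal
cuts: events are scored on the size-detrended coordinate

    u = logicle(F) - shear * (log10(FSC-A) - x_ref)

with the shear slope fitted on the one-copy control (``shear=0`` gives
plain horizontal rectangle boundaries). This mirrors how gates are drawn
by hand on FSC-A × fluorescence plots, where the three copy-number
populations form parallel diagonal bands.

All gate boundaries are lower-inclusive / upper-exclusive, so the copy
gates partition their interval and never double-count an event.

:class:`GatingModel` wraps calibration and application in a scikit-learn
style estimator (``fit`` on control samples, ``predict``/``transform`` on
experimental ones); the module-level ``fit_*``/``apply_template`` functions
are thin wrappers kept for scripting.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .io import EventTable
from .transforms import TransformSpec, transform_logicle, transform_scatter

__all__ = [
    "CalibrationError",
    "RectGate",
    "BandGate",
    "ShearBandGate",
    "GatingTemplate",
    "GateCounts",
    "ContainmentReport",
    "GatingModel",
    "fit_cells_gate",
    "fit_singlet_gate",
    "fit_copy_gates",
    "apply_template",
    "assess_template",
    "calibrate_per_timepoint",
]

COPY_GATE_NAMES = ("Copy0", "Copy1", "Copy2plus")
_CONTROL_GATE = {"control_0": "Copy0", "control_1": "Copy1", "control_2": "Copy2plus"}


class CalibrationError(ValueError):
    """Raised when control samples cannot support gate calibration."""


@dataclass(frozen=True)
class RectGate:
    """Axis-aligned rectangle in a transformed 2-D channel space."""

    name: str
    parent: str
    xchan: str
    ychan: str
    xmin: float
    xmax: float
    ymin: float
    ymax: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.xmin) and np.isfinite(self.ymin)):
            raise ValueError(f"gate {self.name}: bounds must be finite")
        if self.xmin >= self.xmax or self.ymin >= self.ymax:
            raise ValueError(f"gate {self.name}: min must be < max on both axes")

    def contains(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        return (
            (x >= self.xmin) & (x < self.xmax)
            & (y >= self.ymin) & (y < self.ymax)
        )


@dataclass(frozen=True)
class BandGate:
    """Diagonal band |y - x - center| <= width in transformed space."""

    name: str
    parent: str
    xchan: str
    ychan: str
    width: float
    center: float = 0.0

    def __post_init__(self) -> None:
        if self.width < 0 or not np.isfinite(self.width):
            raise ValueError(f"gate {self.name}: band width must be finite and >= 0")

    def contains(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        return np.abs((y - x) - self.center) <= self.width


@dataclass(frozen=True)
class ShearBandGate:
    """Half-open band lo <= u < hi on the sheared fluorescence coordinate
    u = y - shear*(x - x_ref), drawn in transformed FSC-A × FLUOR space."""

    name: str
    parent: str
    xchan: str
    ychan: str
    lo: float
    hi: float
    shear: float
    x_ref: float
    xmin: float
    xmax: float

    def __post_init__(self) -> None:
        if not self.lo < self.hi:
            raise ValueError(f"gate {self.name}: lo must be < hi")

    def coordinate(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        return y - self.shear * (x - self.x_ref)

    def contains(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        u = self.coordinate(x, y)
        return (u >= self.lo) & (u < self.hi)


@dataclass
class GatingTemplate:
    """Calibrated gate hierarchy plus the transforms it was drawn in."""

    transform_spec: TransformSpec
    cells: RectGate
    singlets: BandGate
    copy_gates: tuple[ShearBandGate, ShearBandGate, ShearBandGate]
    metadata: dict = field(default_factory=dict)

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "transform_spec": asdict(self.transform_spec),
            "cells": asdict(self.cells),
            "singlets": asdict(self.singlets),
            "copy_gates": [asdict(g) for g in self.copy_gates],
            "metadata": self.metadata,
        }
        text = json.dumps(payload, indent=2, default=float)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "GatingTemplate":
        if isinstance(source, Path) or not str(source).lstrip().startswith("{"):
            text = Path(source).read_text()
        else:
            text = str(source)
        payload = json.loads(text)
        return cls(
            transform_spec=TransformSpec(**payload["transform_spec"]),
            cells=RectGate(**payload["cells"]),
            singlets=BandGate(**payload["singlets"]),
            copy_gates=tuple(ShearBandGate(**g) for g in payload["copy_gates"]),
            metadata=payload.get("metadata", {}),
        )


@dataclass
class GateCounts:
    """Counts and singlet-relative proportions for one gated sample."""

    n_events: int
    n_cells: int
    n_singlets: int
    counts: dict[str, int]
    proportions: dict[str, float]
    undefined: bool  # True when the sample has no singlets
    singlet_mask: np.ndarray | None = None  # per-event, for downstream summaries

    def as_row(self) -> dict:
        row = {"n_events": self.n_events, "n_cells": self.n_cells,
               "n_singlets": self.n_singlets}
        for name in COPY_GATE_NAMES:
            row[f"count_{name}"] = self.counts[name]
            row[f"p_{name}"] = self.proportions[name]
        return row


@dataclass
class ContainmentReport:
    """Fraction of control events inside their own copy-number gate."""

    per_timepoint: pd.DataFrame  # strain, generation, n_singlets, n_in_gate, fraction
    per_strain: dict[str, float]  # pooled across timepoints
    min_fraction: float
    threshold: float
    passed: bool


def _transformed(events: EventTable, spec: TransformSpec) -> dict[str, np.ndarray]:
    return {
        "FSC-A": transform_scatter(events["FSC-A"], spec),
        "FSC-H": transform_scatter(events["FSC-H"], spec),
        "SSC-A": transform_scatter(events["SSC-A"], spec),
        "FLUOR": transform_logicle(events["FLUOR"], spec),
    }


def fit_cells_gate(
    controls: Iterable[EventTable],
    q_debris: float = 0.05,
    spec: TransformSpec | None = None,
    margin: float = 0.5,
) -> RectGate:
    """Rectangle in log FSC-A × log SSC-A excluding the low-size debris mode.

    The lower FSC-A bound sits at the *q_debris* quantile of pooled control
    FSC-A; the remaining bounds are open (data extremes plus *margin*
    decades).
    """
    spec = spec or TransformSpec()
    controls = list(controls)
    if not controls or all(len(c) == 0 for c in controls):
        raise ValueError("cells gate calibration requires at least one non-empty control")
    if not (0.0 <= q_debris < 1.0):
        raise ValueError("q_debris must lie in [0, 1)")
    tx = np.concatenate([transform_scatter(c["FSC-A"], spec) for c in controls])
    ty = np.concatenate([transform_scatter(c["SSC-A"], spec) for c in controls])
    return RectGate(
        name="Cells", parent="root", xchan="FSC-A", ychan="SSC-A",
        xmin=float(np.quantile(tx, q_debris)),
        xmax=float(tx.max() + margin),
        ymin=float(ty.min() - margin),
        ymax=float(ty.max() + margin),
    )


def fit_singlet_gate(
    controls: Iterable[EventTable],
    cells_gate: RectGate,
    k: float = 4.0,
    min_width: float = 0.02,
    width: float | None = None,
    spec: TransformSpec | None = None,
    min_events: int = 100,
) -> BandGate:
    """Diagonal band around FSC-H = FSC-A, half-width k·MAD of the residual.

    Calibrated on control events inside the Cells gate; *width* overrides
    the fitted half-width (e.g. to reproduce a manually drawn band).
    """
    spec = spec or TransformSpec()
    if width is not None:
        return BandGate(name="Singlets", parent="Cells",
                        xchan="FSC-A", ychan="FSC-H", width=float(width))
    diffs = []
    for ctrl in controls:
        tx = transform_scatter(ctrl["FSC-A"], spec)
        ty = transform_scatter(ctrl["SSC-A"], spec)
        inside = cells_gate.contains(tx, ty)
        th = transform_scatter(ctrl["FSC-H"], spec)
        diffs.append((th - tx)[inside])
    d = np.concatenate(diffs) if diffs else np.array([])
    if len(d) < min_events:
        raise CalibrationError(
            f"singlet gate calibration needs >= {min_events} events inside the "
            f"Cells gate, got {len(d)}"
        )
    mad = float(np.median(np.abs(d - np.median(d))))
    return BandGate(name="Singlets", parent="Cells", xchan="FSC-A", ychan="FSC-H",
                    width=max(k * mad, min_width))


def _singlet_mask(events: EventTable, cells: RectGate, singlets: BandGate,
                  spec: TransformSpec) -> np.ndarray:
    tx = transform_scatter(events["FSC-A"], spec)
    ty = transform_scatter(events["SSC-A"], spec)
    th = transform_scatter(events["FSC-H"], spec)
    return cells.contains(tx, ty) & singlets.contains(tx, th)


def fit_copy_gates(
    control0: EventTable,
    control1: EventTable,
    control2: EventTable,
    cells_gate: RectGate,
    singlet_gate: BandGate,
    spec: TransformSpec | None = None,
    edge_quantiles: tuple[float, float] = (0.005, 0.995),
    shear: float | str = "auto",
) -> tuple[tuple[ShearBandGate, ShearBandGate, ShearBandGate], float, tuple[float, float]]:
    """Three adjacent copy-number gates from the control strains.

    The 0|1 boundary is the midpoint between the upper edge (99.5th
    percentile by default) of the zero-copy control and the lower edge
    (0.5th percentile) of the one-copy control on the sheared fluorescence
    coordinate; likewise 1|2+ between the one- and two-copy controls.
    Copy0 is unbounded below and Copy2plus unbounded above.
    """
    spec = spec or TransformSpec()
    q_lo, q_hi = edge_quantiles
    if not (0.0 <= q_lo < q_hi <= 1.0):
        raise ValueError("edge_quantiles must satisfy 0 <= lo < hi <= 1")

    txs, tfs = [], []
    for ctrl in (control0, control1, control2):
        mask = _singlet_mask(ctrl, cells_gate, singlet_gate, spec)
        if mask.sum() == 0:
            raise CalibrationError(
                f"control role {ctrl.role!r} has no singlet events for calibration"
            )
        txs.append(transform_scatter(ctrl["FSC-A"], spec)[mask])
        tfs.append(transform_logicle(ctrl["FLUOR"], spec)[mask])

    if shear == "auto":
        # size slope of the one-copy control's fluorescence; clipped to a
        # physically sensible range (0 = no size dependence, ~1 = proportional)
        x1, f1 = txs[1], tfs[1]
        slope = float(np.cov(x1, f1)[0, 1] / np.var(x1)) if np.var(x1) > 0 else 0.0
        shear_val = float(np.clip(slope, 0.0, 1.5))
    else:
        shear_val = float(shear)
    x_ref = float(np.median(np.concatenate(txs)))

    u = [tf - shear_val * (tx - x_ref) for tx, tf in zip(txs, tfs)]
    med = [float(np.median(ui)) for ui in u]
    if not (med[0] < med[1] < med[2]):
        raise CalibrationError(
            "control medians must be strictly ordered zero < one < two on the "
            f"fluorescence axis; got {med}"
        )
    b01 = 0.5 * (float(np.quantile(u[0], q_hi)) + float(np.quantile(u[1], q_lo)))
    b12 = 0.5 * (float(np.quantile(u[1], q_hi)) + float(np.quantile(u[2], q_lo)))
    if not b01 < b12:
        raise CalibrationError(
            f"copy-gate boundaries are not ordered (b01={b01:.4g}, b12={b12:.4g}); "
            "control distributions overlap too heavily"
        )
    common = dict(parent="Singlets", xchan="FSC-A", ychan="FLUOR",
                  shear=shear_val, x_ref=x_ref,
                  xmin=cells_gate.xmin, xmax=cells_gate.xmax)
    gates = (
        ShearBandGate(name="Copy0", lo=-np.inf, hi=b01, **common),
        ShearBandGate(name="Copy1", lo=b01, hi=b12, **common),
        ShearBandGate(name="Copy2plus", lo=b12, hi=np.inf, **common),
    )
    return gates, shear_val, (b01, b12)


def apply_template(template: GatingTemplate, sample: EventTable) -> GateCounts:
    """Apply the gate hierarchy; proportions are over singlet events.

    An empty sample yields zero counts with ``undefined`` proportions
    (NaN) rather than an exception.
    """
    spec = template.transform_spec
    n = len(sample)
    if n == 0:
        return GateCounts(0, 0, 0, {g: 0 for g in COPY_GATE_NAMES},
                          {g: float("nan") for g in COPY_GATE_NAMES},
                          undefined=True, singlet_mask=np.zeros(0, dtype=bool))
    t = _transformed(sample, spec)
    cells = template.cells.contains(t["FSC-A"], t["SSC-A"])
    singlets = cells & template.singlets.contains(t["FSC-A"], t["FSC-H"])
    n_singlets = int(singlets.sum())
    counts: dict[str, int] = {}
    for gate in template.copy_gates:
        counts[gate.name] = int((singlets & gate.contains(t["FSC-A"], t["FLUOR"])).sum())
    if n_singlets:
        proportions = {g: counts[g] / n_singlets for g in COPY_GATE_NAMES}
        undefined = False
    else:
        proportions = {g: float("nan") for g in COPY_GATE_NAMES}
        undefined = True
    return GateCounts(n, int(cells.sum()), n_singlets, counts, proportions,
                      undefined, singlet_mask=singlets)


def assess_template(
    template: GatingTemplate,
    controls: Iterable[EventTable],
    threshold: float = 0.85,
) -> ContainmentReport:
    """Containment criterion: for every control strain, the fraction of its
    singlet events (pooled across all timepoints) inside the corresponding
    copy-number gate must exceed *threshold*."""
    rows = []
    pooled_in: dict[str, int] = {r: 0 for r in _CONTROL_GATE}
    pooled_n: dict[str, int] = {r: 0 for r in _CONTROL_GATE}
    seen = set()
    for ctrl in controls:
        role = ctrl.role
        if role not in _CONTROL_GATE:
            raise ValueError(
                f"unknown control role {role!r}; expected one of {sorted(_CONTROL_GATE)}"
            )
        counts = apply_template(template, ctrl)
        gate = _CONTROL_GATE[role]
        n_in = counts.counts[gate]
        rows.append({
            "strain": role, "generation": ctrl.generation,
            "n_singlets": counts.n_singlets, "n_in_gate": n_in,
            "fraction": n_in / counts.n_singlets if counts.n_singlets else float("nan"),
        })
        pooled_in[role] += n_in
        pooled_n[role] += counts.n_singlets
        seen.add(role)
    if not rows:
        raise ValueError("containment assessment requires at least one control sample")
    per_strain = {
        role: (pooled_in[role] / pooled_n[role]) if pooled_n[role] else float("nan")
        for role in sorted(seen)
    }
    fractions = np.array(list(per_strain.values()))
    min_fraction = float(np.nanmin(fractions))
    passed = bool(np.all(fractions > threshold))
    return ContainmentReport(
        per_timepoint=pd.DataFrame(rows),
        per_strain=per_strain,
        min_fraction=min_fraction,
        threshold=threshold,
        passed=passed,
    )


class GatingModel(BaseEstimator):
    """Hierarchical gating as a scikit-learn style estimator.

    ``fit`` calibrates the Cells → Singlets → copy-number gate chain from
    the three control strains; ``predict`` labels each event of a sample;
    ``transform`` returns gate counts/proportions.

    Parameters
    ----------
    transform_spec : TransformSpec, optional
        Display transforms; conventional logicle defaults if omitted.
    q_debris : float
        FSC-A quantile of pooled controls used as the Cells-gate floor.
    singlet_k : float
        Half-width of the singlet band in MADs of the FSC-H − FSC-A residual.
    singlet_min_width : float
        Floor on the singlet band half-width, in decades.
    edge_quantiles : (float, float)
        Lower/upper percentile edges used for the copy-gate midpoints.
    shear : "auto" or float
        Size-slope of the copy-gate boundaries; 0 gives horizontal
        (rectangle) boundaries, "auto" fits it on the one-copy control.
    containment_threshold : float
        Pass bound for :meth:`assess`.
    """

    def __init__(
        self,
        transform_spec: TransformSpec | None = None,
        q_debris: float = 0.05,
        singlet_k: float = 4.0,
        singlet_min_width: float = 0.02,
        edge_quantiles: tuple[float, float] = (0.005, 0.995),
        shear: float | str = "auto",
        containment_threshold: float = 0.85,
        min_calibration_events: int = 100,
    ):
        self.transform_spec = transform_spec
        self.q_debris = q_debris
        self.singlet_k = singlet_k
        self.singlet_min_width = singlet_min_width
        self.edge_quantiles = edge_quantiles
        self.shear = shear
        self.containment_threshold = containment_threshold
        self.min_calibration_events = min_calibration_events

    def _spec(self) -> TransformSpec:
        return self.transform_spec or TransformSpec()

    def fit(self, X: Mapping[str, EventTable] | Iterable[EventTable], y=None) -> "GatingModel":
        """Calibrate from control samples.

        *X* is either a mapping ``{"control_0": ..., "control_1": ...,
        "control_2": ...}`` or an iterable of EventTables whose ``role``
        attributes name the three control strains.
        """
        if isinstance(X, Mapping):
            controls = dict(X)
        else:
            controls = {}
            for table in X:
                if table.role in _CONTROL_GATE and table.role not in controls:
                    controls[table.role] = table
        missing = [r for r in _CONTROL_GATE if r not in controls]
        if missing:
            raise CalibrationError(f"calibration requires control roles {missing}")
        spec = self._spec()
        ordered = [controls["control_0"], controls["control_1"], controls["control_2"]]
        self.cells_gate_ = fit_cells_gate(ordered, q_debris=self.q_debris, spec=spec)
        self.singlet_gate_ = fit_singlet_gate(
            ordered, self.cells_gate_, k=self.singlet_k,
            min_width=self.singlet_min_width, spec=spec,
            min_events=self.min_calibration_events,
        )
        gates, shear_val, bounds = fit_copy_gates(
            *ordered, cells_gate=self.cells_gate_, singlet_gate=self.singlet_gate_,
            spec=spec, edge_quantiles=self.edge_quantiles, shear=self.shear,
        )
        self.copy_gates_ = gates
        self.shear_ = shear_val
        self.boundaries_ = bounds
        self.template_ = GatingTemplate(
            transform_spec=spec,
            cells=self.cells_gate_,
            singlets=self.singlet_gate_,
            copy_gates=gates,
            metadata={
                "calibration_generation": controls["control_1"].generation,
                "q_debris": self.q_debris,
                "singlet_k": self.singlet_k,
                "edge_quantiles": list(self.edge_quantiles),
                "shear": shear_val,
            },
        )
        return self

    def _check_fitted(self) -> None:
        if not hasattr(self, "template_"):
            raise RuntimeError("GatingModel is not fitted; call fit() first")

    def predict(self, X: EventTable) -> np.ndarray:
        """Per-event labels: outside_cells, outside_singlets, or a copy gate."""
        self._check_fitted()
        spec = self.template_.transform_spec
        t = _transformed(X, spec)
        labels = np.full(len(X), "outside_cells", dtype=object)
        cells = self.cells_gate_.contains(t["FSC-A"], t["SSC-A"])
        labels[cells] = "outside_singlets"
        singlets = cells & self.singlet_gate_.contains(t["FSC-A"], t["FSC-H"])
        for gate in self.copy_gates_:
            mask = singlets & gate.contains(t["FSC-A"], t["FLUOR"])
            labels[mask] = gate.name
        return labels

    def transform(self, X: EventTable) -> GateCounts:
        self._check_fitted()
        return apply_template(self.template_, X)

    apply = transform

    def assess(self, controls: Iterable[EventTable],
               threshold: float | None = None) -> ContainmentReport:
        self._check_fitted()
        thr = self.containment_threshold if threshold is None else threshold
        return assess_template(self.template_, controls, threshold=thr)


def calibrate_per_timepoint(
    controls: Iterable[EventTable], **model_params
) -> dict[int, GatingModel]:
    """Fit one GatingModel per generation from that generation's controls."""
    by_gen: dict[int, dict[str, EventTable]] = {}
    for ctrl in controls:
        if ctrl.role in _CONTROL_GATE:
            by_gen.setdefault(int(ctrl.generation), {})[ctrl.role] = ctrl
    return {
        gen: GatingModel(**model_params).fit(group)
        for gen, group in sorted(by_gen.items())
    }
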