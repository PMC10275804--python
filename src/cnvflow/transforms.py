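"""Display-scale transformations for cytometry channels.

Scatter channels (FSC, SSC) are displayed on a floored log10 scale.
Fluorescence is displayed on the logicle (biexponential) scale, which is
near-linear around zero — so autofluorescent and weakly negative events
remain visible — and asymptotically logarithmic at high intensity.

The logicle scale is defined through its inverse, the biexponential

    B(y) = a * exp(b*y) - c * exp(-d*y) - f,

a strictly increasing function of the normalized display position
``y = decades / (M + A)`` with ``B(x1) = 0`` and ``B(1) = T``.  The
coefficients follow from the user parameters T (top of scale), M (total
display decades), W (linearization width in decades) and A (additional
negative decades).  The forward transform inverts B numerically.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "TransformSpec",
    "transform_logicle",
    "inverse_logicle",
    "transform_scatter",
]


@dataclass(frozen=True)
class TransformSpec:
    """Parameters of the display transforms used for gating.

    Attributes
    ----------
    T : float
        Top of the fluorescence scale (maximum expected data value).
    M : float
        Total number of display decades.
    W : float
        Width of the quasi-linear region, in decades. ``0 <= W <= M/2``.
    A : float
        Additional negative display decades below zero.
    scatter_floor : float
        Values below this floor are clamped before the scatter log10
        transform so the log is defined at zero. One instrument unit by
        default.
    """

    T: float = float(2 ** 18)
    M: float = 4.5
    W: float = 0.5
    A: float = 0.0
    scatter_floor: float = 1.0

    def __post_init__(self) -> None:
        if not (self.T > 0):
            raise ValueError(f"T must be positive, got {self.T}")
        if not (self.M > 0):
            raise ValueError(f"M must be positive, got {self.M}")
        if not (0.0 <= self.W <= self.M / 2):
            raise ValueError(f"W must satisfy 0 <= W <= M/2, got W={self.W}")
        if self.A < 0:
            raise ValueError(f"A must be non-negative, got {self.A}")
        if not (self.scatter_floor > 0):
            raise ValueError("scatter_floor must be positive")


def _logicle_coefficients(spec: TransformSpec) -> tuple[float, float, float, float, float]:
    """Coefficients (a, b, c, d, f) of the biexponential for *spec*."""
    T, M, W, A = spec.T, spec.M, spec.W, spec.A
    w = W / (M + A)
    x2 = A / (M + A)
    x1 = x2 + w
    x0 = x2 + 2.0 * w
    b = (M + A) * math.log(10.0)
    if w == 0.0:
        d = b
    else:
        # d solves 2*(ln d - ln b) + w*(b + d) = 0 on (0, b)
        g = lambda d_: 2.0 * (math.log(d_) - math.log(b)) + w * (b + d_)
        d = brentq(g, 1e-12, b, xtol=1e-14, rtol=8.9e-16)
    c_a = math.exp(x0 * (b + d))
    mf_a = math.exp(b * x1) - c_a / math.exp(d * x1)
    a = T / ((math.exp(b) - mf_a) - c_a / math.exp(d))
    c = c_a * a
    f = -mf_a * a
    return a, b, c, d, f


def inverse_logicle(y: np.ndarray | float, spec: TransformSpec | None = None) -> np.ndarray:
    """Map display decades back to data values (the biexponential)."""
    spec = spec or TransformSpec()
    a, b, c, d, f = _logicle_coefficients(spec)
    yn = np.asarray(y, dtype=float) / (spec.M + spec.A)
    return a * np.exp(b * yn) - c * np.exp(-d * yn) + f


def transform_logicle(x: np.ndarray | float, spec: TransformSpec | None = None) -> np.ndarray:
    """Logicle transform of data values *x*, returned in display decades.

    Defined for negative inputs; strictly increasing; exact inverse is
    :func:`inverse_logicle`.  Non-finite inputs are rejected.
    """
    spec = spec or TransformSpec()
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("logicle transform requires finite input values")
    a, b, c, d, f = _logicle_coefficients(spec)

    def biexp(yn: np.ndarray) -> np.ndarray:
        return a * np.exp(b * yn) - c * np.exp(-d * yn) + f

    # Vectorized safeguarded search: bisection to localize, Newton to polish.
    lo = np.full(x.shape, -2.0)
    hi = np.full(x.shape, 3.0)
    for _ in range(30):
        mid = 0.5 * (lo + hi)
        below = biexp(mid) < x
        lo = np.where(below, mid, lo)
        hi = np.where(below, hi, mid)
    yn = 0.5 * (lo + hi)
    for _ in range(4):
        fy = biexp(yn) - x
        dfy = a * b * np.exp(b * yn) + c * d * np.exp(-d * yn)
        step = fy / dfy
        yn = np.clip(yn - step, lo, hi)
    return yn * (spec.M + spec.A)


def transform_scatter(x: np.ndarray | float, spec: TransformSpec | None = None) -> np.ndarray:
    """Floored log10 transform used for FSC/SSC channels."""
    spec = spec or TransformSpec()
    x = np.asarray(x, dtype=float)
    return np.log10(np.maximum(x, spec.scatter_floor))
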