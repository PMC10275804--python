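"""CNV dynamics statistics from a frequency trajectory.

Four quantities summarize a CNV trajectory p_t:

* **T_up** — the generation at which CNVs are first detected. Two rules:
  the *consecutive* rule (first timepoint of the earliest run of k
  consecutive sampled timepoints with p_t > θ, default θ=0.05, k=3) and
  the *fpr* rule (first timepoint with p_t above the one-copy control's
  mean CNV-gate proportion plus one standard deviation, both taken
  across timepoints).
* **S_up** — the per-generation rate of increase during the initial
  expansion: the ordinary-least-squares slope of ln(p_t / (1 − p_t))
  against generation. Under per-generation multiplicative fitness
  (1 + s), the log-odds increase by exactly ln(1 + s) per generation, so
  the slope estimates ln(1 + s); the equivalent percent increase per
  generation is 100·(e^slope − 1).
* **S_down / T_down** — the analogous decline rate after the trajectory
  maximum and the generation the trajectory first falls back below θ;
  both are None when no decline is observed.

Timepoints with p ∈ {0, 1} have undefined log-odds and are excluded from
regression (and counted); a pseudo-count option replaces them with
1/(2·n_singlets) shrinkage instead.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator

from .quantify import CNVTrajectory

__all__ = [
    "RegressionFit",
    "DynamicsSummary",
    "tup_consecutive",
    "tup_fpr",
    "sup",
    "select_rise_window",
    "sdown_tdown",
    "CNVDynamics",
]


@dataclass
class RegressionFit:
    """OLS fit of log-odds against generation."""

    slope: float
    intercept: float
    r_squared: float
    stderr: float
    points: list[tuple[int, float]]  # (generation, logit p) pairs used
    n_excluded: int = 0              # timepoints dropped because p in {0, 1}


@dataclass
class DynamicsSummary:
    """T_up, S_up, S_down, T_down and the settings that produced them."""

    population: str
    t_up: int | None
    t_up_method: str
    s_up: float | None
    s_up_percent: float | None
    s_down: float | None
    t_down: int | None
    window: tuple[int, int] | None
    r_squared: float | None
    n_points: int
    theta: float
    k: int
    fpr_threshold: float | None = None
    window_rule: str = "auto"

    def as_row(self) -> dict:
        return {
            "population": self.population,
            "t_up": self.t_up, "t_up_method": self.t_up_method,
            "s_up": self.s_up, "s_up_percent_per_gen": self.s_up_percent,
            "s_down": self.s_down, "t_down": self.t_down,
            "window_start": None if self.window is None else self.window[0],
            "window_end": None if self.window is None else self.window[1],
            "r_squared": self.r_squared, "n_points": self.n_points,
            "theta": self.theta, "k": self.k,
            "fpr_threshold": self.fpr_threshold, "window_rule": self.window_rule,
        }


def _as_series(traj) -> tuple[np.ndarray, np.ndarray, np.ndarray | None]:
    if isinstance(traj, CNVTrajectory):
        return traj.generations, traj.p, traj.control_p
    gens, p = traj[0], traj[1]
    control = traj[2] if len(traj) > 2 else None
    return (np.asarray(gens, dtype=int), np.asarray(p, dtype=float),
            None if control is None else np.asarray(control, dtype=float))


def tup_consecutive(traj, theta: float = 0.05, k: int = 3) -> int | None:
    """First timepoint of the earliest run of *k* consecutive sampled
    timepoints with p > *theta*; None if no such run exists."""
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    if not (0.0 < theta < 1.0):
        raise ValueError(f"theta must lie in (0, 1), got {theta}")
    gens, p, _ = _as_series(traj)
    if len(gens) == 0:
        raise ValueError("trajectory is empty")
    above = p > theta
    run = 0
    for i in range(len(above)):
        run = run + 1 if above[i] else 0
        if run == k:
            return int(gens[i - k + 1])
    return None


def tup_fpr(traj, control_traj=None) -> tuple[int | None, float]:
    """First-detection generation by the false-positive-rate rule.

    The FPR is the mean of the one-copy control's CNV-gate proportions
    across timepoints; the threshold is FPR plus one (sample) standard
    deviation of that series. Returns ``(generation_or_None, threshold)``.
    """
    gens, p, attached = _as_series(traj)
    control = np.asarray(control_traj, dtype=float) if control_traj is not None else attached
    if control is None:
        raise ValueError("fpr rule requires a one-copy control trajectory")
    control = control[np.isfinite(control)]
    if len(control) < 2:
        raise ValueError("control trajectory needs at least two timepoints")
    threshold = float(np.mean(control) + np.std(control, ddof=1))
    above = np.flatnonzero(p > threshold)
    return (int(gens[above[0]]) if above.size else None), threshold


def _logit_points(
    gens: np.ndarray, p: np.ndarray,
    n_singlets: np.ndarray | None, pseudocount: bool,
) -> tuple[np.ndarray, np.ndarray, int]:
    p = p.astype(float).copy()
    if pseudocount:
        if n_singlets is None:
            raise ValueError("pseudocount shrinkage requires n_singlets")
        eps = 1.0 / (2.0 * np.maximum(n_singlets, 1))
        p = np.clip(p, eps, 1.0 - eps)
    usable = (p > 0.0) & (p < 1.0) & np.isfinite(p)
    return gens[usable], np.log(p[usable] / (1.0 - p[usable])), int((~usable).sum())


def sup(
    traj,
    window: tuple[int, int] | None = None,
    pseudocount: bool = False,
    n_singlets: np.ndarray | None = None,
) -> RegressionFit:
    """OLS slope of ln(p/(1−p)) on generation over *window* (inclusive)."""
    gens, p, _ = _as_series(traj)
    if isinstance(traj, CNVTrajectory) and n_singlets is None:
        n_singlets = traj.n_singlets
    if window is not None:
        lo, hi = window
        keep = (gens >= lo) & (gens <= hi)
        gens, p = gens[keep], p[keep]
        if n_singlets is not None:
            n_singlets = np.asarray(n_singlets)[keep]
    t, logit, n_excluded = _logit_points(gens, p, n_singlets, pseudocount)
    if len(t) < 2:
        raise ValueError(
            f"logit regression needs >= 2 points with 0 < p < 1, got {len(t)}"
        )
    if np.ptp(t) == 0:
        raise ValueError("regression window has zero variance in generation")
    fit = stats.linregress(t.astype(float), logit)
    return RegressionFit(
        slope=float(fit.slope), intercept=float(fit.intercept),
        r_squared=float(fit.rvalue ** 2), stderr=float(fit.stderr),
        points=list(zip(t.tolist(), logit.tolist())), n_excluded=n_excluded,
    )


def select_rise_window(
    traj, t_up: int, p_max_fraction: float = 0.9
) -> tuple[int, int]:
    """Initial-expansion window: from T_up to the first timepoint where
    p reaches *p_max_fraction* of the trajectory maximum (or the last
    timepoint if the rise never plateaus)."""
    gens, p, _ = _as_series(traj)
    if t_up is None:
        raise ValueError("select_rise_window requires a detected T_up")
    after = gens >= t_up
    if after.sum() < 2:
        raise ValueError(
            "rise window collapsed to fewer than 2 timepoints; supply a manual window"
        )
    plateau = np.flatnonzero(after & (p >= p_max_fraction * np.nanmax(p)))
    end = int(gens[plateau[0]]) if plateau.size else int(gens[-1])
    n_inside = int(((gens >= t_up) & (gens <= end)).sum())
    if n_inside < 2:
        end = int(gens[np.flatnonzero(after)[1]])
    return int(t_up), end


def sdown_tdown(
    traj, theta: float = 0.05, window: tuple[int, int] | None = None,
    pseudocount: bool = False,
) -> tuple[RegressionFit | None, int | None]:
    """Decline rate and loss generation after the trajectory maximum.

    T_down is the first generation after the maximum with p < *theta*;
    S_down is the log-odds OLS slope over the declining window (default:
    maximum to end of trajectory). Returns ``(None, None)`` when the
    trajectory never declines.
    """
    gens, p, _ = _as_series(traj)
    i_max = int(np.nanargmax(p))
    after = np.arange(len(gens)) > i_max
    declining = after & (p < p[i_max])
    if not declining.any():
        return None, None
    below = np.flatnonzero(after & (p < theta))
    t_down = int(gens[below[0]]) if below.size else None
    if window is None:
        window = (int(gens[i_max]), int(gens[-1]))
    try:
        fit = sup(traj, window=window, pseudocount=pseudocount)
    except ValueError:
        return None, t_down
    return fit, t_down


class CNVDynamics(BaseEstimator):
    """Dynamics estimator: fit on a trajectory, read T_up/S_up/S_down/T_down.

    Parameters
    ----------
    theta, k : detection threshold and run length for the consecutive rule.
    method : "consecutive" (default) or "fpr" for T_up.
    window : "auto" or an explicit (start, end) generation range for S_up.
    p_max_fraction : plateau fraction ending the automatic rise window.
    pseudocount : replace p in {0,1} by 1/(2 n_singlets) instead of dropping.

    Fitted attributes: ``t_up_``, ``s_up_`` (log-odds slope per
    generation), ``s_up_percent_`` (100·(e^slope − 1)), ``fit_up_``
    (:class:`RegressionFit`), ``s_down_``, ``t_down_``, ``window_``,
    ``summary_`` (:class:`DynamicsSummary`).
    """

    def __init__(
        self,
        theta: float = 0.05,
        k: int = 3,
        method: str = "consecutive",
        window: str | tuple[int, int] = "auto",
        p_max_fraction: float = 0.9,
        pseudocount: bool = False,
    ):
        self.theta = theta
        self.k = k
        self.method = method
        self.window = window
        self.p_max_fraction = p_max_fraction
        self.pseudocount = pseudocount

    def fit(self, X: CNVTrajectory, y=None) -> "CNVDynamics":
        if self.method not in ("consecutive", "fpr"):
            raise ValueError("method must be 'consecutive' or 'fpr'")
        traj = X
        fpr_threshold = None
        if self.method == "fpr":
            self.t_up_, fpr_threshold = tup_fpr(traj)
        else:
            self.t_up_ = tup_consecutive(traj, theta=self.theta, k=self.k)

        self.fit_up_ = None
        self.s_up_ = None
        self.s_up_percent_ = None
        self.window_ = None
        if self.t_up_ is not None:
            if self.window == "auto":
                self.window_ = select_rise_window(
                    traj, self.t_up_, p_max_fraction=self.p_max_fraction
                )
            else:
                self.window_ = tuple(self.window)
            self.fit_up_ = sup(traj, window=self.window_, pseudocount=self.pseudocount)
            self.s_up_ = self.fit_up_.slope
            self.s_up_percent_ = 100.0 * float(np.expm1(self.s_up_))

        fit_down, self.t_down_ = sdown_tdown(
            traj, theta=self.theta, pseudocount=self.pseudocount
        )
        self.s_down_ = None if fit_down is None else fit_down.slope

        self.summary_ = DynamicsSummary(
            population=getattr(traj, "population", "unknown"),
            t_up=self.t_up_, t_up_method=self.method,
            s_up=self.s_up_, s_up_percent=self.s_up_percent_,
            s_down=self.s_down_, t_down=self.t_down_,
            window=self.window_,
            r_squared=None if self.fit_up_ is None else self.fit_up_.r_squared,
            n_points=0 if self.fit_up_ is None else len(self.fit_up_.points),
            theta=self.theta, k=self.k, fpr_threshold=fpr_threshold,
            window_rule="auto" if self.window == "auto" else "manual",
        )
        return self
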