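"""Joint-level aggregation: ankle moment, rotational stiffness, fit metric.

The net ankle moment is the arm-weighted sum of MTU forces,

    tau = sum_i Fmt_i * r_i,

with signed dorsiflexion-positive moment arms (TA positive, plantar flexors
negative), so dorsiflexion moments are positive.

Ankle rotational stiffness is

    K_ankle = sum_i [ Kmt_i * rho_i^2 + (d rho_i / d theta) * Fmt_i ],

where rho_i is the moment arm in the *tendon-excursion* convention
rho = d lmt / d theta = -r.  Written this way the sum equals -d tau / d theta
at frozen activation (verifiable against a brute-force perturbation of the
whole forward chain).  The squared term is convention-independent; only the
arm-slope term changes sign between conventions, and `joint_series` wires the
conversion so callers never have to.  Negative aggregate stiffness steps
(deep descending-limb operation) are clamped to zero and counted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .mtu import MTUTrajectory

__all__ = [
    "JointSeries",
    "STANCE_GRID",
    "ankle_moment",
    "ankle_stiffness",
    "joint_series",
    "time_normalize",
    "nrmse",
]

#: canonical stance-percent grid, 0..100 inclusive (the SPM input convention)
STANCE_GRID = np.linspace(0.0, 100.0, 101)


@dataclass
class JointSeries:
    """Time-normalized ankle moment and stiffness curves for one trial."""

    grid: np.ndarray                 # stance %, strictly increasing 0..100
    moment: np.ndarray               # N*m, dorsiflexion positive
    stiffness: np.ndarray            # N*m/rad, clamped >= 0
    n_clamped: int = 0               # stiffness steps clamped (pre-resampling)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (len(self.grid) == len(self.moment) == len(self.stiffness)):
            raise ValueError("grid, moment and stiffness must share a length")
        if np.any(np.diff(self.grid) <= 0):
            raise ValueError("stance grid must be strictly increasing")


def _stack(series: Mapping[str, np.ndarray] | Sequence[np.ndarray]) -> np.ndarray:
    arrs = list(series.values()) if isinstance(series, Mapping) else list(series)
    lengths = {len(np.atleast_1d(a)) for a in arrs}
    if len(lengths) > 1:
        raise ValueError(f"per-muscle series lengths differ: {sorted(lengths)}")
    return np.vstack([np.atleast_1d(np.asarray(a, float)) for a in arrs])


def ankle_moment(forces, arms) -> np.ndarray:
    """Net joint moment tau = sum_i Fmt_i * r_i (signed arms)."""
    f = _stack(forces)
    r = _stack(arms)
    if f.shape != r.shape:
        raise ValueError("forces and arms must align muscle-by-muscle")
    return np.sum(f * r, axis=0)


def ankle_stiffness(
    mtu_stiffnesses, arms, arm_slopes, forces
) -> tuple[np.ndarray, np.ndarray]:
    """Joint stiffness sum_i (Kmt_i arm_i^2 + slope_i * Fmt_i), then clamp.

    ``arm_slopes`` must be the arm derivative in the excursion convention
    (d(d lmt/d theta)/d theta); see the module docstring.  Returns the clamped
    non-negative stiffness and the boolean mask of clamped steps.
    """
    k = _stack(mtu_stiffnesses)
    r = _stack(arms)
    dr = _stack(arm_slopes)
    f = _stack(forces)
    if not (k.shape == r.shape == dr.shape == f.shape):
        raise ValueError("per-muscle series must align")
    raw = np.sum(k * r**2 + dr * f, axis=0)
    clamped = raw < 0.0
    return np.where(clamped, 0.0, raw), clamped


def joint_series(
    trajectories: Mapping[str, MTUTrajectory],
    geometry: Mapping[str, "GeometrySeries"],  # noqa: F821 - anklemech.geometry
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Moment and stiffness series from solved MTU states + evaluated geometry.

    Handles the sign bookkeeping: moments use the signed dorsiflexion-positive
    arms directly; the stiffness arm-slope term is evaluated in the excursion
    convention (rho = -r).  Returns (moment, stiffness_clamped, clamp_mask).
    """
    names = list(trajectories)
    fmt = {m: trajectories[m].fmt for m in names}
    tau = ankle_moment(fmt, {m: geometry[m].arm for m in names})
    kmt = {}
    for m in names:
        if trajectories[m].kmt is None:
            from .mtu import mtu_stiffness
            mtu_stiffness(trajectories[m])
        kmt[m] = trajectories[m].kmt
    stiff, clamped = ankle_stiffness(
        kmt,
        {m: geometry[m].arm for m in names},
        {m: -geometry[m].arm_slope for m in names},
        fmt,
    )
    return tau, stiff, clamped


def time_normalize(
    series: np.ndarray,
    stance_start: int,
    stance_stop: int,
    n_nodes: int = 101,
) -> np.ndarray:
    """Resample a stance-phase slice onto the 0..100% grid (linear interp).

    ``stance_start``/``stance_stop`` are inclusive sample indices of heel
    strike and toe-off within the series.
    """
    series = np.asarray(series, dtype=float)
    if not 0 <= stance_start < stance_stop < series.size:
        raise ValueError(
            f"invalid stance bounds [{stance_start}, {stance_stop}] for a "
            f"series of {series.size} samples"
        )
    window = series[stance_start: stance_stop + 1]
    if window.size < 2:
        raise ValueError("need at least 2 samples inside stance")
    src = np.linspace(0.0, 100.0, window.size)
    dst = np.linspace(0.0, 100.0, n_nodes)
    return np.interp(dst, src, window)


def nrmse(predicted: np.ndarray, experimental: np.ndarray) -> float:
    """RMSE of (predicted - experimental), normalized by RMS(experimental).

    The normalization is the root-mean-square of the experimental series;
    an all-zero reference makes the metric undefined and raises.
    """
    predicted = np.asarray(predicted, dtype=float)
    experimental = np.asarray(experimental, dtype=float)
    if predicted.shape != experimental.shape:
        raise ValueError("series must share a shape")
    rms_ref = float(np.sqrt(np.mean(experimental**2)))
    if rms_ref == 0.0:
        raise ValueError("NRMSE undefined: experimental series is all zero")
    rmse = float(np.sqrt(np.mean((predicted - experimental) ** 2)))
    return rmse / rms_ref
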