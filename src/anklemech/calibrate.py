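"""Subject-specific model calibration by bounded Nelder-Mead.

The calibration minimizes the mean squared error between the model moment
and the experimental (inverse-dynamics) moment,

    J = (1/N) * sum_i ( tau_EMG(i) - tau_ID(i) )^2,

pooled over all samples of all calibration trials of one subject.  Free
parameters and bounds:

    C1, C2          in [-1, 1]      (shared across muscles)
    A               in [-3, 0]      (shared)
    gamma_df        in [0.5, 1.5]   (Fmax scale, dorsiflexors)
    gamma_pf        in [0.5, 1.5]   (Fmax scale, plantar flexors)
    lm0 multiplier  in [0.975, 1.025]  (per muscle, +-2.5%)
    lst multiplier  in [0.95, 1.05]    (per muscle, +-5%)

Nelder-Mead has no native bound support, so each coordinate is smoothly
reparameterized onto its interval with x = lo + (hi - lo) * sin^2(z)
(clipping would flatten the simplex).  The objective is multimodal, so a
small number of seeded Latin-hypercube multi-starts is used and the best
restart returned.  The electromechanical delay is never calibrated here; it
stays at its fixed default.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import minimize

from .activation import ActivationParams
from .geometry import MTUGeometryModel
from .joint import nrmse
from .mtu import EquilibriumError
from .pipeline import ModelParams, forward_simulate
from .synth import GaitTrial

__all__ = [
    "DEFAULT_BOUNDS",
    "CalibrationSpec",
    "CalibrationResult",
    "check_within_bounds",
    "objective",
    "calibrate",
]

log = logging.getLogger(__name__)

DEFAULT_BOUNDS: dict[str, tuple[float, float]] = {
    "c1": (-1.0, 1.0),
    "c2": (-1.0, 1.0),
    "shape_factor": (-3.0, 0.0),
    "gamma_df": (0.5, 1.5),
    "gamma_pf": (0.5, 1.5),
    "lm0_mult": (0.975, 1.025),
    "lst_mult": (0.95, 1.05),
}

#: objective value substituted when the forward chain fails for a candidate
FAILURE_PENALTY = 1e6


@dataclass(frozen=True)
class CalibrationSpec:
    """Free-parameter layout, bounds and optimizer settings."""

    bounds: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_BOUNDS))
    #: include the per-muscle lm0/lst multipliers as free parameters
    calibrate_lengths: bool = True
    n_restarts: int = 4
    max_fev: int = 4000
    xatol: float = 1e-3
    fatol: float = 1e-4
    seed: int = 0

    def param_names(self, muscles: Sequence[str]) -> list[str]:
        names = ["c1", "c2", "shape_factor", "gamma_df", "gamma_pf"]
        if self.calibrate_lengths:
            names += [f"lm0_mult:{m}" for m in muscles]
            names += [f"lst_mult:{m}" for m in muscles]
        return names

    def bound_for(self, name: str) -> tuple[float, float]:
        return self.bounds[name.split(":")[0]]


@dataclass
class CalibrationResult:
    """Best-restart outcome of a subject calibration."""

    model: ModelParams
    params: dict[str, float]
    objective: float                # J at the optimum, N^2 m^2
    nrmse_per_trial: list[float]
    nrmse_mean: float
    n_fev: int
    n_iter: int
    converged: bool
    best_restart: int
    restart_objectives: list[float]


def check_within_bounds(
    model: ModelParams,
    bounds: Mapping[str, tuple[float, float]] = DEFAULT_BOUNDS,
    *,
    strict: bool = True,
) -> None:
    """Raise if a model's calibratable parameters leave the bound box.

    With ``strict`` (used to validate synthetic ground truth) the values must
    lie strictly inside the bounds.
    """
    def _check(name: str, value: float, key: str) -> None:
        lo, hi = bounds[key]
        ok = lo < value < hi if strict else lo <= value <= hi
        if not ok:
            raise ValueError(
                f"parameter {name} = {value} outside calibration bounds "
                f"({lo}, {hi})"
            )

    _check("c1", model.activation.c1, "c1")
    _check("c2", model.activation.c2, "c2")
    _check("A", model.activation.shape_factor, "shape_factor")
    _check("gamma_df", model.gamma_df, "gamma_df")
    _check("gamma_pf", model.gamma_pf, "gamma_pf")
    for m in model.muscles:
        _check(f"lm0_mult:{m}", model.lm0_mult.get(m, 1.0), "lm0_mult")
        _check(f"lst_mult:{m}", model.lst_mult.get(m, 1.0), "lst_mult")


# ---------------------------------------------------------------------------
# bounding transform


def _to_bounded(z: np.ndarray, lo: np.ndarray, hi: np.ndarray) -> np.ndarray:
    return lo + (hi - lo) * np.sin(z) ** 2


def _from_bounded(x: np.ndarray, lo: np.ndarray, hi: np.ndarray) -> np.ndarray:
    frac = np.clip((x - lo) / (hi - lo), 0.0, 1.0)
    return np.arcsin(np.sqrt(frac))


def _vector_to_model(
    x: np.ndarray, names: Sequence[str], base: ModelParams
) -> ModelParams:
    vals = dict(zip(names, x))
    c1 = float(np.clip(vals["c1"], -1.0 + 1e-9, 1.0 - 1e-9))
    c2 = float(np.clip(vals["c2"], -1.0 + 1e-9, 1.0 - 1e-9))
    act = ActivationParams(
        c1=c1, c2=c2,
        shape_factor=float(np.clip(vals["shape_factor"], -3.0, 0.0)),
        delay_s=base.activation.delay_s,
    )
    lm0_mult = dict(base.lm0_mult)
    lst_mult = dict(base.lst_mult)
    for name, v in vals.items():
        if name.startswith("lm0_mult:"):
            lm0_mult[name.split(":", 1)[1]] = float(v)
        elif name.startswith("lst_mult:"):
            lst_mult[name.split(":", 1)[1]] = float(v)
    return base.replace(
        activation=act,
        gamma_df=float(vals["gamma_df"]),
        gamma_pf=float(vals["gamma_pf"]),
        lm0_mult=lm0_mult,
        lst_mult=lst_mult,
    )


def _model_to_vector(model: ModelParams, names: Sequence[str]) -> np.ndarray:
    lookup = {
        "c1": model.activation.c1,
        "c2": model.activation.c2,
        "shape_factor": model.activation.shape_factor,
        "gamma_df": model.gamma_df,
        "gamma_pf": model.gamma_pf,
    }
    out = []
    for n in names:
        if n in lookup:
            out.append(lookup[n])
        elif n.startswith("lm0_mult:"):
            out.append(model.lm0_mult.get(n.split(":", 1)[1], 1.0))
        else:
            out.append(model.lst_mult.get(n.split(":", 1)[1], 1.0))
    return np.asarray(out, float)


# ---------------------------------------------------------------------------
# objective


def objective(
    model: ModelParams,
    trials: Sequence[GaitTrial],
    geometry: MTUGeometryModel,
) -> float:
    """Mean squared moment error J pooled over all samples of all trials.

    A forward-chain failure (equilibrium breakdown for an extreme candidate)
    returns a large finite penalty instead of raising, keeping the simplex
    alive; the event is logged.
    """
    sq_sum = 0.0
    n_total = 0
    for trial in trials:
        try:
            fwd = forward_simulate(trial.emg, trial.theta, trial.rate, model,
                                   geometry, with_stiffness=False)
        except (EquilibriumError, ValueError) as exc:
            log.warning("forward chain failed during calibration: %s", exc)
            return FAILURE_PENALTY
        err = fwd.moment - trial.tau_id
        sq_sum += float(np.dot(err, err))
        n_total += err.size
    return sq_sum / n_total


def calibrate(
    trials: Sequence[GaitTrial],
    base_model: ModelParams,
    geometry: MTUGeometryModel,
    spec: CalibrationSpec | None = None,
) -> CalibrationResult:
    """Fit the free parameters to one subject's pooled calibration trials.

    Deterministic given ``spec.seed``: restart initial points are a seeded
    Latin-hypercube sample of the interior of the bound box.  Returns the
    best restart; ``converged`` is False when no restart met the optimizer
    tolerances (the best-so-far parameters are still returned).
    """
    if not trials:
        raise ValueError("need at least one calibration trial")
    spec = spec or CalibrationSpec()
    muscles = list(base_model.muscles)
    names = spec.param_names(muscles)
    lo = np.array([spec.bound_for(n)[0] for n in names])
    hi = np.array([spec.bound_for(n)[1] for n in names])
    d = len(names)

    def fun(z: np.ndarray) -> float:
        model = _vector_to_model(_to_bounded(z, lo, hi), names, base_model)
        return objective(model, trials, geometry)

    # Latin hypercube over the interior 10-90% of each interval
    rng = np.random.default_rng(spec.seed)
    fracs = np.empty((spec.n_restarts, d))
    for j in range(d):
        cells = (np.arange(spec.n_restarts) + rng.random(spec.n_restarts)) / spec.n_restarts
        fracs[:, j] = rng.permutation(cells)
    fracs = 0.1 + 0.8 * fracs
    z0s = np.arcsin(np.sqrt(fracs))

    best = None
    restart_objectives: list[float] = []
    total_fev = 0
    for i in range(spec.n_restarts):
        res = minimize(
            fun, z0s[i], method="Nelder-Mead",
            options={
                "maxfev": spec.max_fev,
                "xatol": spec.xatol,
                "fatol": spec.fatol,
                "adaptive": True,
            },
        )
        restart_objectives.append(float(res.fun))
        total_fev += res.nfev
        if best is None or res.fun < best[1].fun:
            best = (i, res)
        log.info("restart %d: J = %.6g (%d evals, success=%s)",
                 i, res.fun, res.nfev, res.success)

    best_idx, res = best
    x = _to_bounded(res.x, lo, hi)
    model = _vector_to_model(x, names, base_model)

    per_trial = []
    for trial in trials:
        fwd = forward_simulate(trial.emg, trial.theta, trial.rate, model,
                               geometry, with_stiffness=False)
        per_trial.append(nrmse(fwd.moment, trial.tau_id))

    return CalibrationResult(
        model=model,
        params=dict(zip(names, map(float, x))),
        objective=float(res.fun),
        nrmse_per_trial=per_trial,
        nrmse_mean=float(np.mean(per_trial)),
        n_fev=total_fev,
        n_iter=int(res.nit),
        converged=bool(res.success),
        best_restart=best_idx,
        restart_objectives=restart_objectives,
    )
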