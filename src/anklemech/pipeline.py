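"""Forward chain: excitations + angle + parameters -> joint moment/stiffness.

This is the glue every caller shares: the synthetic generator uses it as the
plant, the calibration objective evaluates it per candidate parameter set,
and the estimation stage runs it with calibrated parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np

from .activation import ActivationParams, activation_from_excitation
from .geometry import MTUGeometryModel
from .joint import joint_series
from .mtu import MuscleParams, MTUTrajectory, mtu_stiffness, solve_equilibrium

__all__ = ["ModelParams", "ForwardResult", "forward_simulate"]

MUSCLES = ("TA", "SOL", "GAL", "GAM")


@dataclass(frozen=True)
class ModelParams:
    """Complete parameter set of the EMG-driven model for one subject.

    Activation parameters are shared across the four muscles; strength
    coefficients gamma scale Fmax per functional group (gamma_df for the
    dorsiflexor TA, gamma_pf for the plantar flexors SOL/GAL/GAM); optimal
    fiber length and tendon slack length carry per-muscle multipliers.
    """

    activation: ActivationParams
    muscles: Mapping[str, MuscleParams]
    gamma_df: float = 1.0
    gamma_pf: float = 1.0
    lm0_mult: Mapping[str, float] = field(default_factory=dict)
    lst_mult: Mapping[str, float] = field(default_factory=dict)

    def effective_muscles(self) -> dict[str, MuscleParams]:
        """Per-muscle parameters with calibration scalings applied."""
        out = {}
        for name, p in self.muscles.items():
            gamma = self.gamma_df if p.group == "dorsiflexor" else self.gamma_pf
            out[name] = p.with_scaling(
                gamma=gamma,
                lm0_mult=self.lm0_mult.get(name, 1.0),
                lst_mult=self.lst_mult.get(name, 1.0),
            )
        return out

    def replace(self, **kw) -> "ModelParams":
        return replace(self, **kw)


@dataclass
class ForwardResult:
    """Everything the forward chain produces for one trial."""

    moment: np.ndarray               # tau_EMG, N*m, dorsiflexion positive
    stiffness: np.ndarray            # K_ankle, N*m/rad, clamped >= 0
    clamped: np.ndarray              # bool mask of clamped stiffness steps
    activations: dict[str, np.ndarray]
    trajectories: dict[str, MTUTrajectory]


def forward_simulate(
    excitations: Mapping[str, np.ndarray],
    theta: np.ndarray,
    rate: float,
    params: ModelParams,
    geometry: MTUGeometryModel,
    *,
    rigid_tendon: bool = False,
    with_stiffness: bool = True,
    vnorm_override: Mapping[str, np.ndarray] | None = None,
) -> ForwardResult:
    """Run activation dynamics, MTU dynamics and joint aggregation.

    Parameters
    ----------
    excitations :
        Per-muscle normalized excitation series in [0, 1].
    theta :
        Ankle angle series (rad, dorsiflexion positive), same length.
    """
    theta = np.asarray(theta, dtype=float)
    geo = geometry.evaluate(theta)
    muscles = params.effective_muscles()

    activations: dict[str, np.ndarray] = {}
    trajs: dict[str, MTUTrajectory] = {}
    for name, mp in muscles.items():
        e = np.asarray(excitations[name], dtype=float)
        if e.shape != theta.shape:
            raise ValueError(f"{name}: excitation/angle length mismatch")
        a = activation_from_excitation(e, params.activation, rate)
        traj = solve_equilibrium(
            a, geo[name].lmt, mp, rate, rigid_tendon=rigid_tendon,
            vnorm_override=None if vnorm_override is None else vnorm_override[name],
        )
        if with_stiffness:
            mtu_stiffness(traj)
        activations[name] = a
        trajs[name] = traj

    if with_stiffness:
        tau, stiff, clamped = joint_series(trajs, geo)
    else:
        from .joint import ankle_moment
        tau = ankle_moment({m: trajs[m].fmt for m in trajs},
                           {m: geo[m].arm for m in trajs})
        stiff = np.zeros_like(tau)
        clamped = np.zeros_like(tau, dtype=bool)
    return ForwardResult(
        moment=tau, stiffness=stiff, clamped=clamped,
        activations=activations, trajectories=trajs,
    )
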