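"""Synthetic stance-phase gait trials with known ground truth.

No subject-level raw data are published for this kind of study, so every
downstream stage is exercised on generated trials whose "experimental" ankle
moment is the package's own forward model evaluated at known truth
parameters, plus additive Gaussian noise (the simplest stand-in for
inverse-dynamics error).  The generator emulates:

* gait-phased muscle excitations — per-muscle sums of Gaussian bursts over
  stance %, TA bursting in early stance (and again pre-swing), the plantar
  flexors building through mid/late stance;
* a smooth stance ankle-angle trajectory (brief plantarflexion after heel
  strike, progressive dorsiflexion, then push-off plantarflexion);
* angle-dependent MTU geometry built so the tendon-excursion identity
  r = -d lmt/d theta holds exactly;
* double-hump vertical and biphasic anterior-posterior GRF shapes
  (shape-only stand-ins; no contact physics);
* four surface-compliance conditions as fractional scalings of the
  plantar-flexor burst peaks, with the two stiffest surfaces identical.

Everything is reproducible from a single integer seed; per-subject /
per-trial streams are derived by counter-based seed splitting.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from numpy.polynomial import Polynomial
from scipy.interpolate import PchipInterpolator

from .activation import ActivationParams
from .geometry import MTUGeometryModel
from .mtu import MuscleParams
from .pipeline import MUSCLES, ModelParams, forward_simulate

__all__ = [
    "Burst",
    "SyntheticTruth",
    "GaitTrial",
    "default_geometry",
    "default_truth",
    "generate_trial",
    "generate_dataset",
    "emulate_raw_emg",
]

DEFAULT_CONDITIONS = ("rigid", "rubber", "eva", "epe")

#: ankle-angle waypoints (% stance, degrees): heel strike near neutral, foot
#: flat in slight plantarflexion, dorsiflexion through mid-stance, push-off
THETA_WAYPOINTS = ((0.0, -3.0), (10.0, -7.0), (45.0, 5.0),
                   (70.0, 11.0), (85.0, 2.0), (100.0, -18.0))

BODYWEIGHT_N = 630.0


@dataclass(frozen=True)
class Burst:
    """One Gaussian excitation burst: center/width in % stance, peak in [0,1]."""

    center_pct: float
    width_pct: float
    peak: float

    def __post_init__(self) -> None:
        if self.width_pct <= 0:
            raise ValueError("burst width must be > 0")
        if not 0.0 <= self.peak <= 1.0:
            raise ValueError("burst peak must lie in [0, 1]")


# generic values for a standard lower-limb model (TA / soleus / lateral and
# medial gastrocnemius); the strength coefficients and length multipliers of
# ModelParams are the calibrated deviations from these
_DEFAULT_MUSCLES = {
    "TA": MuscleParams("TA", fmax=905.0, lm0=0.098, lst=0.223,
                       phi0=math.radians(5.0), group="dorsiflexor"),
    "SOL": MuscleParams("SOL", fmax=3549.0, lm0=0.050, lst=0.250,
                        phi0=math.radians(25.0), group="plantarflexor"),
    "GAL": MuscleParams("GAL", fmax=683.0, lm0=0.064, lst=0.380,
                        phi0=math.radians(8.0), group="plantarflexor"),
    "GAM": MuscleParams("GAM", fmax=1558.0, lm0=0.060, lst=0.390,
                        phi0=math.radians(17.0), group="plantarflexor"),
}

# moment-arm polynomials r(theta) = r0 + r1*theta + r2*theta^2 (m, signed
# dorsiflexion-positive); magnitudes follow adult ankle geometry
_ARM_COEFFS = {
    "TA": (0.040, -0.006, 0.0),
    "SOL": (-0.048, -0.010, 0.012),
    "GAL": (-0.046, -0.008, 0.010),
    "GAM": (-0.049, -0.009, 0.010),
}

_DEFAULT_BURSTS = {
    "TA": (Burst(4.0, 7.0, 0.65), Burst(97.0, 6.0, 0.25)),
    "SOL": (Burst(72.0, 15.0, 0.20), Burst(42.0, 16.0, 0.06)),
    "GAL": (Burst(66.0, 15.0, 0.14), Burst(42.0, 16.0, 0.05)),
    "GAM": (Burst(70.0, 15.0, 0.18), Burst(42.0, 16.0, 0.05)),
}

_EXCITATION_BASELINE = 0.02


def default_geometry(theta_range: tuple[float, float] = (-0.40, 0.35)) -> MTUGeometryModel:
    """Ground-truth MTU geometry with the excursion identity built in.

    The moment arm r(theta) is a quadratic per muscle and the MTU length is
    its exact negative antiderivative plus the neutral-pose length
    lst + lm0*cos(phi0), so -d lmt/d theta == r identically.
    """
    lmt_polys, arm_polys, residuals = {}, {}, {}
    for name, p in _DEFAULT_MUSCLES.items():
        arm = Polynomial(_ARM_COEFFS[name])
        neutral = p.lst + p.lm0 * math.cos(p.phi0)
        anti = arm.integ()
        lmt = Polynomial([neutral]) - anti
        lmt_polys[name] = lmt
        arm_polys[name] = arm
        residuals[name] = {"lmt": 0.0, "arm": 0.0}
    return MTUGeometryModel(
        lmt_polys=lmt_polys, arm_polys=arm_polys, degree=3,
        theta_range=theta_range, residual_rms=residuals,
    )


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground-truth parameter set a synthetic cohort is generated from."""

    model: ModelParams
    geometry: MTUGeometryModel
    bursts: Mapping[str, tuple[Burst, ...]]
    #: fractional change of plantar-flexor burst peaks per surface condition
    surface_effects: Mapping[str, float]
    noise_sd: float = 2.0            # N*m, additive on the experimental moment
    seed: int = 0
    rate: float = 100.0              # Hz (envelope-mode trials)
    stance_duration: float = 0.65    # s
    angle_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise sd must be >= 0")
        from .calibrate import check_within_bounds
        check_within_bounds(self.model)

    @property
    def conditions(self) -> tuple[str, ...]:
        return tuple(self.surface_effects)


def default_truth(seed: int = 0, **overrides) -> SyntheticTruth:
    """The default study conditions: 4 surfaces, stiffest two identical,
    +5% / +10% plantar-flexor drive on the two compliant surfaces."""
    model = ModelParams(
        activation=ActivationParams(c1=0.25, c2=-0.35, shape_factor=-1.5),
        muscles=dict(_DEFAULT_MUSCLES),
        gamma_df=0.90,
        gamma_pf=1.15,
        lm0_mult={m: 1.0 for m in MUSCLES},
        lst_mult={"TA": 1.005, "SOL": 0.995, "GAL": 1.0, "GAM": 1.0},
    )
    kw = dict(
        model=model,
        geometry=default_geometry(),
        bursts=dict(_DEFAULT_BURSTS),
        surface_effects={"rigid": 0.0, "rubber": 0.0, "eva": 0.05, "epe": 0.10},
        noise_sd=2.0,
        seed=seed,
    )
    kw.update(overrides)
    return SyntheticTruth(**kw)


@dataclass
class GaitTrial:
    """One stance phase: excitations/EMG, angle, experimental moment, GRFs."""

    rate: float
    time: np.ndarray
    emg: dict[str, np.ndarray]       # envelopes in [0,1] (or raw if raw_emg)
    theta: np.ndarray                # rad, dorsiflexion positive
    tau_id: np.ndarray               # N*m, "experimental" moment
    grf_v: np.ndarray | None
    grf_ap: np.ndarray | None
    stance_start: int
    stance_stop: int
    condition: str
    subject: int = 0
    trial: int = 0
    raw_emg: bool = False

    def __post_init__(self) -> None:
        n = self.time.size
        series = [self.theta, self.tau_id, *self.emg.values()]
        series += [s for s in (self.grf_v, self.grf_ap) if s is not None]
        if any(s.size != n for s in series):
            raise ValueError("all trial series must share one length")
        if not 0 <= self.stance_start < self.stance_stop <= n - 1:
            raise ValueError("stance indices out of bounds")


def stance_angle(pct: np.ndarray, scale: float = 1.0) -> np.ndarray:
    """Canonical stance ankle-angle trajectory (rad) on a stance-% grid."""
    xs = np.array([w[0] for w in THETA_WAYPOINTS])
    ys = np.radians([w[1] for w in THETA_WAYPOINTS]) * scale
    return PchipInterpolator(xs, ys)(np.asarray(pct, float))


def excitation_curve(pct: np.ndarray, bursts: Sequence[Burst],
                     baseline: float = _EXCITATION_BASELINE) -> np.ndarray:
    """Sum-of-Gaussian-bursts excitation over stance %, clipped to [0, 1]."""
    pct = np.asarray(pct, float)
    e = np.full_like(pct, baseline)
    for b in bursts:
        e = e + b.peak * np.exp(-0.5 * ((pct - b.center_pct) / b.width_pct) ** 2)
    return np.clip(e, 0.0, 1.0)


def _grf_curves(pct: np.ndarray, rng: np.random.Generator | None
                ) -> tuple[np.ndarray, np.ndarray]:
    hump1 = 1.10 * np.exp(-0.5 * ((pct - 28.0) / 13.0) ** 2)
    hump2 = 1.07 * np.exp(-0.5 * ((pct - 74.0) / 12.0) ** 2)
    v = BODYWEIGHT_N * (hump1 + hump2)
    ap = BODYWEIGHT_N * 0.17 * (
        -np.exp(-0.5 * ((pct - 22.0) / 11.0) ** 2)
        + np.exp(-0.5 * ((pct - 80.0) / 10.0) ** 2)
    )
    if rng is not None:
        v = v * (1.0 + 0.01 * rng.standard_normal())
        ap = ap * (1.0 + 0.02 * rng.standard_normal())
    return v, ap


def _condition_bursts(truth: SyntheticTruth, condition: str
                      ) -> dict[str, tuple[Burst, ...]]:
    if condition not in truth.surface_effects:
        raise ValueError(
            f"unknown surface condition {condition!r}; configured: "
            f"{list(truth.surface_effects)}"
        )
    effect = truth.surface_effects[condition]
    out = {}
    for m, bursts in truth.bursts.items():
        if truth.model.muscles[m].group == "plantarflexor":
            out[m] = tuple(
                replace(b, peak=min(1.0, b.peak * (1.0 + effect))) for b in bursts
            )
        else:
            out[m] = tuple(bursts)
    return out


def _trial_rng(truth: SyntheticTruth, condition: str, trial_index: int,
               stream: int = 0) -> np.random.Generator:
    cidx = list(truth.surface_effects).index(condition)
    ss = np.random.SeedSequence(
        entropy=truth.seed, spawn_key=(stream, cidx, trial_index)
    )
    return np.random.default_rng(ss)


def generate_trial(
    truth: SyntheticTruth,
    condition: str,
    trial_index: int = 0,
    *,
    subject: int = 0,
    raw_emg: bool = False,
    raw_rate: float = 1500.0,
) -> GaitTrial:
    """Generate one stance-phase trial under the given surface condition.

    The experimental moment is the forward-simulated moment of the truth
    parameters plus zero-mean Gaussian noise of the configured sd; identical
    (seed, condition, trial_index) calls return bit-identical trials.

    With ``raw_emg=True`` the trial is sampled at ``raw_rate`` and the EMG
    channels are envelope-amplitude-modulated band-limited noise, suitable
    for exercising the raw-EMG processing chain.
    """
    if condition not in truth.surface_effects:
        raise ValueError(
            f"unknown surface condition {condition!r}; configured: "
            f"{list(truth.surface_effects)}"
        )
    rate = raw_rate if raw_emg else truth.rate
    n = int(round(truth.stance_duration * rate)) + 1
    time = np.arange(n) / rate
    pct = 100.0 * time / time[-1]
    rng = _trial_rng(truth, condition, trial_index)

    bursts = _condition_bursts(truth, condition)
    excitations = {m: excitation_curve(pct, bursts[m]) for m in truth.model.muscles}
    theta = stance_angle(pct, truth.angle_scale)

    fwd = forward_simulate(excitations, theta, rate, truth.model,
                           truth.geometry, with_stiffness=False)
    noise = truth.noise_sd * rng.standard_normal(n) if truth.noise_sd > 0 else 0.0
    tau_id = fwd.moment + noise
    grf_v, grf_ap = _grf_curves(pct, rng if truth.noise_sd > 0 else None)

    if raw_emg:
        emg = {m: emulate_raw_emg(excitations[m], rate, rng) for m in excitations}
    else:
        emg = excitations

    return GaitTrial(
        rate=rate, time=time, emg=emg, theta=theta, tau_id=tau_id,
        grf_v=grf_v, grf_ap=grf_ap, stance_start=0, stance_stop=n - 1,
        condition=condition, subject=subject, trial=trial_index,
        raw_emg=raw_emg,
    )


def emulate_raw_emg(envelope: np.ndarray, rate: float,
                    rng: np.random.Generator) -> np.ndarray:
    """Amplitude-modulate band-limited Gaussian noise by an envelope.

    The carrier is white noise band-passed to the physiological EMG band
    (a crude interference-pattern model); scaling is chosen so the standard
    6 Hz envelope chain recovers roughly the input envelope.
    """
    from scipy.signal import butter, filtfilt

    envelope = np.asarray(envelope, float)
    carrier = rng.standard_normal(envelope.size)
    b, a = butter(2, (30.0, min(450.0, 0.45 * rate)), btype="bandpass", fs=rate)
    carrier = filtfilt(b, a, carrier)
    carrier /= np.sqrt(np.mean(carrier**2))
    # mean(|band-limited gaussian|) = sqrt(2/pi); undo so the rectified mean
    # tracks the envelope
    return envelope * carrier / math.sqrt(2.0 / math.pi)


def _jitter_truth(truth: SyntheticTruth, rng: np.random.Generator,
                  jitter: float) -> SyntheticTruth:
    """Per-subject copy of the base truth with jittered bursts and strengths,
    kept strictly inside the calibration bounds."""
    if jitter == 0.0:
        return truth
    bursts = {
        m: tuple(
            replace(b, peak=float(np.clip(
                b.peak * (1.0 + jitter * rng.standard_normal()), 0.01, 0.95)))
            for b in bs
        )
        for m, bs in truth.bursts.items()
    }
    model = truth.model.replace(
        gamma_df=float(np.clip(
            truth.model.gamma_df * (1.0 + jitter * rng.standard_normal()),
            0.55, 1.45)),
        gamma_pf=float(np.clip(
            truth.model.gamma_pf * (1.0 + jitter * rng.standard_normal()),
            0.55, 1.45)),
    )
    return replace(truth, model=model, bursts=bursts,
                   angle_scale=truth.angle_scale
                   * float(1.0 + 0.5 * jitter * rng.standard_normal()))


def generate_dataset(
    truth: SyntheticTruth,
    n_subjects: int = 10,
    trials_per_condition: int = 4,
    *,
    subject_jitter: float = 0.05,
) -> list[GaitTrial]:
    """Generate a subject x condition x trial cohort.

    Per-subject truths are jittered copies of the base truth (seeded); the
    returned trials carry complete subject/condition/trial labels so
    repeated-measures curve statistics can be formed downstream.
    """
    if n_subjects < 1 or trials_per_condition < 1:
        raise ValueError("subject and trial counts must be >= 1")
    trials: list[GaitTrial] = []
    for s in range(n_subjects):
        srng = np.random.default_rng(
            np.random.SeedSequence(entropy=truth.seed, spawn_key=(1, s)))
        subject_truth = _jitter_truth(truth, srng, subject_jitter)
        # distinct noise streams per subject via the stream key
        for condition in truth.conditions:
            for k in range(trials_per_condition):
                t = generate_trial(
                    replace(subject_truth, seed=subject_truth.seed + 1000003 * (s + 1)),
                    condition, k, subject=s)
                trials.append(t)
    return trials
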