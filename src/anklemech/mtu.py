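"""Hill-type muscle-tendon dynamics: forces, equilibrium, stiffness.

Each muscle-tendon unit (MTU) is a contractile fiber bundle at pennation
angle Phi in series with an elastic tendon.  At every time step the fiber
and tendon lengths partition the known MTU length,

    lm * cos(Phi) + lt = lmt,       lm * sin(Phi) = lm0 * sin(Phi0),

(the second relation is the constant-thickness pennation closure) and the
force balance along the tendon line of action is

    Ft(eps) = Fm(a, l~m, v~m) * cos(Phi),    eps = (lt - lst) / lst.

Fiber force combines activation-scaled active force-length and
force-velocity curves with a passive elastic term:

    Fm = Fmax * [ f(l~m) * f(v~m) * a + fP(l~m) ].

Tendon force is the piecewise toe/linear law

    Ft = 0                          for eps <= 0
       = 1480.3 * Fmax * eps^2      for 0 < eps <= 0.0127
       = (37.5 * eps - 0.2375) * Fmax   for eps >= 0.0127.

Stiffnesses: Km is the fiber-force length derivative (activation and
velocity frozen) projected onto the tendon line, Kt the tendon force-length
slope, and the series combination Kmt = (1/Km + 1/Kt)^-1 is the MTU
stiffness entering the joint-stiffness sum.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "MuscleParams",
    "MTUTrajectory",
    "force_length",
    "force_length_deriv",
    "force_velocity",
    "passive_force_length",
    "passive_force_length_deriv",
    "fiber_force",
    "fiber_stiffness",
    "tendon_force",
    "tendon_stiffness",
    "series_stiffness",
    "rigid_fiber_length",
    "solve_equilibrium",
    "mtu_stiffness",
]

# ---------------------------------------------------------------------------
# curve constants (all configurable at call sites that need it; these are the
# standard forms for this model family)

FL_WIDTH = 0.45            # Gaussian width of the active force-length curve
FV_CURVATURE = 0.25        # Hill hyperbola shape factor a_f (shortening)
FV_ECC_PLATEAU = 1.4       # eccentric force plateau, x isometric
FV_ECC_RATE = 12.5         # chosen so the eccentric branch is C1 at v~ = 0
PASSIVE_RATE = 10.0
PASSIVE_NORM = math.expm1(5.0)   # fP(1.5) = 1 by construction

TENDON_TOE_COEFF = 1480.3        # quadratic toe-region coefficient, / Fmax
TENDON_LINEAR_SLOPE = 37.5       # linear-branch slope, Fmax per unit strain
TENDON_LINEAR_INTERCEPT = 0.2375
TENDON_TOE_STRAIN = 0.0127       # toe-to-linear transition strain

#: activation floor inside the equilibrium solver; avoids a degenerate flat
#: residual at a = 0 with an elastic tendon
ACTIVATION_FLOOR = 0.005

_EQUILIBRIUM_XTOL = 1e-12        # m, root tolerance on the fiber projection


@dataclass(frozen=True)
class MuscleParams:
    """Hill-model parameters for one MTU.

    ``vmax`` is in optimal fiber lengths per second.  ``group`` tags the
    muscle as ``"dorsiflexor"`` or ``"plantarflexor"`` for strength-coefficient
    scaling during calibration.
    """

    name: str
    fmax: float          # maximum isometric force, N
    lm0: float           # optimal fiber length, m
    lst: float           # tendon slack length, m
    phi0: float          # pennation angle at lm0, rad
    vmax: float = 10.0   # lm0 / s
    group: str = "plantarflexor"

    def __post_init__(self) -> None:
        if min(self.fmax, self.lm0, self.lst, self.vmax) <= 0:
            raise ValueError(f"{self.name}: Fmax, lm0, lst, vmax must be > 0")
        if not 0.0 <= self.phi0 < math.pi / 2:
            raise ValueError(f"{self.name}: pennation must lie in [0, pi/2)")
        if self.group not in ("dorsiflexor", "plantarflexor"):
            raise ValueError(f"{self.name}: unknown group {self.group!r}")

    def with_scaling(
        self, gamma: float = 1.0, lm0_mult: float = 1.0, lst_mult: float = 1.0
    ) -> "MuscleParams":
        """Return a copy with strength/length calibration multipliers applied."""
        return MuscleParams(
            name=self.name,
            fmax=self.fmax * gamma,
            lm0=self.lm0 * lm0_mult,
            lst=self.lst * lst_mult,
            phi0=self.phi0,
            vmax=self.vmax,
            group=self.group,
        )


# ---------------------------------------------------------------------------
# normalized curves


def force_length(lnorm):
    """Active force-length curve, Gaussian with f(1) = 1."""
    lnorm = np.asarray(lnorm, dtype=float)
    return np.exp(-((lnorm - 1.0) ** 2) / FL_WIDTH)


def force_length_deriv(lnorm):
    lnorm = np.asarray(lnorm, dtype=float)
    return -2.0 * (lnorm - 1.0) / FL_WIDTH * force_length(lnorm)


def force_velocity(vnorm):
    """Force-velocity curve: Hill hyperbola (shortening, vnorm < 0) with a
    smooth eccentric branch plateauing at 1.4 x isometric; f(0) = 1,
    f(-1) = 0."""
    v = np.asarray(vnorm, dtype=float)
    vs = np.clip(v, -1.0, 0.0)
    shortening = (1.0 + vs) / (1.0 - vs / FV_CURVATURE)
    ecc = FV_ECC_PLATEAU - (FV_ECC_PLATEAU - 1.0) * np.exp(-FV_ECC_RATE * np.maximum(v, 0.0))
    return np.where(v <= 0.0, shortening, ecc)


def passive_force_length(lnorm):
    """Passive elastic force-length curve: 0 up to optimal length, then
    exponential (normalized so fP(1.5) = 1)."""
    lnorm = np.asarray(lnorm, dtype=float)
    stretched = np.maximum(lnorm - 1.0, 0.0)
    return np.expm1(PASSIVE_RATE * stretched) / PASSIVE_NORM


def passive_force_length_deriv(lnorm):
    lnorm = np.asarray(lnorm, dtype=float)
    out = PASSIVE_RATE * np.exp(PASSIVE_RATE * (lnorm - 1.0)) / PASSIVE_NORM
    return np.where(lnorm > 1.0, out, 0.0)


# ---------------------------------------------------------------------------
# forces


def fiber_force(a, lnorm, vnorm, fmax):
    """Fiber force Fm = Fmax [ f(l~) f(v~) a + fP(l~) ]."""
    a = np.asarray(a, dtype=float)
    if np.any(~np.isfinite(a)) or np.any(~np.isfinite(np.asarray(lnorm, float))):
        raise ValueError("non-finite input to fiber_force")
    return fmax * (force_length(lnorm) * force_velocity(vnorm) * a
                   + passive_force_length(lnorm))


def fiber_stiffness(a, lnorm, vnorm, fmax, lm0):
    """Fiber stiffness dFm/dlm (N/m) at frozen activation and velocity."""
    return (fmax / lm0) * (
        np.asarray(a, float) * force_velocity(vnorm) * force_length_deriv(lnorm)
        + passive_force_length_deriv(lnorm)
    )


def tendon_force(strain, fmax):
    """Piecewise tendon force-strain law (toe quadratic + linear branch)."""
    eps = np.asarray(strain, dtype=float)
    toe = TENDON_TOE_COEFF * eps**2
    lin = TENDON_LINEAR_SLOPE * eps - TENDON_LINEAR_INTERCEPT
    # the transition strain itself belongs to the linear branch
    out = np.where(eps <= 0.0, 0.0, np.where(eps < TENDON_TOE_STRAIN, toe, lin))
    return fmax * out


def tendon_stiffness(strain, fmax, lst):
    """Tendon stiffness Kt = dFt/dlt (N/m): branch-wise analytic derivative."""
    eps = np.asarray(strain, dtype=float)
    toe = 2.0 * TENDON_TOE_COEFF * eps
    deriv = np.where(eps <= 0.0, 0.0,
                     np.where(eps < TENDON_TOE_STRAIN, toe, TENDON_LINEAR_SLOPE))
    return fmax * deriv / lst


def series_stiffness(km, kt):
    """Series combination Kmt = (1/Km + 1/Kt)^-1.

    Zero if either component is zero; equals Km in the rigid-tendon limit
    Kt -> inf.  A negative Km (descending limb) flows through the signed
    formula — callers flag and clamp at the joint level.
    """
    km = np.asarray(km, dtype=float)
    kt = np.asarray(kt, dtype=float)
    out = np.zeros(np.broadcast(km, kt).shape)
    rigid = np.isinf(kt) & np.isfinite(km)
    both = np.isfinite(km) & np.isfinite(kt) & (km != 0.0) & (kt != 0.0)
    denom = np.where(both, km + kt, 1.0)
    degenerate = both & (denom == 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        series = km * kt / denom
    out = np.where(both & ~degenerate, series, out)
    out = np.where(rigid, km, out)
    if out.ndim == 0:
        return float(out)
    return out


def rigid_fiber_length(lmt, p: MuscleParams):
    """Closed-form fiber length with an inextensible tendon (lt = lst)."""
    w = p.lm0 * math.sin(p.phi0)
    return np.sqrt(np.maximum(np.asarray(lmt, float) - p.lst, 0.0) ** 2 + w**2)


# ---------------------------------------------------------------------------
# equilibrium trajectory


@dataclass
class MTUTrajectory:
    """Per-step MTU state for one muscle across a trial."""

    params: MuscleParams
    rate: float
    activation: np.ndarray
    lmt: np.ndarray
    lm: np.ndarray
    lt: np.ndarray
    phi: np.ndarray
    lnorm: np.ndarray
    vnorm: np.ndarray
    strain: np.ndarray
    fm: np.ndarray
    ft: np.ndarray
    fmt: np.ndarray
    residual: np.ndarray
    #: per-step flags: equilibrium fallback used
    fallback: np.ndarray
    km: np.ndarray | None = None
    kt: np.ndarray | None = None
    kmt: np.ndarray | None = None
    #: steps where the projected muscle stiffness went negative
    negative_km: np.ndarray | None = None
    rigid_tendon: bool = False
    meta: dict = field(default_factory=dict)


class EquilibriumError(RuntimeError):
    """Raised when no force-balance root can be bracketed at some step."""

    def __init__(self, message: str, state: dict):
        super().__init__(message)
        self.state = state


def _scalar_tendon_force(eps: float, fmax: float) -> float:
    if eps <= 0.0:
        return 0.0
    if eps < TENDON_TOE_STRAIN:
        return TENDON_TOE_COEFF * fmax * eps * eps
    return (TENDON_LINEAR_SLOPE * eps - TENDON_LINEAR_INTERCEPT) * fmax


def _scalar_fv(v: float) -> float:
    if v <= 0.0:
        if v < -1.0:
            v = -1.0
        return (1.0 + v) / (1.0 - v / FV_CURVATURE)
    return FV_ECC_PLATEAU - (FV_ECC_PLATEAU - 1.0) * math.exp(-FV_ECC_RATE * v)


def _scalar_fv_deriv(v: float) -> float:
    if v <= 0.0:
        if v < -1.0:
            return 0.0
        return (1.0 + 1.0 / FV_CURVATURE) / (1.0 - v / FV_CURVATURE) ** 2
    return (FV_ECC_PLATEAU - 1.0) * FV_ECC_RATE * math.exp(-FV_ECC_RATE * v)


def _bracketed_fallback(resid, x_lo: float, x_hi: float, p: "MuscleParams",
                        t: int, L: float, aeff: float) -> float:
    """Robust sign-change scan + brentq when Newton fails to converge."""
    rlo, rhi = resid(x_lo), resid(x_hi)
    if rlo * rhi <= 0.0:
        return brentq(resid, x_lo, x_hi, xtol=_EQUILIBRIUM_XTOL)
    grid = np.linspace(x_lo, x_hi, 65)
    vals = [resid(g) for g in grid]
    for i in range(len(grid) - 1):
        if vals[i] * vals[i + 1] <= 0.0:
            return brentq(resid, grid[i], grid[i + 1], xtol=_EQUILIBRIUM_XTOL)
    raise EquilibriumError(
        f"{p.name}: no sign change in equilibrium residual at step {t}",
        state={"step": t, "lmt": L, "activation": aeff,
               "residual_lo": rlo, "residual_hi": rhi, "params": p},
    )


def solve_equilibrium(
    a: np.ndarray,
    lmt: np.ndarray,
    p: MuscleParams,
    rate: float,
    *,
    rigid_tendon: bool = False,
    activation_floor: float = ACTIVATION_FLOOR,
    vnorm_override: np.ndarray | None = None,
) -> MTUTrajectory:
    """Solve the fiber/tendon force balance at every time step.

    For each step the fiber projection x = lm cos(Phi) in (0, lmt) is found
    such that Ft(eps) = Fm cos(Phi), with the constant-thickness pennation
    closure and the normalized fiber velocity taken from a two-point backward
    difference of lm (zero at the first step).  The previous step's root seeds
    the bracket, keeping the solution continuous in time.

    In ``rigid_tendon`` mode the tendon is inextensible (lt = lst) and the
    fiber length follows in closed form; Kt is infinite so Kmt = Km.

    ``vnorm_override`` pins the normalized fiber velocity to a given series
    instead of the backward difference — the quasi-static evaluation used
    when differentiating the chain at frozen velocity.
    """
    a = np.clip(np.asarray(a, dtype=float), 0.0, 1.0)
    lmt = np.asarray(lmt, dtype=float)
    if a.shape != lmt.shape or a.ndim != 1:
        raise ValueError("activation and MTU length series must be 1-D and equal length")
    n = a.size
    dt = 1.0 / rate
    w = p.lm0 * math.sin(p.phi0)

    lm = np.empty(n)
    lt = np.empty(n)
    vnorm = np.zeros(n)
    fallback = np.zeros(n, dtype=bool)
    residual = np.zeros(n)

    if vnorm_override is not None:
        vnorm_override = np.asarray(vnorm_override, dtype=float)
        if vnorm_override.shape != a.shape:
            raise ValueError("vnorm_override must match the series length")

    if rigid_tendon:
        lm[:] = rigid_fiber_length(lmt, p)
        lt[:] = p.lst
        if vnorm_override is not None:
            vnorm[:] = vnorm_override
        elif n > 1:
            vnorm[1:] = np.diff(lm) / dt / (p.vmax * p.lm0)
        phi = np.arcsin(np.clip(w / lm, 0.0, 1.0))
        lnorm = lm / p.lm0
        fm = fiber_force(np.maximum(a, activation_floor), lnorm, vnorm, p.fmax)
        ft = fm * np.cos(phi)
        fmt = ft
        strain = np.zeros(n)
        return MTUTrajectory(
            params=p, rate=rate, activation=a, lmt=lmt, lm=lm, lt=lt, phi=phi,
            lnorm=lnorm, vnorm=vnorm, strain=strain, fm=fm, ft=ft, fmt=fmt,
            residual=residual, fallback=fallback, rigid_tendon=True,
        )

    fmax, lm0, lst, vmax = p.fmax, p.lm0, p.lst, p.vmax
    inv_vscale = 1.0 / (vmax * lm0)
    dvn_dlm = inv_vscale / dt
    x_prev = None
    lm_prev = 0.0

    for t in range(n):
        L = lmt[t]
        aeff = max(a[t], activation_floor)
        first = t == 0

        vn_fixed = None if vnorm_override is None else float(vnorm_override[t])

        def resid(x: float, _deriv: bool = False):
            lm_x = math.hypot(x, w)
            cosphi = x / lm_x if lm_x > 0 else 0.0
            if vn_fixed is not None:
                vn = vn_fixed
            else:
                vn = 0.0 if first else (lm_x - lm_prev) / dt * inv_vscale
            eps = (L - x - lst) / lst
            ln = lm_x / lm0
            fl = math.exp(-((ln - 1.0) ** 2) / FL_WIDTH)
            stretched = ln - 1.0
            fp = math.expm1(PASSIVE_RATE * stretched) / PASSIVE_NORM if stretched > 0 else 0.0
            fv = _scalar_fv(vn)
            fm_x = fmax * (fl * fv * aeff + fp)
            r = _scalar_tendon_force(eps, fmax) - fm_x * cosphi
            if not _deriv:
                return r
            # analytic dR/dx for Newton (includes the velocity coupling,
            # which is part of the true residual slope even though the
            # reported Km freezes velocity)
            if eps <= 0.0:
                dft_deps = 0.0
            elif eps < TENDON_TOE_STRAIN:
                dft_deps = 2.0 * TENDON_TOE_COEFF * eps
            else:
                dft_deps = TENDON_LINEAR_SLOPE
            dfl_dln = -2.0 * (ln - 1.0) / FL_WIDTH * fl
            dfp_dln = (PASSIVE_RATE * math.exp(PASSIVE_RATE * stretched) / PASSIVE_NORM
                       if stretched > 0 else 0.0)
            dfv_dvn = _scalar_fv_deriv(vn)
            dvn = 0.0 if (vn_fixed is not None or first) else dvn_dlm
            dfm_dlm = fmax * (aeff * (dfl_dln / lm0 * fv + fl * dfv_dvn * dvn)
                              + dfp_dln / lm0)
            sinphi2 = 1.0 - cosphi * cosphi
            dfalong_dx = dfm_dlm * cosphi * cosphi + (
                fm_x * sinphi2 / lm_x if lm_x > 0 else 0.0)
            return r, -dft_deps * fmax / lst - dfalong_dx

        x_lo, x_hi = 1e-9, L - 1e-9
        if L <= lst * (1.0 + 1e-12) + x_lo:
            # slack MTU: tendon at (at most) natural length, no meaningful
            # equilibrium with tension; record state and flag
            x = max(L - lst, x_lo)
            fallback[t] = True
        else:
            # warm-started safeguarded Newton; R is positive at x_lo (strained
            # tendon, vanishing fiber projection) and negative at x_hi, and in
            # practice monotone, so bisection safeguards guarantee progress
            lo, hi = x_lo, x_hi
            x = x_prev if x_prev is not None else max(L - lst, 0.25 * lm0)
            x = min(max(x, lo), hi)
            converged = False
            for _ in range(60):
                r, dr = resid(x, _deriv=True)
                if abs(r) < 1e-7:
                    converged = True
                    break
                if r > 0.0:
                    lo = x
                else:
                    hi = x
                x_new = x - r / dr if dr != 0.0 else 0.5 * (lo + hi)
                if not lo < x_new < hi:
                    x_new = 0.5 * (lo + hi)
                if abs(x_new - x) < _EQUILIBRIUM_XTOL:
                    x = x_new
                    converged = abs(resid(x)) < 1e-6 * max(fmax, 1.0)
                    break
                x = x_new
            if not converged:
                x = _bracketed_fallback(resid, x_lo, x_hi, p, t, L, aeff)

        lm_t = math.hypot(x, w)
        residual[t] = resid(x)
        if vn_fixed is not None:
            vnorm[t] = vn_fixed
        else:
            vnorm[t] = 0.0 if first else (lm_t - lm_prev) / dt * inv_vscale
        lm[t] = lm_t
        lt[t] = L - x
        lm_prev = lm_t
        x_prev = x

    phi = np.arcsin(np.clip(w / lm, 0.0, 1.0))
    lnorm = lm / p.lm0
    strain = (lt - p.lst) / p.lst
    fm = fiber_force(np.maximum(a, activation_floor), lnorm, vnorm, p.fmax)
    ft = tendon_force(strain, p.fmax)
    fmt = ft.copy()

    return MTUTrajectory(
        params=p, rate=rate, activation=a, lmt=lmt, lm=lm, lt=lt, phi=phi,
        lnorm=lnorm, vnorm=vnorm, strain=strain, fm=fm, ft=ft, fmt=fmt,
        residual=residual, fallback=fallback,
    )


def mtu_stiffness(traj: MTUTrajectory) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Compute (Km, Kt, Kmt) along the trajectory and store them on it.

    Km is the fiber stiffness dFm/dlm (frozen activation and velocity)
    projected onto the tendon line of action: cos^2(Phi) scaling plus the
    geometric term Fm sin^2(Phi)/lm from the pennation change with length.
    Kt is the analytic tendon slope; Kmt their series combination, zero when
    either component is zero, with negative-Km steps flagged.
    """
    p = traj.params
    a_eff = np.maximum(traj.activation, ACTIVATION_FLOOR)
    km_fiber = fiber_stiffness(a_eff, traj.lnorm, traj.vnorm, p.fmax, p.lm0)
    cos_phi = np.cos(traj.phi)
    sin_phi = np.sin(traj.phi)
    km = km_fiber * cos_phi**2 + traj.fm * sin_phi**2 / traj.lm
    if traj.rigid_tendon:
        kt = np.full_like(km, np.inf)
    else:
        kt = tendon_stiffness(traj.strain, p.fmax, p.lst)
    kmt = np.asarray(series_stiffness(km, kt))
    traj.km, traj.kt, traj.kmt = km, kt, kmt
    traj.negative_km = km < 0.0
    return km, kt, kmt
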