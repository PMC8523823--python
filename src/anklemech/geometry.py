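"""Polynomial surrogates for MTU length and moment arm vs ankle angle.

Musculotendon length lmt(theta) and moment arm r(theta) are fitted
independently per muscle as low-order polynomials of the ankle angle, the way
gait models tabulate scaled-model geometry.  The moment-arm derivative
dr/dtheta needed by the joint-stiffness sum is the exact analytic derivative
of the fitted polynomial.

Sign convention: angle and moment are dorsiflexion-positive, so the
dorsiflexor (TA) arm is positive and plantar-flexor arms are negative.  With
this convention the tendon-excursion identity reads r = -d lmt / d theta.

Evaluation outside the fitted angle interval is an error, never
extrapolation: polynomial surrogates are wild outside their fit range and
would silently corrupt the dr/dtheta stiffness term.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
from numpy.polynomial import Polynomial

__all__ = ["GeometrySeries", "MTUGeometryModel", "fit_geometry", "excursion_check"]

DEFAULT_DEGREE = 3


@dataclass
class GeometrySeries:
    """Angle-evaluated geometry for one muscle: lengths, arms, arm slopes."""

    lmt: np.ndarray       # MTU length, m
    arm: np.ndarray       # moment arm, m, signed (dorsiflexion-positive)
    arm_slope: np.ndarray  # dr/dtheta, m/rad


@dataclass
class MTUGeometryModel:
    """Fitted per-muscle polynomials for lmt(theta) and r(theta).

    ``lmt_polys`` / ``arm_polys`` map muscle name to ``numpy`` ``Polynomial``
    objects in the unscaled angle variable (rad).  ``theta_range`` is the
    closed validity interval; ``residual_rms`` stores per-muscle fit quality.
    """

    lmt_polys: dict[str, Polynomial]
    arm_polys: dict[str, Polynomial]
    degree: int
    theta_range: tuple[float, float]
    residual_rms: dict[str, dict[str, float]] = field(default_factory=dict)

    @property
    def muscles(self) -> list[str]:
        return list(self.lmt_polys)

    def _check_domain(self, theta: np.ndarray) -> None:
        lo, hi = self.theta_range
        tol = 1e-12
        bad = (theta < lo - tol) | (theta > hi + tol)
        if np.any(bad):
            i = int(np.argmax(bad))
            raise ValueError(
                f"angle sample {i} ({theta.flat[i]:.4f} rad) outside the "
                f"geometry validity range [{lo:.4f}, {hi:.4f}] rad; "
                "refusing to extrapolate"
            )

    def evaluate(self, theta: np.ndarray) -> dict[str, GeometrySeries]:
        """Evaluate lmt, r and dr/dtheta for every muscle at given angles."""
        theta = np.atleast_1d(np.asarray(theta, dtype=float))
        self._check_domain(theta)
        out: dict[str, GeometrySeries] = {}
        for m in self.lmt_polys:
            lmt = self.lmt_polys[m](theta)
            if np.any(lmt <= 0):
                raise ValueError(f"non-positive MTU length for muscle {m!r}")
            arm_poly = self.arm_polys[m]
            out[m] = GeometrySeries(
                lmt=lmt,
                arm=arm_poly(theta),
                arm_slope=arm_poly.deriv()(theta),
            )
        return out


def _fit_one(theta: np.ndarray, y: np.ndarray, degree: int) -> tuple[Polynomial, float]:
    # Polynomial.fit uses a scaled domain for conditioning; convert back so
    # coefficients are in plain powers of theta.
    p = Polynomial.fit(theta, y, deg=degree).convert()
    resid = y - p(theta)
    return p, float(np.sqrt(np.mean(resid**2)))


def fit_geometry(
    samples: Mapping[str, tuple[Iterable[float], Iterable[float], Iterable[float]]],
    degree: int = DEFAULT_DEGREE,
) -> MTUGeometryModel:
    """Least-squares polynomial fit of (theta, lmt, r) samples per muscle.

    Parameters
    ----------
    samples :
        Mapping muscle name -> (theta, lmt, r) sample arrays; theta in rad,
        lengths/arms in m, arms signed dorsiflexion-positive.
    degree :
        Polynomial degree, 2..5 (default 3 — ankle MTU curves over
        stance-range angles are smooth and low-order).

    Raises
    ------
    ValueError
        Fewer than ``degree + 2`` distinct angle samples, or a degree outside
        [2, 5].
    """
    if not 2 <= degree <= 5:
        raise ValueError(f"degree must be in [2, 5], got {degree}")
    if not samples:
        raise ValueError("no geometry samples supplied")

    lmt_polys: dict[str, Polynomial] = {}
    arm_polys: dict[str, Polynomial] = {}
    residuals: dict[str, dict[str, float]] = {}
    lo, hi = np.inf, -np.inf
    for name, (theta, lmt, arm) in samples.items():
        theta = np.asarray(theta, dtype=float)
        lmt = np.asarray(lmt, dtype=float)
        arm = np.asarray(arm, dtype=float)
        n_distinct = np.unique(theta).size
        if n_distinct < degree + 2:
            raise ValueError(
                f"muscle {name!r}: need at least degree+2 = {degree + 2} "
                f"distinct angle samples, got {n_distinct}"
            )
        lmt_polys[name], rms_l = _fit_one(theta, lmt, degree)
        arm_polys[name], rms_r = _fit_one(theta, arm, degree)
        residuals[name] = {"lmt": rms_l, "arm": rms_r}
        lo = min(lo, float(theta.min()))
        hi = max(hi, float(theta.max()))

    return MTUGeometryModel(
        lmt_polys=lmt_polys,
        arm_polys=arm_polys,
        degree=degree,
        theta_range=(lo, hi),
        residual_rms=residuals,
    )


def excursion_check(
    model: MTUGeometryModel, n_grid: int = 41
) -> dict[str, float]:
    """Tendon-excursion consistency ratio, reported but never enforced.

    Returns, per muscle, the median ratio of the fitted arm r(theta) to
    -d lmt/d theta over the validity range.  The two quantities are fitted
    independently, so exact equality is not expected; ratios outside
    [0.5, 2] suggest inconsistent source geometry.
    """
    lo, hi = model.theta_range
    theta = np.linspace(lo, hi, n_grid)
    out = {}
    for m in model.muscles:
        arm = model.arm_polys[m](theta)
        excursion = -model.lmt_polys[m].deriv()(theta)
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(np.abs(excursion) > 1e-9, arm / excursion, np.nan)
        out[m] = float(np.nanmedian(ratio))
    return out
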