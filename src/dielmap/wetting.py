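"""Membrane-wetting mechanics.

From the three apparent contact angles of an axisymmetric
vesicle-condensate pair (interior, external and condensate angles,
closing to 360 degrees around the contact line) this module derives:

* the intrinsic contact angle
  ``cos(theta_in) = (sin(theta_e) - sin(theta_c)) / sin(theta_i)``,
  a scale-invariant material parameter;
* the membrane-segment tension ratios from the law of sines of the
  tension triangle;
* the affinity contrast ``W = cos(theta_in) * sigma_ce`` — negative
  when the membrane prefers the condensate phase, positive otherwise;
* a linear fit of intrinsic contact angle versus permittivity contrast.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "WettingGeometry",
    "WettingResult",
    "TrendFit",
    "intrinsic_contact_angle",
    "affinity_contrast",
    "fit_wetting_trend",
    "InconsistentAnglesError",
]

CLOSURE_WARN_DEG = 2.0
CLOSURE_ERROR_DEG = 5.0


class InconsistentAnglesError(ValueError):
    """Raised for angle triples violating closure or the arccos domain."""


@dataclass(frozen=True)
class WettingGeometry:
    """Apparent contact angles (degrees) of a vesicle-condensate pair.

    ``theta_i``, ``theta_e``, ``theta_c`` face the vesicle interior,
    the external (depleted) phase and the condensate respectively; they
    must close to 360 degrees around the three-phase contact line.
    ``sigma_ce`` is the condensate-external interfacial tension
    (force/length), optional.
    """

    theta_i: float
    theta_e: float
    theta_c: float
    sigma_ce: Optional[float] = None

    def __post_init__(self) -> None:
        for name, ang in (
            ("theta_i", self.theta_i),
            ("theta_e", self.theta_e),
            ("theta_c", self.theta_c),
        ):
            if not 0.0 < ang < 360.0:
                raise ValueError(f"{name}={ang} outside (0, 360) degrees")
        closure = self.theta_i + self.theta_e + self.theta_c - 360.0
        if abs(closure) > CLOSURE_ERROR_DEG:
            raise InconsistentAnglesError(
                f"contact angles sum to {360 + closure:.2f} degrees; "
                f"deviation from closure exceeds {CLOSURE_ERROR_DEG} degrees"
            )
        if abs(closure) > CLOSURE_WARN_DEG:
            warnings.warn(
                f"contact-angle closure off by {closure:+.2f} degrees",
                RuntimeWarning,
                stacklevel=3,
            )
        if math.sin(math.radians(self.theta_i)) == 0.0:
            raise InconsistentAnglesError("sin(theta_i) vanishes")


@dataclass(frozen=True)
class WettingResult:
    """Derived wetting quantities for one angle triple."""

    theta_in: float  # intrinsic contact angle, degrees
    cos_theta_in: float
    W_over_sigma: float  # rescaled affinity contrast (= cos theta_in)
    tension_ratio_ie: float  # sigma_ie^m / sigma_ce
    tension_ratio_ic: float  # sigma_ic^m / sigma_ce
    W: Optional[float] = None  # affinity contrast, force/length


def intrinsic_contact_angle(geom: WettingGeometry) -> WettingResult:
    """Intrinsic contact angle and derived mechanics from apparent angles.

    Raises
    ------
    InconsistentAnglesError
        When ``|sin(theta_e) - sin(theta_c)| > sin(theta_i)`` so that no
        consistent tension balance exists.
    """
    ti = math.radians(geom.theta_i)
    te = math.radians(geom.theta_e)
    tc = math.radians(geom.theta_c)
    sin_i = math.sin(ti)
    arg = (math.sin(te) - math.sin(tc)) / sin_i
    if abs(arg) > 1.0 + 1e-12:
        raise InconsistentAnglesError(
            f"(sin theta_e - sin theta_c)/sin theta_i = {arg:.6f} "
            "lies outside [-1, 1]; inconsistent angle triple"
        )
    arg = min(1.0, max(-1.0, arg))
    theta_in = math.degrees(math.acos(arg))
    ratio_ie = math.sin(tc) / sin_i
    ratio_ic = math.sin(te) / sin_i
    w = arg * geom.sigma_ce if geom.sigma_ce is not None else None
    return WettingResult(
        theta_in=theta_in,
        cos_theta_in=arg,
        W_over_sigma=arg,
        tension_ratio_ie=ratio_ie,
        tension_ratio_ic=ratio_ic,
        W=w,
    )


def affinity_contrast(theta_in: float, sigma_ce: float) -> float:
    """Affinity contrast W = cos(theta_in) * sigma_ce.

    Negative W means the membrane prefers the condensate phase over the
    external depleted phase; positive means the opposite.
    """
    if not 0.0 <= theta_in <= 180.0:
        raise ValueError("theta_in must lie in [0, 180] degrees")
    if sigma_ce <= 0:
        raise ValueError("sigma_ce must be positive")
    return math.cos(math.radians(theta_in)) * sigma_ce


@dataclass
class TrendFit:
    """Linear trend of intrinsic contact angle versus permittivity contrast."""

    slope: float  # degrees per permittivity unit
    intercept: float  # degrees
    slope_stderr: float
    intercept_stderr: float
    residuals: np.ndarray

    def predict(self, delta_epsilon) -> np.ndarray:
        return self.slope * np.asarray(delta_epsilon, float) + self.intercept

    def to_dict(self) -> dict:
        return {
            "slope": self.slope,
            "intercept": self.intercept,
            "slope_stderr": self.slope_stderr,
            "intercept_stderr": self.intercept_stderr,
            "residuals": list(map(float, self.residuals)),
        }


def fit_wetting_trend(
    delta_epsilon: Sequence[float],
    theta_in: Sequence[float],
    uncertainties: Optional[Sequence[float]] = None,
) -> TrendFit:
    """Least-squares line theta_in = slope * delta_epsilon + intercept.

    With ``uncertainties`` given (standard deviations of theta_in), the
    fit is weighted by 1/uncertainty^2.
    """
    x = np.asarray(delta_epsilon, dtype=float)
    y = np.asarray(theta_in, dtype=float)
    if x.size != y.size:
        raise ValueError("delta_epsilon and theta_in lengths differ")
    if x.size < 3:
        raise ValueError(
            f"insufficient data: need >= 3 points, got {x.size}"
        )
    if np.ptp(x) == 0:
        raise ValueError("zero variance in delta_epsilon; singular fit")
    if uncertainties is not None:
        u = np.asarray(uncertainties, dtype=float)
        if np.any(u <= 0):
            raise ValueError("uncertainties must be positive")
        w = 1.0 / u**2
    else:
        w = np.ones_like(x)

    design = np.column_stack([x, np.ones_like(x)])
    wd = design * w[:, None]
    ata = design.T @ wd
    atb = wd.T @ y
    beta = np.linalg.solve(ata, atb)
    resid = y - design @ beta
    dof = max(x.size - 2, 1)
    if uncertainties is None:
        s2 = float(resid @ resid) / dof
        cov = s2 * np.linalg.inv(ata)
    else:
        chi2 = float((w * resid**2).sum()) / dof
        cov = chi2 * np.linalg.inv(ata)
    return TrendFit(
        slope=float(beta[0]),
        intercept=float(beta[1]),
        slope_stderr=float(np.sqrt(cov[0, 0])),
        intercept_stderr=float(np.sqrt(cov[1, 1])),
        residuals=resid,
    )
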