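"""Calibration between dye spectral readout and dielectric permittivity.

The forward model links the emission maximum to the relative
permittivity of the dye microenvironment through the lumped relation

    1 / lambda_max = a * f(epsilon) + b

where ``f`` is a reaction-field (generalized Debye) function of the
permittivity — by default ``f(eps) = (eps - 1) / (2 eps + 1)`` — and
``a``, ``b`` lump the dye dipole moments, molecular volume and physical
constants.  Fitting references in 1/lambda space makes the problem
exactly linear.

Phasor phases are converted to emission wavelengths through the linear
window mapping ``lambda_max = phase * (lambda_f - lambda_0)/(2 pi) +
lambda_0``, so a single fitted model serves both readout kinds.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence, Union

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "ReferenceSolution",
    "CalibrationModel",
    "MixtureSpec",
    "debye_f",
    "lippert_mataga_lambda_max",
    "fit_calibration",
    "phase_to_lambda_max",
    "lambda_max_to_phase",
    "invert_to_epsilon",
    "maxwell_garnett",
    "InsufficientReferencesError",
    "NonPhysicalModelError",
]

TWO_PI = 2.0 * math.pi


class InsufficientReferencesError(ValueError):
    """Raised when too few (or degenerate) references are supplied."""


class NonPhysicalModelError(ValueError):
    """Raised when the lumped parameters imply a nonpositive 1/lambda."""


_DEBYE_VARIANTS: dict[str, Callable[[np.ndarray], np.ndarray]] = {
    # Onsager reaction-field form; the refractive-index term of the
    # classic orientation polarizability is absorbed into the intercept.
    "debye": lambda eps: (eps - 1.0) / (2.0 * eps + 1.0),
    # Clausius-Mossotti form, offered as an alternative.
    "clausius_mossotti": lambda eps: (eps - 1.0) / (eps + 2.0),
}


def debye_f(epsilon, variant: str = "debye"):
    """Reaction-field function f(epsilon), strictly increasing in epsilon.

    Parameters
    ----------
    epsilon : float or array
        Relative permittivity, >= 1.
    variant : str
        One of ``"debye"`` (default, ``(eps-1)/(2 eps+1)``) or
        ``"clausius_mossotti"``.
    """
    eps = np.asarray(epsilon, dtype=float)
    if np.any(eps < 1.0):
        raise ValueError("epsilon must be >= 1")
    try:
        f = _DEBYE_VARIANTS[variant]
    except KeyError:
        raise ValueError(
            f"unknown variant {variant!r}; choose from {sorted(_DEBYE_VARIANTS)}"
        ) from None
    out = f(eps)
    return float(out) if np.isscalar(epsilon) else out


def phase_to_lambda_max(phase: float, axis: tuple[float, float]) -> float:
    """Map a phasor phase in [0, 2*pi] linearly onto the detection window."""
    lam0, lamf = axis
    if not 0.0 <= phase <= TWO_PI:
        raise ValueError(f"phase {phase} outside [0, 2*pi]")
    return phase * (lamf - lam0) / TWO_PI + lam0


def lambda_max_to_phase(lambda_max: float, axis: tuple[float, float]) -> float:
    """Inverse of :func:`phase_to_lambda_max`."""
    lam0, lamf = axis
    if not lam0 <= lambda_max <= lamf:
        raise ValueError(f"wavelength {lambda_max} outside window [{lam0}, {lamf}]")
    return (lambda_max - lam0) / (lamf - lam0) * TWO_PI


@dataclass(frozen=True)
class ReferenceSolution:
    """A reference of known permittivity with a measured spectral readout.

    ``readout`` is an emission maximum in nm (``readout_kind="lambda_max"``)
    or a phasor phase in radians (``readout_kind="phase"``).
    """

    name: str
    epsilon: float
    readout: float
    readout_kind: str = "lambda_max"
    source: str = "literature"

    def __post_init__(self) -> None:
        if self.epsilon <= 1.0:
            raise ValueError("reference epsilon must exceed 1")
        if self.readout_kind not in ("lambda_max", "phase"):
            raise ValueError(f"unknown readout_kind {self.readout_kind!r}")
        if self.readout_kind == "phase" and not 0.0 <= self.readout <= TWO_PI:
            raise ValueError("phase readout outside [0, 2*pi]")

    def lambda_max(self, axis: tuple[float, float]) -> float:
        if self.readout_kind == "lambda_max":
            return self.readout
        return phase_to_lambda_max(self.readout, axis)


@dataclass
class CalibrationModel:
    """Bijective map between permittivity and spectral readout.

    Attributes
    ----------
    a, b : float
        Lumped slope and intercept of the 1/lambda_max linearization
        (nm^-1).
    debye_variant : str
        Which reaction-field function the model was fitted with.
    epsilon_range : tuple
        Calibrated permittivity interval; inversions outside it clamp.
    axis : tuple
        (lambda_0, lambda_f) window endpoints for phase conversion.
    """

    a: float
    b: float
    debye_variant: str = "debye"
    epsilon_range: tuple[float, float] = (2.0, 80.0)
    axis: tuple[float, float] = (416.0, 728.0)
    residuals: dict = field(default_factory=dict)
    monotone: bool = True

    def lambda_max(self, epsilon) -> float:
        return lippert_mataga_lambda_max(epsilon, self)

    def phase(self, epsilon: float) -> float:
        return lambda_max_to_phase(self.lambda_max(epsilon), self.axis)

    def to_json(self) -> str:
        return json.dumps(
            {
                "a": self.a,
                "b": self.b,
                "debye_variant": self.debye_variant,
                "epsilon_range": list(self.epsilon_range),
                "axis": list(self.axis),
                "residuals": self.residuals,
                "monotone": self.monotone,
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "CalibrationModel":
        d = json.loads(text)
        return cls(
            a=d["a"],
            b=d["b"],
            debye_variant=d.get("debye_variant", "debye"),
            epsilon_range=tuple(d.get("epsilon_range", (2.0, 80.0))),
            axis=tuple(d.get("axis", (416.0, 728.0))),
            residuals=d.get("residuals", {}),
            monotone=d.get("monotone", True),
        )


def lippert_mataga_lambda_max(epsilon, model: CalibrationModel):
    """Forward map: permittivity -> emission maximum (nm)."""
    inv = model.a * debye_f(epsilon, model.debye_variant) + model.b
    if np.any(np.asarray(inv) <= 0):
        raise NonPhysicalModelError(
            "a*f(epsilon)+b must be positive; got nonpositive 1/lambda"
        )
    out = 1.0 / inv
    return float(out) if np.isscalar(epsilon) else out


def fit_calibration(
    refs: Sequence[ReferenceSolution],
    debye_variant: str = "debye",
    epsilon_range: tuple[float, float] = (2.0, 80.0),
    axis: tuple[float, float] = (416.0, 728.0),
) -> CalibrationModel:
    """Fit the lumped (a, b) parameters to reference solutions.

    Performs exact linear least squares on 1/lambda_max versus
    f(epsilon).  Phase readouts are converted to wavelengths through
    the window mapping first.

    Raises
    ------
    InsufficientReferencesError
        For fewer than 3 references or a degenerate epsilon range.
    """
    if len(refs) < 3:
        raise InsufficientReferencesError(
            f"insufficient references: need >= 3, got {len(refs)}"
        )
    eps = np.array([r.epsilon for r in refs])
    lam = np.array([r.lambda_max(axis) for r in refs])
    f = debye_f(eps, debye_variant)
    if np.ptp(f) == 0:
        raise InsufficientReferencesError(
            "references span a degenerate permittivity range"
        )
    design = np.column_stack([f, np.ones_like(f)])
    y = 1.0 / lam
    (a, b), *_ = np.linalg.lstsq(design, y, rcond=None)
    model = CalibrationModel(
        a=float(a),
        b=float(b),
        debye_variant=debye_variant,
        epsilon_range=epsilon_range,
        axis=axis,
    )
    pred = design @ np.array([a, b])
    model.residuals = {
        r.name: float(1.0 / p - l) for r, p, l in zip(refs, pred, lam)
    }
    # bijectivity check over the calibrated range
    grid = np.linspace(epsilon_range[0], epsilon_range[1], 256)
    lam_grid = lippert_mataga_lambda_max(grid, model)
    d = np.diff(lam_grid)
    model.monotone = bool(np.all(d > 0) or np.all(d < 0))
    if not model.monotone:
        import warnings

        warnings.warn(
            "fitted calibration model is not monotone over epsilon_range",
            RuntimeWarning,
            stacklevel=2,
        )
    return model


def invert_to_epsilon(
    readout: float,
    model: CalibrationModel,
    readout_kind: str = "lambda_max",
) -> tuple[float, bool]:
    """Invert a spectral readout to permittivity.

    Returns ``(epsilon, clamped)``.  Readouts mapping outside the
    calibrated wavelength interval are clamped to the nearest bound and
    flagged, never silently extrapolated.

    Parameters
    ----------
    readout : float
        Emission maximum in nm or phasor phase in radians, per
        ``readout_kind``.
    """
    if readout_kind == "phase":
        lam = phase_to_lambda_max(readout, model.axis)
    elif readout_kind == "lambda_max":
        lam = float(readout)
    else:
        raise ValueError(f"unknown readout_kind {readout_kind!r}")
    if not model.axis[0] <= lam <= model.axis[1]:
        raise ValueError(
            f"readout {lam:.2f} nm lies outside the detection window {model.axis}"
        )
    eps_min, eps_max = model.epsilon_range
    lam_lo = lippert_mataga_lambda_max(eps_min, model)
    lam_hi = lippert_mataga_lambda_max(eps_max, model)
    lo, hi = (lam_lo, lam_hi) if lam_lo <= lam_hi else (lam_hi, lam_lo)
    tol = 1e-9  # float fuzz at the calibrated boundary is not a clamp
    if lam <= lo:
        eps = eps_min if lam_lo <= lam_hi else eps_max
        return (eps, lam < lo - tol)
    if lam >= hi:
        eps = eps_max if lam_lo <= lam_hi else eps_min
        return (eps, lam > hi + tol)

    def g(eps):
        return lippert_mataga_lambda_max(eps, model) - lam

    eps = brentq(g, eps_min, eps_max, xtol=1e-12, rtol=1e-14)
    return (float(eps), False)


def invert_many(
    lam: np.ndarray, model: CalibrationModel
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized wavelength -> permittivity inversion with clamp flags.

    Uses the closed-form inverse of the linearized model (solving
    ``f(eps) = (1/lam - b)/a`` for eps) which matches the bracketed
    root-finding inverse to solver tolerance for the built-in variants.
    """
    lam = np.asarray(lam, dtype=float)
    eps_min, eps_max = model.epsilon_range
    with np.errstate(divide="ignore", invalid="ignore"):
        fval = (1.0 / lam - model.b) / model.a
        if model.debye_variant == "debye":
            # f = (e-1)/(2e+1)  =>  e = (1+f)/(1-2f)
            eps = (1.0 + fval) / (1.0 - 2.0 * fval)
        elif model.debye_variant == "clausius_mossotti":
            # f = (e-1)/(e+2)  =>  e = (1+2f)/(1-f)
            eps = (1.0 + 2.0 * fval) / (1.0 - fval)
        else:  # pragma: no cover - fallback for plug-in variants
            eps = np.array(
                [invert_to_epsilon(v, model)[0] for v in lam.ravel()]
            ).reshape(lam.shape)
            clamped = (eps <= eps_min) | (eps >= eps_max)
            return eps, clamped
    bad = ~np.isfinite(eps)
    clamped = bad | (eps < eps_min) | (eps > eps_max)
    eps = np.clip(np.where(bad, eps_max, eps), eps_min, eps_max)
    return eps, clamped


# ---------------------------------------------------------------------------
# Maxwell-Garnett effective-medium mixing
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MixtureSpec:
    """Two-component mixture for effective-medium permittivity."""

    epsilon_host: float
    epsilon_inclusion: float
    volume_fraction_inclusion: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.volume_fraction_inclusion <= 1.0:
            raise ValueError("volume fraction must lie in [0, 1]")
        if self.epsilon_host <= 0 or self.epsilon_inclusion <= 0:
            raise ValueError("permittivities must be positive")


def maxwell_garnett(spec: MixtureSpec) -> float:
    """Effective permittivity of a dilute two-component mixture.

    Solves ``(e_eff - e_h)/(e_eff + 2 e_h) = delta (e_i - e_h)/(e_i + 2 e_h)``
    for ``e_eff`` in closed form.
    """
    e_h = spec.epsilon_host
    e_i = spec.epsilon_inclusion
    delta = spec.volume_fraction_inclusion
    q = delta * (e_i - e_h) / (e_i + 2.0 * e_h)
    return float(e_h * (1.0 + 2.0 * q) / (1.0 - q))
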