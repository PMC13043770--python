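"""Synthetic hyperspectral data with known ground truth.

The forward model renders per-pixel skewed-Gaussian emission spectra
whose peak position follows a calibration model, composes two-phase
droplet scenes with optional Poisson shot noise, and can emulate the
"sedimenting droplet" artifact in which the short-wavelength channels
of a droplet are missing (which inflates the spectral phase).

Two anchoring conventions are supported when placing a spectrum for a
given permittivity:

``anchor="mode"``
    The numeric mode of the spectrum equals the calibration wavelength
    — the natural convention for the Gaussian-fit readout route.
``anchor="phase"`` (default)
    The discrete phasor phase of the spectrum, mapped linearly onto the
    detection window, equals the calibration wavelength — the
    convention that makes the phasor readout route self-consistent,
    mirroring a calibration measured through the same transform.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import brentq

from .calibration import (
    CalibrationModel,
    ReferenceSolution,
    lambda_max_to_phase,
    lippert_mataga_lambda_max,
    phase_to_lambda_max,
)
from .spectra import (
    DEFAULT_AXIS,
    HyperspectralStack,
    SpectralAxis,
    Spectrum,
    _standard_mode_offset,
    phasor_transform,
    skew_gaussian,
)

__all__ = [
    "Droplet",
    "SceneSpec",
    "ForwardModel",
    "GroundTruth",
    "default_calibration",
    "forward_spectrum",
    "generate_stack",
    "generate_reference_set",
]


def default_calibration(
    lambda_at_min: float = 440.0,
    lambda_at_max: float = 520.0,
    epsilon_range: tuple[float, float] = (2.0, 80.0),
    axis: tuple[float, float] = (416.0, 728.0),
    debye_variant: str = "debye",
) -> CalibrationModel:
    """A plausible generating calibration: emission shifts redward from
    ``lambda_at_min`` nm at the low-permittivity end to ``lambda_at_max``
    nm at the high end.  The lumped (a, b) are solved exactly from the
    two anchor wavelengths."""
    from .calibration import debye_f

    f_lo = debye_f(epsilon_range[0], debye_variant)
    f_hi = debye_f(epsilon_range[1], debye_variant)
    a = (1.0 / lambda_at_max - 1.0 / lambda_at_min) / (f_hi - f_lo)
    b = 1.0 / lambda_at_min - a * f_lo
    return CalibrationModel(
        a=a,
        b=b,
        debye_variant=debye_variant,
        epsilon_range=epsilon_range,
        axis=axis,
    )


@dataclass
class ForwardModel:
    """Spectral forward model: permittivity -> emission spectrum.

    ``sigma_law`` maps permittivity to spectral width (nm); the default
    is affine-decreasing (45 nm at the low end of the calibrated range
    to 35 nm at the high end), a fixture mimicking quenching-related
    broadening trends, not a literature claim.
    """

    calibration: CalibrationModel = field(default_factory=default_calibration)
    sigma_at_min: float = 45.0
    sigma_at_max: float = 35.0
    gamma: float = 1.0
    anchor: str = "phase"

    def __post_init__(self) -> None:
        if self.anchor not in ("mode", "phase"):
            raise ValueError(f"unknown anchor {self.anchor!r}")
        if self.sigma_at_min <= 0 or self.sigma_at_max <= 0:
            raise ValueError("spectral widths must be positive")

    def sigma(self, epsilon: float) -> float:
        lo, hi = self.calibration.epsilon_range
        t = (epsilon - lo) / (hi - lo)
        return self.sigma_at_min + t * (self.sigma_at_max - self.sigma_at_min)


def _discrete_phase_lambda(
    mu: float, sigma: float, gamma: float, axis: SpectralAxis,
    window: tuple[float, float],
) -> float:
    """Phase of the discrete phasor of a skew-Gaussian, as a wavelength."""
    intens = skew_gaussian(axis.channel_centers, 1.0, mu, sigma, gamma)
    n_c = axis.n_channels
    angles = 2.0 * np.pi * np.arange(n_c) / n_c
    total = intens.sum()
    g = float(np.dot(intens, np.cos(angles)) / total)
    s = float(np.dot(intens, np.sin(angles)) / total)
    phase = math.atan2(s, g) % (2.0 * math.pi)
    return phase_to_lambda_max(phase, window)


def _solve_mu(
    target_lambda: float, sigma: float, gamma: float, axis: SpectralAxis,
    anchor: str, window: tuple[float, float],
) -> float:
    if anchor == "mode":
        return target_lambda - sigma * _standard_mode_offset(float(gamma))

    def g(mu):
        return _discrete_phase_lambda(mu, sigma, gamma, axis, window) - target_lambda

    # phase-wavelength is monotone in mu over the central window
    lo = target_lambda - 3.0 * sigma
    hi = target_lambda + 3.0 * sigma
    return brentq(g, lo, hi, xtol=1e-10)


def forward_spectrum(
    epsilon: float,
    model: ForwardModel,
    axis: SpectralAxis = DEFAULT_AXIS,
    peak_counts: float = 100.0,
) -> Spectrum:
    """Noise-free emission spectrum for a pixel of given permittivity.

    The spectrum is sampled at channel centers and scaled so its
    brightest channel carries ``peak_counts``.

    Raises
    ------
    ValueError
        If ``epsilon`` lies outside the calibrated range.
    """
    lo, hi = model.calibration.epsilon_range
    if not lo <= epsilon <= hi:
        raise ValueError(
            f"epsilon {epsilon} outside calibrated range [{lo}, {hi}]"
        )
    target = lippert_mataga_lambda_max(epsilon, model.calibration)
    sigma = model.sigma(epsilon)
    mu = _solve_mu(
        target, sigma, model.gamma, axis, model.anchor, model.calibration.axis
    )
    intens = skew_gaussian(axis.channel_centers, 1.0, mu, sigma, model.gamma)
    intens = intens * (peak_counts / intens.max())
    return Spectrum(axis, intens)


@dataclass(frozen=True)
class Droplet:
    """A disk of condensed phase in a synthetic scene."""

    center: tuple[float, float]  # (row, col), px
    radius: float  # px
    epsilon: float
    peak_counts: float
    artifact_cutoff: Optional[int] = None  # zero channels below this index

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("droplet radius must be positive")
        if self.peak_counts < 0:
            raise ValueError("peak counts must be nonnegative")


@dataclass
class SceneSpec:
    """Declarative description of a synthetic two-phase scene."""

    shape: tuple[int, int] = (64, 64)
    droplets: Sequence[Droplet] = ()
    background_epsilon: float = 60.0
    background_peak_counts: float = 100.0
    noise: str = "none"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise not in ("none", "poisson"):
            raise ValueError(f"unknown noise model {self.noise!r}")


@dataclass
class GroundTruth:
    """Per-pixel truth accompanying a generated stack.

    ``labels``: 0 for background (depleted phase), 1..n for droplets in
    draw order (later droplets win overlaps).
    """

    labels: np.ndarray
    epsilon_map: np.ndarray
    artifact_mask: np.ndarray
    seed: int

    def condensate_mask(self, include_artifacts: bool = False) -> np.ndarray:
        m = self.labels > 0
        return m if include_artifacts else (m & ~self.artifact_mask)

    def background_mask(self) -> np.ndarray:
        return self.labels == 0


def generate_stack(
    scene: SceneSpec,
    model: ForwardModel,
    axis: SpectralAxis = DEFAULT_AXIS,
) -> tuple[HyperspectralStack, GroundTruth]:
    """Render a scene into a hyperspectral stack plus ground truth.

    Deterministic for a fixed ``scene.seed``.  Artifact droplets (those
    with ``artifact_cutoff``) have their expected counts zeroed in all
    channels below the cutoff before noise is applied.
    """
    rows, cols = scene.shape
    labels = np.zeros((rows, cols), dtype=np.int32)
    eps_map = np.full((rows, cols), scene.background_epsilon, dtype=float)
    peak_map = np.full((rows, cols), scene.background_peak_counts, dtype=float)
    cutoff_map = np.zeros((rows, cols), dtype=np.int32)
    artifact = np.zeros((rows, cols), dtype=bool)

    rr, cc = np.mgrid[0:rows, 0:cols]
    for i, d in enumerate(scene.droplets, start=1):
        sel = (rr - d.center[0]) ** 2 + (cc - d.center[1]) ** 2 <= d.radius**2
        labels[sel] = i
        eps_map[sel] = d.epsilon
        peak_map[sel] = d.peak_counts
        if d.artifact_cutoff is not None:
            cutoff_map[sel] = d.artifact_cutoff
            artifact[sel] = True
        else:
            cutoff_map[sel] = 0
            artifact[sel] = False

    # one base (unit-peak) spectrum per distinct permittivity
    cube = np.empty((rows, cols, axis.n_channels), dtype=float)
    for eps in np.unique(eps_map):
        base = forward_spectrum(eps, model, axis, peak_counts=1.0).intensities
        sel = eps_map == eps
        cube[sel] = base[None, :] * peak_map[sel, None]

    if artifact.any():
        chan = np.arange(axis.n_channels)
        kill = chan[None, None, :] < cutoff_map[:, :, None]
        cube = np.where(kill, 0.0, cube)

    if scene.noise == "poisson":
        rng = np.random.default_rng(scene.seed)
        cube = rng.poisson(cube).astype(float)

    stack = HyperspectralStack(
        axis=axis,
        cube=cube,
        metadata={
            "generator": "dielmap.synth",
            "seed": scene.seed,
            "noise": scene.noise,
            "anchor": model.anchor,
            "gamma": model.gamma,
            "sigma_law": [model.sigma_at_min, model.sigma_at_max],
        },
    )
    truth = GroundTruth(
        labels=labels,
        epsilon_map=eps_map,
        artifact_mask=artifact,
        seed=scene.seed,
    )
    return stack, truth


def generate_reference_set(
    epsilons: Sequence[float],
    model: ForwardModel,
    noise_sd: float = 0.0,
    seed: int = 0,
    readout_kind: str = "phase",
    axis: SpectralAxis = DEFAULT_AXIS,
) -> list[ReferenceSolution]:
    """Synthetic calibration references with known generating model.

    Readouts are measured from noise-free forward spectra: the phasor
    phase for ``readout_kind="phase"``, or the generating peak
    wavelength for ``readout_kind="lambda_max"``.  ``noise_sd`` adds a
    Gaussian perturbation (nm scale; converted for phase readouts).
    """
    if len(epsilons) < 3:
        raise ValueError("need at least 3 reference permittivities")
    rng = np.random.default_rng(seed)
    window = model.calibration.axis
    refs = []
    for i, eps in enumerate(epsilons):
        if readout_kind == "phase":
            spec = forward_spectrum(eps, model, axis)
            lam = phase_to_lambda_max(phasor_transform(spec).phase, window)
        elif readout_kind == "lambda_max":
            lam = lippert_mataga_lambda_max(eps, model.calibration)
        else:
            raise ValueError(f"unknown readout_kind {readout_kind!r}")
        if noise_sd > 0:
            lam = lam + rng.normal(0.0, noise_sd)
        if readout_kind == "phase":
            readout = lambda_max_to_phase(lam, window)
        else:
            readout = lam
        refs.append(
            ReferenceSolution(
                name=f"synthetic_{i}",
                epsilon=float(eps),
                readout=float(readout),
                readout_kind=readout_kind,
                source="literature",
            )
        )
    return refs
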