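"""Permittivity mapping of hyperspectral stacks.

Pipeline: intensity thresholding on the channel-mean image, per-pixel
phasor transform, phase -> wavelength -> permittivity inversion through
a fitted calibration model, two-class condensate/depleted segmentation
on the mean-intensity image, and per-phase statistics including the
permittivity contrast between condensate and depleted phases.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label

from .calibration import CalibrationModel, invert_many, invert_to_epsilon
from .spectra import (
    HyperspectralStack,
    PhasorImage,
    fit_skewed_gaussian,
    phasor_image,
)

__all__ = [
    "PixelMask",
    "PermittivityMap",
    "PhaseSegmentation",
    "PhaseStats",
    "LabelStats",
    "threshold_mask",
    "permittivity_map",
    "segment_phases",
    "phase_statistics",
    "CONDENSATE",
    "DEPLETED",
    "EXCLUDED",
]

# segmentation label codes
EXCLUDED = 0
CONDENSATE = 1
DEPLETED = 2


@dataclass
class PixelMask:
    """Boolean inclusion mask with threshold provenance."""

    include: np.ndarray
    threshold_value: float
    method: str

    @property
    def n_included(self) -> int:
        return int(self.include.sum())


@dataclass
class PermittivityMap:
    """Per-pixel permittivity with clamp flags and validity mask."""

    epsilon: np.ndarray
    clamped_flags: np.ndarray
    valid_mask: np.ndarray
    model_id: str = ""

    def valid_epsilon(self) -> np.ndarray:
        return self.epsilon[self.valid_mask]


@dataclass
class PhaseSegmentation:
    """Condensate / depleted / excluded pixel labels."""

    labels: np.ndarray
    counts: dict = field(default_factory=dict)
    polarity: str = "bright_condensate"
    single_class: bool = False

    def mask(self, code: int) -> np.ndarray:
        return self.labels == code


@dataclass
class LabelStats:
    """Summary statistics for one segmentation label."""

    mean_phase: float
    epsilon_from_mean_phase: float
    median_epsilon: float
    iqr_epsilon: float
    n_pixels: int


@dataclass
class PhaseStats:
    """Per-phase permittivity statistics and the condensate-depleted contrast.

    ``contrast`` is ``epsilon_condensate - epsilon_depleted`` computed
    from the mean-phase permittivities; None when either phase is empty.
    """

    condensate: Optional[LabelStats]
    depleted: Optional[LabelStats]
    contrast: Optional[float]


def threshold_mask(
    stack: HyperspectralStack,
    method: str = "quantile",
    value: float = 0.5,
) -> PixelMask:
    """Intensity threshold on the channel-mean image.

    Parameters
    ----------
    method : {"absolute", "quantile", "otsu"}
        ``absolute`` keeps pixels with mean intensity >= ``value``;
        ``quantile`` derives the cutoff from the given quantile of the
        mean-intensity distribution (default 0.5); ``otsu`` ignores
        ``value``.
    """
    mean_img = stack.mean_intensity_image()
    if method == "absolute":
        cutoff = float(value)
    elif method == "quantile":
        if not 0.0 < value < 1.0:
            raise ValueError("quantile must lie in (0, 1)")
        cutoff = float(np.quantile(mean_img, value))
    elif method == "otsu":
        cutoff = float(threshold_otsu(mean_img))
    else:
        raise ValueError(f"unknown threshold method {method!r}")
    include = mean_img >= cutoff
    if not include.any():
        warnings.warn(
            "threshold excludes every pixel", RuntimeWarning, stacklevel=2
        )
    return PixelMask(include=include, threshold_value=cutoff, method=method)


def permittivity_map(
    stack: HyperspectralStack,
    model: CalibrationModel,
    mask: Optional[PixelMask] = None,
    harmonic: int = 1,
    method: str = "phase",
) -> PermittivityMap:
    """Convert a stack to a per-pixel permittivity map.

    ``method="phase"`` (default, the production route) runs the phasor
    transform, maps each pixel phase linearly to a wavelength and
    inverts the calibration model.  ``method="fit"`` fits a
    skewed-Gaussian per pixel and inverts its mode; it is slow and
    intended for cross-validation on small images.

    Out-of-range pixels are clamped to the calibrated permittivity
    interval and flagged.
    """
    if mask is not None and mask.include.shape != stack.shape:
        raise ValueError("mask dimensions do not match stack")
    include = (
        mask.include if mask is not None else np.ones(stack.shape, dtype=bool)
    )
    if not include.any():
        warnings.warn("all pixels excluded", RuntimeWarning, stacklevel=2)

    if method == "phase":
        ph_img = phasor_image(stack, harmonic=harmonic)
        valid = include & ph_img.valid_mask
        phase = ph_img.phase_map
        lam0, lamf = model.axis
        lam = phase * (lamf - lam0) / (2.0 * np.pi) + lam0
        lam = np.where(valid, lam, lam0)
        eps, clamped = invert_many(lam, model)
    elif method == "fit":
        valid = include & (stack.cube.sum(axis=2) > 0)
        eps = np.zeros(stack.shape, dtype=float)
        clamped = np.zeros(stack.shape, dtype=bool)
        for r, c in zip(*np.nonzero(valid)):
            fit = fit_skewed_gaussian(stack.pixel_spectrum(r, c))
            lam = min(max(fit.lambda_max, model.axis[0]), model.axis[1])
            eps[r, c], clamped[r, c] = invert_to_epsilon(lam, model)
    else:
        raise ValueError(f"unknown method {method!r}")

    eps = np.where(valid, eps, np.nan)
    clamped = clamped & valid
    return PermittivityMap(
        epsilon=eps, clamped_flags=clamped, valid_mask=valid
    )


def segment_phases(
    stack: HyperspectralStack,
    mask: Optional[PixelMask] = None,
    polarity: str = "bright_condensate",
    bimodality_min_separation: float = 0.5,
) -> PhaseSegmentation:
    """Two-class condensate/depleted split on the mean-intensity image.

    Included pixels are split at the Otsu threshold of their
    mean-intensity distribution.  By default the brighter class is
    labeled condensate (the dye partitions into the dense phase);
    ``polarity="dim_condensate"`` inverts the assignment.  When the
    intensity distribution is effectively unimodal — the Otsu class
    separation falls below ``bimodality_min_separation`` standard
    deviations or one class is empty — a single-class result is
    returned with a warning.
    """
    if polarity not in ("bright_condensate", "dim_condensate"):
        raise ValueError(f"unknown polarity {polarity!r}")
    mean_img = stack.mean_intensity_image()
    include = (
        mask.include if mask is not None else np.ones(stack.shape, dtype=bool)
    )
    if not include.any():
        raise ValueError("mask excludes every pixel; nothing to segment")

    vals = mean_img[include]
    labels = np.full(stack.shape, EXCLUDED, dtype=np.int8)
    single = False
    std = vals.std()
    if np.ptp(vals) == 0 or std == 0:
        single = True
    else:
        cut = threshold_otsu(vals)
        bright = vals > cut
        if not bright.any() or bright.all():
            single = True
        else:
            separation = (vals[bright].mean() - vals[~bright].mean()) / std
            if separation < bimodality_min_separation:
                single = True
    if single:
        warnings.warn(
            "intensity distribution is unimodal; single-class segmentation",
            RuntimeWarning,
            stacklevel=2,
        )
        labels[include] = (
            CONDENSATE if polarity == "bright_condensate" else DEPLETED
        )
    else:
        bright_map = include & (mean_img > cut)
        dim_map = include & ~bright_map
        if polarity == "bright_condensate":
            labels[bright_map] = CONDENSATE
            labels[dim_map] = DEPLETED
        else:
            labels[bright_map] = DEPLETED
            labels[dim_map] = CONDENSATE
    counts = {
        "condensate": int((labels == CONDENSATE).sum()),
        "depleted": int((labels == DEPLETED).sum()),
        "excluded": int((labels == EXCLUDED).sum()),
    }
    return PhaseSegmentation(
        labels=labels, counts=counts, polarity=polarity, single_class=single
    )


def label_condensate_droplets(
    seg: PhaseSegmentation,
) -> tuple[np.ndarray, np.ndarray]:
    """8-connected condensate droplet labels plus a border-touch flag array."""
    lab = cc_label(seg.labels == CONDENSATE, connectivity=2)
    n = lab.max()
    touches = np.zeros(n + 1, dtype=bool)
    border = np.zeros(lab.shape, dtype=bool)
    border[0, :] = border[-1, :] = border[:, 0] = border[:, -1] = True
    for idx in np.unique(lab[border]):
        touches[idx] = True
    touches[0] = False
    return lab, touches


def _label_stats(
    phases: np.ndarray, eps: np.ndarray, model: CalibrationModel
) -> LabelStats:
    mean_phase = float(phases.mean())
    eps_mean_phase, _ = invert_to_epsilon(
        mean_phase, model, readout_kind="phase"
    )
    q1, med, q3 = np.percentile(eps, [25.0, 50.0, 75.0])
    return LabelStats(
        mean_phase=mean_phase,
        epsilon_from_mean_phase=float(eps_mean_phase),
        median_epsilon=float(med),
        iqr_epsilon=float(q3 - q1),
        n_pixels=int(phases.size),
    )


def phase_statistics(
    pmap: PermittivityMap,
    seg: PhaseSegmentation,
    phasor: PhasorImage,
    model: CalibrationModel,
) -> PhaseStats:
    """Per-phase statistics: mean phase converted to permittivity, plus
    median/IQR of per-pixel permittivity, and the condensate-depleted
    contrast.

    The per-stack statistic follows the averaging order used for the
    reported values: average the phase first, then convert to
    permittivity.
    """
    if not (
        pmap.epsilon.shape == seg.labels.shape == phasor.G_map.shape
    ):
        raise ValueError("map, segmentation and phasor dimensions must agree")
    phase_map = phasor.phase_map
    stats: dict[int, Optional[LabelStats]] = {}
    for code in (CONDENSATE, DEPLETED):
        sel = seg.mask(code) & pmap.valid_mask & phasor.valid_mask
        if not sel.any():
            stats[code] = None
            continue
        stats[code] = _label_stats(
            phase_map[sel], pmap.epsilon[sel], model
        )
    contrast = None
    if stats[CONDENSATE] is not None and stats[DEPLETED] is not None:
        contrast = (
            stats[CONDENSATE].epsilon_from_mean_phase
            - stats[DEPLETED].epsilon_from_mean_phase
        )
    return PhaseStats(
        condensate=stats[CONDENSATE],
        depleted=stats[DEPLETED],
        contrast=contrast,
    )
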