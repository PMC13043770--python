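"""Readers and writers: TIFF stacks, reference CSVs, wetting tables,
run configuration, and provenance logging."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd
import tifffile
import yaml

from .calibration import CalibrationModel, ReferenceSolution
from .spectra import HyperspectralStack, SpectralAxis

__all__ = [
    "RunConfig",
    "read_stack",
    "write_stack",
    "write_epsilon_map",
    "read_references_csv",
    "write_references_csv",
    "read_wetting_csv",
    "load_calibration",
    "save_calibration",
    "write_run_log",
]

PathLike = Union[str, Path]


@dataclass
class RunConfig:
    """Pipeline configuration; serializable to/from YAML."""

    lambda_start: float = 416.0
    lambda_end: float = 728.0
    n_channels: int = 32
    harmonic: int = 1
    threshold_method: str = "quantile"
    threshold_value: float = 0.5
    segmentation_polarity: str = "bright_condensate"
    calibration_path: Optional[str] = None
    output_dir: str = "."
    seed: int = 0
    verbose: bool = False
    extras: dict = field(default_factory=dict)

    @property
    def axis(self) -> SpectralAxis:
        return SpectralAxis(self.lambda_start, self.lambda_end, self.n_channels)

    @classmethod
    def from_yaml(cls, path: PathLike) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        extras = dict(data.pop("extras", {}))
        known = {f for f in cls.__dataclass_fields__ if f != "extras"}
        kwargs = {k: v for k, v in data.items() if k in known}
        extras.update({k: v for k, v in data.items() if k not in known})
        return cls(**kwargs, extras=extras)

    def to_yaml(self, path: PathLike) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    def digest(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def read_stack(path: PathLike, config: Optional[RunConfig] = None) -> HyperspectralStack:
    """Read a multipage/OME TIFF as a hyperspectral stack.

    Pages (or the leading axis of a 3-D series) are interpreted as
    spectral channels, channel 0 being the bluest window.  For
    multi-series files only the first series is read, with a warning.

    Raises
    ------
    ValueError
        When the channel count disagrees with the configured axis.
    """
    config = config or RunConfig()
    path = Path(path)
    with tifffile.TiffFile(path) as tf:
        if len(tf.series) > 1:
            import warnings

            warnings.warn(
                f"{path.name} holds {len(tf.series)} series; reading the "
                "first and ignoring the rest",
                RuntimeWarning,
                stacklevel=2,
            )
        data = tf.series[0].asarray()
    if data.ndim != 3:
        raise ValueError(f"expected a 3-D stack, got shape {data.shape}")
    # channel-first on disk -> (row, col, channel) in memory
    cube = np.moveaxis(data, 0, -1).astype(float)
    axis = config.axis
    if cube.shape[2] != axis.n_channels:
        raise ValueError(
            f"channel mismatch: file has {cube.shape[2]} channels, "
            f"config declares {axis.n_channels}"
        )
    return HyperspectralStack(axis=axis, cube=cube, metadata={"path": str(path)})


def write_stack(path: PathLike, stack: HyperspectralStack) -> None:
    """Write a stack as a channel-first multipage TIFF (float32)."""
    data = np.moveaxis(stack.cube, -1, 0).astype(np.float32)
    tifffile.imwrite(
        path,
        data,
        metadata={
            "axes": "CYX",
            "lambda_start_nm": stack.axis.lambda_start,
            "lambda_end_nm": stack.axis.lambda_end,
            "channel0": "bluest window",
        },
    )


def write_epsilon_map(
    path: PathLike,
    epsilon: np.ndarray,
    png_path: Optional[PathLike] = None,
) -> None:
    """Write a permittivity map as 32-bit TIFF, optionally with a PNG render."""
    tifffile.imwrite(path, epsilon.astype(np.float32))
    if png_path is not None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(5, 4))
        im = ax.imshow(epsilon, cmap="viridis")
        fig.colorbar(im, ax=ax, label="relative permittivity")
        ax.set_axis_off()
        fig.savefig(png_path, dpi=150, bbox_inches="tight")
        plt.close(fig)


def read_references_csv(path: PathLike) -> list[ReferenceSolution]:
    """References CSV: columns name, epsilon, readout, readout_kind[, source]."""
    df = pd.read_csv(path)
    required = {"name", "epsilon", "readout"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"references CSV missing columns: {sorted(missing)}")
    refs = []
    for _, row in df.iterrows():
        refs.append(
            ReferenceSolution(
                name=str(row["name"]),
                epsilon=float(row["epsilon"]),
                readout=float(row["readout"]),
                readout_kind=str(row.get("readout_kind", "lambda_max")),
                source=str(row.get("source", "literature")),
            )
        )
    return refs


def write_references_csv(path: PathLike, refs: list[ReferenceSolution]) -> None:
    pd.DataFrame(
        [
            {
                "name": r.name,
                "epsilon": r.epsilon,
                "readout": r.readout,
                "readout_kind": r.readout_kind,
                "source": r.source,
            }
            for r in refs
        ]
    ).to_csv(path, index=False)


def read_wetting_csv(path: PathLike) -> pd.DataFrame:
    """Wetting CSV: condition_id, theta_i_deg, theta_e_deg, theta_c_deg
    [, sigma_ce, delta_epsilon]."""
    df = pd.read_csv(path)
    required = {"condition_id", "theta_i_deg", "theta_e_deg", "theta_c_deg"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"wetting CSV missing columns: {sorted(missing)}")
    return df


def load_calibration(path: PathLike) -> CalibrationModel:
    return CalibrationModel.from_json(Path(path).read_text())


def save_calibration(path: PathLike, model: CalibrationModel) -> None:
    Path(path).write_text(model.to_json())


def write_run_log(path: PathLike, config: RunConfig, **entries) -> None:
    """Machine-readable run log with config echo and provenance."""
    log = {
        "config": asdict(config),
        "config_digest": config.digest(),
        **entries,
    }
    Path(path).write_text(json.dumps(log, indent=2, default=str))
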