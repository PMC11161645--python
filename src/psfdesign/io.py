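"""Bit-exact file I/O: TIFF payloads with JSON sidecars.

Masks and stacks are stored as 32-bit float TIFF (single page for masks,
one page per z for stacks) so any microscopy toolchain can open them; the
accompanying ``<file>.json`` sidecar carries the optical configuration and
axial grid, keeping metadata diffable and portable.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import tifffile
import yaml

from .fisher_crlb import NoiseModel
from .pupil_optics import OpticalConfig, PhaseMask, PSFStack

__all__ = [
    "save_mask",
    "load_mask",
    "save_stack",
    "load_stack",
    "save_run_config",
    "load_run_config",
    "RunConfig",
]

logger = logging.getLogger("psfdesign")


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def _config_dict(config: OpticalConfig) -> dict:
    return dataclasses.asdict(config)


def save_mask(path: str | Path, mask: PhaseMask, config: OpticalConfig | None = None) -> Path:
    """Write a mask as single-page float32 TIFF + JSON sidecar."""
    path = Path(path)
    tifffile.imwrite(path, mask.phase.astype(np.float32))
    meta = {"label": mask.label}
    if config is not None:
        meta["optical_config"] = _config_dict(config)
    _sidecar(path).write_text(json.dumps(meta, indent=2))
    return path


def load_mask(
    path: str | Path, expect_grid_n: int | None = None
) -> tuple[PhaseMask, OpticalConfig | None]:
    """Read a mask TIFF; missing sidecar loads with defaults and a warning."""
    path = Path(path)
    phase = np.asarray(tifffile.imread(path), dtype=np.float64)
    if expect_grid_n is not None and phase.shape != (expect_grid_n, expect_grid_n):
        raise ValueError(
            f"mask grid {phase.shape} does not match requested grid_n="
            f"{expect_grid_n}; no silent resampling"
        )
    sidecar = _sidecar(path)
    config = None
    label = path.stem
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        label = meta.get("label", label)
        if "optical_config" in meta:
            config = OpticalConfig(**meta["optical_config"])
    else:
        logger.warning("no sidecar for %s; loading with default metadata", path)
    return PhaseMask(phase, label=label), config


def save_stack(
    path: str | Path,
    stack: PSFStack | np.ndarray,
    z_grid: np.ndarray | None = None,
    pixel_pitch: float | None = None,
    config: OpticalConfig | None = None,
) -> Path:
    """Write a z-stack as multi-page float32 TIFF (ascending z) + sidecar."""
    path = Path(path)
    if isinstance(stack, PSFStack):
        values, z_grid, pixel_pitch = stack.values, stack.z_grid, stack.pixel_pitch
    else:
        values = np.asarray(stack)
        if z_grid is None:
            raise ValueError("z_grid required when saving a bare array")
    tifffile.imwrite(path, values.astype(np.float32), photometric="minisblack")
    meta = {
        "z_grid": np.asarray(z_grid, dtype=float).tolist(),
        "pixel_pitch": float(pixel_pitch) if pixel_pitch is not None else None,
    }
    if config is not None:
        meta["optical_config"] = _config_dict(config)
    _sidecar(path).write_text(json.dumps(meta, indent=2))
    return path


def load_stack(path: str | Path) -> PSFStack:
    """Read a stack TIFF + sidecar back into a :class:`PSFStack`."""
    path = Path(path)
    values = np.asarray(tifffile.imread(path), dtype=np.float64)
    if values.ndim == 2:
        values = values[None]
    sidecar = _sidecar(path)
    if not sidecar.exists():
        raise IOError(f"missing sidecar {sidecar}")
    meta = json.loads(sidecar.read_text())
    z_grid = np.asarray(meta["z_grid"], dtype=float)
    if len(z_grid) != values.shape[0]:
        raise ValueError(
            f"sidecar z_grid length {len(z_grid)} does not match "
            f"{values.shape[0]} TIFF pages"
        )
    return PSFStack(values, z_grid, meta.get("pixel_pitch") or 1.0)


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class RunConfig:
    """Serializable bundle of everything a CLI run needs to be reproduced."""

    optical: OpticalConfig = dataclasses.field(default_factory=OpticalConfig)
    noise: NoiseModel = dataclasses.field(default_factory=NoiseModel)
    seed: int = 0
    log_level: str = "INFO"
    extra: dict = dataclasses.field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "optical": dataclasses.asdict(self.optical),
            "noise": dataclasses.asdict(self.noise),
            "seed": self.seed,
            "log_level": self.log_level,
            "extra": self.extra,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        return cls(
            optical=OpticalConfig(**d.get("optical", {})),
            noise=NoiseModel(**d.get("noise", {})),
            seed=int(d.get("seed", 0)),
            log_level=d.get("log_level", "INFO"),
            extra=d.get("extra", {}),
        )


def save_run_config(path: str | Path, config: RunConfig) -> Path:
    path = Path(path)
    text = (
        yaml.safe_dump(config.to_dict())
        if path.suffix in {".yml", ".yaml"}
        else json.dumps(config.to_dict(), indent=2)
    )
    path.write_text(text)
    return path


def load_run_config(path: str | Path) -> RunConfig:
    path = Path(path)
    text = path.read_text()
    data = (
        yaml.safe_load(text)
        if path.suffix in {".yml", ".yaml"}
        else json.loads(text)
    )
    return RunConfig.from_dict(data)
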