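"""Image and configuration file I/O.

Canonical image format is 32-bit float TIFF (lossless concentration values);
8-bit grayscale PNG export is provided for display.  Simulation parameters
load from a flat YAML mapping mirroring the :class:`SimulationParams` fields.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import yaml

from .forward_model import SimulationParams

__all__ = [
    "read_image",
    "write_tiff",
    "write_png",
    "load_sim_config",
    "dump_sim_config",
]


def read_image(path: str | Path) -> np.ndarray:
    """Read a grayscale image (TIFF float or 8-bit PNG) onto the [0, 1] scale."""
    path = Path(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        import tifffile

        arr = np.asarray(tifffile.imread(path), dtype=float)
    else:
        import imageio.v3 as iio

        arr = np.asarray(iio.imread(path), dtype=float)
        if arr.ndim == 3:
            arr = arr.mean(axis=-1)
        arr = arr / 255.0
    return arr


def write_tiff(path: str | Path, image: np.ndarray) -> None:
    import tifffile

    tifffile.imwrite(Path(path), np.asarray(image, dtype=np.float32))


def write_png(path: str | Path, image: np.ndarray) -> None:
    import imageio.v3 as iio

    arr = (np.clip(np.asarray(image, dtype=float), 0.0, 1.0) * 255).astype(np.uint8)
    iio.imwrite(Path(path), arr)


_SIM_FIELDS = (
    "mu0",
    "particle_diameter_nm",
    "temperature_k",
    "boltzmann_k",
    "magnetic_moment",
    "gradient",
    "snr_db_range",
    "h_sat",
)


def load_sim_config(path: str | Path) -> SimulationParams:
    """Load simulation parameters from a YAML mapping; unknown keys rejected."""
    with open(path) as fh:
        payload = yaml.safe_load(fh) or {}
    unknown = set(payload) - set(_SIM_FIELDS)
    if unknown:
        raise ValueError(f"unknown simulation config keys: {sorted(unknown)}")
    if "snr_db_range" in payload:
        payload["snr_db_range"] = tuple(payload["snr_db_range"])
    return SimulationParams(**payload)


def dump_sim_config(path: str | Path, params: SimulationParams) -> None:
    payload = {
        "mu0": params.mu0,
        "particle_diameter_nm": params.particle_diameter_nm,
        "temperature_k": params.temperature_k,
        "boltzmann_k": params.boltzmann_k,
        "magnetic_moment": params.magnetic_moment,
        "gradient": params.gradient,
        "snr_db_range": list(params.snr_db_range),
        "h_sat": params.h_sat,
    }
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=True)
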