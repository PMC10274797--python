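"""Disk I/O, configuration and run persistence for the speckle rheology pipeline.

Speckle movies are stored as multi-page grayscale TIFF stacks (or flat raw
binary) accompanied by a plain ``key: value`` sidecar file carrying the
acquisition metadata.  All numeric artifacts written by this module are in SI
units (rad/s, Pa, m^2, s); the writers never rescale silently.
"""

from __future__ import annotations

import dataclasses
import logging
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Tuple

import h5py
import numpy as np
import pandas as pd
import tifffile
import yaml

logger = logging.getLogger("shears")

#: sidecar metadata keys that must always be present
_REQUIRED_META = (
    "frame_rate",
    "n_frames",
    "exposure",
    "wavelength",
    "pixel_pitch",
    "bit_depth",
)


@dataclass
class SpeckleSeries:
    """A speckle intensity time series with its acquisition metadata.

    ``frames`` is a ``(height, width, n_frames)`` array of photon-count
    proportional non-negative integers.
    """

    frames: np.ndarray
    frame_rate: float  # frames per second
    exposure: float  # seconds
    wavelength: float  # metres
    pixel_pitch: float  # metres
    bit_depth: int  # bits

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a (height, width, n_frames) array")
        if self.n_frames < 2:
            raise ValueError("a speckle series needs at least 2 frames")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")
        if self.exposure > 1.0 / self.frame_rate + 1e-15:
            raise ValueError("exposure cannot exceed one frame period")
        if self.frames.size and self.frames.min() < 0:
            raise ValueError("intensities must be non-negative")
        if self.frames.size and self.frames.max() > 2 ** self.bit_depth - 1:
            raise ValueError(
                f"intensity {self.frames.max()} exceeds {self.bit_depth}-bit range"
            )

    @property
    def n_frames(self) -> int:
        return self.frames.shape[2]

    @property
    def shape(self) -> Tuple[int, int]:
        return self.frames.shape[0], self.frames.shape[1]

    @property
    def duration(self) -> float:
        """Acquisition duration tau in seconds (n_frames / frame_rate)."""
        return self.n_frames / self.frame_rate

    def metadata(self) -> dict:
        return {
            "frame_rate": float(self.frame_rate),
            "n_frames": int(self.n_frames),
            "height": int(self.frames.shape[0]),
            "width": int(self.frames.shape[1]),
            "exposure": float(self.exposure),
            "wavelength": float(self.wavelength),
            "pixel_pitch": float(self.pixel_pitch),
            "bit_depth": int(self.bit_depth),
            "dtype": str(self.frames.dtype),
        }


@dataclass
class SampleConfig:
    """Optical and thermodynamic description of the probed sample."""

    refractive_index: float = 1.33
    temperature: float = 295.0  # kelvin (room temperature)
    particle_radius: float = 1.5e-6  # metres
    #: (mu_s_prime [1/m], mu_a [1/m], anisotropy g) or None
    optical_properties: Optional[Tuple[float, float, float]] = None
    #: direct (gamma, zeta) override, bypassing the Monte Carlo lookup
    gamma_zeta_override: Optional[Tuple[float, float]] = None

    def __post_init__(self) -> None:
        if self.refractive_index < 1:
            raise ValueError("refractive_index must be >= 1")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        if self.particle_radius <= 0:
            raise ValueError("particle_radius must be positive")
        if self.optical_properties is not None:
            mus, mua, g = self.optical_properties
            if mus <= 0:
                raise ValueError("mu_s_prime must be positive")
            if mua < 0:
                raise ValueError("mu_a must be non-negative")
            if not 0 <= g < 1:
                raise ValueError("anisotropy g must be in [0, 1)")

    @classmethod
    def from_yaml(cls, path) -> "SampleConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = {}
        for key in ("refractive_index", "temperature", "particle_radius"):
            if key in raw:
                kwargs[key] = float(raw[key])
        if raw.get("optical_properties") is not None:
            op = raw["optical_properties"]
            kwargs["optical_properties"] = (
                float(op["mu_s_prime"]),
                float(op["mu_a"]),
                float(op.get("g", 0.0)),
            )
        if raw.get("gamma_zeta_override") is not None:
            gz = raw["gamma_zeta_override"]
            kwargs["gamma_zeta_override"] = (float(gz["gamma"]), float(gz["zeta"]))
        return cls(**kwargs)

    def to_yaml(self, path) -> None:
        data = {
            "refractive_index": self.refractive_index,
            "temperature": self.temperature,
            "particle_radius": self.particle_radius,
        }
        if self.optical_properties is not None:
            mus, mua, g = self.optical_properties
            data["optical_properties"] = {"mu_s_prime": mus, "mu_a": mua, "g": g}
        if self.gamma_zeta_override is not None:
            data["gamma_zeta_override"] = {
                "gamma": self.gamma_zeta_override[0],
                "zeta": self.gamma_zeta_override[1],
            }
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh)


# ---------------------------------------------------------------------------
# movie readers / writers
# ---------------------------------------------------------------------------


def _parse_sidecar(metadata_path) -> dict:
    with open(metadata_path) as fh:
        meta = yaml.safe_load(fh)
    if not isinstance(meta, dict):
        raise ValueError(f"sidecar {metadata_path} is not a key: value mapping")
    for key in _REQUIRED_META:
        if key not in meta:
            raise ValueError(f"sidecar metadata is missing required field '{key}'")
    return meta


def write_speckle_series(series: SpeckleSeries, path, metadata_path=None) -> None:
    """Write a movie as a multi-page TIFF (``.tif``) or raw binary (``.raw``)
    plus a sidecar metadata file (defaults to ``<path>.meta.yaml``)."""
    path = Path(path)
    if metadata_path is None:
        metadata_path = path.with_suffix(path.suffix + ".meta.yaml")
    # pages along the first axis for TIFF
    stack = np.moveaxis(series.frames, 2, 0)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, stack, photometric="minisblack")
    elif path.suffix.lower() == ".raw":
        stack.tofile(path)
    else:
        raise ValueError(f"unsupported movie format '{path.suffix}'")
    with open(metadata_path, "w") as fh:
        yaml.safe_dump(series.metadata(), fh)


def read_speckle_series(path, metadata_path=None) -> SpeckleSeries:
    """Read a speckle movie (multi-page TIFF or raw binary) and its sidecar.

    Raises ``ValueError`` on missing metadata fields, frame-count mismatch
    between header and file, or intensities exceeding the declared bit depth.
    """
    path = Path(path)
    if metadata_path is None:
        metadata_path = path.with_suffix(path.suffix + ".meta.yaml")
    meta = _parse_sidecar(metadata_path)
    n_frames = int(meta["n_frames"])
    if path.suffix.lower() in (".tif", ".tiff"):
        stack = tifffile.imread(path)
        if stack.ndim == 2:
            stack = stack[None]
        if stack.shape[0] != n_frames:
            raise ValueError(
                f"frame-count mismatch: sidecar declares {n_frames} frames "
                f"but {path.name} holds {stack.shape[0]}"
            )
    elif path.suffix.lower() == ".raw":
        for key in ("height", "width", "dtype"):
            if key not in meta:
                raise ValueError(f"sidecar metadata is missing required field '{key}'")
        h, w = int(meta["height"]), int(meta["width"])
        dtype = np.dtype(meta["dtype"])
        expected = n_frames * h * w
        flat = np.fromfile(path, dtype=dtype)
        if flat.size != expected:
            raise ValueError(
                f"frame-count mismatch: sidecar declares {n_frames} frames "
                f"({expected} samples) but {path.name} holds {flat.size} samples"
            )
        stack = flat.reshape(n_frames, h, w)
    else:
        raise ValueError(f"unsupported movie format '{path.suffix}'")
    frames = np.moveaxis(stack, 0, 2)
    return SpeckleSeries(
        frames=frames,
        frame_rate=float(meta["frame_rate"]),
        exposure=float(meta["exposure"]),
        wavelength=float(meta["wavelength"]),
        pixel_pitch=float(meta["pixel_pitch"]),
        bit_depth=int(meta["bit_depth"]),
    )


# ---------------------------------------------------------------------------
# result tables
# ---------------------------------------------------------------------------

SPECTRUM_COLUMNS = [
    "omega_rad_s",
    "G_storage_Pa",
    "G_loss_Pa",
    "G_mag_Pa",
    "alpha",
    "valid",
]


def write_results(spectrum, params, out_dir) -> Tuple[Path, Path]:
    """Persist a viscoelastic spectrum and its parameter table as CSV.

    Writes ``spectrum.csv`` (one row per frequency) and ``parameters.csv``
    (one row per spectroscopic parameter, with explicit spread method).
    Returns the two paths.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if spectrum is None or len(spectrum.omega) == 0:
        raise ValueError("refusing to write an empty spectrum")
    for name in ("omega", "g_storage", "g_loss", "g_mag"):
        if not np.all(np.isfinite(getattr(spectrum, name))):
            raise ValueError(f"spectrum field '{name}' contains non-finite values")

    spec_path = out_dir / "spectrum.csv"
    df = pd.DataFrame(
        {
            "omega_rad_s": spectrum.omega,
            "G_storage_Pa": spectrum.g_storage,
            "G_loss_Pa": spectrum.g_loss,
            "G_mag_Pa": spectrum.g_mag,
            "alpha": spectrum.alpha,
            "valid": spectrum.valid.astype(int),
        }
    )
    # shortest round-trip float repr: read-back equals stored values exactly
    df.to_csv(spec_path, index=False, float_format=lambda v: repr(float(v)))

    par_path = out_dir / "parameters.csv"
    rows = params.to_rows() if params is not None else []
    pdf = pd.DataFrame(
        rows,
        columns=[
            "parameter",
            "regime",
            "value",
            "spread",
            "spread_method",
            "units",
            "fit_lo_rad_s",
            "fit_hi_rad_s",
        ],
    )
    pdf.to_csv(par_path, index=False, float_format="%.17g")
    return spec_path, par_path


def read_spectrum_csv(path):
    """Read back a ``spectrum.csv`` written by :func:`write_results`."""
    from .rheology_core import ViscoSpectrum

    df = pd.read_csv(path, float_precision="round_trip")
    return ViscoSpectrum(
        omega=df["omega_rad_s"].to_numpy(),
        g_storage=df["G_storage_Pa"].to_numpy(),
        g_loss=df["G_loss_Pa"].to_numpy(),
        g_mag=df["G_mag_Pa"].to_numpy(),
        alpha=df["alpha"].to_numpy(),
        valid=df["valid"].to_numpy().astype(bool),
    )


# ---------------------------------------------------------------------------
# hierarchical run store (resumable intermediates)
# ---------------------------------------------------------------------------


class RunStore:
    """Single HDF5 container per run holding g2 / MSD / alpha / spectrum.

    Long correlations are expensive to recompute, so each pipeline stage is
    checkpointed under its own group and can be reloaded independently.
    """

    def __init__(self, path, mode: str = "a"):
        self.path = Path(path)
        self._fh = h5py.File(self.path, mode)

    def close(self) -> None:
        self._fh.close()

    def __enter__(self):
        return self

    def __exit__(self, *exc):
        self.close()

    def _write_group(self, name: str, arrays: dict, attrs: dict | None = None):
        if name in self._fh:
            del self._fh[name]
        grp = self._fh.create_group(name)
        for key, val in arrays.items():
            grp.create_dataset(key, data=np.asarray(val))
        for key, val in (attrs or {}).items():
            grp.attrs[key] = val
        self._fh.flush()

    def has(self, name: str) -> bool:
        return name in self._fh

    def save_g2(self, corr) -> None:
        self._write_group(
            "g2",
            {"lags": corr.lags, "g2": corr.g2, "n_pairs": corr.n_pairs},
            {"normalized": corr.normalized},
        )

    def load_g2(self):
        from .correlogram import CorrelationCurve

        grp = self._fh["g2"]
        return CorrelationCurve(
            lags=grp["lags"][()],
            g2=grp["g2"][()],
            n_pairs=grp["n_pairs"][()],
            normalized=bool(grp.attrs["normalized"]),
        )

    def save_msd(self, msd) -> None:
        self._write_group(
            "msd", {"times": msd.times, "msd": msd.msd, "valid": msd.valid}
        )

    def load_msd(self):
        from .rheology_core import MSDCurve

        grp = self._fh["msd"]
        return MSDCurve(
            times=grp["times"][()], msd=grp["msd"][()], valid=grp["valid"][()].astype(bool)
        )

    def save_spectrum(self, spectrum) -> None:
        self._write_group(
            "spectrum",
            {
                "omega": spectrum.omega,
                "g_storage": spectrum.g_storage,
                "g_loss": spectrum.g_loss,
                "g_mag": spectrum.g_mag,
                "alpha": spectrum.alpha,
                "valid": spectrum.valid,
            },
        )

    def load_spectrum(self):
        from .rheology_core import ViscoSpectrum

        grp = self._fh["spectrum"]
        return ViscoSpectrum(
            omega=grp["omega"][()],
            g_storage=grp["g_storage"][()],
            g_loss=grp["g_loss"][()],
            g_mag=grp["g_mag"][()],
            alpha=grp["alpha"][()],
            valid=grp["valid"][()].astype(bool),
        )


def log_seed(op_name: str, seed) -> None:
    """Every seeded operation reports its seed for reproducibility."""
    logger.info("%s: seed=%s", op_name, seed)
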