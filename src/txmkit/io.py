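"""Image-stack I/O, reference (flat-field) correction, and optical density.

Stacks live either as a series of single-page grayscale TIFFs with a CSV
metadata sidecar (columns ``file,energy_eV,angle_deg,motor_x_um,motor_y_um``)
or as a single self-describing HDF5 container with datasets ``/data`` and
``/energies_eV`` (or ``/angles_deg``), plus ``/motor_xy_um`` and a
``pixel_size_nm`` attribute.

Conventions used throughout the package: arrays are indexed ``(row, col)``
with the origin at the top-left, 0-based.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import h5py
import numpy as np
import pandas as pd
import tifffile

logger = logging.getLogger(__name__)

#: Floor applied to transmission before taking -log, guaranteeing finite OD.
T_FLOOR = 1e-6

#: Reference pixels below this fraction of the reference median are invalid.
REF_FLOOR_FRAC = 1e-6


@dataclass
class ImageFrame:
    """A single 2D transmission (or counts) image with beamline metadata."""

    pixels: np.ndarray
    energy_eV: float = np.nan
    angle_deg: float = np.nan
    motor_x_um: float = np.nan
    motor_y_um: float = np.nan
    pixel_size_nm: float = np.nan
    exposure_s: float | None = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ValueError("ImageFrame.pixels must be 2D")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass
class EnergyStack:
    """Aligned 3D cube (energy, row, col) of optical density spectra."""

    data: np.ndarray
    energies_eV: np.ndarray
    corrected: bool = False
    pixel_size_nm: float = np.nan
    motor_xy_um: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.energies_eV = np.asarray(self.energies_eV, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("EnergyStack.data must be 3D (energy, row, col)")
        if self.data.shape[0] != self.energies_eV.size:
            raise ValueError("energies_eV length must match data.shape[0]")
        if np.any(np.diff(self.energies_eV) <= 0):
            raise ValueError("energies must be strictly increasing")

    @property
    def n_energies(self) -> int:
        return self.data.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.data.shape[1:]


@dataclass
class ProjectionSeries:
    """3D cube (angle, row, col) of projections for tomography."""

    data: np.ndarray
    angles_deg: np.ndarray
    pixel_size_nm: float = np.nan

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.angles_deg = np.asarray(self.angles_deg, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("ProjectionSeries.data must be 3D")
        if self.data.shape[0] != self.angles_deg.size:
            raise ValueError("angles_deg length must match data.shape[0]")
        if self.angles_deg.size > 1:
            if np.any(np.diff(self.angles_deg) <= 0):
                raise ValueError("angles must be strictly increasing")
            if np.ptp(self.angles_deg) > 360.0:
                raise ValueError("angles must lie within one 360 degree span")

    @property
    def n_angles(self) -> int:
        return self.data.shape[0]


# ---------------------------------------------------------------------------
# reading / writing


def _read_tiff_frames(paths: Sequence[str | Path]) -> np.ndarray:
    frames = []
    shape = None
    for i, p in enumerate(paths):
        img = tifffile.imread(str(p))
        if img.ndim != 2:
            raise ValueError(f"frame {p} is not a single-page 2D image")
        if shape is None:
            shape = img.shape
        elif img.shape != shape:
            raise ValueError(
                f"shape mismatch: frame {p} has shape {img.shape}, "
                f"expected {shape}"
            )
        frames.append(img)
    return np.stack(frames).astype(float)


def read_stack(
    source: Sequence[str | Path] | str | Path,
    metadata: pd.DataFrame | str | Path | None = None,
    kind: str = "auto",
) -> EnergyStack | ProjectionSeries:
    """Read an image stack from a TIFF series + CSV sidecar, or from HDF5.

    Parameters
    ----------
    source:
        Either an ordered list of single-page TIFF paths, or one HDF5 path.
    metadata:
        For TIFF series: a CSV path or DataFrame with one row per frame and
        columns ``energy_eV`` (energy stack) or ``angle_deg`` (projection
        series); optional ``motor_x_um, motor_y_um, pixel_size_nm``.
        Ignored for HDF5 input.
    kind:
        ``"energy"``, ``"projection"``, or ``"auto"`` (decide from available
        metadata; energy wins if both are present and non-constant).

    Frames are sorted by energy (energy stacks) or angle (projection series).
    """
    if isinstance(source, (str, Path)):
        return _read_hdf5(Path(source), kind)

    paths = [Path(p) for p in source]
    if metadata is None:
        raise ValueError("a metadata sidecar is required for TIFF series")
    meta = (
        metadata
        if isinstance(metadata, pd.DataFrame)
        else pd.read_csv(metadata)
    )
    if len(meta) != len(paths):
        raise ValueError(
            f"metadata has {len(meta)} rows but {len(paths)} frames given"
        )
    data = _read_tiff_frames(paths)
    pixel_size = float(meta["pixel_size_nm"].iloc[0]) if "pixel_size_nm" in meta else np.nan

    has_energy = "energy_eV" in meta.columns
    has_angle = "angle_deg" in meta.columns
    if kind == "auto":
        if has_energy:
            kind = "energy"
        elif has_angle:
            kind = "projection"
        else:
            raise ValueError("metadata must contain energy_eV or angle_deg")

    if kind == "energy":
        if not has_energy:
            raise ValueError("missing metadata column energy_eV")
        key = meta["energy_eV"].to_numpy(dtype=float)
    else:
        if not has_angle:
            raise ValueError("missing metadata column angle_deg")
        key = meta["angle_deg"].to_numpy(dtype=float)

    order = np.argsort(key, kind="stable")
    data = data[order]
    key = key[order]

    motor = None
    if {"motor_x_um", "motor_y_um"} <= set(meta.columns):
        motor = meta[["motor_x_um", "motor_y_um"]].to_numpy(dtype=float)[order]

    if kind == "energy":
        return EnergyStack(
            data, key, pixel_size_nm=pixel_size, motor_xy_um=motor
        )
    return ProjectionSeries(data, key, pixel_size_nm=pixel_size)


def _read_hdf5(path: Path, kind: str) -> EnergyStack | ProjectionSeries:
    with h5py.File(path, "r") as f:
        data = f["/data"][...]
        pixel_size = float(f.attrs.get("pixel_size_nm", np.nan))
        if kind in ("energy", "auto") and "energies_eV" in f:
            energies = f["/energies_eV"][...]
            motor = f["/motor_xy_um"][...] if "motor_xy_um" in f else None
            return EnergyStack(
                data, energies, pixel_size_nm=pixel_size, motor_xy_um=motor
            )
        if "angles_deg" in f:
            angles = f["/angles_deg"][...]
            return ProjectionSeries(data, angles, pixel_size_nm=pixel_size)
    raise ValueError(f"{path}: no /energies_eV or /angles_deg dataset found")


def write_stack(
    stack: EnergyStack | ProjectionSeries, path: str | Path
) -> None:
    """Write a stack to the HDF5 container layout understood by read_stack."""
    with h5py.File(path, "w") as f:
        f.create_dataset("/data", data=stack.data)
        if isinstance(stack, EnergyStack):
            f.create_dataset("/energies_eV", data=stack.energies_eV)
            if stack.motor_xy_um is not None:
                f.create_dataset("/motor_xy_um", data=stack.motor_xy_um)
        else:
            f.create_dataset("/angles_deg", data=stack.angles_deg)
        f.attrs["pixel_size_nm"] = stack.pixel_size_nm


def write_tiff_series(
    frames: np.ndarray,
    directory: str | Path,
    metadata: pd.DataFrame,
    prefix: str = "frame",
) -> list[Path]:
    """Write frames as single-page TIFFs plus a CSV sidecar; returns paths."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for i, frame in enumerate(frames):
        p = directory / f"{prefix}_{i:04d}.tiff"
        tifffile.imwrite(str(p), np.asarray(frame))
        paths.append(p)
    meta = metadata.copy()
    meta.insert(0, "file", [p.name for p in paths])
    meta.to_csv(directory / f"{prefix}_metadata.csv", index=False)
    return paths


# ---------------------------------------------------------------------------
# reference correction and optical density


def reference_correct(
    sample: np.ndarray, reference: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Divide a sample image by its flat-field reference.

    Returns ``(transmission, valid_mask)`` where ``valid_mask`` is False at
    pixels whose reference value lies at or below the floor
    (``REF_FLOOR_FRAC`` times the reference median).
    """
    sample = np.asarray(sample, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if sample.shape != reference.shape:
        raise ValueError(
            f"sample shape {sample.shape} != reference shape {reference.shape}"
        )
    if np.all(reference <= 0):
        raise ValueError("reference image is entirely non-positive")
    median = np.median(reference[reference > 0])
    floor = REF_FLOOR_FRAC * median
    valid = reference > floor
    safe_ref = np.where(valid, reference, floor)
    return sample / safe_ref, valid


def to_optical_density(
    transmission: np.ndarray, t_floor: float = T_FLOOR
) -> np.ndarray:
    """Convert transmission to optical density, OD = -ln(T).

    Transmission values at or below ``t_floor`` are clipped to ``t_floor`` so
    the result is finite everywhere; the number of clipped pixels is logged.
    """
    t = np.asarray(transmission, dtype=float)
    n_clipped = int(np.sum(t <= t_floor))
    if n_clipped:
        logger.info("to_optical_density: clipped %d pixels at T_floor", n_clipped)
    return -np.log(np.clip(t, t_floor, None))


def correct_stack(
    raw: np.ndarray, references: np.ndarray, energies_eV: np.ndarray, **kw
) -> EnergyStack:
    """Reference-correct raw frames per energy and convert to OD."""
    raw = np.asarray(raw, dtype=float)
    references = np.asarray(references, dtype=float)
    if references.ndim == 2:
        references = np.broadcast_to(references, raw.shape)
    od = np.empty_like(raw)
    for i in range(raw.shape[0]):
        trans, valid = reference_correct(raw[i], references[i])
        if not valid.all():
            warnings.warn(
                f"frame {i}: {int((~valid).sum())} invalid reference pixels"
            )
        od[i] = to_optical_density(trans)
    return EnergyStack(od, energies_eV, corrected=True, **kw)
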