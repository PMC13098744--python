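"""Modality image containers and their on-disk formats.

Containers carry the raw image arrays together with the physical axis
metadata the extractors need (wavelength lists, pixel pitches, detector
capacity).  2-D image stacks are stored as multi-page TIFF, cubes / volumes /
Mueller fields as HDF5 with axis metadata in attributes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import h5py
import numpy as np
import tifffile

from .core import ParameterError

__all__ = [
    "AFStack",
    "HSICube",
    "OCTVolume",
    "MuellerField",
    "StokesMeasurementSet",
    "save_af_stack",
    "load_af_stack",
    "save_hdf5",
    "load_hdf5",
]


@dataclass
class AFStack:
    """Autofluorescence image stack indexed by (excitation, emission cut-on)."""

    images: dict  # (excitation_nm, cuton_nm) -> 2-D array
    dark: np.ndarray | None = None
    flat: np.ndarray | None = None
    detector_capacity: float = 1.0

    def __post_init__(self):
        shapes = {img.shape for img in self.images.values()}
        if len(shapes) > 1:
            raise ParameterError(f"AF images disagree on grid shape: {shapes}")

    @property
    def shape(self):
        return next(iter(self.images.values())).shape


@dataclass
class HSICube:
    """Hyperspectral cube: (rows, cols, bands) with band-center wavelengths."""

    data: np.ndarray
    wavelengths_nm: np.ndarray
    white_reference: np.ndarray | None = None
    detector_capacity: float = 1.0

    def __post_init__(self):
        self.wavelengths_nm = np.asarray(self.wavelengths_nm, dtype=float)
        if self.data.shape[-1] != self.wavelengths_nm.size:
            raise ParameterError("band count does not match wavelength list")
        if np.any(np.diff(self.wavelengths_nm) <= 0):
            raise ParameterError("wavelengths must be strictly increasing")


@dataclass
class OCTVolume:
    """OCT intensity volume: (rows, cols, depth) with per-axis pitches in um."""

    data: np.ndarray
    pitch_um: tuple  # (row, col, z) pixel pitches
    detector_capacity: float = 1.0

    def __post_init__(self):
        if any(p <= 0 for p in self.pitch_um):
            raise ParameterError("pixel pitches must be positive")

    @property
    def z_pitch_mm(self) -> float:
        return self.pitch_um[2] / 1000.0

    def xz_slice(self, row_index: int) -> np.ndarray:
        """Vertical (depth) slice at a fixed row: axes (cols, depth) -> (depth, cols)."""
        return self.data[row_index, :, :].T

    def xy_slice(self, z_index: int) -> np.ndarray:
        """Horizontal (en-face) slice at a fixed depth."""
        return self.data[:, :, z_index]


@dataclass
class MuellerField:
    """Per-pixel 4x4 Mueller matrices at one wavelength: (rows, cols, 4, 4)."""

    matrices: np.ndarray
    wavelength_nm: float
    valid: np.ndarray = None

    def __post_init__(self):
        if self.matrices.shape[-2:] != (4, 4):
            raise ParameterError("Mueller field must be (..., 4, 4)")
        if self.valid is None:
            self.valid = np.isfinite(self.matrices).all(axis=(-2, -1)) & (
                self.matrices[..., 0, 0] > 0
            )


@dataclass
class StokesMeasurementSet:
    """Output Stokes images for a set of input (generator) polarization states.

    ``input_states`` has shape (n_states, 4) with S0 = 1; ``outputs`` has
    shape (rows, cols, n_states, 4).
    """

    input_states: np.ndarray
    outputs: np.ndarray
    wavelength_nm: float

    def __post_init__(self):
        self.input_states = np.asarray(self.input_states, dtype=float)
        if self.input_states.shape[0] < 4:
            raise ParameterError("need at least 4 generator states")
        if np.linalg.matrix_rank(self.input_states) < 4:
            raise ParameterError("generator state matrix must have rank 4")


def save_af_stack(stack: AFStack, path) -> None:
    keys = sorted(stack.images)
    pages = [np.asarray(stack.images[k], dtype=np.float32) for k in keys]
    meta = {
        "keys": [list(map(int, k)) for k in keys],
        "detector_capacity": stack.detector_capacity,
        "has_dark": stack.dark is not None,
        "has_flat": stack.flat is not None,
    }
    if stack.dark is not None:
        pages.append(np.asarray(stack.dark, dtype=np.float32))
    if stack.flat is not None:
        pages.append(np.asarray(stack.flat, dtype=np.float32))
    tifffile.imwrite(path, np.stack(pages), metadata=meta)


def load_af_stack(path) -> AFStack:
    with tifffile.TiffFile(path) as tif:
        pages = tif.asarray()
        meta = tif.shaped_metadata[0]
    keys = [tuple(k) for k in meta["keys"]]
    images = {k: pages[i] for i, k in enumerate(keys)}
    i = len(keys)
    dark = flat = None
    if meta["has_dark"]:
        dark = pages[i]
        i += 1
    if meta["has_flat"]:
        flat = pages[i]
    return AFStack(images, dark=dark, flat=flat, detector_capacity=meta["detector_capacity"])


def save_hdf5(obj, path) -> None:
    """Write an HSICube, OCTVolume, MuellerField or StokesMeasurementSet."""
    with h5py.File(path, "w") as fh:
        if isinstance(obj, HSICube):
            fh.attrs["kind"] = "hsi"
            fh.attrs["detector_capacity"] = obj.detector_capacity
            fh.create_dataset("data", data=obj.data)
            fh.create_dataset("wavelengths_nm", data=obj.wavelengths_nm)
            if obj.white_reference is not None:
                fh.create_dataset("white_reference", data=obj.white_reference)
        elif isinstance(obj, OCTVolume):
            fh.attrs["kind"] = "oct"
            fh.attrs["pitch_um"] = obj.pitch_um
            fh.attrs["detector_capacity"] = obj.detector_capacity
            fh.create_dataset("data", data=obj.data)
        elif isinstance(obj, MuellerField):
            fh.attrs["kind"] = "mueller"
            fh.attrs["wavelength_nm"] = obj.wavelength_nm
            fh.create_dataset("matrices", data=obj.matrices)
            fh.create_dataset("valid", data=obj.valid)
        elif isinstance(obj, StokesMeasurementSet):
            fh.attrs["kind"] = "stokes"
            fh.attrs["wavelength_nm"] = obj.wavelength_nm
            fh.create_dataset("input_states", data=obj.input_states)
            fh.create_dataset("outputs", data=obj.outputs)
        else:
            raise ParameterError(f"cannot serialize {type(obj).__name__}")


def load_hdf5(path):
    with h5py.File(path, "r") as fh:
        kind = fh.attrs["kind"]
        if kind == "hsi":
            white = fh["white_reference"][()] if "white_reference" in fh else None
            return HSICube(
                fh["data"][()],
                fh["wavelengths_nm"][()],
                white_reference=white,
                detector_capacity=float(fh.attrs["detector_capacity"]),
            )
        if kind == "oct":
            return OCTVolume(
                fh["data"][()],
                tuple(fh.attrs["pitch_um"]),
                detector_capacity=float(fh.attrs["detector_capacity"]),
            )
        if kind == "mueller":
            return MuellerField(
                fh["matrices"][()],
                float(fh.attrs["wavelength_nm"]),
                valid=fh["valid"][()].astype(bool),
            )
        if kind == "stokes":
            return StokesMeasurementSet(
                fh["input_states"][()], fh["outputs"][()], float(fh.attrs["wavelength_nm"])
            )
    raise ParameterError(f"unrecognized HDF5 payload kind in {path}")
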