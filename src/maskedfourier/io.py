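"""File formats: volumes (NPY/NPZ/NIfTI), coefficient containers, caches.

Volumes come in as NPY/NPZ arrays or NIfTI images; NIfTI voxel spacing
defines the grid coordinates (0-based, in millimeters).  4D inputs are a
series of 3D snapshots: the time axis is the last one for NIfTI (its
native convention) and the first one for NPY/NPZ (time-major stacking).

Fitted coefficients round-trip through an NPZ container carrying the
complex coefficients, the grid geometry, diagnostics, and a provenance
block with an integrity checksum, so a fit written on one machine can be
reconstructed on another from the file alone.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np

from .errors import InconsistencyError, InvalidGridError
from .fields import FitResult
from .grid import StructuredGrid, build_grid, build_mode_set, grid_from_coords
from .solver import FitDiagnostics, FourierCoefficients

_FORMAT_VERSION = 1


@dataclass
class VolumeData:
    """A loaded volume (or series) plus the grid it lives on."""

    frames: list            # list of ndarray, one per time step
    grid: StructuredGrid
    spacing: Optional[tuple] = None

    @property
    def is_series(self) -> bool:
        return len(self.frames) > 1


def _grid_for_array(
    shape: tuple[int, ...],
    spacing: Optional[tuple] = None,
    bounds=None,
    padding_fraction: float = 0.1,
    half_open: bool = False,
) -> StructuredGrid:
    if bounds is not None:
        return build_grid(shape, bounds, padding_fraction, half_open)
    if spacing is None:
        spacing = (1.0,) * len(shape)
    coords = [np.arange(L) * s for L, s in zip(shape, spacing)]
    return grid_from_coords(coords, padding_fraction, half_open)


def read_volume(
    path,
    bounds=None,
    padding_fraction: float = 0.1,
    half_open: bool = False,
    npz_key: Optional[str] = None,
) -> VolumeData:
    """Load a 1D-4D real volume and derive its grid.

    NPY/NPZ arrays use index coordinates (or explicit ``bounds``); NIfTI
    files use the header voxel spacing.  4D data become a time series of
    3D frames.
    """
    path = Path(path)
    suffixes = "".join(path.suffixes).lower()
    if suffixes.endswith((".nii", ".nii.gz")):
        import nibabel as nib

        img = nib.load(str(path))
        data = np.asarray(img.dataobj, dtype=float)
        zooms = img.header.get_zooms()
        if data.ndim > 4:
            raise InvalidGridError(f"cannot handle {data.ndim}-dimensional NIfTI")
        if data.ndim == 4:
            frames = [np.ascontiguousarray(data[..., t]) for t in range(data.shape[-1])]
            spatial_shape = data.shape[:3]
            spacing = tuple(float(z) for z in zooms[:3])
        else:
            frames = [data]
            spatial_shape = data.shape
            spacing = tuple(float(z) for z in zooms[: data.ndim])
        grid = _grid_for_array(spatial_shape, spacing, bounds, padding_fraction, half_open)
        return VolumeData(frames=frames, grid=grid, spacing=spacing)
    if suffixes.endswith(".npz"):
        with np.load(path) as z:
            key = npz_key or list(z.keys())[0]
            data = np.asarray(z[key], dtype=float)
    elif suffixes.endswith(".npy"):
        data = np.asarray(np.load(path), dtype=float)
    else:
        raise InvalidGridError(f"unknown volume format: {path.name}")
    if data.ndim > 4:
        raise InvalidGridError(f"cannot handle {data.ndim}-dimensional arrays")
    if data.ndim == 4:
        frames = [np.ascontiguousarray(f) for f in data]  # time-major
        spatial_shape = data.shape[1:]
    else:
        frames = [data]
        spatial_shape = data.shape
    grid = _grid_for_array(spatial_shape, None, bounds, padding_fraction, half_open)
    return VolumeData(frames=frames, grid=grid, spacing=None)


def read_mask(path, npz_key: Optional[str] = None) -> np.ndarray:
    """Load a boolean mask volume (nonzero = data present)."""
    vol = read_volume(path, npz_key=npz_key)
    if vol.is_series:
        raise InvalidGridError("mask must be a single volume, not a series")
    return vol.frames[0] != 0


# ---------------------------------------------------------------------------
# coefficient containers
# ---------------------------------------------------------------------------

def _coeff_digest(a: np.ndarray) -> str:
    return hashlib.sha256(np.ascontiguousarray(a).tobytes()).hexdigest()


def write_coefficients(result: FitResult, grid: StructuredGrid, path) -> None:
    """Write a fit to an NPZ container (coefficients + grid + provenance)."""
    a = result.coefficients.a
    modes = result.coefficients.modes
    diag = result.diagnostics
    meta = {
        "format_version": _FORMAT_VERSION,
        "provenance": result.provenance,
        "diagnostics": {
            "retained_rank": diag.retained_rank,
            "iterations": diag.iterations,
            "converged": bool(diag.converged),
            "relative_system_residual": diag.relative_system_residual,
            "absolute_system_residual": diag.absolute_system_residual,
            "residual_objective": diag.residual_objective,
        },
        "checksum": _coeff_digest(a),
    }
    np.savez(
        path,
        a=a,
        harmonics=np.asarray(modes.harmonics),
        grid_shape=np.asarray(grid.shape),
        axis_start=np.asarray([c[0] for c in grid.axis_coords]),
        axis_stop=np.asarray([c[-1] for c in grid.axis_coords]),
        padding_fraction=np.asarray(grid.padding_fraction),
        half_open=np.asarray(grid.half_open),
        meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
    )


def read_coefficients(path) -> tuple[FitResult, StructuredGrid]:
    """Read a coefficient container back into a fit result and its grid."""
    with np.load(path) as z:
        meta = json.loads(bytes(z["meta"]).decode())
        if meta.get("format_version") != _FORMAT_VERSION:
            raise InconsistencyError(
                f"coefficient file format version {meta.get('format_version')} "
                f"!= {_FORMAT_VERSION}"
            )
        a = z["a"]
        if _coeff_digest(a) != meta["checksum"]:
            raise InconsistencyError("coefficient checksum mismatch: file corrupted")
        harmonics = tuple(int(N) for N in z["harmonics"])
        shape = tuple(int(L) for L in z["grid_shape"])
        start = z["axis_start"]
        stop = z["axis_stop"]
        pad = float(z["padding_fraction"])
        half_open = bool(z["half_open"])
    if half_open:
        # stored stop is the last half-open coordinate; recover the bound
        bounds = []
        for L, lo, hi in zip(shape, start, stop):
            step = (hi - lo) / (L - 1) if L > 1 else 1.0
            bounds.append((lo, hi + step))
    else:
        bounds = list(zip(start, stop))
    grid = build_grid(shape, bounds, pad, half_open)
    modes = build_mode_set(harmonics, grid)
    coeffs = FourierCoefficients(a=a, modes=modes)
    d = meta["diagnostics"]
    diag = FitDiagnostics(
        retained_rank=d["retained_rank"],
        iterations=d["iterations"],
        converged=d["converged"],
        relative_system_residual=d["relative_system_residual"],
        absolute_system_residual=d["absolute_system_residual"],
        residual_objective=d["residual_objective"],
    )
    return FitResult(coefficients=coeffs, diagnostics=diag,
                     provenance=meta["provenance"]), grid
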