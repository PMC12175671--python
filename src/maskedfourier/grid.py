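"""Grids, truncated mode lattices, and precomputed exponential tables.

A fit lives on a regular rectangular grid with 1--3 spatial axes.  The
Fourier basis is periodic with a per-axis period ``l_i`` that is the data
extent enlarged by a padding fraction; padding loosens the periodic
boundary so the basis can extrapolate beyond the data without being forced
back to its starting value.  Only the period enters the mathematics (through
the fundamental wavenumber ``k_i0 = 2*pi/l_i``): no ghost points are added,
because masked-out padding points would contribute nothing to any sum.

The truncated basis keeps integer mode multi-indices ``n`` with
``-N_i <= n_i <= N_i`` ("full lattice", ``M = prod(2N_i+1)`` modes).  The
normal equations additionally need kernel sums at index sums and
differences, which live on the "extended lattice" ``-2N_i <= n_i <= 2N_i``.
All complex exponentials the method ever needs are separable products of
per-axis factors ``exp(j*n*k_i0*coord)``; these are evaluated once into an
:class:`ExponentialTable` and looked up afterwards.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import InvalidGridError
from .instrument import counters

_SPACING_RTOL = 1e-9


# ---------------------------------------------------------------------------
# structured grid
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StructuredGrid:
    """A regular rectangular grid with per-axis periods for the Fourier basis.

    Attributes
    ----------
    shape
        Number of points per axis, ``(L_x, ..)``.
    axis_coords
        Per-axis 1D coordinate arrays, uniformly spaced.
    padding_fraction
        Fractional enlargement of the period beyond the data extent.
    half_open
        If True the coordinates subdivide ``[min, max)`` in ``L`` steps
        (DFT convention); if False they subdivide ``[min, max]`` inclusively.
    """

    shape: tuple[int, ...]
    axis_coords: tuple[np.ndarray, ...]
    padding_fraction: float
    half_open: bool
    data_extent: tuple[float, ...]
    period: tuple[float, ...]
    fundamental_wavenumbers: tuple[float, ...]

    @property
    def ndim(self) -> int:
        return len(self.shape)

    @property
    def npoints(self) -> int:
        return int(np.prod(self.shape))

    def __post_init__(self):
        if not 1 <= self.ndim <= 3:
            raise InvalidGridError(f"dimensionality must be 1-3, got {self.ndim}")
        for L, c in zip(self.shape, self.axis_coords):
            if L < 1:
                raise InvalidGridError("axis point count must be >= 1")
            if len(c) != L:
                raise InvalidGridError("coordinate length does not match shape")
            if L > 2:
                d = np.diff(c)
                if not np.allclose(d, d[0], rtol=_SPACING_RTOL, atol=0.0):
                    raise InvalidGridError("coordinates are not uniformly spaced")
        for ext, per in zip(self.data_extent, self.period):
            if per < ext:
                raise InvalidGridError("period must be >= data extent")


def build_grid(
    shape: int | Sequence[int],
    bounds: Sequence[float] | Sequence[Sequence[float]],
    padding_fraction: float = 0.1,
    half_open: bool = False,
) -> StructuredGrid:
    """Construct a uniform grid over rectangular bounds.

    Parameters
    ----------
    shape
        Points per axis; a scalar for 1D.
    bounds
        ``(min, max)`` per axis (a single pair for 1D).
    padding_fraction
        Period enlargement factor; the default 10 % is a practical choice
        that keeps extrapolation from being pinned by periodicity.
    half_open
        Use the half-open DFT coordinate convention instead of the
        endpoint-inclusive one.
    """
    if np.isscalar(shape):
        shape = (int(shape),)
    shape = tuple(int(L) for L in shape)
    bounds = np.atleast_2d(np.asarray(bounds, dtype=float))
    if bounds.shape != (len(shape), 2):
        raise InvalidGridError(
            f"bounds shape {bounds.shape} does not match {len(shape)} axes"
        )
    if padding_fraction < 0:
        raise InvalidGridError("padding_fraction must be >= 0")

    coords, extents, periods, k0 = [], [], [], []
    for L, (lo, hi) in zip(shape, bounds):
        if L < 1:
            raise InvalidGridError("axis point count must be >= 1")
        if not hi > lo:
            raise InvalidGridError(f"inverted bounds ({lo}, {hi})")
        extent = hi - lo
        if half_open:
            c = lo + np.arange(L) * (extent / L)
        else:
            c = np.linspace(lo, hi, L)
        per = (1.0 + padding_fraction) * extent
        coords.append(c)
        extents.append(extent)
        periods.append(per)
        k0.append(2.0 * np.pi / per)
    return StructuredGrid(
        shape=shape,
        axis_coords=tuple(coords),
        padding_fraction=float(padding_fraction),
        half_open=bool(half_open),
        data_extent=tuple(extents),
        period=tuple(periods),
        fundamental_wavenumbers=tuple(k0),
    )


def grid_from_coords(
    axis_coords: Sequence[np.ndarray],
    padding_fraction: float = 0.1,
    half_open: bool = False,
) -> StructuredGrid:
    """Build a grid from explicit uniformly spaced axis coordinates.

    Used by the volume readers, where voxel spacing defines the coordinates.
    The data extent is the coordinate span (inclusive convention) or span
    plus one spacing (half-open convention).
    """
    coords = tuple(np.asarray(c, dtype=float) for c in axis_coords)
    shape = tuple(len(c) for c in coords)
    extents, periods, k0 = [], [], []
    for c in coords:
        if len(c) > 1:
            step = c[1] - c[0]
            span = c[-1] - c[0]
        else:
            step = 1.0
            span = 1.0
        extent = span + step if half_open else span
        if extent <= 0:
            raise InvalidGridError("degenerate coordinate axis")
        per = (1.0 + padding_fraction) * extent
        extents.append(extent)
        periods.append(per)
        k0.append(2.0 * np.pi / per)
    return StructuredGrid(
        shape=shape,
        axis_coords=coords,
        padding_fraction=float(padding_fraction),
        half_open=bool(half_open),
        data_extent=tuple(extents),
        period=tuple(periods),
        fundamental_wavenumbers=tuple(k0),
    )


# ---------------------------------------------------------------------------
# mode lattices
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ModeSet:
    """Truncated mode lattice for a given per-axis harmonic count.

    ``full_lattice`` is an ``(M, ndim)`` integer array listing every mode
    multi-index with ``-N_i <= n_i <= N_i``, ordered lexicographically with
    the x-component varying fastest.  The ordering is negation-symmetric:
    entry ``M-1-p`` is the elementwise negation of entry ``p``, and the zero
    mode sits exactly in the middle.  That symmetry is what lets the real
    system be reduced to half size.
    """

    harmonics: tuple[int, ...]
    full_lattice: np.ndarray          # (M, ndim) int
    extended_shape: tuple[int, ...]   # (4N_i+1) per axis

    @property
    def ndim(self) -> int:
        return len(self.harmonics)

    @property
    def n_modes(self) -> int:
        """M = prod(2N_i + 1); always odd."""
        return self.full_lattice.shape[0]

    @property
    def zero_index(self) -> int:
        """Position of the all-zero mode: (M-1)/2."""
        return (self.n_modes - 1) // 2

    @property
    def full_shape(self) -> tuple[int, ...]:
        return tuple(2 * N + 1 for N in self.harmonics)

    @property
    def n_extended(self) -> int:
        return int(np.prod(self.extended_shape))

    def wavevectors(self, grid: StructuredGrid) -> np.ndarray:
        """Physical wavevectors ``k_n = n_i * k_i0`` for every full-lattice mode."""
        k0 = np.asarray(grid.fundamental_wavenumbers)
        return self.full_lattice * k0


def build_mode_set(harmonics: int | Sequence[int], grid: StructuredGrid) -> ModeSet:
    """Build the full mode lattice for ``-N_i <= n_i <= N_i`` on ``grid``.

    The lattice is ordered with the innermost (x) index fastest, so that
    entry ``p`` and entry ``M-1-p`` are negations of each other.
    """
    if np.isscalar(harmonics):
        harmonics = (int(harmonics),) * grid.ndim
    harmonics = tuple(int(N) for N in harmonics)
    if len(harmonics) != grid.ndim:
        raise InvalidGridError("harmonics dimensionality does not match grid")
    if any(N < 0 for N in harmonics):
        raise InvalidGridError("harmonics must be >= 0")

    # meshgrid in reversed axis order => n_x varies fastest when raveled
    axes_rev = [np.arange(-N, N + 1) for N in harmonics[::-1]]
    mesh = np.meshgrid(*axes_rev, indexing="ij")
    lattice = np.stack([m.ravel() for m in mesh[::-1]], axis=1)
    return ModeSet(
        harmonics=harmonics,
        full_lattice=lattice,
        extended_shape=tuple(4 * N + 1 for N in harmonics),
    )


# ---------------------------------------------------------------------------
# exponential tables
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ExponentialTable:
    """Per-axis tables of ``exp(j * n * k_i0 * coord_i[m])``.

    ``tables[i]`` has shape ``(4N_i + 1, L_i)`` with row index ``n + 2N_i``
    covering the extended per-axis mode range.  Every later stage builds its
    kernels as outer products of rows of these tables, so the costly
    transcendental evaluations happen exactly once, here:
    ``sum_i (4N_i + 1) * L_i`` of them.
    """

    harmonics: tuple[int, ...]
    tables: tuple[np.ndarray, ...]

    def axis_rows(self, axis: int, n_lo: int, n_hi: int) -> np.ndarray:
        """Rows for modes ``n_lo..n_hi`` (inclusive) along ``axis``."""
        off = 2 * self.harmonics[axis]
        return self.tables[axis][n_lo + off : n_hi + off + 1]

    def full_range(self, axis: int) -> np.ndarray:
        """Rows for the full per-axis range ``-N..N``."""
        N = self.harmonics[axis]
        return self.axis_rows(axis, -N, N)

    def extended_range(self, axis: int) -> np.ndarray:
        """Rows for the extended per-axis range ``-2N..2N``."""
        return self.tables[axis]


def precompute_exponentials(grid: StructuredGrid, modes: ModeSet) -> ExponentialTable:
    """Evaluate all per-axis exponential factors once.

    Exactly ``sum_i (4N_i + 1) * L_i`` complex exponentials are evaluated;
    everything downstream is table lookups and linear algebra.
    """
    if modes.ndim != grid.ndim:
        raise InvalidGridError("mode set and grid dimensionality differ")
    tables = []
    for N, k0, c in zip(modes.harmonics, grid.fundamental_wavenumbers, grid.axis_coords):
        n = np.arange(-2 * N, 2 * N + 1)
        tab = np.exp(1j * np.outer(n * k0, c))
        counters.exponential_evaluations += tab.size
        tables.append(tab)
    return ExponentialTable(harmonics=modes.harmonics, tables=tuple(tables))


def table_at_coords(
    grid: StructuredGrid, modes: ModeSet, coords: Sequence[np.ndarray]
) -> ExponentialTable:
    """Exponential table at arbitrary (off-grid) per-axis coordinates.

    Supports off-grid evaluation of a fitted basis; the padded period still
    applies, so evaluation beyond one period wraps periodically.
    """
    tables = []
    for N, k0, c in zip(
        modes.harmonics, grid.fundamental_wavenumbers, coords
    ):
        c = np.asarray(c, dtype=float)
        n = np.arange(-2 * N, 2 * N + 1)
        tab = np.exp(1j * np.outer(n * k0, c))
        counters.exponential_evaluations += tab.size
        tables.append(tab)
    return ExponentialTable(harmonics=modes.harmonics, tables=tuple(tables))
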