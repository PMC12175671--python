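"""Structure factors, data spectra, and normal-equation assembly.

The least-squares conditions for a truncated real Fourier fit on masked
grid data form a linear system whose matrix entries are *structure factors*

    S_i = sum_r M(r) exp(j k_i . r)

summed over unmasked points only.  Because the kernel is separable, S is
computed by a chain of single-axis contractions (innermost axis first),
which reduces the naive ``points x modes`` complexity to

    L_x*L_y*(4N_z+1) + L_x*(4N_y+1)*(4N_z+1) + (4N_x+1)*(4N_y+1)*(4N_z+1)

scalar products.  The right-hand-side spectrum of the masked data uses the
same scheme on the full (non-extended) lattice.  The normal equations in
real unknowns ``(b_n, c_n)`` have the block form

    b-row m:  [ Re{S_{m+n} + S_{m-n}},  -Im{S_{m+n} - S_{m-n}} ]
    c-row m:  [ Im{S_{m+n} + S_{m-n}},   Re{S_{m+n} - S_{m-n}} ]

with right-hand side ``(Re, Im)`` of the data spectrum.  Conjugate
symmetry of the coefficients makes half of the unknowns redundant, so the
reduced system keeps only the (b, c) pairs of the first half of the mode
lattice plus the zero mode's b row; the zero mode's c row is identically
zero and is dropped.  The reduced system is assembled directly from S --
the full matrix is only materialized on demand for cross-checks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .errors import EmptyMaskError, InconsistencyError, InvalidGridError
from .grid import ExponentialTable, ModeSet, StructuredGrid
from .instrument import counters

_SYMMETRY_RTOL = 1e-10


# ---------------------------------------------------------------------------
# masked fields
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MaskedField:
    """Real values on a grid together with a boolean data-present mask."""

    values: np.ndarray
    mask: np.ndarray

    def __post_init__(self):
        if self.values.shape != self.mask.shape:
            raise InvalidGridError("values and mask shapes differ")

    @property
    def n_unmasked(self) -> int:
        return int(np.count_nonzero(self.mask))


# ---------------------------------------------------------------------------
# separable axis contractions
# ---------------------------------------------------------------------------

def _as3d(arr: np.ndarray) -> np.ndarray:
    """Promote to 3 axes (x, y, z) with trailing singletons."""
    return arr.reshape(arr.shape + (1,) * (3 - arr.ndim))


def _axis_rows(
    table: ExponentialTable, axis: int, n_lo: int, n_hi: int
) -> np.ndarray:
    """Table rows for one axis, or the trivial [1] row beyond the grid's ndim."""
    if axis >= len(table.harmonics):
        return np.ones((1, 1), dtype=complex)
    return table.axis_rows(axis, n_lo, n_hi)


def _alias_fold(
    rows: np.ndarray, ns: np.ndarray, L: int, active: bool
) -> tuple[np.ndarray, np.ndarray, Optional[np.ndarray]]:
    """Collapse aliased per-axis modes ``n = n' (mod L)`` to unique residues.

    On a half-open unpadded grid the per-axis kernel satisfies
    ``exp(j n k0 x_m) = exp(j (n+L) k0 x_m)``, so when the extended mode
    range exceeds the axis length the duplicate contractions are skipped
    and their results copied.  Returns possibly reduced rows, the modes
    they correspond to, and a gather index to expand back (None if no
    folding happened).
    """
    if not active or len(ns) <= L:
        return rows, ns, None
    residues = np.mod(ns, L)
    uniq, first, inverse = np.unique(residues, return_index=True, return_inverse=True)
    if len(uniq) == len(ns):
        return rows, ns, None
    return rows[first], ns[first], inverse


def _contract(
    arr: np.ndarray,
    table: ExponentialTable,
    grid: StructuredGrid,
    extended: bool,
    count_attr: str,
) -> np.ndarray:
    """Chain of single-axis contractions, innermost (z) axis first.

    Input has spatial axes (x, y, z); output has per-axis mode axes in
    (n_z, n_y, n_x) order, so raveling matches the lattice ordering
    (x fastest).  Missing axes are carried as singletons with N = 0.
    """
    arr = _as3d(np.asarray(arr, dtype=float)).astype(complex)
    alias_ok = grid.half_open and grid.padding_fraction == 0.0
    for axis in (2, 1, 0):
        if axis < len(table.harmonics):
            N = table.harmonics[axis]
            lim = 2 * N if extended else N
        else:
            lim = 0
        ns = np.arange(-lim, lim + 1)
        rows = _axis_rows(table, axis, -lim, lim)
        L = grid.shape[axis] if axis < grid.ndim else 1
        rows, ns, gather = _alias_fold(rows, ns, L, alias_ok)
        # remove spatial axis `axis`, append its mode axis last
        arr = np.tensordot(arr, rows, axes=([axis], [1]))
        products = arr.size
        setattr(counters, count_attr, getattr(counters, count_attr) + products)
        counters.contraction_log.append((count_attr, axis, arr.shape))
        if gather is not None:
            arr = arr[..., gather]
    return arr


# ---------------------------------------------------------------------------
# structure factors
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StructureFactors:
    """Mask kernel sums over the extended mode lattice.

    ``values`` has axes ``(n_z, n_y, n_x)`` (mode index offset by ``2N_i``),
    so that raveling follows the lattice ordering with x fastest.  Satisfies
    ``S_{-i} = conj(S_i)``; ``S_0`` equals the number of unmasked points.
    """

    values: np.ndarray
    harmonics: tuple[int, ...]

    @property
    def s0(self) -> float:
        center = tuple((s - 1) // 2 for s in self.values.shape)
        return float(self.values[center].real)

    def lookup(self, n: tuple[int, ...]) -> complex:
        """Value at mode multi-index ``n`` given in (x, y, z) axis order."""
        n = tuple(n) + (0,) * (len(self.values.shape) - len(n))
        idx = tuple(
            ni + 2 * (self.harmonics[a] if a < len(self.harmonics) else 0)
            for a, ni in enumerate(n)
        )[::-1]
        return complex(self.values[idx])


def compute_structure_factors(
    mask: np.ndarray, table: ExponentialTable, grid: StructuredGrid
) -> StructureFactors:
    """Mask spectrum ``S_i = sum_r M(r) exp(j k_i . r)`` over the extended lattice."""
    mask = np.asarray(mask)
    if mask.shape != grid.shape:
        raise InvalidGridError("mask shape does not match grid")
    if not mask.any():
        raise EmptyMaskError("mask excludes every grid point")
    S = _contract(mask.astype(float), table, grid, extended=True,
                  count_attr="mask_contraction_products")
    # Hermitian symmetry: reversing every mode axis must conjugate S.
    flipped = np.conj(S[::-1, ::-1, ::-1])
    scale = np.abs(S).max()
    if scale > 0 and np.abs(S - flipped).max() > _SYMMETRY_RTOL * scale * 10:
        raise InconsistencyError("structure factors violate Hermitian symmetry")
    return StructureFactors(values=S, harmonics=table.harmonics)


def compute_rhs_spectrum(
    field: MaskedField, table: ExponentialTable, grid: StructuredGrid
) -> np.ndarray:
    """Masked-data spectrum ``sum_r f(r) M(r) exp(j k_m . r)`` on the full lattice.

    Returned flattened in lattice order (length M).
    """
    if not field.mask.any():
        raise EmptyMaskError("mask excludes every grid point")
    masked = np.where(field.mask, field.values, 0.0)
    F = _contract(masked, table, grid, extended=False,
                  count_attr="data_contraction_products")
    return F.ravel()


# ---------------------------------------------------------------------------
# linear systems
# ---------------------------------------------------------------------------

@dataclass
class LinearSystem:
    """Normal equations in real unknowns; full (A, B) and/or reduced (AA, BB).

    Row/column pair ``(2p, 2p+1)`` of the full system corresponds to mode
    ``p``'s ``(b, c)`` unknowns in lattice order.  The reduced system keeps
    the pairs of the first ``(M-1)/2`` modes followed by the zero mode's b
    row, matching the expansion rule in the solver.
    """

    modes: ModeSet
    structure: StructureFactors
    spectrum: np.ndarray
    A: Optional[np.ndarray] = None
    B: Optional[np.ndarray] = None
    AA: Optional[np.ndarray] = None
    BB: Optional[np.ndarray] = None

    @property
    def full_dim(self) -> int:
        return 2 * self.modes.n_modes

    @property
    def reduced_dim(self) -> int:
        return self.modes.n_modes


def _pair_sums(
    S: StructureFactors,
    modes: ModeSet,
    row_modes: np.ndarray,
    col_modes: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """S_{m+n} and S_{m-n} for all row/column mode combinations."""
    Sarr = S.values
    d = row_modes.shape[1]
    # spatial axis a maps to Sarr axis (2 - a) after 3-axis promotion
    strides = [0, 0, 0]
    acc = 1
    for arr_axis in (2, 1, 0):
        strides[arr_axis] = acc
        acc *= Sarr.shape[arr_axis]
    flat = Sarr.ravel()
    shape = (len(row_modes), len(col_modes))
    idx_p = np.zeros(shape, dtype=np.int64)
    idx_m = np.zeros(shape, dtype=np.int64)
    for a in range(3):
        N = modes.harmonics[a] if a < d else 0
        rm = row_modes[:, a] if a < d else np.zeros(len(row_modes), dtype=int)
        cm = col_modes[:, a] if a < d else np.zeros(len(col_modes), dtype=int)
        stride = strides[2 - a]
        idx_p += (rm[:, None] + cm[None, :] + 2 * N) * stride
        idx_m += (rm[:, None] - cm[None, :] + 2 * N) * stride
    return flat[idx_p], flat[idx_m]


def assemble_full_system(
    S: StructureFactors, spectrum: np.ndarray, modes: ModeSet
) -> LinearSystem:
    """Materialize the full 2M x 2M real system (used for cross-checks)."""
    lat = modes.full_lattice
    P, Q = _pair_sums(S, modes, lat, lat)
    M = modes.n_modes
    A = np.empty((2 * M, 2 * M))
    A[0::2, 0::2] = (P + Q).real
    A[0::2, 1::2] = -(P - Q).imag
    A[1::2, 0::2] = (P + Q).imag
    A[1::2, 1::2] = (P - Q).real
    B = np.empty(2 * M)
    B[0::2] = spectrum.real
    B[1::2] = spectrum.imag
    return LinearSystem(modes=modes, structure=S, spectrum=spectrum, A=A, B=B)


def assemble_reduced_system(
    S: StructureFactors, spectrum: np.ndarray, modes: ModeSet
) -> LinearSystem:
    """Assemble the half-size system directly from S, without forming A.

    Rows/columns: interleaved (b, c) for modes ``0 .. (M-1)/2 - 1`` in
    lattice order, then the zero mode's b row.  Redundant unknowns are
    folded by the conjugate symmetry of the coefficients, which is exactly
    the halving the solution-expansion rule undoes.
    """
    M = modes.n_modes
    h = (M - 1) // 2
    sel = modes.full_lattice[: h + 1]       # first half + zero mode
    P, Q = _pair_sums(S, modes, sel, sel)
    AA = np.empty((M, M))
    AA[0:2 * h:2, 0:2 * h:2] = (P + Q).real[:h, :h]
    AA[0:2 * h:2, 1:2 * h:2] = -(P - Q).imag[:h, :h]
    AA[1:2 * h:2, 0:2 * h:2] = (P + Q).imag[:h, :h]
    AA[1:2 * h:2, 1:2 * h:2] = (P - Q).real[:h, :h]
    AA[2 * h, 0:2 * h:2] = (P + Q).real[h, :h]
    AA[2 * h, 1:2 * h:2] = -(P - Q).imag[h, :h]
    AA[0:2 * h:2, 2 * h] = (P + Q).real[:h, h]
    AA[1:2 * h:2, 2 * h] = (P + Q).imag[:h, h]
    AA[2 * h, 2 * h] = (P + Q).real[h, h]
    BB = reduce_rhs(spectrum, modes)
    return LinearSystem(modes=modes, structure=S, spectrum=spectrum, AA=AA, BB=BB)


def reduce_rhs(spectrum: np.ndarray, modes: ModeSet) -> np.ndarray:
    """Reduced right-hand side: interleaved (Re, Im) of the first-half
    spectrum, then the real part at the zero mode."""
    M = modes.n_modes
    h = (M - 1) // 2
    BB = np.empty(M)
    BB[0:2 * h:2] = spectrum.real[:h]
    BB[1:2 * h:2] = spectrum.imag[:h]
    BB[2 * h] = spectrum.real[h]
    return BB


def reduce_system(system: LinearSystem, modes: ModeSet) -> LinearSystem:
    """Populate the reduced (AA, BB) half of an assembled system.

    Equivalent to selecting the retained rows/columns of the full matrix,
    but built directly from the structure factors so the full matrix never
    needs to exist.
    """
    red = assemble_reduced_system(system.structure, system.spectrum, modes)
    system.AA = red.AA
    system.BB = red.BB
    return system


def reduced_row_indices(modes: ModeSet) -> np.ndarray:
    """Indices into the full system's rows/columns kept by the reduction."""
    h = (modes.n_modes - 1) // 2
    idx = np.empty(modes.n_modes, dtype=int)
    idx[0:2 * h:2] = 2 * np.arange(h)
    idx[1:2 * h:2] = 2 * np.arange(h) + 1
    idx[2 * h] = 2 * h
    return idx
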