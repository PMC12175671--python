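"""Field reconstruction, the end-to-end fit, and factorization reuse.

The fitted field is

    fhat(r) = 2 Re{ sum_n a_n exp(j k_n . r) }

evaluated by per-axis contractions (the mirror image of the assembly
scheme), on the grid or on arbitrary coordinates within the padded period.
``fit_masked_field`` wires the whole pipeline together; ``fit_time_series``
exploits that the structure factors, the reduced matrix, and its SVD depend
only on the mask geometry, so a series of snapshots sharing one mask pays
for the expensive factorization exactly once.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .assembly import (
    MaskedField,
    StructureFactors,
    assemble_reduced_system,
    compute_rhs_spectrum,
    compute_structure_factors,
    reduce_rhs,
)
from .errors import CacheInvalidationError, EmptyMaskError, InvalidGridError
from .grid import (
    ExponentialTable,
    ModeSet,
    StructuredGrid,
    precompute_exponentials,
    table_at_coords,
)
from .solver import (
    FitDiagnostics,
    FourierCoefficients,
    RegularizerConfig,
    SVDFactorization,
    coefficients_from_solution,
    expand_solution,
    solve_direct,
    solve_regularized,
    svd_factorize,
)


def mask_checksum(mask: np.ndarray) -> str:
    """Stable digest of a boolean mask (shape-sensitive)."""
    h = hashlib.sha256()
    h.update(str(mask.shape).encode())
    h.update(np.ascontiguousarray(mask, dtype=np.uint8).tobytes())
    return h.hexdigest()


# ---------------------------------------------------------------------------
# reconstruction
# ---------------------------------------------------------------------------

def evaluate_field(
    coeffs: FourierCoefficients,
    grid: StructuredGrid,
    table: Optional[ExponentialTable] = None,
    coords: Optional[Sequence[np.ndarray]] = None,
) -> np.ndarray:
    """Reconstruct the real field from coefficients.

    Parameters
    ----------
    coeffs
        Conjugate-symmetric coefficients on the full lattice.
    grid
        Grid defining the fundamental wavenumbers.
    table
        Optional precomputed exponential table to reuse.
    coords
        Optional per-axis coordinate arrays for off-grid evaluation (the
        result is on their tensor-product grid).  Beyond one padded period
        the basis repeats, so far extrapolation wraps periodically.
    """
    modes = coeffs.modes
    if coords is not None:
        coords = [np.atleast_1d(np.asarray(c, dtype=float)) for c in coords]
        if len(coords) != grid.ndim:
            raise InvalidGridError("coords dimensionality does not match grid")
        table = table_at_coords(grid, modes, coords)
        out_shape = tuple(len(c) for c in coords)
    else:
        if table is None:
            table = precompute_exponentials(grid, modes)
        out_shape = grid.shape

    # mirror of the assembly contraction: expand one axis at a time,
    # x first, starting from coefficient axes (n_z, n_y, n_x)
    d = grid.ndim
    arr = coeffs.as_lattice_array()
    arr = np.tensordot(arr, table.full_range(0), axes=([2], [0]))  # (nz, ny, Lx)
    if d >= 2:
        arr = np.tensordot(arr, table.full_range(1), axes=([1], [0]))  # (nz, Lx, Ly)
        if d == 3:
            arr = np.tensordot(arr, table.full_range(2), axes=([0], [0]))  # (Lx, Ly, Lz)
        else:
            arr = arr[0]  # (Lx, Ly)
    else:
        arr = arr[0, 0]  # (Lx,)
    out = 2.0 * arr.real
    return out.reshape(out_shape)


# ---------------------------------------------------------------------------
# fit results and factorization cache
# ---------------------------------------------------------------------------

@dataclass
class FitResult:
    """Coefficients plus solver diagnostics and reproducibility provenance."""

    coefficients: FourierCoefficients
    diagnostics: FitDiagnostics
    provenance: dict


@dataclass
class CacheEntry:
    """Everything that depends only on (mask, grid, modes): reusable.

    Once factorized, ``AA`` is released (set to None): the factorization
    supersedes it, and dropping the matrix before the eigendecomposition
    halves the peak memory of large fits.
    """

    table: ExponentialTable
    structure: StructureFactors
    AA: Optional[np.ndarray]
    factorization: Optional[SVDFactorization] = None


class FactorizationCache:
    """Reuse of structure factors, reduced matrices, and SVDs.

    Keyed by mask checksum, grid geometry, mode set, and solver method, so
    a hit guarantees a bitwise-identical reduced matrix.
    """

    def __init__(self):
        self._store: dict = {}

    @staticmethod
    def _key(mask_digest, grid: StructuredGrid, modes: ModeSet) -> tuple:
        gkey = (
            grid.shape,
            tuple(float(c[0]) for c in grid.axis_coords),
            tuple(float(c[-1]) for c in grid.axis_coords),
            grid.padding_fraction,
            grid.half_open,
        )
        return (mask_digest, gkey, modes.harmonics)

    def get_or_build(
        self, mask: np.ndarray, grid: StructuredGrid, modes: ModeSet
    ) -> CacheEntry:
        key = self._key(mask_checksum(mask), grid, modes)
        entry = self._store.get(key)
        if entry is None:
            table = precompute_exponentials(grid, modes)
            S = compute_structure_factors(mask, table, grid)
            spectrum0 = np.zeros(modes.n_modes, dtype=complex)
            system = assemble_reduced_system(S, spectrum0, modes)
            entry = CacheEntry(table=table, structure=S, AA=system.AA)
            self._store[key] = entry
        return entry

    def factorization_for(self, entry: CacheEntry) -> SVDFactorization:
        if entry.factorization is None:

            def _release():
                entry.AA = None

            entry.factorization = svd_factorize(entry.AA, release=_release)
        return entry.factorization


# ---------------------------------------------------------------------------
# end-to-end fitting
# ---------------------------------------------------------------------------

def _as_masked_field(field, mask=None) -> MaskedField:
    if isinstance(field, MaskedField):
        return field
    return MaskedField(values=np.asarray(field, dtype=float),
                       mask=np.asarray(mask, dtype=bool))


def fit_masked_field(
    field: MaskedField,
    grid: StructuredGrid,
    modes: ModeSet,
    config: RegularizerConfig = RegularizerConfig(),
    cache: Optional[FactorizationCache] = None,
    method: str = "svd",
    compute_objective: bool = True,
) -> FitResult:
    """Fit the truncated Fourier basis to masked data.

    Pipeline: exponential tables -> structure factors -> data spectrum ->
    reduced system -> (regularized) solve -> expansion -> coefficients.

    Parameters
    ----------
    method
        ``"svd"`` (default) for the adaptive truncated-SVD solve, or
        ``"direct"`` for a plain minimal-norm least-squares solve.
    """
    if not field.mask.any():
        raise EmptyMaskError("mask excludes every grid point")
    if not np.all(np.isfinite(field.values[field.mask])):
        raise FloatingPointError("non-finite data under the mask")
    if field.values.shape != grid.shape:
        raise InvalidGridError("field shape does not match grid")
    if field.n_unmasked < modes.n_modes:
        warnings.warn(
            f"only {field.n_unmasked} data points for {modes.n_modes} modes: "
            "the fit is underdetermined",
            stacklevel=2,
        )

    own_cache = cache if cache is not None else FactorizationCache()
    entry = own_cache.get_or_build(field.mask, grid, modes)
    spectrum = compute_rhs_spectrum(field, entry.table, grid)
    BB = reduce_rhs(spectrum, modes)

    if method == "svd":
        fact = own_cache.factorization_for(entry)
        xx, diag = solve_regularized(entry.AA, BB, config, factorization=fact)
    elif method == "direct":
        if entry.AA is None:
            # the matrix was superseded by its factorization on a previous
            # svd-solve of the same cache entry; the minimal-norm solution
            # is the full-rank truncated solve through the factors
            fact = entry.factorization
            cfg = RegularizerConfig(initial_sv_threshold=0.0,
                                    residual_criterion=np.inf)
            xx, diag = solve_regularized(None, BB, cfg, factorization=fact)
            diag.converged = True
        else:
            xx = solve_direct(entry.AA, BB)
            res = np.abs(entry.AA @ xx - BB).max()
            scale = np.abs(BB).max() or 1.0
            diag = FitDiagnostics(
                retained_rank=min(entry.AA.shape),
                iterations=1,
                converged=True,
                relative_system_residual=float(res / scale),
                absolute_system_residual=float(res),
            )
    else:
        raise ValueError(f"unknown method {method!r}")

    x = expand_solution(xx)
    coeffs = coefficients_from_solution(x, modes)

    if compute_objective:
        recon = evaluate_field(coeffs, grid, table=entry.table)
        resid = field.values[field.mask] - recon[field.mask]
        diag.residual_objective = float(np.sum(resid**2))

    provenance = {
        "harmonics": modes.harmonics,
        "padding_fraction": grid.padding_fraction,
        "half_open": grid.half_open,
        "method": method,
        "solver": {
            "initial_sv_threshold": config.initial_sv_threshold,
            "residual_criterion": config.residual_criterion,
            "rank_growth_factor": config.rank_growth_factor,
            "residual_mode": config.residual_mode,
            "threshold_mode": config.threshold_mode,
        },
        "mask_checksum": mask_checksum(field.mask),
    }
    return FitResult(coefficients=coeffs, diagnostics=diag, provenance=provenance)


def fit_time_series(
    fields: Sequence[MaskedField],
    grid: StructuredGrid,
    modes: ModeSet,
    config: RegularizerConfig = RegularizerConfig(),
    cache: Optional[FactorizationCache] = None,
    method: str = "svd",
    compute_objective: bool = False,
) -> list[FitResult]:
    """Fit a sequence of snapshots sharing one mask.

    The structure factors, reduced matrix, and SVD are computed once; each
    snapshot only pays for its data spectrum, a back-substitution, and
    (optionally) a reconstruction for the objective.
    """
    if len(fields) == 0:
        return []
    fields = [_as_masked_field(f) for f in fields]
    ref = mask_checksum(fields[0].mask)
    for i, f in enumerate(fields[1:], start=1):
        if mask_checksum(f.mask) != ref:
            raise CacheInvalidationError(
                f"snapshot {i} has a different mask than snapshot 0; "
                "the factorization is only reusable under a constant mask -- "
                "fit differing masks separately with fit_masked_field"
            )
    own_cache = cache if cache is not None else FactorizationCache()
    # build (and factorize) once up front
    entry = own_cache.get_or_build(fields[0].mask, grid, modes)
    if method == "svd":
        own_cache.factorization_for(entry)
    return [
        fit_masked_field(
            f, grid, modes, config=config, cache=own_cache, method=method,
            compute_objective=compute_objective,
        )
        for f in fields
    ]


def combine_polarities(positive: np.ndarray, negative: np.ndarray) -> np.ndarray:
    """Combine two opposite-polarity acquisitions into one displacement field.

    Returns ``(positive - negative) / 2``: the subtraction cancels
    common-mode background, and the half keeps the displacement amplitude
    of a single polarity.
    """
    positive = np.asarray(positive, dtype=float)
    negative = np.asarray(negative, dtype=float)
    if positive.shape != negative.shape:
        raise InvalidGridError("polarity shapes differ")
    return (positive - negative) / 2.0
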