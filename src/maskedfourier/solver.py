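"""Solving the reduced system, with adaptive truncated-SVD regularization.

Masking generically makes the normal-equation matrix ill-conditioned: the
kernel loses orthogonality on an incomplete grid and nearly-degenerate
mode combinations appear.  The regularized solve decomposes ``AA = U S V^T``
once, zeroes singular values below a threshold, computes the pseudo-inverse
solution, and checks the system residual.  If the residual criterion is not
met, the retained rank is enlarged by a small factor (2 % by default) and
the back-substitution repeated -- the factorization itself is never redone.

The reduced solution ``xx`` carries each coefficient pair once; the
expansion back to the full interleaved ``(b, c)`` vector halves the shared
entries and mirrors them with the sign pattern required by conjugate
symmetry (``b_{-n} = b_n``, ``c_{-n} = -c_n``, ``c_0 = 0``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.linalg import eigh as scipy_eigh

from .errors import InconsistencyError
from .grid import ModeSet
from .instrument import counters

_COEFF_SYMMETRY_RTOL = 1e-10


# ---------------------------------------------------------------------------
# configuration and diagnostics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RegularizerConfig:
    """Settings of the adaptive truncated-SVD regularization.

    Attributes
    ----------
    initial_sv_threshold
        Singular values strictly below this are zeroed on the first pass.
        Interpreted on raw singular values by default; set
        ``threshold_mode="relative"`` to scale it by the largest singular
        value instead.
    residual_criterion
        Acceptance level for the system residual ``max|AA.xx - BB|``.
        Compared in relative form (divided by ``max|BB|``) by default;
        ``residual_mode="absolute"`` compares the raw max-norm.
    rank_growth_factor
        Multiplicative increase of the retained rank per retry (with a
        floor of +1 so small ranks still progress).
    max_iterations
        Optional cap on retries; by default the loop may grow to full rank.
    """

    initial_sv_threshold: float = 0.1
    residual_criterion: float = 3e-3
    rank_growth_factor: float = 1.02
    max_iterations: Optional[int] = None
    residual_mode: str = "relative"
    threshold_mode: str = "absolute"

    def __post_init__(self):
        if self.rank_growth_factor <= 1.0:
            raise ValueError("rank_growth_factor must be > 1")
        if self.residual_criterion <= 0:
            raise ValueError("residual_criterion must be > 0")
        if self.residual_mode not in ("relative", "absolute"):
            raise ValueError("residual_mode must be 'relative' or 'absolute'")
        if self.threshold_mode not in ("absolute", "relative"):
            raise ValueError("threshold_mode must be 'absolute' or 'relative'")


@dataclass
class FitDiagnostics:
    """What the solver did and how well the system is satisfied."""

    retained_rank: int = 0
    iterations: int = 0
    converged: bool = False
    relative_system_residual: float = np.nan
    absolute_system_residual: float = np.nan
    #: relative max-norm residual per retry (not guaranteed monotone)
    residual_history: list = field(default_factory=list)
    #: 2-norm residual per retry (monotone non-increasing by construction)
    residual_history_l2: list = field(default_factory=list)
    #: value of the least-squares objective at the solution (filled by the
    #: field-level fit, which knows the data)
    residual_objective: Optional[float] = None


@dataclass(frozen=True)
class SVDFactorization:
    """One-time decomposition ``AA = U diag(s) Vt`` reused across solves."""

    U: np.ndarray
    singular_values: np.ndarray
    Vt: np.ndarray

    @property
    def full_rank(self) -> int:
        s = self.singular_values
        if len(s) == 0:
            return 0
        tiny = np.finfo(float).eps * max(s[0], 1.0) * len(s)
        return int(np.count_nonzero(s > tiny))


def svd_factorize(AA: np.ndarray, release=None) -> SVDFactorization:
    """Compute (and count) the SVD of the reduced matrix.

    The reduced matrix is a signed-row relabeling of a Gram matrix:
    negating its c-rows (odd indices) makes it symmetric positive
    semidefinite.  When that structure is present the SVD is obtained from
    one symmetric eigendecomposition -- ``AA = (D W sgn) |L| W^T`` with
    ``D`` the row-sign matrix and ``W L W^T`` the eigendecomposition of the
    symmetrized matrix -- which is substantially faster and leaner than
    general bidiagonalization at the same exactness.  Matrices without the
    structure fall back to a general SVD.

    ``release``, if given, is a zero-argument callable that drops the
    caller's reference to ``AA``; it is invoked (on the structured route
    only) once the symmetrized working copy exists, so the original matrix
    is freed before the memory-intensive eigendecomposition.  The
    factorization fully supersedes the matrix: products ``AA @ x`` are
    available as ``U @ (s * (Vt @ x))``.
    """
    if not np.all(np.isfinite(AA)):
        raise FloatingPointError("non-finite entries in reduced matrix")
    counters.svd_calls += 1
    M = AA.shape[0]
    D = np.ones(M)
    D[1::2] = -1.0
    sym = AA * D[:, None]
    scale = np.abs(sym).max()
    if M > 1 and np.abs(sym - sym.T).max() <= 1e-8 * max(scale, 1.0):
        # exact symmetrization: eigendecomposition route
        if release is not None:
            release()
        del AA
        # divide-and-conquer driver: robust to the highly clustered
        # spectra that symmetric masks produce (MRRR degrades there).
        # sym is symmetric, so its transpose view is the same matrix in
        # Fortran order -- LAPACK takes it without an extra n^2 copy.
        w, W = scipy_eigh(sym.T, overwrite_a=True, driver="evd")
        order = np.argsort(np.abs(w), kind="stable")[::-1]
        s = np.abs(w)[order]
        V = W[:, order]
        del W, sym
        signs = np.where(w[order] >= 0.0, 1.0, -1.0)
        U = (D[:, None] * V) * signs[None, :]
        return SVDFactorization(U=U, singular_values=s, Vt=V.T)
    del sym
    U, s, Vt = np.linalg.svd(AA, full_matrices=False)
    return SVDFactorization(U=U, singular_values=s, Vt=Vt)


# ---------------------------------------------------------------------------
# solving
# ---------------------------------------------------------------------------

def solve_direct(AA: np.ndarray, BB: np.ndarray) -> np.ndarray:
    """Minimal-norm least-squares solution of the reduced system."""
    if not (np.all(np.isfinite(AA)) and np.all(np.isfinite(BB))):
        raise FloatingPointError("non-finite entries in system")
    counters.solve_calls += 1
    xx, *_ = np.linalg.lstsq(AA, BB, rcond=None)
    return xx


def solve_regularized(
    AA: Optional[np.ndarray],
    BB: np.ndarray,
    config: RegularizerConfig = RegularizerConfig(),
    factorization: Optional[SVDFactorization] = None,
) -> tuple[np.ndarray, FitDiagnostics]:
    """Truncated-SVD solve with residual-driven adaptive rank.

    The SVD is computed exactly once (or reused if supplied); only the
    back-substitution is repeated while the retained rank grows.  ``AA``
    may be None when a factorization is supplied; system residuals are
    then evaluated through the factors (``U (s Vt x) - BB``), which agrees
    with the matrix product to factorization accuracy.
    """
    BB = np.asarray(BB, dtype=float)
    diag = FitDiagnostics()
    if factorization is None:
        if AA is None:
            raise ValueError("either AA or a factorization must be supplied")
        factorization = svd_factorize(AA)
    counters.solve_calls += 1
    U, s, Vt = factorization.U, factorization.singular_values, factorization.Vt
    M = len(BB)
    bb_scale = np.abs(BB).max() if M else 0.0
    if bb_scale == 0.0:
        diag.converged = True
        diag.retained_rank = 0
        diag.iterations = 0
        diag.relative_system_residual = 0.0
        diag.absolute_system_residual = 0.0
        return np.zeros(M), diag

    full_rank = factorization.full_rank
    thr = config.initial_sv_threshold
    if config.threshold_mode == "relative" and len(s):
        thr = thr * s[0]
    rank = int(np.count_nonzero(s >= thr))
    rank = min(max(rank, 1), full_rank)

    proj = U.T @ BB  # fixed across retries
    xx = np.zeros(M)
    while True:
        diag.iterations += 1
        xx = Vt[:rank].T @ (proj[:rank] / s[:rank])
        if AA is not None:
            resvec = AA @ xx - BB
        else:
            resvec = U @ (s * (Vt @ xx)) - BB
        res = np.abs(resvec).max()
        diag.absolute_system_residual = float(res)
        diag.relative_system_residual = float(res / bb_scale)
        diag.residual_history.append(diag.relative_system_residual)
        diag.residual_history_l2.append(float(np.linalg.norm(resvec)))
        metric = (
            diag.relative_system_residual
            if config.residual_mode == "relative"
            else diag.absolute_system_residual
        )
        diag.retained_rank = rank
        if metric <= config.residual_criterion:
            diag.converged = True
            break
        if rank >= full_rank:
            break
        if (
            config.max_iterations is not None
            and diag.iterations >= config.max_iterations
        ):
            break
        rank = min(
            max(rank + 1, math.ceil(rank * config.rank_growth_factor)), full_rank
        )
    return xx, diag


# ---------------------------------------------------------------------------
# expansion back to full coefficients
# ---------------------------------------------------------------------------

def expand_solution(xx: np.ndarray) -> np.ndarray:
    """Expand the reduced solution to the full interleaved (b, c) vector.

    The reduced unknowns carry the folded weight of each conjugate pair;
    expansion halves the shared entries, copies the zero-mode b unchanged,
    and mirrors the first-half pairs with ``b`` even and ``c`` odd under
    mode negation.  The zero mode's c entry is identically zero.
    """
    xx = np.asarray(xx, dtype=float)
    M = len(xx)
    if M % 2 != 1:
        raise InconsistencyError(f"reduced solution length {M} is not odd")
    h = (M - 1) // 2
    x = np.zeros(2 * M)
    x[: M - 1] = 0.5 * xx[: M - 1]
    x[M - 1] = xx[M - 1]
    q = np.arange(h)
    x[2 * M - 2 * q - 2] = 0.5 * xx[2 * q]
    x[2 * M - 2 * q - 1] = -0.5 * xx[2 * q + 1]
    return x


@dataclass(frozen=True)
class FourierCoefficients:
    """Complex coefficients ``a_n = b_n + j c_n`` over the full lattice.

    Conjugate-symmetric (``a_{-n} = conj(a_n)``), which is what makes the
    reconstructed field real.
    """

    a: np.ndarray
    modes: ModeSet

    def __post_init__(self):
        if len(self.a) != self.modes.n_modes:
            raise InconsistencyError("coefficient count does not match mode set")

    def as_lattice_array(self) -> np.ndarray:
        """Coefficients reshaped to ``(2N_z+1, 2N_y+1, 2N_x+1)`` (singletons for
        missing axes)."""
        shape = self.modes.full_shape[::-1]
        shape = (1,) * (3 - len(shape)) + shape
        return self.a.reshape(shape)


def coefficients_from_solution(x: np.ndarray, modes: ModeSet) -> FourierCoefficients:
    """Pack the full interleaved (b, c) vector into complex coefficients."""
    x = np.asarray(x, dtype=float)
    if len(x) != 2 * modes.n_modes:
        raise InconsistencyError(
            f"expected length {2 * modes.n_modes}, got {len(x)}"
        )
    a = x[0::2] + 1j * x[1::2]
    mirrored = np.conj(a[::-1])
    scale = np.abs(a).max()
    if scale > 0 and np.abs(a - mirrored).max() > _COEFF_SYMMETRY_RTOL * scale * 10:
        raise InconsistencyError("coefficients violate conjugate symmetry")
    return FourierCoefficients(a=a, modes=modes)
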