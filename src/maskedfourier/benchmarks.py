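"""Ackley-type reconstruction benchmarks and deviation metrics.

Three deterministic benchmark problems (1D, 2D, 3D) exercise the whole
pipeline on a known ground truth: a multimodal Ackley-type surface --
an exponential envelope plus cosine oscillations -- sampled on a uniform
grid over ``[-5, 5]`` per axis, min-max normalized to ``[0, 1]``, with
axis-aligned box "holes" where the mask is zero.  The fit sees only the
masked data; the reported metrics compare the reconstruction against the
(unmasked) truth separately inside the data region and inside the holes,
the latter probing genuine inter-/extrapolation.

Everything here is deterministic: repeated runs are bitwise identical.
"""

from __future__ import annotations

import time
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .assembly import MaskedField
from .fields import FitResult, evaluate_field, fit_masked_field
from .grid import StructuredGrid, build_grid, build_mode_set
from .solver import RegularizerConfig

Hole = Sequence[Sequence[float]]  # ((lo, hi) per axis)

_DEFAULT_HOLES: dict[int, list] = {
    1: [((-3.5, -2.5),), ((-0.5, 0.5),), ((2.5, 3.5),)],
    2: [
        ((-0.5, 0.5), (-0.5, 0.5)),
        ((-0.5, 0.5), (2.0, 3.0)),
        ((2.0, 3.0), (2.0, 3.0)),
    ],
    3: [
        ((-0.5, 0.5), (-0.5, 0.5), (-0.5, 0.5)),
        ((-0.5, 0.5), (2.0, 3.0), (-0.5, 0.5)),
        ((2.0, 3.0), (2.0, 3.0), (-0.5, 0.5)),
        ((-0.5, 0.5), (-0.5, 0.5), (2.0, 3.0)),
    ],
}


@dataclass(frozen=True)
class BenchmarkSpec:
    """Parameters of one benchmark problem.

    ``a`` scales the envelope, ``b`` its decay rate, and ``c`` the angular
    frequency of the cosine oscillations (defaults 5, 0.2, 1.5*pi).  Holes
    are closed axis-aligned boxes; points exactly on a hole boundary count
    as masked out.
    """

    dimension: int
    a: float = 5.0
    b: float = 0.2
    c: float = 1.5 * np.pi
    bounds: tuple[float, float] = (-5.0, 5.0)
    resolution: int = 200
    holes: Optional[list] = None
    harmonics: int = 11
    normalize: bool = True
    padding_fraction: float = 0.1
    half_open: bool = False

    def __post_init__(self):
        if not 1 <= self.dimension <= 3:
            raise ValueError("dimension must be 1-3")
        if min(self.a, self.b, self.c) <= 0:
            raise ValueError("parameters a, b, c must be positive")

    @property
    def hole_boxes(self) -> list:
        return _DEFAULT_HOLES[self.dimension] if self.holes is None else self.holes

    def make_grid(self) -> StructuredGrid:
        return build_grid(
            (self.resolution,) * self.dimension,
            [self.bounds] * self.dimension,
            padding_fraction=self.padding_fraction,
            half_open=self.half_open,
        )


@dataclass(frozen=True)
class DeviationReport:
    """Reconstruction-vs-truth deviation summaries, in normalized units.

    ``max_*`` are maxima of absolute deviations; ``std_*`` are standard
    deviations of signed deviations (``std_abs_*`` of absolute ones, since
    either reading of "standard deviation" is defensible).  ``in_mask``
    restricts to data-present points, ``out_mask`` to hole points.
    """

    max_in_mask: float
    std_in_mask: float
    max_out_mask: float
    std_out_mask: float
    std_abs_in_mask: float
    std_abs_out_mask: float

    def as_dict(self) -> dict:
        return {
            "max_in_mask": self.max_in_mask,
            "std_in_mask": self.std_in_mask,
            "max_out_mask": self.max_out_mask,
            "std_out_mask": self.std_out_mask,
            "std_abs_in_mask": self.std_abs_in_mask,
            "std_abs_out_mask": self.std_abs_out_mask,
        }


def ackley_field(spec: BenchmarkSpec, grid: StructuredGrid) -> np.ndarray:
    """Evaluate the dimension-appropriate Ackley-type surface on the grid.

    The d-dimensional form averages the squared radius inside the envelope
    and the cosines inside the oscillation term:

        f(r) = -a exp(-b sqrt(sum x_i^2 / d)) - exp(sum cos(c x_i) / d)
               + a + e

    except that the 1D variant divides the cosine by ``a`` rather than by
    the dimension.  With ``normalize`` the sampled field is min-max scaled
    to [0, 1] over the full grid (before any masking).
    """
    a, b, c = spec.a, spec.b, spec.c
    mesh = np.meshgrid(*grid.axis_coords, indexing="ij")
    d = spec.dimension
    radius = np.sqrt(sum(m**2 for m in mesh) / d)
    if d == 1:
        oscill = np.cos(c * mesh[0]) / a
    else:
        oscill = sum(np.cos(c * m) for m in mesh) / d
    f = -a * np.exp(-b * radius) - np.exp(oscill) + a + np.e
    if spec.normalize:
        fmin, fmax = f.min(), f.max()
        f = (f - fmin) / (fmax - fmin)
    return f


def benchmark_mask(spec: BenchmarkSpec, grid: Optional[StructuredGrid] = None) -> np.ndarray:
    """Boolean mask that is False inside every (closed) hole box."""
    if grid is None:
        grid = spec.make_grid()
    mask = np.ones(grid.shape, dtype=bool)
    for box in spec.hole_boxes:
        inside = np.ones(grid.shape, dtype=bool)
        for axis, (lo, hi) in enumerate(box):
            coord = grid.axis_coords[axis]
            sel = (coord >= lo) & (coord <= hi)
            shape = [1] * grid.ndim
            shape[axis] = len(coord)
            inside &= sel.reshape(shape)
        mask &= ~inside
    return mask


def deviation_metrics(
    truth: np.ndarray, reconstruction: np.ndarray, mask: np.ndarray
) -> DeviationReport:
    """Deviation summaries over the data region and over the holes."""
    if truth.shape != reconstruction.shape or truth.shape != mask.shape:
        raise ValueError("truth, reconstruction, and mask shapes must agree")
    dev = truth - reconstruction

    def _metrics(sel):
        if not np.any(sel):
            return np.nan, np.nan, np.nan
        d = dev[sel]
        return float(np.abs(d).max()), float(np.std(d)), float(np.std(np.abs(d)))

    max_in, std_in, std_abs_in = _metrics(mask)
    max_out, std_out, std_abs_out = _metrics(~mask)
    return DeviationReport(
        max_in_mask=max_in,
        std_in_mask=std_in,
        max_out_mask=max_out,
        std_out_mask=std_out,
        std_abs_in_mask=std_abs_in,
        std_abs_out_mask=std_abs_out,
    )


@dataclass
class BenchmarkResult:
    """Everything one benchmark run produced."""

    spec: BenchmarkSpec
    report: DeviationReport
    fit: FitResult
    fit_seconds: float
    reconstruct_seconds: float

    def as_dict(self) -> dict:
        return {
            "case": f"{self.spec.dimension}d",
            "resolution": self.spec.resolution,
            "harmonics": self.spec.harmonics,
            "c": self.spec.c,
            "padding_fraction": self.spec.padding_fraction,
            "half_open": self.spec.half_open,
            "metrics": self.report.as_dict(),
            "retained_rank": self.fit.diagnostics.retained_rank,
            "solver_iterations": self.fit.diagnostics.iterations,
            "relative_system_residual": self.fit.diagnostics.relative_system_residual,
            "fit_seconds": self.fit_seconds,
            "reconstruct_seconds": self.reconstruct_seconds,
        }


def run_benchmark(
    case: str | int,
    config: RegularizerConfig = RegularizerConfig(),
    **overrides,
) -> BenchmarkResult:
    """Run one benchmark end to end: field -> mask -> fit -> metrics.

    ``case`` is ``"1d"``, ``"2d"``, ``"3d"`` (or 1/2/3); keyword overrides
    are forwarded to :class:`BenchmarkSpec` (e.g. ``c=0.8*np.pi``,
    ``resolution=50``, ``harmonics=8``).
    """
    dim = int(str(case).rstrip("dD"))
    spec = BenchmarkSpec(dimension=dim, **overrides)
    grid = spec.make_grid()
    truth = ackley_field(spec, grid)
    mask = benchmark_mask(spec, grid)
    modes = build_mode_set(spec.harmonics, grid)

    t0 = time.perf_counter()
    fit = fit_masked_field(
        MaskedField(values=truth, mask=mask), grid, modes,
        config=config, compute_objective=False,
    )
    t1 = time.perf_counter()
    recon = evaluate_field(fit.coefficients, grid)
    t2 = time.perf_counter()

    report = deviation_metrics(truth, recon, mask)
    return BenchmarkResult(
        spec=spec,
        report=report,
        fit=fit,
        fit_seconds=t1 - t0,
        reconstruct_seconds=t2 - t1,
    )
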