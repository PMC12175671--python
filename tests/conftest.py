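import numpy as np
import pytest

import maskedfourier as mf


@pytest.fixture
def rng():
    return np.random.default_rng(20240613)


@pytest.fixture
def small_3d(rng):
    """A 4x4x4 masked random field with N=(1,1,1), small enough for
    brute-force oracles over every point and mode."""
    grid = mf.build_grid((4, 4, 4), [(-1.0, 1.0)] * 3, padding_fraction=0.1)
    modes = mf.build_mode_set((1, 1, 1), grid)
    table = mf.precompute_exponentials(grid, modes)
    mask = rng.random((4, 4, 4)) > 0.4
    values = rng.standard_normal((4, 4, 4))
    return grid, modes, table, mask, values


def brute_structure_factor(mask, grid, n):
    """Direct triple-loop sum over all grid points for one mode tuple."""
    coords = np.meshgrid(*grid.axis_coords, indexing="ij")
    k0 = grid.fundamental_wavenumbers
    phase = sum(n[a] * k0[a] * coords[a] for a in range(grid.ndim))
    return np.sum(mask * np.exp(1j * phase))


def brute_spectrum(values, mask, grid, n):
    coords = np.meshgrid(*grid.axis_coords, indexing="ij")
    k0 = grid.fundamental_wavenumbers
    phase = sum(n[a] * k0[a] * coords[a] for a in range(grid.ndim))
    return np.sum(mask * values * np.exp(1j * phase))
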