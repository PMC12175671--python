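"""Structure factors, spectra, and system assembly against brute-force oracles."""

import numpy as np
import pytest

import maskedfourier as mf
from maskedfourier.assembly import MaskedField
from maskedfourier.errors import EmptyMaskError
from maskedfourier.instrument import counters, reset_counters

from conftest import brute_spectrum, brute_structure_factor


class TestStructureFactors:
    def test_full_mask_orthogonality(self):
        # on a half-open unpadded grid with full mask, only S_0 survives
        L = 8
        g = mf.build_grid(L, (0.0, 2.0), padding_fraction=0.0, half_open=True)
        m = mf.build_mode_set(3, g)
        t = mf.precompute_exponentials(g, m)
        S = mf.compute_structure_factors(np.ones(L, bool), t, g)
        assert S.lookup((0,)) == pytest.approx(L)
        for n in range(1, 4):
            assert abs(S.lookup((n,))) < 1e-12
            assert abs(S.lookup((-n,))) < 1e-12

    def test_hermitian_symmetry_and_s0(self, small_3d):
        grid, modes, table, mask, _ = small_3d
        S = mf.compute_structure_factors(mask, table, grid)
        assert S.s0 == mask.sum()
        vals = S.values
        np.testing.assert_allclose(vals, np.conj(vals[::-1, ::-1, ::-1]), atol=1e-12)
        assert np.abs(vals).max() <= S.s0 + 1e-9

    @pytest.mark.parametrize("dim", [1, 2, 3])
    def test_matches_brute_force(self, dim, rng):
        shape = (5, 4, 6)[:dim]
        grid = mf.build_grid(shape, [(-1.0, 2.0)] * dim, padding_fraction=0.13)
        modes = mf.build_mode_set((2,) * dim, grid)
        table = mf.precompute_exponentials(grid, modes)
        mask = rng.random(shape) > 0.35
        S = mf.compute_structure_factors(mask, table, grid)
        for n in np.ndindex(*(9,) * dim):
            n = tuple(np.array(n) - 4)
            expected = brute_structure_factor(mask, grid, n)
            assert S.lookup(n) == pytest.approx(expected, abs=1e-11 * mask.sum())

    def test_empty_mask_rejected(self, small_3d):
        grid, modes, table, _, _ = small_3d
        with pytest.raises(EmptyMaskError):
            mf.compute_structure_factors(np.zeros((4, 4, 4), bool), table, grid)

    def test_alias_entries_copied_not_recomputed(self):
        # 4N > L on a half-open unpadded grid: aliased modes fold onto L residues
        L, N = 6, 2
        g = mf.build_grid(L, (0.0, 1.0), padding_fraction=0.0, half_open=True)
        m = mf.build_mode_set(N, g)
        t = mf.precompute_exponentials(g, m)
        mask = np.array([1, 0, 1, 1, 0, 1], bool)
        reset_counters()
        S = mf.compute_structure_factors(mask, t, g)
        # the x-stage runs only the L unique residues instead of 4N+1 modes
        # (the two singleton-axis stages contribute L products each)
        assert counters.mask_contraction_products == 2 * L + min(4 * N + 1, L)
        for n in range(L - 2 * N, 2 * N + 1):
            assert S.lookup((n,)) == pytest.approx(S.lookup((n - L,)), abs=1e-12)


class TestRhsSpectrum:
    def test_zero_field_zero_spectrum(self, small_3d):
        grid, modes, table, mask, _ = small_3d
        f = MaskedField(np.zeros((4, 4, 4)), mask)
        spec = mf.compute_rhs_spectrum(f, table, grid)
        np.testing.assert_array_equal(spec, 0)

    def test_unit_field_equals_structure_factors(self, small_3d):
        grid, modes, table, mask, _ = small_3d
        spec = mf.compute_rhs_spectrum(MaskedField(np.ones((4, 4, 4)), mask), table, grid)
        S = mf.compute_structure_factors(mask, table, grid)
        expected = np.array([S.lookup(tuple(n)) for n in modes.full_lattice])
        np.testing.assert_allclose(spec, expected, atol=1e-12 * mask.sum())

    def test_matches_brute_force_2d(self, rng):
        grid = mf.build_grid((4, 4), [(-1, 1)] * 2, padding_fraction=0.1)
        modes = mf.build_mode_set((2, 2), grid)
        table = mf.precompute_exponentials(grid, modes)
        mask = rng.random((4, 4)) > 0.4
        values = rng.standard_normal((4, 4))
        spec = mf.compute_rhs_spectrum(MaskedField(values, mask), table, grid)
        for p, n in enumerate(modes.full_lattice):
            assert spec[p] == pytest.approx(
                brute_spectrum(values, mask, grid, tuple(n)), abs=1e-12 * mask.size
            )

    def test_masked_points_never_influence_results(self, small_3d, rng):
        grid, modes, table, mask, values = small_3d
        spec1 = mf.compute_rhs_spectrum(MaskedField(values, mask), table, grid)
        tampered = values.copy()
        tampered[~mask] = rng.standard_normal((~mask).sum()) * 1e6
        spec2 = mf.compute_rhs_spectrum(MaskedField(tampered, mask), table, grid)
        np.testing.assert_array_equal(spec1, spec2)


class TestSystemAssembly:
    def _system(self, small_3d):
        grid, modes, table, mask, values = small_3d
        S = mf.compute_structure_factors(mask, table, grid)
        spec = mf.compute_rhs_spectrum(MaskedField(values, mask), table, grid)
        return grid, modes, S, spec

    def test_full_system_matches_termwise_oracle(self, small_3d):
        grid, modes, S, spec = self._system(small_3d)
        sys_full = mf.assemble_full_system(S, spec, modes)
        M = modes.n_modes
        assert sys_full.A.shape == (2 * M, 2 * M)
        lat = modes.full_lattice
        for p in range(M):
            for q in range(M):
                Sp = S.lookup(tuple(lat[p] + lat[q]))
                Sm = S.lookup(tuple(lat[p] - lat[q]))
                assert sys_full.A[2 * p, 2 * q] == pytest.approx((Sp + Sm).real)
                assert sys_full.A[2 * p, 2 * q + 1] == pytest.approx(-(Sp - Sm).imag)
                assert sys_full.A[2 * p + 1, 2 * q] == pytest.approx((Sp + Sm).imag)
                assert sys_full.A[2 * p + 1, 2 * q + 1] == pytest.approx((Sp - Sm).real)
            assert sys_full.B[2 * p] == spec[p].real
            assert sys_full.B[2 * p + 1] == spec[p].imag

    def test_full_mask_rows_are_deltas(self):
        # orthogonal case: the b-row of mode m couples only to modes +-m
        L = 8
        g = mf.build_grid(L, (0.0, 1.0), padding_fraction=0.0, half_open=True)
        modes = mf.build_mode_set(2, g)
        t = mf.precompute_exponentials(g, modes)
        S = mf.compute_structure_factors(np.ones(L, bool), t, g)
        spec = mf.compute_rhs_spectrum(MaskedField(np.ones(L), np.ones(L, bool)), t, g)
        A = mf.assemble_full_system(S, spec, modes).A
        lat = modes.full_lattice
        for p, m in enumerate(lat[:, 0]):
            row = A[2 * p, 0::2]  # b-row, b-columns
            expected = np.zeros(len(lat))
            expected[lat[:, 0] == m] += L
            expected[lat[:, 0] == -m] += L
            np.testing.assert_allclose(row, expected, atol=1e-9)

    def test_reduction_equals_leading_block(self, small_3d):
        grid, modes, S, spec = self._system(small_3d)
        sys_full = mf.assemble_full_system(S, spec, modes)
        red = mf.assemble_reduced_system(S, spec, modes)
        M = modes.n_modes
        np.testing.assert_array_equal(red.AA, sys_full.A[:M, :M])
        np.testing.assert_array_equal(red.BB, sys_full.B[:M])
        # reduce_system populates the same matrices
        sys2 = mf.reduce_system(sys_full, modes)
        np.testing.assert_array_equal(sys2.AA, red.AA)
        np.testing.assert_array_equal(sys2.BB, red.BB)

    def test_reduced_dimension_formula(self):
        g = mf.build_grid((6, 6, 6), [(0, 1)] * 3)
        modes = mf.build_mode_set((1, 2, 1), g)
        t = mf.precompute_exponentials(g, modes)
        S = mf.compute_structure_factors(np.ones((6, 6, 6), bool), t, g)
        spec = np.zeros(modes.n_modes, complex)
        red = mf.assemble_reduced_system(S, spec, modes)
        assert red.AA.shape == (3 * 5 * 3, 3 * 5 * 3)

    def test_reduced_solution_matches_full_pseudoinverse(self, rng):
        # expand(solve(AA, BB)) reconstructs the same field as pinv of the
        # full system on a small 1D case
        g = mf.build_grid(10, (0.0, 1.0), padding_fraction=0.1)
        modes = mf.build_mode_set(2, g)
        t = mf.precompute_exponentials(g, modes)
        mask = rng.random(10) > 0.3
        values = rng.standard_normal(10)
        S = mf.compute_structure_factors(mask, t, g)
        spec = mf.compute_rhs_spectrum(MaskedField(values, mask), t, g)
        sys_full = mf.assemble_full_system(S, spec, modes)
        red = mf.assemble_reduced_system(S, spec, modes)

        xx = mf.solve_direct(red.AA, red.BB)
        recon = mf.evaluate_field(
            mf.coefficients_from_solution(mf.expand_solution(xx), modes), g
        )
        x_full = np.linalg.pinv(sys_full.A) @ sys_full.B
        recon_full = mf.evaluate_field(
            mf.coefficients_from_solution(x_full, modes), g
        )
        np.testing.assert_allclose(recon, recon_full, atol=1e-10)

    def test_contraction_operation_counts(self):
        # scalar-product accounting of the separable assembly
        Lx, Ly, Lz = 5, 4, 6
        Nx, Ny, Nz = 2, 1, 2
        g = mf.build_grid((Lx, Ly, Lz), [(0, 1)] * 3, padding_fraction=0.1)
        modes = mf.build_mode_set((Nx, Ny, Nz), g)
        t = mf.precompute_exponentials(g, modes)
        reset_counters()
        mf.compute_structure_factors(np.ones((Lx, Ly, Lz), bool), t, g)
        Kx, Ky, Kz = 4 * Nx + 1, 4 * Ny + 1, 4 * Nz + 1
        expected = Lx * Ly * Kz + Lx * Ky * Kz + Kx * Ky * Kz
        assert counters.mask_contraction_products == expected
        reset_counters()
        mf.compute_rhs_spectrum(
            MaskedField(np.ones((Lx, Ly, Lz)), np.ones((Lx, Ly, Lz), bool)), t, g
        )
        kx, ky, kz = 2 * Nx + 1, 2 * Ny + 1, 2 * Nz + 1
        assert counters.data_contraction_products == (
            Lx * Ly * kz + Lx * ky * kz + kx * ky * kz
        )
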