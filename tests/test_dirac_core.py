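"""Dirac matrix assembly, metrics, spectra, and the kernel identity."""

import numpy as np
import pytest

from pdirac import (
    SimplicialComplex,
    assemble_dirac,
    assemble_weighted_dirac,
    boundary_matrix,
    complete_complex,
    dirac_spectrum,
    hodge_blocks,
    homology_eigenvectors,
    kernel_decomposition,
    metric_matrices,
    non_homology_eigenvectors,
    supersymmetry_check,
)
from pdirac.dirac_core import default_scales

from conftest import random_rips
from oracles import hodge_entrywise


def unit_weights(K):
    return {s: 1.0 for s in K.all_simplices()}


class TestAssembleDirac:
    def test_triangle_block_structure(self, triangle):
        D = assemble_dirac(triangle, 1)
        assert D.side == 7
        A = D.toarray()
        assert np.array_equal(A, A.T)
        B1 = boundary_matrix(triangle, 1).toarray()
        B2 = boundary_matrix(triangle, 2).toarray()
        assert np.array_equal(A[0:3, 3:6], B1)
        assert np.array_equal(A[3:6, 6:7], B2)
        assert np.abs(A[0:3, 6:7]).max() == 0

    def test_isolated_vertices_are_zero_matrices(self):
        K = SimplicialComplex([(i,) for i in range(16)])
        for p in (0, 1, 2):
            D = assemble_dirac(K, p)
            assert D.side == 16
            assert D.matrix.nnz == 0

    def test_complete_complex_sides(self):
        assert assemble_dirac(complete_complex(16, 2), 1).side == 696
        assert assemble_dirac(complete_complex(16, 1), 0).side == 136


class TestMetricMatrices:
    def test_triangle_coface_recursion(self, triangle):
        m = metric_matrices(triangle, unit_weights(triangle))
        assert np.allclose(m.G[2], [1.0])
        assert np.allclose(m.G[1], [2.0, 2.0, 2.0])
        assert np.allclose(m.G[0], [5.0, 5.0, 5.0])

    def test_single_edge(self):
        K = SimplicialComplex([(0, 1)])
        m = metric_matrices(K, unit_weights(K))
        assert np.allclose(m.G[1], [1.0])
        assert np.allclose(m.G[0], [2.0, 2.0])

    def test_top_dimension_is_plain_weights(self):
        K = SimplicialComplex([(i,) for i in range(4)])
        w = {(i,): float(i + 1) for i in range(4)}
        m = metric_matrices(K, w)
        assert np.allclose(m.G[0], [1.0, 2.0, 3.0, 4.0])

    def test_nonpositive_weight_rejected(self, triangle):
        w = unit_weights(triangle)
        w[(0, 1)] = 0.0
        with pytest.raises(ValueError, match=r"\(0, 1\)"):
            metric_matrices(triangle, w)


class TestWeightedDirac:
    def test_identity_metric_reduces_to_discrete(self, triangle):
        m = metric_matrices(triangle, unit_weights(triangle))
        m.G = {k: np.ones_like(v) for k, v in m.G.items()}
        Dw = assemble_weighted_dirac(triangle, 1, m, a={1: 1.0, 2: 1.0})
        D = assemble_dirac(triangle, 1)
        assert (Dw.matrix != D.matrix).nnz == 0

    def test_triangle_eigenvalues_bounded_by_one(self, triangle):
        m = metric_matrices(triangle, unit_weights(triangle))
        Dw = assemble_weighted_dirac(triangle, 1, m)
        spec = dirac_spectrum(Dw)
        assert np.all(np.isreal(spec.eigenvalues))
        assert np.abs(spec.eigenvalues).max() <= 1.0 + 1e-9

    @pytest.mark.parametrize("seed", range(8))
    def test_eigenvalue_bound_random_weights(self, seed):
        K = random_rips(seed, n=7, max_dim=2, radius=1.4).complex
        rng = np.random.default_rng(seed + 100)
        w = {s: float(rng.uniform(0.1, 5.0)) for s in K.all_simplices()}
        Dw = assemble_weighted_dirac(K, 1, metric_matrices(K, w))
        spec = dirac_spectrum(Dw)
        assert np.abs(spec.eigenvalues).max() <= 1.0 + 1e-9

    @pytest.mark.parametrize("seed", range(5))
    def test_symmetrized_spectrum_matches_nonsymmetric(self, seed):
        K = random_rips(seed, n=7, max_dim=2, radius=1.4).complex
        rng = np.random.default_rng(seed)
        w = {s: float(rng.uniform(0.2, 3.0)) for s in K.all_simplices()}
        Dw = assemble_weighted_dirac(K, 1, metric_matrices(K, w))
        direct = np.sort(np.linalg.eigvals(Dw.toarray()).real)
        sym = np.sort(dirac_spectrum(Dw).eigenvalues)
        assert np.allclose(direct, sym, atol=1e-8)

    def test_metric_size_mismatch_rejected(self, triangle):
        m = metric_matrices(triangle, unit_weights(triangle))
        m.G[1] = np.ones(2)
        with pytest.raises(ValueError, match="metric size"):
            assemble_weighted_dirac(triangle, 1, m)


class TestSpectrum:
    def test_triangle_spectrum(self, triangle):
        spec = dirac_spectrum(assemble_dirac(triangle, 1))
        root3 = np.sqrt(3.0)
        expected = sorted([-root3] * 3 + [0.0] + [root3] * 3)
        assert np.allclose(np.sort(spec.eigenvalues), expected)
        assert spec.nullity == 1
        assert spec.positive.size == 3

    def test_complete_graph_d0_nullity(self):
        spec = dirac_spectrum(assemble_dirac(complete_complex(16, 1), 0))
        assert spec.nullity == 106

    def test_zero_matrix_nullity(self):
        K = SimplicialComplex([(i,) for i in range(16)])
        spec = dirac_spectrum(assemble_dirac(K, 1))
        assert spec.nullity == 16

    @pytest.mark.parametrize("seed", range(10))
    def test_plus_minus_pairing(self, seed):
        K = random_rips(seed).complex
        lam = np.sort(dirac_spectrum(assemble_dirac(K, 1)).eigenvalues)
        assert np.allclose(lam, -lam[::-1], atol=1e-9)

    def test_nullity_plus_pairs_is_side(self, seed=4):
        K = random_rips(seed).complex
        D = assemble_dirac(K, 1)
        spec = dirac_spectrum(D)
        assert spec.nullity + 2 * spec.positive.size == D.side


class TestHodgeBlocks:
    def test_triangle_l0_is_cycle_laplacian(self, triangle):
        L0 = hodge_blocks(triangle, 1)[0]
        assert np.allclose(L0, 2 * np.eye(3) - (np.ones((3, 3)) - np.eye(3)))

    @pytest.mark.parametrize("seed", range(6))
    def test_square_blocks_match_entrywise_tables(self, seed):
        K = random_rips(seed, n=7, max_dim=2, radius=1.4).complex
        D = assemble_dirac(K, 1)
        D2 = (D.matrix @ D.matrix).toarray()
        blocks = hodge_blocks(K, 1)
        for k, L in enumerate(blocks):
            sl = D.block_slice(k)
            assert np.abs(D2[sl, sl] - L).max() <= 1e-10
            if k < len(blocks) - 1:  # full Laplacians, not the trailing down block
                assert np.abs(L - hodge_entrywise(K, k)).max() <= 1e-10

    def test_weighted_blocks_match_dirac_square(self, triangle):
        m = metric_matrices(triangle, unit_weights(triangle))
        Dw = assemble_weighted_dirac(triangle, 1, m)
        D2 = (Dw.matrix @ Dw.matrix).toarray()
        for k, L in enumerate(hodge_blocks(triangle, 1, m)):
            sl = Dw.block_slice(k)
            assert np.abs(D2[sl, sl] - L).max() <= 1e-10


class TestSupersymmetry:
    def test_triangle_and_tetrahedron_exact(self, triangle, tetrahedron):
        assert supersymmetry_check(assemble_dirac(triangle, 1)) == (True, 0.0)
        assert supersymmetry_check(assemble_dirac(tetrahedron, 2)) == (True, 0.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_random_rips_exact(self, seed):
        K = random_rips(seed).complex
        ok, resid = supersymmetry_check(assemble_dirac(K, 1))
        assert ok and resid == 0.0


class TestKernelDecomposition:
    def test_complete_complex_values(self):
        dec = kernel_decomposition(complete_complex(16, 2), 0, spectral=False)
        assert dec.rank_next == 105
        assert dec.identity_nullity == 106
        assert dec.nullity == 106

    def test_two_disjoint_edges(self):
        K = SimplicialComplex([(0, 1), (2, 3)])
        dec = kernel_decomposition(K, 0)
        assert dec.nullity == 2 == dec.identity_nullity
        assert dec.betti == [2, 0]

    @pytest.mark.parametrize("seed", range(25))
    def test_nullity_identity_on_random_complexes(self, seed):
        K = random_rips(seed).complex
        for p in (0, 1):
            dec = kernel_decomposition(K, p)
            assert dec.nullity == dec.identity_nullity


class TestEigenvectors:
    def test_four_cycle_harmonic_edge_block(self, four_cycle):
        D = assemble_dirac(four_cycle, 1)
        gens = homology_eigenvectors(D)
        edge_blocks = [g[1] for g in gens if np.linalg.norm(g[1]) > 1e-8]
        assert len(edge_blocks) == 1
        mags = np.abs(edge_blocks[0])
        assert np.allclose(mags, mags[0], atol=1e-9)

    def test_triangle_kernel_is_constant_vertex_block(self, triangle):
        D = assemble_dirac(triangle, 1)
        gens = homology_eigenvectors(D)
        assert len(gens) == 1
        w0, w1, w2 = gens[0]
        assert np.allclose(w0, w0[0]) and abs(w0[0]) > 0.1
        assert np.abs(w1).max() < 1e-9 and np.abs(w2).max() < 1e-9

    def test_kernel_blocks_are_laplacian_kernels(self, four_cycle):
        D = assemble_dirac(four_cycle, 1)
        blocks = hodge_blocks(four_cycle, 1)
        for gen in homology_eigenvectors(D):
            for k, w in enumerate(gen):
                assert np.linalg.norm(blocks[k] @ w) <= 1e-8

    def test_non_homology_truncation_warns(self, triangle):
        D = assemble_dirac(triangle, 1)
        with pytest.warns(UserWarning):
            out = non_homology_eigenvectors(D, 10)
        assert len(out) == 3
        assert out[0][0] == pytest.approx(np.sqrt(3.0))


class TestWeightInversion:
    def test_harmonic_magnitude_grows_as_weight_shrinks(self, four_cycle):
        # shrinking one edge's weight must monotonically boost that
        # edge's share of the harmonic 1-generator
        target = (0, 1)
        rel = []
        for w_e in (10.0, 1.0, 0.01):
            w = {s: 1.0 for s in four_cycle.all_simplices()}
            w[target] = w_e
            Dw = assemble_weighted_dirac(four_cycle, 1, metric_matrices(four_cycle, w))
            gens = homology_eigenvectors(Dw)
            # the kernel basis may mix the vertex and edge generators:
            # extract the one-dimensional edge-block direction by SVD
            stacked = np.array([g[1] for g in gens])
            _, svals, vt = np.linalg.svd(stacked)
            assert np.sum(svals > 1e-8) == 1
            block = vt[0]
            idx = four_cycle.index(1)[target]
            rel.append(abs(block[idx]) / np.linalg.norm(block))
        assert rel[0] < rel[1] < rel[2]


def test_default_scales():
    assert default_scales(3) == {
        1: pytest.approx(2 ** -0.5),
        2: pytest.approx(3 ** -0.5),
        3: pytest.approx(0.5),
    }
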