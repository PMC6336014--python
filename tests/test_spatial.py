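"""Spatial statistics: distances, correlograms, Dutilleul test, PCNM, buffers."""

import numpy as np
import pytest

from germfda.raster import Grid
from germfda.spatial import (EARTH_RADIUS_KM, buffer_mean_extract,
                             dutilleul_modified_t, haversine_distances,
                             make_distance_classes, morans_i,
                             morans_i_correlogram, pcnm_eigenvectors)


class TestHaversine:
    def test_identical_points_zero(self):
        assert haversine_distances([[10.0, 45.0], [10.0, 45.0]])[0, 1] == 0.0

    def test_half_great_circle(self):
        d = haversine_distances([[0.0, 0.0], [180.0, 0.0]])[0, 1]
        assert d == pytest.approx(np.pi * EARTH_RADIUS_KM, rel=1e-9)

    def test_symmetry(self, rng):
        pts = np.column_stack([rng.uniform(-180, 180, 8), rng.uniform(-90, 90, 8)])
        D = haversine_distances(pts)
        assert np.allclose(D, D.T)
        assert np.all(np.diag(D) == 0)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            haversine_distances([[0.0, 91.0], [0.0, 0.0]])


class TestDistanceClasses:
    def test_equal_frequency_counts(self, rng):
        pts = np.column_stack([rng.uniform(0, 30, 10), rng.uniform(30, 50, 10)])
        classes = make_distance_classes(haversine_distances(pts), 10)
        counts = classes.pair_counts()
        assert counts.sum() == 45
        assert counts.min() >= 4 and counts.max() <= 5

    def test_boundaries_match_sort_and_slice_oracle(self, rng):
        pts = np.column_stack([rng.uniform(0, 30, 12), rng.uniform(30, 50, 12)])
        D = haversine_distances(pts)
        classes = make_distance_classes(D, 6)
        iu = np.triu_indices(12, 1)
        d_sorted = np.sort(D[iu])
        expected = np.quantile(d_sorted, np.linspace(0, 1, 7))
        assert np.allclose(classes.boundaries, expected)

    def test_collinear_points_increasing_boundaries(self):
        pts = np.column_stack([np.arange(8.0), np.zeros(8)])
        classes = make_distance_classes(haversine_distances(pts), 5)
        assert np.all(np.diff(classes.boundaries) > 0)


class TestCorrelogram:
    def test_null_expectation(self, rng):
        pts = np.column_stack([rng.uniform(0, 30, 11), rng.uniform(30, 50, 11)])
        classes = make_distance_classes(haversine_distances(pts), 3)
        cg = morans_i_correlogram(rng.standard_normal(11), classes, seed=0)
        assert cg.expectation == pytest.approx(-0.1)

    def test_transect_alternating_matches_bruteforce_double_sum(self):
        # 6 equispaced points on a line, values +1/-1 alternating; weights:
        # adjacent pairs only
        z = np.array([1.0, -1.0, 1.0, -1.0, 1.0, -1.0])
        n = 6
        W = np.zeros((n, n))
        for i in range(n - 1):
            W[i, i + 1] = W[i + 1, i] = 1.0
        zc = z - z.mean()
        brute = 0.0
        for i in range(n):
            for j in range(n):
                brute += W[i, j] * zc[i] * zc[j]
        brute = n / W.sum() * brute / np.sum(zc**2)
        assert morans_i(z, W) == pytest.approx(brute)
        assert brute == pytest.approx(-1.0)  # perfect alternation

    def test_constant_surface_errors(self, rng):
        pts = np.column_stack([rng.uniform(0, 30, 8), rng.uniform(30, 50, 8)])
        classes = make_distance_classes(haversine_distances(pts), 3)
        with pytest.raises(ValueError, match="constant"):
            morans_i_correlogram(np.ones(8), classes)

    def test_centering_invariance(self, rng):
        pts = np.column_stack([rng.uniform(0, 30, 15), rng.uniform(30, 50, 15)])
        classes = make_distance_classes(haversine_distances(pts), 4)
        z = rng.standard_normal(15)
        a = morans_i_correlogram(z, classes, n_permutations=9, seed=1)
        b = morans_i_correlogram(z + 100.0, classes, n_permutations=9, seed=1)
        assert np.allclose(a.i_values, b.i_values, equal_nan=True)

    def test_global_verdict_monotone_in_alpha(self, rng):
        pts = np.column_stack([rng.uniform(0, 5, 20), rng.uniform(40, 44, 20)])
        classes = make_distance_classes(haversine_distances(pts), 5)
        # strongly gradient-structured surface
        z = pts[:, 0] + 0.1 * rng.standard_normal(20)
        verdicts = [
            morans_i_correlogram(z, classes, alpha=a, seed=3).global_significant
            for a in (0.001, 0.01, 0.05, 0.2)
        ]
        assert verdicts == sorted(verdicts)


class TestDutilleul:
    def test_zero_correlation_p_one(self):
        x = np.array([1.0, -1.0, 1.0, -1.0, 1.0, -1.0])
        y = np.array([1.0, 1.0, -1.0, -1.0, 1.0, 1.0])  # orthogonal to x
        pts = np.column_stack([np.arange(6.0), np.zeros(6)])
        res = dutilleul_modified_t(x, y, coords=pts, n_classes=3)
        assert res.r == pytest.approx(0.0, abs=1e-12)
        assert res.p_corrected == pytest.approx(1.0)

    def test_white_noise_effective_n_near_n(self, rng):
        n = 50
        pts = np.column_stack([rng.uniform(0, 20, n), rng.uniform(30, 45, n)])
        classes = make_distance_classes(haversine_distances(pts),
                                        exclude_largest=False)
        nh = [
            dutilleul_modified_t(rng.standard_normal(n), rng.standard_normal(n),
                                 classes=classes).effective_n
            for _ in range(200)
        ]
        assert abs(np.mean(nh) - n) / n < 0.10

    def test_autocorrelated_null_calibration(self, rng):
        # shared strong exponential autocorrelation, range = half extent:
        # corrected test holds its level where the classical test does not
        n = 50
        pts = np.column_stack([rng.uniform(0, 20, n), rng.uniform(30, 45, n)])
        D = haversine_distances(pts)
        C = np.exp(-D / (D.max() / 2))
        C[np.diag_indices(n)] += 1e-8
        L = np.linalg.cholesky(C)
        classes = make_distance_classes(D, exclude_largest=False)
        rej_corr = rej_class = 0
        n_hats = []
        for _ in range(500):
            x = L @ rng.standard_normal(n)
            y = L @ rng.standard_normal(n)
            res = dutilleul_modified_t(x, y, classes=classes)
            rej_corr += res.p_corrected <= 0.05
            rej_class += res.p_classical <= 0.05
            n_hats.append(res.effective_n)
        assert np.mean(n_hats) < n  # strictly reduced effective sample size
        assert rej_corr / 500 <= 0.08
        assert rej_class / 500 > 0.10


class TestPCNM:
    def test_orthogonal_and_centered(self, rng):
        pts = np.column_stack([rng.uniform(0, 30, 25), rng.uniform(30, 50, 25)])
        V, vals, _ = pcnm_eigenvectors(coords=pts)
        G = V.T @ V
        assert np.abs(G - np.diag(np.diag(G))).max() < 1e-8
        assert np.abs(V.mean(axis=0)).max() < 1e-10
        assert np.all(np.diff(vals) <= 1e-9)

    def test_transect_wave_ordering(self):
        pts = np.column_stack([np.linspace(0, 19, 20), np.zeros(20)])
        V, _, _ = pcnm_eigenvectors(coords=pts)
        sign_changes = [int(np.sum(np.diff(np.sign(V[:, j])) != 0))
                        for j in range(min(4, V.shape[1]))]
        assert sign_changes[0] >= 1
        assert all(a <= b for a, b in zip(sign_changes, sign_changes[1:]))

    def test_eigenvalues_match_independent_pcoa(self, rng):
        # scikit-bio PCoA on the same truncated distance matrix
        from skbio.stats.ordination import pcoa

        pts = np.column_stack([rng.uniform(0, 10, 12), rng.uniform(40, 46, 12)])
        from germfda.spatial import haversine_distances
        D = haversine_distances(pts)
        V, vals, trunc = pcnm_eigenvectors(dist=D)
        Dt = D.copy()
        Dt[Dt > trunc] = 4 * trunc
        np.fill_diagonal(Dt, 0)
        ref = pcoa(Dt, method="eigh")
        ref_pos = np.sort(ref.eigvals[ref.eigvals > 1e-6])[::-1]
        assert np.allclose(vals, ref_pos[: len(vals)], atol=1e-8)

    def test_identical_points_error(self):
        with pytest.raises(ValueError):
            pcnm_eigenvectors(coords=np.zeros((5, 2)))


class TestBufferMean:
    def grid(self, values, mask_value=None):
        v = np.ma.masked_equal(values, mask_value) if mask_value is not None else values
        # 0.01-degree cells (~1.1 km) around (10E, 45N)
        return Grid(v, 10.0, 45.0, 0.01)

    def test_constant_raster(self):
        g = self.grid(np.full((10, 10), 7.5))
        assert buffer_mean_extract(g, 10.05, 45.05, 5.0) == 7.5

    def test_three_cell_hand_mean(self):
        vals = np.full((1, 3), np.nan)
        vals[0] = [1.0, 2.0, 3.0]
        g = Grid(vals, 10.0, 45.0, 0.01)
        # center of middle cell; 0.6 km covers all three centers (~0.78 km apart)
        assert buffer_mean_extract(g, 10.015, 45.005, 1.0) == pytest.approx(2.0)

    def test_masked_cells_excluded(self):
        vals = np.array([[4.0, -99.0, 6.0]])
        g = self.grid(vals, mask_value=-99.0)
        assert buffer_mean_extract(g, 10.015, 45.005, 1.0) == pytest.approx(5.0)

    def test_outside_extent_errors(self):
        g = self.grid(np.ones((5, 5)))
        with pytest.raises(ValueError, match="extent"):
            buffer_mean_extract(g, 50.0, 45.0, 5.0)

    def test_empty_buffer_errors(self):
        vals = np.ma.masked_all((5, 5))
        g = Grid(vals, 10.0, 45.0, 0.01)
        with pytest.raises(ValueError, match="[Ee]mpty buffer"):
            buffer_mean_extract(g, 10.02, 45.02, 5.0)
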