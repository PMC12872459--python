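"""Group tests, surrogates, split-half, searchlight, TFCE, clusters, bootstrap."""

import numpy as np
import pytest
from scipy import stats as sps

import cortexcf as c
from cortexcf.mesh import geodesic_matrix


@pytest.fixture(scope="module")
def surrogate_mesh():
    """16 x 16 mm patch with a 40-mode constant-inclusive basis."""
    mesh = c.flat_patch_mesh(16.0, 16.0, 1.0)
    basis = c.compute_basis(mesh, 40, drop_constant=False)
    return mesh, basis


class TestGroupTest:
    def test_dz_equals_t_over_sqrt_n(self):
        rng = np.random.default_rng(0)
        scores = rng.standard_normal((30, 8)) + 0.3
        res = c.group_topography_test(scores)
        assert np.allclose(res.d_z, res.t / np.sqrt(30), atol=1e-10)

    def test_published_style_dz_readouts(self):
        # printed group t statistics at n = 174 convert to d_z of 0.28/0.23
        assert round(c.cohens_dz_from_t(3.70, 174), 2) == 0.28
        assert round(c.cohens_dz_from_t(3.06, 174), 2) == 0.23

    def test_holm_never_decreases_p_and_monotone(self):
        rng = np.random.default_rng(1)
        scores = rng.standard_normal((20, 15)) + 0.2
        res = c.group_topography_test(scores)
        assert np.all(res.p >= res.p_raw - 1e-15)
        order = np.argsort(res.p_raw)
        assert np.all(np.diff(res.p[order]) >= -1e-12)

    def test_degenerate_zero_variance_flagged(self):
        scores = np.zeros((5, 2))
        scores[:, 1] = [0.1, 0.2, 0.3, 0.2, 0.1]
        res = c.group_topography_test(scores)
        assert res.degenerate[0] and not res.degenerate[1]
        assert np.isnan(res.t[0])


class TestCriticalEffectSize:
    def test_reference_sample_size(self):
        # analytic value 0.14963; agrees with the printed 0.149 at 3 d.p.
        assert c.critical_effect_size(174, alpha=0.05) == pytest.approx(
            0.149, abs=1e-3)

    def test_small_n_from_t_table(self):
        # t_crit(0.975, df=3) = 3.1824 -> / sqrt(4)
        assert np.isclose(c.critical_effect_size(4, alpha=0.05),
                          3.18244630528 / 2, atol=1e-6)

    def test_alpha_one_limit_zero(self):
        assert abs(c.critical_effect_size(20, alpha=1.0)) < 1e-12

    def test_invalid_alpha_rejected(self):
        with pytest.raises(ValueError):
            c.critical_effect_size(20, alpha=1.5)


class TestGMMThreshold:
    def test_balanced_mixture_splits_midway(self):
        rng = np.random.default_rng(2)
        v = np.r_[rng.normal(0, 1, 3000), rng.normal(10, 1, 3000)]
        thr = c.gmm_threshold(v, seed=0)
        assert abs(thr - 5.0) < 0.3

    def test_unbalanced_mixture_shifts_threshold_up(self):
        rng = np.random.default_rng(3)
        v = np.r_[rng.normal(0, 1, 9000), rng.normal(10, 1, 1000)]
        thr = c.gmm_threshold(v, seed=0)
        # closed-form posterior crossing: 5 + ln(9)/10 ~ 5.22; must be > 5
        assert thr > 5.0
        assert abs(thr - (5.0 + np.log(9.0) / 10.0)) < 0.3

    def test_degenerate_single_component_flagged(self):
        # identical values: both component means coincide -> no threshold
        with pytest.warns(UserWarning, match="indistinguishable"):
            thr = c.gmm_threshold(np.zeros(200), seed=0)
        assert thr is None


class TestSurrogates:
    def test_all_plus_signs_reproduce_empirical(self, surrogate_mesh):
        mesh, basis = surrogate_mesh
        rng = np.random.default_rng(5)
        coef = rng.standard_normal((3, basis.k))
        ens = c.make_surrogates(coef, basis, n=200, seed=6)
        ens.signs[0] = 1.0  # force the identity sign vector
        assert np.allclose(ens.surrogate_fields(0),
                           coef @ basis.eigenfunctions.T)

    def test_amplitude_spectrum_exactly_preserved(self, surrogate_mesh):
        _, basis = surrogate_mesh
        rng = np.random.default_rng(7)
        coef = rng.standard_normal((4, basis.k))
        ens = c.make_surrogates(coef, basis, n=500, seed=8)
        for i in (0, 123, 499):
            assert np.array_equal(np.abs(ens.coefficients * ens.signs[i]),
                                  np.abs(coef))

    def test_reproducible_from_seed(self, surrogate_mesh):
        _, basis = surrogate_mesh
        coef = np.ones(basis.k)
        a = c.make_surrogates(coef, basis, n=150, seed=9)
        b = c.make_surrogates(coef, basis, n=150, seed=9)
        assert np.array_equal(a.signs, b.signs)

    def test_surrogate_fields_decorrelated_from_empirical(self, surrogate_mesh):
        _, basis = surrogate_mesh
        rng = np.random.default_rng(10)
        coef = rng.standard_normal(basis.k)
        emp = coef @ basis.eigenfunctions.T
        ens = c.make_surrogates(coef, basis, n=1000, seed=11)
        cors = np.array([np.corrcoef(ens.surrogate_fields(i)[0], emp)[0, 1]
                         for i in range(1000)])
        assert abs(cors.mean()) < 0.05

    def test_small_ensemble_warns(self, surrogate_mesh):
        _, basis = surrogate_mesh
        with pytest.warns(UserWarning, match="100"):
            c.make_surrogates(np.ones(basis.k), basis, n=10, seed=0)


class TestSplitHalf:
    def _maps(self, basis, rng, coef=None):
        coef = rng.standard_normal(basis.k) if coef is None else coef
        return coef, coef @ basis.eigenfunctions.T

    def test_identical_structured_maps_small_p(self, surrogate_mesh):
        _, basis = surrogate_mesh
        rng = np.random.default_rng(12)
        coef, m = self._maps(basis, rng)
        ens = c.make_surrogates(coef, basis, n=300, seed=13)
        surr = np.stack([ens.surrogate_fields(i)[0] for i in range(300)])
        res = c.splithalf_permutation(m, m, surr, surr)
        assert res.p_sum <= 2.0 / 300 + 1e-9
        assert res.z_capped  # r = 1 guard

    def test_independent_noise_p_centered_near_one(self, surrogate_mesh):
        _, basis = surrogate_mesh
        rng = np.random.default_rng(14)
        sums = []
        for _ in range(60):
            ca, ma = self._maps(basis, rng)
            cb, mb = self._maps(basis, rng)
            ea = c.make_surrogates(ca, basis, n=100,
                                   seed=int(rng.integers(2**31)))
            eb = c.make_surrogates(cb, basis, n=100,
                                   seed=int(rng.integers(2**31)))
            sa = np.stack([ea.surrogate_fields(i)[0] for i in range(100)])
            sb = np.stack([eb.surrogate_fields(i)[0] for i in range(100)])
            sums.append(c.splithalf_permutation(ma, mb, sa, sb).p_sum)
        assert 0.75 <= np.mean(sums) <= 1.25

    def test_null_p_uniform(self, surrogate_mesh):
        """Direction-wise split-half p values are uniform under the null."""
        _, basis = surrogate_mesh
        rng = np.random.default_rng(15)
        p1s = []
        for _ in range(150):
            ca, ma = self._maps(basis, rng)
            _, mb = self._maps(basis, rng)
            ea = c.make_surrogates(ca, basis, n=99,
                                   seed=int(rng.integers(2**31)))
            sa = np.stack([ea.surrogate_fields(i)[0] for i in range(99)])
            res = c.splithalf_permutation(ma, mb, sa, sa)
            p1s.append(res.p1)
        assert sps.kstest(p1s, "uniform").pvalue > 0.01


class TestSearchlight:
    def test_single_chunk_equals_global_permutation(self, surrogate_mesh):
        mesh, basis = surrogate_mesh
        rng = np.random.default_rng(16)
        coef = rng.standard_normal(basis.k)
        som = coef @ basis.eigenfunctions.T
        target = rng.standard_normal(mesh.n_vertices)
        ens = c.make_surrogates(coef, basis, n=200, seed=17)
        surr = np.stack([ens.surrogate_fields(i)[0] for i in range(200)])
        res = c.searchlight_alignment(som, target, mesh, surr,
                                      radius_mm=1000.0)
        # every chunk covers the whole mesh: all chunk stats identical
        assert np.allclose(res.chunk_r, res.chunk_r[0])
        r_global = np.corrcoef(som, target)[0, 1]
        assert np.isclose(res.chunk_r[0], r_global)

    def test_monotone_target_floors_p(self, surrogate_mesh):
        mesh, basis = surrogate_mesh
        rng = np.random.default_rng(18)
        coef = rng.standard_normal(basis.k)
        som = coef @ basis.eigenfunctions.T
        target = 2.0 * som + 1.0   # perfect monotone function
        ens = c.make_surrogates(coef, basis, n=300, seed=19)
        surr = np.stack([ens.surrogate_fields(i)[0] for i in range(300)])
        res = c.searchlight_alignment(som, target, mesh, surr, radius_mm=5.0)
        assert np.allclose(np.abs(res.chunk_r), 1.0)
        assert res.chunk_p_raw.max() <= 0.05

    def test_null_chunk_p_uniform_across_draws(self, surrogate_mesh):
        """Chunk p at a fixed location is uniform over independent null
        draws (chunk p values within one map are mutually dependent, so
        uniformity must be assessed across draws)."""
        mesh, basis = surrogate_mesh
        rng = np.random.default_rng(20)
        ps = []
        for _ in range(120):
            coef = rng.standard_normal(basis.k)
            som = coef @ basis.eigenfunctions.T
            target = rng.standard_normal(basis.k) @ basis.eigenfunctions.T
            ens = c.make_surrogates(coef, basis, n=150,
                                    seed=int(rng.integers(2 ** 31)))
            surr = np.stack([ens.surrogate_fields(i)[0] for i in range(150)])
            res = c.searchlight_alignment(som, target, mesh, surr,
                                          radius_mm=4.0)
            mid = np.argmin(np.abs(res.chunk_centers
                                   - mesh.n_vertices // 2))
            ps.append(res.chunk_p_raw[mid])
        assert sps.kstest(ps, "uniform").pvalue > 0.01

    def test_low_range_chunks_excluded(self, surrogate_mesh):
        mesh, basis = surrogate_mesh
        rng = np.random.default_rng(22)
        som = rng.standard_normal(mesh.n_vertices)
        target = np.zeros(mesh.n_vertices)
        target[:10] = np.linspace(0, 5, 10)   # variation only in one corner
        surr = rng.standard_normal((120, mesh.n_vertices))
        res = c.searchlight_alignment(som, target, mesh, surr,
                                      radius_mm=3.0, min_range=1.0)
        assert res.excluded_centers.size > 0
        assert np.isnan(res.vertex_min_p[res.excluded_centers]).sum() >= 0

    def test_protected_p_in_unit_interval(self, surrogate_mesh):
        mesh, basis = surrogate_mesh
        rng = np.random.default_rng(23)
        som = rng.standard_normal(mesh.n_vertices)
        target = rng.standard_normal(mesh.n_vertices)
        surr = rng.standard_normal((150, mesh.n_vertices))
        res = c.searchlight_alignment(som, target, mesh, surr, radius_mm=4.0)
        assert np.all(res.chunk_p > 0) and np.all(res.chunk_p <= 1)


class TestTFCE:
    def test_zero_map_identity(self, surrogate_mesh):
        mesh, _ = surrogate_mesh
        res = c.tfce_correct(np.zeros((5, mesh.n_vertices)), mesh,
                             n_perm=120, seed=0)
        assert np.all(res.tfce == 0)
        assert np.all(res.p_corrected >= 1.0 - 1e-12)

    def test_doubling_scores_strictly_increases_tfce(self, surrogate_mesh):
        mesh, _ = surrogate_mesh
        rng = np.random.default_rng(24)
        scores = rng.standard_normal((12, mesh.n_vertices))
        r1 = c.tfce_correct(scores, mesh, n_perm=120, seed=1)
        r2 = c.tfce_correct(2 * scores, mesh, n_perm=120, seed=1)
        nz = r1.tfce != 0
        assert np.all(np.abs(r2.tfce[nz]) > np.abs(r1.tfce[nz]))

    def test_corrected_p_floor(self, surrogate_mesh):
        mesh, _ = surrogate_mesh
        rng = np.random.default_rng(25)
        scores = rng.standard_normal((10, mesh.n_vertices)) + 2.0
        res = c.tfce_correct(scores, mesh, n_perm=150, seed=2)
        assert res.p_corrected.min() >= 1.0 / 151 - 1e-12

    def test_blob_detected_flat_noise_not(self):
        """A contiguous d_z >= 1 blob at n = 20 survives correction."""
        mesh = c.flat_patch_mesh(16.0, 16.0, 1.0)
        gd = geodesic_matrix(mesh)
        blob = gd[mesh.n_vertices // 2] < 4.0
        rng = np.random.default_rng(26)
        scores = rng.standard_normal((20, mesh.n_vertices)) + blob * 1.0
        res = c.tfce_correct(scores, mesh, n_perm=2000, alpha=0.01, seed=3)
        core = gd[mesh.n_vertices // 2] < 2.5
        assert res.significant[core].mean() >= 0.9
        assert res.significant[~blob].mean() <= 0.05


class TestColocalization:
    def test_everything_above_threshold_single_cluster(self, surrogate_mesh):
        mesh, basis = surrogate_mesh
        n_part = 20
        maps = np.ones((n_part, mesh.n_vertices, 2), dtype=bool)
        res = c.colocalization_clusters(maps, mesh, k_min=15, n_surr=40,
                                        basis_k=40, seed=0, basis=basis)
        assert len(res.clusters) == 1
        assert res.cluster_sums[0] == n_part * mesh.n_vertices

    def test_nvs_matches_double_loop_oracle(self, surrogate_mesh):
        mesh, basis = surrogate_mesh
        rng = np.random.default_rng(27)
        maps = rng.random((8, mesh.n_vertices, 2)) < 0.4
        res = c.colocalization_clusters(maps, mesh, k_min=8, n_surr=10,
                                        basis_k=40, seed=1, basis=basis)
        want = np.zeros(mesh.n_vertices, dtype=int)
        for v in range(mesh.n_vertices):
            for p in range(8):
                if maps[p, v, 0] and maps[p, v, 1]:
                    want[v] += 1
        assert np.array_equal(res.nvs, want)

    def test_independent_maps_rarely_cluster(self, surrogate_mesh):
        mesh, basis = surrogate_mesh
        rng = np.random.default_rng(28)
        n_part = 30
        # k_min at the upper binomial limit for p = 0.25 co-occurrence
        k_min = int(sps.binom.ppf(1 - 0.05 / mesh.n_vertices, n_part, 0.25)) + 1
        hits = 0
        for trial in range(10):
            maps = rng.random((n_part, mesh.n_vertices, 2)) < 0.5
            nvs = (maps[:, :, 0] & maps[:, :, 1]).sum(axis=0)
            hits += int((nvs >= k_min).any())
        assert hits <= 2  # empirical clusters are rare under independence

    def test_k_min_above_n_rejected(self, surrogate_mesh):
        mesh, basis = surrogate_mesh
        with pytest.raises(ValueError, match="k_min"):
            c.colocalization_clusters(
                np.ones((5, mesh.n_vertices, 2), dtype=bool), mesh,
                k_min=6, n_surr=5, basis=basis)


class TestBootstrapCoverage:
    def test_strong_effect_full_coverage(self):
        rng = np.random.default_rng(29)
        scores = rng.normal(3.0, 1.0, size=(40, 60))   # d_z = 3 everywhere
        res = c.bootstrap_coverage(scores, ["a"] * 30 + ["b"] * 30,
                                   n_boot=300, seed=0)
        for roi in ("a", "b"):
            mean, lo, hi = res.coverage[roi]
            assert lo >= 99.0 and hi == 100.0

    def test_pure_noise_coverage_small(self):
        rng = np.random.default_rng(30)
        scores = rng.standard_normal((40, 400))
        res = c.bootstrap_coverage(scores, ["roi"] * 400, n_boot=200, seed=1)
        mean, lo, hi = res.coverage["roi"]
        # resampling a null sample inflates the nominal 2.5% rate somewhat,
        # but coverage stays an order of magnitude below a true effect's
        assert hi <= 20.0
        assert lo <= mean <= hi

    def test_fixed_seed_identical(self):
        rng = np.random.default_rng(31)
        scores = rng.normal(0.3, 1.0, (25, 50))
        a = c.bootstrap_coverage(scores, ["r"] * 50, n_boot=150, seed=7)
        b = c.bootstrap_coverage(scores, ["r"] * 50, n_boot=150, seed=7)
        assert a.coverage == b.coverage

    def test_empty_roi_skipped_and_exclusion(self):
        rng = np.random.default_rng(32)
        scores = rng.normal(1.0, 1.0, (20, 30))
        exclude = np.zeros(30, dtype=bool)
        exclude[:10] = True   # ROI "src" fully excluded
        res = c.bootstrap_coverage(scores, ["src"] * 10 + ["tgt"] * 20,
                                   n_boot=50, seed=2, exclude=exclude)
        assert "src" in res.skipped_rois
        assert "tgt" in res.coverage

    def test_correlation_difference_detects_matching_map(self):
        rng = np.random.default_rng(33)
        ref = rng.standard_normal(80)
        scores = np.tile(ref, (30, 1)) + rng.standard_normal((30, 80)) * 0.5
        other = rng.standard_normal(80)
        res = c.bootstrap_coverage(
            scores, ["r"] * 80, n_boot=200, seed=3,
            ref_maps={"body": ref, "place": other}, ref_key="body")
        assert res.corr_diff_p["place"] < 0.05
        lo, hi = res.corr_diff_ci["place"]
        assert lo > 0
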