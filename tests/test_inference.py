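"""Contrast inference, Monte-Carlo cluster thresholds, reports, ANCOVA."""

import numpy as np
import pytest
from scipy import ndimage, stats

import restica as r
from restica.core import StatMap, VolumeGrid
from restica.preprocess import T_CAP

CONTRAST = r.ContrastSpec(dict(r.DEFAULT_CONTRAST))
CONDS = ["WD-T3", "WD-T1", "FD-T1", "FD-T3"]


def random_maps(grid, n_subjects, rng, offset=None):
    maps = {}
    for i in range(n_subjects):
        maps[f"sub{i:02d}"] = {
            c: rng.standard_normal(grid.n_voxels) + (offset[i] if offset is not None else 0.0)
            for c in CONDS
        }
    return maps


class TestContrastTmap:
    def test_identical_condition_maps_give_zero(self, grid):
        rng = np.random.default_rng(0)
        maps = {}
        for i in range(5):
            m = rng.standard_normal(grid.n_voxels)
            maps[f"sub{i:02d}"] = {c: m.copy() for c in CONDS}
        tmap = r.contrast_tmap(maps, CONTRAST, grid)
        np.testing.assert_array_equal(tmap.values, 0.0)

    def test_uniform_shift_gives_capped_positive_t(self, grid):
        rng = np.random.default_rng(1)
        maps = {}
        for i in range(5):
            base = rng.standard_normal(grid.n_voxels)
            maps[f"sub{i:02d}"] = {c: base.copy() for c in CONDS}
            maps[f"sub{i:02d}"]["WD-T3"] = base + 0.7  # same delta for all subjects
        tmap = r.contrast_tmap(maps, CONTRAST, grid)
        assert tmap.capped
        np.testing.assert_array_equal(tmap.values, T_CAP)

    def test_matches_ols_intercept_oracle(self, grid):
        """t equals the OLS t of the contrast scores on an intercept, and the
        numerator equals the GLM contrast estimate with subject effects."""
        rng = np.random.default_rng(2)
        n = 8
        maps = random_maps(grid, n, rng)
        tmap = r.contrast_tmap(maps, CONTRAST, grid)
        w = CONTRAST.weights
        v = 11
        y = np.array([[maps[f"sub{i:02d}"][c][v] for c in CONDS] for i in range(n)])
        c_s = y @ np.array([w[c] for c in CONDS])
        # intercept-only OLS: beta = mean, se = sqrt(RSS / (n-1) / n)
        beta = c_s.mean()
        se = np.sqrt(((c_s - beta) ** 2).sum() / (n - 1) / n)
        assert tmap.values[v] == pytest.approx(beta / se, abs=1e-8)
        # GLM with subject + condition effects reproduces the point estimate
        subj = np.kron(np.eye(n), np.ones((4, 1)))
        cond = np.kron(np.ones((n, 1)), np.eye(4))
        x = np.hstack([subj, cond])
        bhat = np.linalg.pinv(x) @ y.ravel()
        west = sum(w[c] * bhat[n + j] for j, c in enumerate(CONDS))
        assert west == pytest.approx(beta, abs=1e-8)

    def test_invariant_to_subject_constant_maps(self, grid):
        rng = np.random.default_rng(3)
        maps = random_maps(grid, 6, rng)
        t0 = r.contrast_tmap(maps, CONTRAST, grid).values
        offsets = rng.standard_normal(6) * 10
        shifted = {
            s: {c: m + offsets[i] for c, m in cm.items()}
            for i, (s, cm) in enumerate(sorted(maps.items()))
        }
        t1 = r.contrast_tmap(shifted, CONTRAST, grid).values
        np.testing.assert_allclose(t0, t1, atol=1e-6)

    def test_missing_condition_names_subject(self, grid):
        rng = np.random.default_rng(4)
        maps = random_maps(grid, 4, rng)
        del maps["sub02"]["FD-T3"]
        with pytest.raises(ValueError, match="sub02"):
            r.contrast_tmap(maps, CONTRAST, grid)

    def test_weights_must_sum_to_zero(self):
        with pytest.raises(ValueError, match="sum to 0"):
            r.ContrastSpec({"WD-T3": 3.0, "WD-T1": -1.0})


class TestSmoothness:
    def test_white_noise_fwhm_near_voxel_size(self, study_grid):
        rng = np.random.default_rng(5)
        estimates = [
            r.estimate_smoothness(rng.standard_normal(study_grid.n_voxels), study_grid)
            for _ in range(20)
        ]
        # derivative-variance estimator gives 2.3548/2 = 1.177 voxels on white noise
        assert abs(np.mean(estimates) - study_grid.voxel_size_mm) / study_grid.voxel_size_mm < 0.2

    def test_recovers_known_6mm_kernel(self, study_grid):
        rng = np.random.default_rng(6)
        sigma_vox = 6.0 / 2.3548 / study_grid.voxel_size_mm
        estimates = []
        for _ in range(10):
            field = ndimage.gaussian_filter(rng.standard_normal(study_grid.dims), sigma_vox)
            estimates.append(r.estimate_smoothness(study_grid.from_volume(field), study_grid))
        assert abs(np.mean(estimates) - 6.0) / 6.0 < 0.2

    def test_monotone_in_applied_smoothing(self, study_grid):
        rng = np.random.default_rng(7)
        noise = rng.standard_normal(study_grid.dims)
        prev = 0.0
        for sigma in (0.5, 1.0, 1.5, 2.0):
            est = r.estimate_smoothness(
                study_grid.from_volume(ndimage.gaussian_filter(noise, sigma)), study_grid)
            assert est > prev
            prev = est

    def test_constant_map_rejected(self, grid):
        with pytest.raises(ValueError, match="constant"):
            r.estimate_smoothness(np.ones(grid.n_voxels), grid)


class TestClusterThresholdMC:
    def test_matches_independent_bernoulli_oracle_at_zero_fwhm(self):
        g = VolumeGrid((10, 10, 10), 3.0, np.ones((10, 10, 10), dtype=bool))
        k = r.cluster_threshold_mc(g, fwhm_mm=0.0, voxel_p=0.01, alpha=0.05,
                                   n_iter=2000, seed=1)
        # brute-force oracle: independent Bernoulli(0.01) exceedance fields
        rng = np.random.default_rng(991)
        structure = ndimage.generate_binary_structure(3, 1)
        max_sizes = np.empty(2000, dtype=int)
        for i in range(2000):
            field = rng.random((10, 10, 10)) < 0.01
            labels, n = ndimage.label(field, structure=structure)
            max_sizes[i] = np.bincount(labels.ravel())[1:].max() if n else 0
        k_oracle = 1
        while (max_sizes >= k_oracle).mean() >= 0.05:
            k_oracle += 1
        assert abs(k - k_oracle) <= 1

    def test_stricter_alpha_never_lowers_threshold(self, study_grid):
        k5 = r.cluster_threshold_mc(study_grid, 6.0, alpha=0.05, n_iter=300, seed=2)
        k1 = r.cluster_threshold_mc(study_grid, 6.0, alpha=0.01, n_iter=300, seed=2)
        assert k1 >= k5

    def test_network_count_adjustment(self):
        assert r.network_adjusted_alpha(0.05, 7) == pytest.approx(0.05 / 7)
        assert r.network_adjusted_alpha(0.05, 1) == 0.05


class TestExtractClusters:
    def make_tmap(self, grid, values):
        return StatMap(values, df=7, grid=grid, tail="two")

    def test_extension_is_voxel_count_times_voxel_volume(self, grid):
        vol = np.zeros(grid.dims)
        blob = np.argwhere(grid.brain_mask)[:13]  # consecutive C-order voxels
        # build a face-connected 13-voxel bar instead: walk along y
        x0, y0, z0 = 8, 3, 6
        coords = [(x0, y0 + i // 2, z0 + i % 2) for i in range(13)]
        for c in coords:
            vol[c] = 10.0
        tmap = self.make_tmap(grid, grid.from_volume(vol))
        clusters = r.extract_clusters(tmap, voxel_p=0.01, min_size=1)
        assert len(clusters) == 1
        assert clusters[0].n_voxels == 13
        assert clusters[0].extension_mm3 == pytest.approx(13 * 27.0)
        assert clusters[0].sign == "enhancement"

    def test_diagonal_voxels_split_under_face_connectivity(self, grid):
        vol = np.zeros(grid.dims)
        vol[8, 8, 6] = 10.0
        vol[9, 9, 6] = 10.0  # touches only on an edge
        clusters = r.extract_clusters(self.make_tmap(grid, grid.from_volume(vol)),
                                      voxel_p=0.01, min_size=1)
        assert len(clusters) == 2

    def test_signs_reported_separately_and_min_size_drops(self, grid):
        vol = np.zeros(grid.dims)
        vol[8, 8, 6] = vol[8, 9, 6] = 10.0
        vol[4, 4, 6] = -10.0
        tmap = self.make_tmap(grid, grid.from_volume(vol))
        both = r.extract_clusters(tmap, voxel_p=0.01, min_size=1)
        assert {c.sign for c in both} == {"enhancement", "suppression"}
        only_big = r.extract_clusters(tmap, voxel_p=0.01, min_size=2)
        assert len(only_big) == 1 and only_big[0].sign == "enhancement"

    def test_center_of_mass_in_mm(self, grid):
        vol = np.zeros(grid.dims)
        vol[8, 8, 6] = vol[8, 9, 6] = 10.0  # equal weights
        c = r.extract_clusters(self.make_tmap(grid, grid.from_volume(vol)),
                               voxel_p=0.01, min_size=1)[0]
        assert c.center_of_mass_mm == (24.0, 25.5, 18.0)


class TestRegionalScores:
    def make_region(self, grid, idx):
        return r.RegionCluster(voxel_indices=np.asarray(idx), center_of_mass_mm=(0, 0, 0),
                               extension_mm3=27.0 * len(idx), avg_t=1.0, max_t=1.0,
                               sign="enhancement")

    def test_single_voxel_and_constant_region(self, grid):
        rng = np.random.default_rng(8)
        m = rng.standard_normal(grid.n_voxels)
        maps = {"sub00": {"WD-T2": m, "WD-T3": np.full(grid.n_voxels, 2.5)}}
        tbl = r.regional_scores(maps, self.make_region(grid, [42]), grid)
        assert tbl.loc[tbl["scan"] == "WD-T2", "score"].iloc[0] == pytest.approx(m[42])
        assert tbl.loc[tbl["scan"] == "WD-T3", "score"].iloc[0] == pytest.approx(2.5)

    def test_mean_oracle_on_random_region(self, grid):
        rng = np.random.default_rng(9)
        m = rng.standard_normal(grid.n_voxels)
        idx = rng.choice(grid.n_voxels, 25, replace=False)
        maps = {"sub00": {"WD-T3": m}}
        tbl = r.regional_scores(maps, self.make_region(grid, idx), grid)
        assert tbl["score"].iloc[0] == pytest.approx(m[idx].mean(), abs=1e-12)


class TestAncova:
    def make_table(self, scores, vas, scans):
        import pandas as pd
        return pd.DataFrame({
            "subject": [f"sub{i:02d}" for i in range(len(scores))],
            "scan": scans, "score": scores, "vas": vas,
        })

    def test_exact_linear_dependence(self):
        rng = np.random.default_rng(10)
        vas = rng.uniform(20, 120, 12)
        scores = 0.3 + 0.02 * vas
        tbl = self.make_table(scores, vas, ["WD-T2"] * 6 + ["WD-T3"] * 6)
        res = r.ancova_scores(tbl)
        assert res["F_vas"] > 1e6
        assert res["F_interaction"] == pytest.approx(0.0, abs=1e-6)

    def test_matches_statsmodels_partial_f_oracle(self):
        import statsmodels.formula.api as smf
        from statsmodels.stats.anova import anova_lm

        rng = np.random.default_rng(11)
        vas = rng.uniform(0, 100, 12)
        scores = rng.standard_normal(12) + 0.01 * vas
        tbl = self.make_table(scores, vas, ["WD-T2"] * 6 + ["WD-T3"] * 6)
        res = r.ancova_scores(tbl)
        m_scan = smf.ols("score ~ C(scan)", tbl).fit()
        m_add = smf.ols("score ~ C(scan) + vas", tbl).fit()
        m_full = smf.ols("score ~ C(scan) * vas", tbl).fit()
        f_vas = float(anova_lm(m_scan, m_add)["F"].iloc[1])
        f_int = float(anova_lm(m_add, m_full)["F"].iloc[1])
        assert res["F_vas"] == pytest.approx(f_vas, abs=1e-8)
        assert res["F_interaction"] == pytest.approx(f_int, abs=1e-8)

    def test_null_covariate_rejection_calibrated(self):
        """With no true VAS effect the covariate test rejects at ~5%."""
        rng = np.random.default_rng(12)
        rejections = 0
        n_rep = 500
        for _ in range(n_rep):
            vas = rng.uniform(0, 100, 16)
            scores = np.concatenate([rng.standard_normal(8), 1.0 + rng.standard_normal(8)])
            tbl = self.make_table(scores, vas, ["WD-T2"] * 8 + ["WD-T3"] * 8)
            rejections += r.ancova_scores(tbl)["p_vas"] < 0.05
        assert 0.03 <= rejections / n_rep <= 0.07

    def test_collinear_design_rejected(self):
        tbl = self.make_table(np.arange(8.0), np.ones(8), ["WD-T2"] * 4 + ["WD-T3"] * 4)
        with pytest.raises(ValueError, match="collinear"):
            r.ancova_scores(tbl)


class TestEndToEndRecovery:
    def test_planted_effects_recovered_with_correct_signs(self, group_study, study_grid):
        """Single-seed full pipeline: the enhancement region surfaces as a
        positive cluster, the suppression region as a negative one."""
        scans, confounds, behavior, truth = group_study
        res = r.run_study(scans, confounds, behavior=behavior,
                          reference_maps=truth.atlas.maps[:2],
                          reference_labels=["net0", "net1"], k=10,
                          cluster_alpha=0.05, n_networks_tested=5,
                          mc_iter=300, seed=2024)
        assert res.adjusted_alpha == pytest.approx(0.01)
        enh = truth.region_vector(0)
        sup = truth.region_vector(1)
        pos = [c for c in res.networks["net0"].clusters if c.sign == "enhancement"]
        neg = [c for c in res.networks["net1"].clusters if c.sign == "suppression"]
        assert max(r.dice(c.region_mask(study_grid), enh) for c in pos) >= 0.5
        assert max(r.dice(c.region_mask(study_grid), sup) for c in neg) >= 0.5
        # never the reverse sign inside the planted regions
        for c in res.networks["net0"].clusters:
            if c.sign == "suppression":
                assert r.dice(c.region_mask(study_grid), enh) < 0.5
        for c in res.networks["net1"].clusters:
            if c.sign == "enhancement":
                assert r.dice(c.region_mask(study_grid), sup) < 0.5
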