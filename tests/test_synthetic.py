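"""Generator contracts: determinism, planted-effect confinement, spectra."""

import numpy as np
import pytest

import restica as r


class TestMakeAtlas:
    def test_deterministic(self, grid):
        a1 = r.make_atlas(grid, 3, fwhm_mm=6.0, seed=5)
        a2 = r.make_atlas(grid, 3, fwhm_mm=6.0, seed=5)
        np.testing.assert_array_equal(a1.maps, a2.maps)
        np.testing.assert_array_equal(a1.core_masks, a2.core_masks)

    def test_zero_fwhm_gives_binary_indicator_maps(self, grid):
        atlas = r.make_atlas(grid, 3, fwhm_mm=0.0, seed=5)
        for m in atlas.maps:
            assert set(np.unique(m)) <= {0.0, 1.0}

    def test_seven_disjoint_cores_on_study_grid(self, study_grid):
        atlas = r.make_atlas(study_grid, 7, fwhm_mm=6.0, seed=3)
        for i in range(7):
            assert atlas.core_masks[i].any()
            for j in range(i + 1, 7):
                assert not (atlas.core_masks[i] & atlas.core_masks[j]).any()

    def test_cores_inside_map_support(self, atlas):
        for k in range(atlas.n_networks):
            assert not (atlas.core_masks[k] & ~atlas.support(k)).any()

    def test_too_small_grid_fails_naming_constraint(self):
        g = r.VolumeGrid((4, 4, 4), 3.0, np.ones((4, 4, 4), dtype=bool))
        with pytest.raises(ValueError, match="blob|cores"):
            r.make_atlas(g, 5, fwhm_mm=0.0, seed=0)


class TestSimulateScan:
    def test_single_network_proportionality(self, atlas):
        amps = np.array([1.0, 0.0, 0.0])
        scan, _, truth = r.simulate_scan(
            atlas, [], "FD-T1", n_vol=64, noise_sd=0.0, seed=4,
            amplitudes=amps, physio_amp=0.0, drift_amp=0.0,
        )
        expected = np.outer(truth.courses[0], atlas.maps[0])
        np.testing.assert_allclose(scan.data, expected, atol=1e-12)

    def test_planted_gain_scales_regional_sd_exactly(self, atlas):
        region = atlas.grid.to_volume(atlas.core_masks[0].astype(float)) > 0.5
        eff = r.EffectSpec(0, region, {"WD-T3": 1.5})
        scan, _, _ = r.simulate_scan(
            atlas, [eff], "WD-T3", n_vol=64, noise_sd=0.0, seed=4,
            physio_amp=0.0, drift_amp=0.0,
        )
        # courses are orthonormal, so voxel SD = sqrt(sum_k (g_k w_k)^2)
        gains = np.ones_like(atlas.maps)
        gains[0, atlas.grid.from_volume(region)] = 1.5
        expected_sd = np.sqrt(((gains * atlas.maps) ** 2).sum(axis=0))
        np.testing.assert_allclose(scan.data.std(axis=0), expected_sd, atol=1e-10)

    def test_effect_confined_to_region(self, atlas):
        """Outside the target region the data are bit-identical across gains."""
        region = atlas.grid.to_volume(atlas.core_masks[0].astype(float)) > 0.5
        rvec = atlas.grid.from_volume(region)
        out = {}
        for gain in (1.0, 2.0):
            eff = r.EffectSpec(0, region, {"WD-T3": gain})
            scan, _, _ = r.simulate_scan(atlas, [eff], "WD-T3", n_vol=64,
                                         noise_sd=0.0, seed=4)
            out[gain] = scan.data
        np.testing.assert_array_equal(out[1.0][:, ~rvec], out[2.0][:, ~rvec])
        assert not np.array_equal(out[1.0][:, rvec], out[2.0][:, rvec])

    def test_course_power_confined_to_band(self, atlas):
        _, _, truth = r.simulate_scan(atlas, [], "FD-T1", n_vol=128, seed=9)
        spectra = np.abs(np.fft.rfft(truth.courses, axis=1)) ** 2
        freqs = np.fft.rfftfreq(128, d=2.0)
        in_band = (freqs >= 0.01) & (freqs <= 0.1)
        frac = spectra[:, in_band].sum() / spectra.sum()
        assert frac >= 0.99

    def test_confounds_returned_as_mixed(self, atlas):
        """Order-2 regressors built from the returned phases remove the physio term."""
        base, conf, _ = r.simulate_scan(atlas, [], "FD-T1", n_vol=64, noise_sd=0.0,
                                        seed=4, physio_amp=0.0, drift_amp=0.0)
        noisy, conf2, _ = r.simulate_scan(atlas, [], "FD-T1", n_vol=64, noise_sd=0.0,
                                          seed=4, physio_amp=0.5, drift_amp=0.0)
        physio = r.build_physio_regressors(conf2.cardiac_phase, conf2.resp_phase, order=2)
        cleaned = r.regress_confounds(noisy, physio)
        reference = r.regress_confounds(base, physio)
        np.testing.assert_allclose(cleaned.data, reference.data, atol=1e-8)

    def test_unknown_condition_rejected(self, atlas):
        with pytest.raises(ValueError, match="condition"):
            r.simulate_scan(atlas, [], "XX-T9", n_vol=64, seed=0)

    def test_effect_region_outside_support_rejected(self, atlas):
        region = np.zeros(atlas.grid.dims, dtype=bool)
        outside = atlas.grid.to_volume((~atlas.support(0)).astype(float)) > 0.5
        region[outside] = True
        with pytest.raises(ValueError, match="support"):
            r.EffectSpec(0, region, {"WD-T3": 2.0}).validate_against(atlas)


class TestGroupStudy:
    def test_forty_scans_each_reproducible(self, group_study, study_grid):
        scans, _, _, truth = group_study
        assert len(scans) == 40
        assert len({(s.subject, s.condition) for s in scans}) == 40
        # any single scan is reproducible from (seed, subject, condition)
        scan = next(s for s in scans if s.subject == "sub03" and s.condition == "WD-T3")
        si = truth.subject_ids.index("sub03")
        subj_atlas = r.jitter_atlas(truth.atlas, truth.subject_shifts[si])
        redo, _, _ = r.simulate_scan(
            subj_atlas, truth.effects, "WD-T3", n_vol=120,
            seed=r.scan_seed(truth.seed, si, "WD-T3"),
            subject="sub03", amplitudes=truth.subject_amp_factors[si],
        )
        np.testing.assert_array_equal(scan.data, redo.data)

    def test_null_study_is_marked_and_exchangeable(self, study_grid):
        atlas = r.make_atlas(study_grid, 3, seed=1)
        region = study_grid.to_volume(atlas.core_masks[0].astype(float)) > 0.5
        null_effects = [r.EffectSpec(0, region, {"WD-T3": 1.0})]
        scans, _, _, truth = r.simulate_group_study(
            n_subjects=3, atlas=atlas, effects=null_effects,
            n_vol=48, noise_sd=0.0, physio_amp=0.0, drift_amp=0.0, seed=5,
        )
        assert truth.is_null
        # regional SD identical across all conditions for each subject
        rvec = study_grid.from_volume(region)
        for sid in truth.subject_ids:
            sds = [s.data.std(axis=0)[rvec].mean() for s in scans if s.subject == sid]
            np.testing.assert_allclose(sds, sds[0], atol=1e-10)

    def test_gain_schedule_monotone_in_truth(self, study_grid):
        atlas = r.make_atlas(study_grid, 3, seed=1)
        region = study_grid.to_volume(atlas.core_masks[0].astype(float)) > 0.5
        eff = [r.EffectSpec(0, region, {"WD-T2": 1.25, "WD-T3": 1.5})]
        _, _, _, truth = r.simulate_group_study(
            n_subjects=3, atlas=atlas, effects=eff, n_vol=48, seed=5,
        )
        amp = truth.realizations.pivot_table(
            index="subject", columns="condition", values="regional_amplitude"
        )
        assert (amp["WD-T1"] < amp["WD-T2"]).all()
        assert (amp["WD-T2"] < amp["WD-T3"]).all()

    def test_behavior_couples_to_planted_gain(self, group_study):
        _, _, behavior, _ = group_study
        pooled = r.pooled_exhaustion_table(behavior)
        by_cond = pooled.groupby(pooled["day"] + "-" + pooled["timepoint"])["exhaustion"].mean()
        assert by_cond["WD-T3"] > by_cond["WD-T2"] > by_cond["WD-T1"]
        assert by_cond["WD-T3"] > by_cond["FD-T3"]
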