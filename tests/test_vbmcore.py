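"""Smoothing, volumes, and the single-case / paired t statistics."""

import numpy as np
import pytest
from scipy import stats

from mp2vbm.segment import fit_segmentation
from mp2vbm.vbmcore import (SingleCaseTTest, SmoothingSpec, analysis_mask,
                            compute_tiv, individual_tmap, paired_tmap,
                            smooth_volume, tissue_volume)


class TestSmoothing:
    def test_sigma_from_fwhm(self):
        spec = SmoothingSpec(fwhm=4.0, voxel_size=1.0)
        assert spec.sigma_voxels == pytest.approx(4.0 / 2.3548200450309493)
        assert SmoothingSpec(8.0, 2.0).sigma_voxels == pytest.approx(
            SmoothingSpec(4.0, 1.0).sigma_voxels)

    def test_uniform_input_unchanged(self):
        vol = np.full((12, 12, 12), 3.7)
        out = smooth_volume(vol, SmoothingSpec(8.0, 2.0))
        assert np.allclose(out, 3.7)

    def test_unit_impulse_mass_conserved(self):
        vol = np.zeros((21, 21, 21))
        vol[10, 10, 10] = 1.0
        out = smooth_volume(vol, SmoothingSpec(6.0, 2.0))
        assert out.sum() == pytest.approx(1.0, abs=1e-9)

    def test_interior_supported_input_conserves_mass(self, rng):
        vol = np.zeros((24, 24, 24))
        vol[9:15, 9:15, 9:15] = rng.random((6, 6, 6))
        out = smooth_volume(vol, SmoothingSpec(4.0, 2.0))
        assert out.sum() == pytest.approx(vol.sum(), rel=1e-9)

    def test_invalid_fwhm_rejected(self):
        with pytest.raises(ValueError):
            SmoothingSpec(fwhm=0.0, voxel_size=1.0)


class TestVolumes:
    @pytest.mark.parametrize(
        "n_vox, value, voxel_size, expected_ml",
        [(1000, 1.0, 1.0, 1.0), (500, 0.0, 1.0, 0.0), (500, 0.5, 2.0, 2.0)],
    )
    def test_tissue_volume(self, n_vox, value, voxel_size, expected_ml):
        vol = np.full((n_vox, 1, 1), value)
        assert tissue_volume(vol, voxel_size) == pytest.approx(expected_ml)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            tissue_volume(np.full((2, 2, 2), 1.5), 1.0)

    def test_tiv_additivity_exact(self):
        report = compute_tiv(600.0, 500.0, 300.0)
        assert report.tiv_ml == 600.0 + 500.0 + 300.0
        assert compute_tiv(0, 0, 0).tiv_ml == 0

    def test_negative_volume_rejected(self):
        with pytest.raises(ValueError):
            compute_tiv(-1.0, 0.0, 0.0)


class TestAnalysisMask:
    def test_threshold_zero_keeps_variance_positive_voxels(self, rng):
        maps = [rng.random((6, 6, 6)) + 0.5 for _ in range(4)]
        mask = analysis_mask(maps, threshold=0.0)
        stack = np.stack(maps)
        assert np.array_equal(mask, stack.var(axis=0) > 0)

    def test_impossible_threshold_rejected(self, rng):
        maps = [rng.random((6, 6, 6)) for _ in range(3)]
        with pytest.raises(ValueError):
            analysis_mask(maps, threshold=1.0)


class TestIndividualTMap:
    def test_hand_computed_value(self):
        shape = (3, 3, 3)
        controls = [np.full(shape, v) for v in (1.0, 2.0, 3.0)]
        # break the constant variance away from the probe voxel
        for i, c in enumerate(controls):
            c[0, 0, 0] = [0.9, 2.0, 3.1][i]
        subject = np.full(shape, 4.0)
        mask = np.ones(shape, dtype=bool)
        tmap = individual_tmap(subject, controls, mask)
        assert tmap.df == 2
        assert tmap.t[1, 1, 1] == pytest.approx(2.0 / np.sqrt(4.0 / 3.0), abs=1e-12)

    def test_subject_at_control_mean_gives_zero(self, rng):
        controls = [rng.normal(size=(4, 4, 4)) for _ in range(5)]
        subject = np.mean(controls, axis=0)
        mask = np.ones((4, 4, 4), dtype=bool)
        tmap = individual_tmap(subject, controls, mask)
        assert np.allclose(tmap.t[tmap.mask], 0.0, atol=1e-12)

    def test_direction_negates_map(self, rng):
        controls = [rng.normal(size=(4, 4, 4)) for _ in range(5)]
        subject = rng.normal(size=(4, 4, 4))
        mask = np.ones((4, 4, 4), dtype=bool)
        inc = individual_tmap(subject, controls, mask, "increase")
        dec = individual_tmap(subject, controls, mask, "decrease")
        assert np.allclose(inc.t, -dec.t)

    def test_subject_in_control_set_rejected(self, rng):
        controls = [rng.normal(size=(4, 4, 4)) for _ in range(4)]
        mask = np.ones((4, 4, 4), dtype=bool)
        with pytest.raises(ValueError, match="control set"):
            individual_tmap(controls[1], controls, mask)

    def test_matches_two_group_glm_oracle(self, rng):
        """The single-case t equals the two-group GLM with group sizes 1, n."""
        n = 6
        controls = [rng.normal(size=(5, 5, 5)) for _ in range(n)]
        subject = rng.normal(size=(5, 5, 5))
        mask = np.ones((5, 5, 5), dtype=bool)
        tmap = individual_tmap(subject, controls, mask)

        design = np.column_stack([np.ones(n + 1), np.r_[np.zeros(n), 1.0]])
        xtx_inv = np.linalg.inv(design.T @ design)
        contrast = np.array([0.0, 1.0])
        for idx in np.ndindex(5, 5, 5):
            y = np.r_[[c[idx] for c in controls], subject[idx]]
            beta = xtx_inv @ design.T @ y
            resid = y - design @ beta
            sigma2 = resid @ resid / (n + 1 - 2)
            se = np.sqrt(sigma2 * contrast @ xtx_inv @ contrast)
            assert tmap.t[idx] == pytest.approx(beta[1] / se, abs=1e-10)
        assert tmap.df == n - 1

    def test_estimator_interface(self, rng):
        X = rng.normal(size=(6, 50))
        est = SingleCaseTTest().fit(X)
        assert est.df_ == 5
        t = est.transform(rng.normal(size=(2, 50)))
        assert t.shape == (2, 50)


class TestPairedTMap:
    def test_identical_maps_fully_masked(self, rng):
        maps = [rng.normal(size=(4, 4, 4)) for _ in range(3)]
        mask = np.ones((4, 4, 4), dtype=bool)
        with pytest.raises(ValueError, match="variance"):
            paired_tmap(maps, [m.copy() for m in maps], mask)

    def test_constant_offset_zero_variance_masked(self, rng):
        # dyadic-rational values keep the per-subject offset exactly constant
        a = [rng.integers(0, 16, size=(4, 4, 4)) / 4.0 for _ in range(4)]
        b = [m + 1.0 for m in a]
        # make one voxel's differences vary so the map is not degenerate
        b[0][0, 0, 0] += 0.5
        mask = np.ones((4, 4, 4), dtype=bool)
        tmap, _ = paired_tmap(a, b, mask)
        assert tmap.mask.sum() == 1

    def test_bonferroni_threshold_value(self, rng):
        a = [rng.normal(size=(5, 5, 5)) for _ in range(8)]
        b = [rng.normal(size=(5, 5, 5)) for _ in range(8)]
        mask = np.ones((5, 5, 5), dtype=bool)
        tmap, t_fwe = paired_tmap(a, b, mask)
        m = int(tmap.mask.sum())
        assert t_fwe == pytest.approx(stats.t.isf(0.05 / (2 * m), 7))

    def test_mismatched_lengths_rejected(self, rng):
        maps = [rng.normal(size=(3, 3, 3)) for _ in range(3)]
        with pytest.raises(ValueError):
            paired_tmap(maps, maps[:2], np.ones((3, 3, 3), dtype=bool))

    def test_channel_set_difference_concentrates_in_dura_shell(self, small_atlas,
                                                               tiny_cohort):
        """GM maps from a T1-only vs a T1+FLAIR segmentation differ mainly at
        the dura confounder, mirroring how adding FLAIR reassigns meninges."""
        _, subjects, atlas = tiny_cohort
        controls = [s for s in subjects if s.group == "control"]
        seg_mask = atlas.mask | controls[0].dura_mask
        gm_t1, gm_mc = [], []
        for s in controls:
            ch = s.channels.channels
            _, tpm1, _ = fit_segmentation([ch["T1"]], seg_mask, seed=s.seed,
                                          voxel_size=2.0)
            _, tpm2, _ = fit_segmentation([ch["T1"], ch["FLAIR"]], seg_mask,
                                          seed=s.seed, voxel_size=2.0)
            spec = SmoothingSpec(4.0, 2.0)
            gm_t1.append(smooth_volume(tpm1.gm, spec))
            gm_mc.append(smooth_volume(tpm2.gm, spec))
        tmap, t_fwe = paired_tmap(gm_t1, gm_mc, seg_mask)
        supra = (np.abs(tmap.t) >= t_fwe) & tmap.mask
        assert supra.any()
        from scipy.ndimage import binary_dilation

        shell = binary_dilation(controls[0].dura_mask, iterations=2)
        assert (supra & shell).sum() / supra.sum() > 0.5
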