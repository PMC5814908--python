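"""Ghost-band construction, phase unwrapping, the reference-based
estimators and the referenceless exhaustive searches."""

import warnings

import numpy as np
import pytest

from epighost import (
    AcquisitionParams,
    GhostBands,
    ImageGrid,
    LowSnrWarning,
    PhantomSpec,
    PhaseCoeffs,
    RoiSet,
    SearchConfig,
    acquire_epi,
    acquire_integrated_echoes,
    acquire_reference,
    apply_phase_error,
    apply_workflow,
    build_ghost_bands,
    correct_with_coeffs,
    estimate_from_integrated_echoes,
    estimate_from_reference,
    ghosting_level,
    make_dynamic_series,
    make_phantom,
    phase_unwrap_1d,
    reconstruct,
    scale_reference_coeffs,
    search_1d,
    search_2d,
)
from epighost.model import GAMMA_RATIO_C13_H1
from epighost.simulate import noise_sd_for_target_snr

from conftest import full_kspace


class TestBuildGhostBands:
    def test_bands_surround_object_extent(self):
        mask = np.zeros((32, 32), bool)
        mask[:, 10:21] = True  # object spans PE lines 10..20
        bands = build_ghost_bands(mask)
        cols = np.flatnonzero(bands.mask.any(axis=0))
        assert list(cols) == list(range(0, 10)) + list(range(21, 32))
        assert bands.mask[:, cols].all()

    def test_object_spanning_all_lines_raises(self):
        with pytest.raises(ValueError, match="manually"):
            build_ghost_bands(np.ones((32, 32), bool))

    def test_single_roi_over_dual_phantom(self):
        mask = np.zeros((32, 32), bool)
        mask[:, 6:13] = True
        mask[:, 18:26] = True  # two blobs, one enclosing ROI
        bands = build_ghost_bands(mask)
        cols = np.flatnonzero(bands.mask.any(axis=0))
        assert list(cols) == list(range(0, 6)) + list(range(26, 32))

    def test_margin_shrinks_bands(self):
        mask = np.zeros((32, 32), bool)
        mask[:, 10:21] = True
        bands = build_ghost_bands(mask, margin_rows=2)
        cols = np.flatnonzero(bands.mask.any(axis=0))
        assert list(cols) == list(range(0, 8)) + list(range(23, 32))


class TestPhaseUnwrap:
    def test_smooth_slope_passes_through(self):
        phase = 0.1 * np.arange(50)
        res = phase_unwrap_1d(np.mod(phase + np.pi, 2 * np.pi) - np.pi,
                              np.ones(50))
        assert np.abs(res.phase - phase).max() < 1e-12

    def test_steep_slope_unwrapped_back_to_line(self):
        true = 2.5 * np.arange(40)
        wrapped = np.angle(np.exp(1j * true))
        res = phase_unwrap_1d(wrapped, np.ones(40))
        assert np.abs(res.phase - true).max() < 1e-10

    def test_single_wrap_continues_past_pi(self):
        phase = np.array([np.pi - 0.01, -np.pi + 0.01])
        res = phase_unwrap_1d(phase, np.ones(2))
        assert res.phase[1] == pytest.approx(np.pi + 0.01)

    def test_zero_magnitude_carries_phase_and_flags(self):
        phase = np.array([0.2, 0.3, 1.9, 0.4])
        mag = np.array([1.0, 0.0, 0.0, 1.0])
        res = phase_unwrap_1d(phase, mag)
        assert res.phase[1] == res.phase[0] == pytest.approx(0.2)
        assert list(res.carried) == [False, True, True, False]


class TestReferenceEstimator:
    def test_noiseless_reference_recovers_truth_per_line(self, disk):
        true = PhaseCoeffs(0.25, 0.40)
        ref = acquire_reference(disk, AcquisitionParams(coeffs=true))
        est = estimate_from_reference(ref)
        assert np.abs(est.alpha - true.alpha).max() < 1e-6
        assert np.abs(est.beta - true.beta).max() < 1e-6

    def test_zero_corruption_estimates_zero(self, disk):
        ref = acquire_reference(disk, AcquisitionParams(coeffs=PhaseCoeffs(0, 0)))
        est = estimate_from_reference(ref)
        assert np.abs(est.alpha).max() < 1e-9
        assert np.abs(est.beta).max() < 1e-9

    def test_noisy_reference_is_unbiased(self, disk, disk_mask):
        # mean estimate over 100 seeds within 3 standard errors of truth
        true = PhaseCoeffs(0.25, 0.40)
        p0 = AcquisitionParams(coeffs=true)
        sd = noise_sd_for_target_snr(disk, p0, 20.0, disk_mask)
        alphas, betas = [], []
        for seed in range(100):
            ref = acquire_reference(disk, AcquisitionParams(
                coeffs=true, noise_sd=sd, seed=seed))
            est = estimate_from_reference(ref)
            alphas.append(est.alpha.mean())
            betas.append(est.beta.mean())
        for vals, truth in ((alphas, true.alpha), (betas, true.beta)):
            se = np.std(vals, ddof=1) / np.sqrt(len(vals))
            assert abs(np.mean(vals) - truth) < 3 * se + 1e-12

    def test_corrects_its_own_corruption(self, disk, disk_rois):
        true = PhaseCoeffs(0.3, 0.05)
        ref = acquire_reference(disk, AcquisitionParams(coeffs=true))
        k = acquire_epi(disk, AcquisitionParams(coeffs=true))
        img = correct_with_coeffs(k, estimate_from_reference(ref))
        clean = reconstruct(acquire_epi(disk, AcquisitionParams(
            coeffs=PhaseCoeffs(0, 0))))
        assert np.abs(img.magnitude - clean.magnitude).max() < 1e-6


class TestIntegratedEchoEstimator:
    def test_noiseless_echoes_recover_truth(self, disk):
        true = PhaseCoeffs(0.25, 0.40)
        echoes, _ = acquire_integrated_echoes(
            disk, AcquisitionParams(coeffs=true))
        est = estimate_from_integrated_echoes(echoes)
        assert est.alpha == pytest.approx(true.alpha, abs=1e-9)
        assert est.beta == pytest.approx(true.beta, abs=1e-9)

    def test_identical_echoes_give_zero(self, disk):
        echoes, _ = acquire_integrated_echoes(
            disk, AcquisitionParams(coeffs=PhaseCoeffs(0, 0)))
        est = estimate_from_integrated_echoes(echoes)
        assert est.alpha == pytest.approx(0.0, abs=1e-12)
        assert est.beta == pytest.approx(0.0, abs=1e-12)

    def test_magnitude_decay_carries_no_phase(self, disk):
        echoes, _ = acquire_integrated_echoes(
            disk, AcquisitionParams(coeffs=PhaseCoeffs(0, 0), t2star=0.02))
        est = estimate_from_integrated_echoes(echoes)
        assert est.alpha == pytest.approx(0.0, abs=1e-12)
        assert est.beta == pytest.approx(0.0, abs=1e-12)

    def test_single_echo_rejected(self):
        with pytest.raises(ValueError):
            estimate_from_integrated_echoes(np.ones((32, 1), complex))


class TestGammaScaling:
    def test_unit_ratios_are_identity(self):
        c = PhaseCoeffs(0.3, 0.1)
        assert scale_reference_coeffs(c, 1.0, 1.0) == c

    def test_quarter_fov_proton_reference_arithmetic(self):
        c = PhaseCoeffs(1.0, 1.0)
        out = scale_reference_coeffs(c, 0.2515, 0.25)
        assert out.alpha == pytest.approx(0.2515)
        assert out.beta == pytest.approx(1.006)

    def test_round_trip_with_reciprocal_ratios(self):
        c = PhaseCoeffs(0.3, 0.1)
        out = scale_reference_coeffs(
            scale_reference_coeffs(c, 0.2515, 0.25), 1 / 0.2515, 1 / 0.25)
        assert out.alpha == pytest.approx(c.alpha)
        assert out.beta == pytest.approx(c.beta)

    def test_h1_reference_round_trip_recovers_c13_truth(self, disk):
        true = PhaseCoeffs(0.25, 0.40)
        ref = acquire_reference(disk, AcquisitionParams(coeffs=true),
                                nucleus="H1")
        est = scale_reference_coeffs(estimate_from_reference(ref),
                                     GAMMA_RATIO_C13_H1, 0.25)
        assert np.abs(est.alpha - true.alpha).max() < 1e-6
        assert np.abs(est.beta - true.beta).max() < 1e-6

    def test_nonpositive_ratio_rejected(self):
        with pytest.raises(ValueError):
            scale_reference_coeffs(PhaseCoeffs(0, 0), 0.0)


class TestSearch1D:
    def test_on_grid_recovery_is_exact(self, disk, disk_bands):
        cfg = SearchConfig()
        g = cfg.grid
        for ia, ib in [(30, 52), (60, 48), (49, 55)]:
            true = PhaseCoeffs(float(g[ia]), float(g[ib]))
            k = acquire_epi(disk, AcquisitionParams(coeffs=true))
            res = search_1d(k, disk_bands, cfg)
            assert res.coeffs == true

    def test_off_grid_recovery_within_one_step(self, disk, disk_bands):
        cfg = SearchConfig()
        true = PhaseCoeffs(0.123, 0.071)
        k = acquire_epi(disk, AcquisitionParams(coeffs=true))
        res = search_1d(k, disk_bands, cfg)
        assert abs(res.coeffs.alpha - true.alpha) <= cfg.step
        assert abs(res.coeffs.beta - true.beta) <= cfg.step

    def test_objective_is_exhaustively_minimal(self, disk, disk_bands):
        cfg = SearchConfig(n_steps=21)
        k = acquire_epi(disk, AcquisitionParams(
            coeffs=PhaseCoeffs(0.3, 0.05), noise_sd=0.02, seed=7))
        res = search_1d(k, disk_bands, cfg)
        ia = int(np.flatnonzero(res.alphas == res.coeffs.alpha)[0])
        ib = int(np.flatnonzero(res.betas == res.coeffs.beta)[0])
        assert res.objective[ia, ib] <= res.objective.min() + 1e-15
        assert res.objective.shape == (21, 21)

    def test_ghost_free_input_stays_ghost_free(self, disk, disk_bands, disk_rois):
        k = acquire_epi(disk, AcquisitionParams(coeffs=PhaseCoeffs(0, 0)))
        res = search_1d(k, disk_bands, SearchConfig())
        base = reconstruct(k).magnitude
        band_change = (np.abs(res.corrected.magnitude - base)[disk_bands.mask]
                       .mean())
        assert band_change < 0.05 * base.max()
        # the returned near-zero grid point perturbs Eq.-3 ghosting by at
        # most the effect of one grid step of each coefficient
        assert abs(ghosting_level(res.corrected.magnitude, disk_rois)
                   - ghosting_level(base, disk_rois)) < 5.0

    def test_empty_bands_rejected(self, disk):
        k = acquire_epi(disk, AcquisitionParams())
        with pytest.raises(ValueError):
            GhostBands(np.zeros((32, 32), bool))
        with pytest.raises(ValueError):
            search_1d(k, GhostBands(np.ones((16, 16), bool)), SearchConfig())


class TestSearch2D:
    def test_consistent_with_1d_model_on_full_kspace(self, disk, disk_bands):
        cfg = SearchConfig()
        g = cfg.grid
        true = PhaseCoeffs(float(g[55]), float(g[51]))
        k = apply_phase_error(full_kspace(disk), true)
        res = search_2d(k, disk_bands, cfg)
        # beta_y grid-optimal at zero (the grid has no exact 0)
        assert abs(res.coeffs.beta_y) <= cfg.step / 2 + 1e-12
        obj_rows = np.flatnonzero(disk.magnitude.any(axis=1))
        theta_true = true.theta(k.readout_coords)
        err = np.abs(res.coeffs.theta_col[obj_rows] - theta_true[obj_rows])
        assert err.max() <= cfg.step + 1e-12

    def test_noiseless_single_source_residual_is_quantization_limited(
            self, disk, disk_bands, disk_rois):
        true = PhaseCoeffs(0.3, 0.05)
        k = apply_phase_error(full_kspace(disk), true)
        # odd step count puts 0 on the grid, so only the per-column theta
        # quantization (half a grid step) remains
        res = search_2d(k, disk_bands, SearchConfig(n_steps=101))
        assert abs(res.coeffs.beta_y) < 1e-12
        assert ghosting_level(res.corrected.magnitude, disk_rois) < 1.0
        # the default even grid cannot represent beta_y = 0 exactly
        res100 = search_2d(k, disk_bands, SearchConfig())
        assert ghosting_level(res100.corrected.magnitude, disk_rois) < 2.5

    def test_multi_source_bias_exceeds_1d_residual(self, disk_rois):
        # per-column minimization is biased in columns with little ghost
        dual = make_phantom(PhantomSpec.dual())
        mask = dual.magnitude > 0
        bands = build_ghost_bands(mask)
        rois = RoiSet.from_object_mask(mask)
        p = AcquisitionParams(coeffs=PhaseCoeffs(0.3, 0.05), noise_sd=0.01,
                              seed=3)
        k = acquire_epi(dual, p)
        g1 = ghosting_level(search_1d(k, bands, SearchConfig()).corrected
                            .magnitude, rois)
        g2 = ghosting_level(search_2d(k, bands, SearchConfig()).corrected
                            .magnitude, rois)
        assert g2 > g1

    def test_rows_without_bands_inherit_1d_solution(self, disk):
        mask = np.zeros((32, 32), bool)
        mask[10:20, :8] = True  # bands only in some readout rows
        k = acquire_epi(disk, AcquisitionParams(coeffs=PhaseCoeffs(0.3, 0.05)))
        res = search_2d(k, GhostBands(mask), SearchConfig(n_steps=21))
        assert set(res.flagged_rows) == set(range(32)) - set(range(10, 20))


class TestEstimatorConcordance:
    def test_all_noiseless_estimators_agree_within_one_grid_step(self, disk,
                                                                 disk_bands):
        cfg = SearchConfig()
        true = PhaseCoeffs(0.3, 0.05)
        p = AcquisitionParams(coeffs=true)
        ref_est = estimate_from_reference(acquire_reference(disk, p)).mean()
        echoes, _ = acquire_integrated_echoes(disk, p)
        echo_est = estimate_from_integrated_echoes(echoes)
        search_est = search_1d(acquire_epi(disk, p), disk_bands, cfg).coeffs
        for a, b in [(ref_est, echo_est), (ref_est, search_est),
                     (echo_est, search_est)]:
            assert abs(a.alpha - b.alpha) <= cfg.step + 1e-12
            assert abs(a.beta - b.beta) <= cfg.step + 1e-12


class TestAlphaBetaSensitivity:
    def test_residual_ghosting_is_steeper_in_beta(self, disk, disk_rois):
        # around the optimum the objective valley is elongated along alpha:
        # a 5-step beta error ghosts far more than any small alpha error
        cfg = SearchConfig()
        true = PhaseCoeffs(0.3, 0.05)
        k = apply_phase_error(full_kspace(disk), true)
        alpha_slice = max(
            ghosting_level(correct_with_coeffs(
                k, PhaseCoeffs(true.alpha + d * cfg.step, true.beta)
            ).magnitude, disk_rois)
            for d in range(-5, 6)
        )
        beta_slice = min(
            ghosting_level(correct_with_coeffs(
                k, PhaseCoeffs(true.alpha, true.beta + s * 5 * cfg.step)
            ).magnitude, disk_rois)
            for s in (-1, 1)
        )
        assert alpha_slice < beta_slice


class TestApplyWorkflow:
    def test_noiseless_series_fully_corrected(self, disk_rois):
        true = PhaseCoeffs(0.3, 0.05)
        p = AcquisitionParams(coeffs=true, noise_sd=0.0)
        phantoms = {"pyruvate": PhantomSpec.disk(0.5),
                    "lactate": PhantomSpec.disk(0.3)}
        series = make_dynamic_series(phantoms, None, p, n_frames=5)
        mask = make_phantom(phantoms["pyruvate"]).magnitude > 0
        rois = RoiSet.from_object_mask(mask)
        wf = apply_workflow(series, mask)
        # the residual equals the zero-fill baseline of each clean frame
        clean = make_dynamic_series(
            phantoms, None,
            AcquisitionParams(coeffs=PhaseCoeffs(0, 0)), n_frames=5)
        for m in series.metabolites:
            for i, img in enumerate(wf.images[m]):
                baseline = ghosting_level(
                    reconstruct(clean.frames[m][i]).magnitude, rois)
                got = ghosting_level(img.magnitude, rois)
                assert got == pytest.approx(baseline, abs=0.5)

    def test_summed_search_agrees_with_peak_search(self, disk_mask):
        p = AcquisitionParams(coeffs=PhaseCoeffs(0.3, 0.05), noise_sd=0.01,
                              seed=11)
        series = make_dynamic_series(p=p, n_frames=6)
        mask = np.zeros((32, 32), bool)
        mask[5:28, 3:25] = True  # generous ROI over both phantoms
        cfg = SearchConfig()
        peak = apply_workflow(series, mask, cfg, "peak-lactate")
        summed = apply_workflow(series, mask, cfg, "sum-lactate")
        assert abs(peak.coeffs.beta - summed.coeffs.beta) <= 2 * cfg.step

    def test_low_snr_search_frame_warns(self):
        p = AcquisitionParams(coeffs=PhaseCoeffs(0.3, 0.05), noise_sd=2.0,
                              seed=4)
        series = make_dynamic_series(p=p, n_frames=3)
        mask = np.zeros((32, 32), bool)
        mask[10:22, 10:22] = True
        with pytest.warns(LowSnrWarning):
            apply_workflow(series, mask, SearchConfig(n_steps=11))

    def test_explicit_frame_selector(self):
        p = AcquisitionParams(coeffs=PhaseCoeffs(0.3, 0.05), noise_sd=0.0)
        series = make_dynamic_series(p=p, n_frames=3)
        mask = np.zeros((32, 32), bool)
        mask[5:28, 3:25] = True
        wf = apply_workflow(series, mask, frame_selector=("pyruvate", 2))
        assert wf.search_frame == ("pyruvate", 2)
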