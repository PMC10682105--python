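import numpy as np
import pytest

import waterpet as wp
from waterpet.aif import fine_time_base, frame_average_curve
from waterpet.kinetics import (
    KineticParams,
    MBFResult,
    fit_parametric,
    polar_map,
    territorial_mbf,
)


class TestForwardModel:
    def test_no_flow_limit_is_spillover_only(self, grid, aif, aif_curves):
        _, _, aif_frames = aif_curves
        curve = wp.forward_tissue_curve(KineticParams(0.0, 0.7, 0.2), aif, grid)
        assert np.allclose(curve, 0.2 * aif_frames, rtol=1e-6)

    def test_steady_state_reaches_partition_coefficient(self):
        # constant input c: convolution steady state K1*c/k2 = p*c
        g = wp.build_frame_grid([(40, 30)])          # 20-minute grid
        t_fine = fine_time_base(g)
        c = 1000.0
        ca_fine = np.full_like(t_fine, c)
        curve = wp.forward_tissue_curve(
            KineticParams(2.5, 1.0, 0.0), ca_fine, g, t_fine=t_fine
        )
        assert np.isclose(curve[-1], 0.91 * c, rtol=1e-3)

    def test_curve_nonnegative(self, grid, aif):
        for mbf, ptf, va in [(0.5, 0.4, 0.0), (2.5, 0.7, 0.15), (5.0, 1.0, 0.4)]:
            curve = wp.forward_tissue_curve(KineticParams(mbf, ptf, va), aif, grid)
            assert np.all(curve >= 0)


class TestFitTac:
    @pytest.mark.parametrize("mbf", [0.5, 1.5, 2.5, 4.0])
    @pytest.mark.parametrize("ptf", [0.4, 0.7, 1.0])
    def test_noise_free_round_trip(self, grid, aif, aif_curves, mbf, ptf):
        _, ca_fine, aif_frames = aif_curves
        tac = wp.forward_tissue_curve(KineticParams(mbf, ptf, 0.15), aif, grid)
        fit = wp.fit_tac(tac, aif_frames, grid, aif_fine=ca_fine)
        assert abs(fit.mbf - mbf) / mbf < 0.01
        assert abs(fit.ptf - ptf) < 0.02
        assert abs(fit.va - 0.15) < 0.02

    def test_no_flow_curve_recovers_spillover(self, grid, aif_curves):
        _, ca_fine, aif_frames = aif_curves
        fit = wp.fit_tac(0.3 * aif_frames, aif_frames, grid, aif_fine=ca_fine)
        assert fit.mbf == 0.0
        assert abs(fit.va - 0.3) < 0.003

    def test_scale_equivariance(self, grid, aif, aif_curves):
        _, ca_fine, aif_frames = aif_curves
        tac = wp.forward_tissue_curve(KineticParams(2.0, 0.8, 0.1), aif, grid)
        a = wp.fit_tac(tac, aif_frames, grid, aif_fine=ca_fine)
        b = wp.fit_tac(1e3 * tac, 1e3 * aif_frames, grid, aif_fine=1e3 * ca_fine)
        assert np.isclose(a.mbf, b.mbf, rtol=1e-6)
        assert np.isclose(a.ptf, b.ptf, rtol=1e-4)
        assert np.isclose(a.va, b.va, atol=1e-6)

    def test_monotone_in_true_flow(self, grid, aif, aif_curves):
        _, ca_fine, aif_frames = aif_curves
        fitted = []
        for mbf in np.linspace(0.5, 5.0, 12):
            tac = wp.forward_tissue_curve(KineticParams(mbf, 0.7, 0.15), aif, grid)
            fitted.append(wp.fit_tac(tac, aif_frames, grid, aif_fine=ca_fine,
                                     refine=False).mbf)
        assert np.all(np.diff(fitted) >= 0)

    def test_basis_rss_matches_nonlinear_optimizer(self, grid, aif, aif_curves):
        # independent oracle: generic bounded nonlinear least squares over
        # (MBF, PTF, V_A) from several starts
        from scipy.optimize import least_squares

        t_fine, ca_fine, aif_frames = aif_curves
        rng = np.random.default_rng(7)

        def model(x):
            return wp.forward_tissue_curve(
                KineticParams(x[0], min(x[1], 1.2), min(x[2], 1.0), 0.91),
                ca_fine, grid, t_fine=t_fine,
            )

        for _ in range(5):
            true = KineticParams(rng.uniform(0.8, 4.5), rng.uniform(0.4, 1.0),
                                 rng.uniform(0.0, 0.4))
            tac = wp.forward_tissue_curve(true, aif, grid)
            tac = tac + rng.normal(0, 0.01 * tac.max(), tac.shape)
            tac = np.maximum(tac, 0)
            fit = wp.fit_tac(tac, aif_frames, grid, aif_fine=ca_fine)
            rss_basis = np.sum((tac - model([fit.mbf, fit.ptf, fit.va])) ** 2)
            rss_nl = np.inf
            for x0 in ([1.0, 0.6, 0.1], [3.0, 0.8, 0.2], [true.mbf, true.ptf, true.va]):
                res = least_squares(
                    lambda x: tac - model(x), x0,
                    bounds=([0.01, 0.0, 0.0], [6.0, 1.2, 1.0]),
                )
                rss_nl = min(rss_nl, 2 * res.cost)
            assert rss_basis <= rss_nl * 1.01

    def test_degenerate_inputs_rejected(self, grid, aif_curves):
        _, _, aif_frames = aif_curves
        with pytest.raises(ValueError):
            wp.fit_tac(np.zeros(len(grid)), aif_frames, grid)
        with pytest.raises(ValueError):
            wp.fit_tac(aif_frames, np.zeros(len(grid)), grid)


class TestExtractAif:
    def test_single_voxel_mask_returns_that_tac(self, clean_phantom):
        _, image, truth = clean_phantom
        idx = tuple(np.argwhere(truth.lv_cavity_mask)[0])
        mask = np.zeros(image.spatial_shape, bool)
        mask[idx] = True
        assert np.allclose(wp.extract_aif(image, mask), image.voxels[(slice(None),) + idx])

    def test_cavity_mask_recovers_true_input(self, clean_phantom, aif_curves):
        _, image, truth = clean_phantom
        _, _, aif_frames = aif_curves
        got = wp.extract_aif(image, truth.lv_cavity_mask)
        assert np.max(np.abs(got - aif_frames)) <= 0.01 * aif_frames.max()

    def test_uniform_image_gives_constant(self, grid):
        img = wp.DynamicImage(np.full((21, 8, 8, 8), 5.0, np.float32), 3.27, grid)
        mask = np.zeros((8, 8, 8), bool)
        mask[2:5, 2:5, 2:5] = True
        assert np.allclose(img.tac(mask), 5.0)

    def test_empty_mask_rejected(self, clean_phantom):
        _, image, _ = clean_phantom
        with pytest.raises(ValueError):
            wp.extract_aif(image, np.zeros(image.spatial_shape, bool))


class TestParametric:
    def test_territory_means_recover_truth(self, clean_phantom, clean_analysis):
        _, _, truth = clean_phantom
        for t, params in truth.true_params.items():
            rec = clean_analysis.territory_mbf[t]
            assert abs(rec - params.mbf) / params.mbf < 0.02

    def test_single_voxel_mask_equals_fit_tac(self, clean_phantom, aif_curves):
        _, image, truth = clean_phantom
        _, _, aif_frames = aif_curves
        idx = tuple(np.argwhere(truth.territory_masks["LAD"])[5])
        mask = np.zeros(image.spatial_shape, bool)
        mask[idx] = True
        vols = fit_parametric(image, aif_frames, mask)
        single = wp.fit_tac(
            image.voxels[(slice(None),) + idx].astype(float),
            aif_frames, image.frame_grid, refine=False,
        )
        assert np.isclose(vols["mbf"][idx], single.mbf, rtol=1e-9)
        assert np.isclose(vols["va"][idx], single.va, atol=1e-9)

    def test_degenerate_voxels_flagged_not_fatal(self, grid, aif_curves):
        _, _, aif_frames = aif_curves
        vox = np.zeros((21, 6, 6, 6), np.float32)
        mask = np.zeros((6, 6, 6), bool)
        mask[1, 1, 1] = True                     # all-zero voxel
        mask[2, 2, 2] = True
        vox[:, 2, 2, 2] = aif_frames
        img = wp.DynamicImage(vox, 3.27, grid)
        vols = fit_parametric(img, aif_frames, mask)
        assert vols["degenerate"][1, 1, 1]
        assert np.isnan(vols["mbf"][1, 1, 1])
        assert not vols["degenerate"][2, 2, 2]


class TestTerritorialSummary:
    def _uniform_setup(self, value):
        shape = (6, 6, 6)
        vol = np.full(shape, float(value))
        terr = {
            "LAD": np.zeros(shape, bool), "RCA": np.zeros(shape, bool),
            "LCx": np.zeros(shape, bool),
        }
        terr["LAD"][0:2], terr["RCA"][2:4], terr["LCx"][4:6] = True, True, True
        return vol, terr

    def test_uniform_volume_gives_uniform_result(self):
        vol, terr = self._uniform_setup(2.7)
        res = territorial_mbf({"mbf": vol}, terr)
        assert all(np.isclose(v, 2.7) for v in res.territory_mbf.values())
        assert np.isclose(res.global_mbf, 2.7)

    def test_equal_count_territories_average_exactly(self):
        vol, terr = self._uniform_setup(0.0)
        vol[terr["LAD"]], vol[terr["RCA"]], vol[terr["LCx"]] = 2.0, 3.0, 4.0
        res = territorial_mbf({"mbf": vol}, terr)
        assert np.isclose(res.global_mbf, 3.0)
        assert np.isclose(res.global_mbf_territory_mean, 3.0)

    def test_empty_territory_rejected(self):
        vol, terr = self._uniform_setup(1.0)
        terr["RCA"][:] = False
        with pytest.raises(ValueError):
            territorial_mbf({"mbf": vol}, terr)

    def test_global_outside_territorial_range_rejected(self):
        with pytest.raises(ValueError):
            MBFResult(territory_mbf={"LAD": 2.0, "RCA": 3.0, "LCx": 2.5},
                      global_mbf=3.5, global_mbf_territory_mean=2.5)


class TestPolarMap:
    def test_uniform_volume_fills_17_segments(self, clean_phantom):
        _, image, truth = clean_phantom
        vol = np.full(image.spatial_shape, 3.3)
        segs = polar_map(vol, truth.myocardium_mask, truth.center_vox,
                         truth.long_axis, truth.anterior_ref)
        assert segs.shape == (17,)
        assert np.allclose(segs[np.isfinite(segs)], 3.3)
        assert np.isfinite(segs).sum() == 17

    def test_segment_and_voxel_aggregation_agree(self, clean_phantom, clean_analysis,
                                                 aif_curves, grid):
        # two aggregation paths onto the LAD territory should agree within
        # sampling differences
        _, image, truth = clean_phantom
        _, _, aif_frames = aif_curves
        vols = fit_parametric(image, aif_frames, truth.myocardium_mask)
        segs = polar_map(vols["mbf"], truth.myocardium_mask, truth.center_vox,
                         truth.long_axis, truth.anterior_ref)
        # anterior + anteroseptal columns and the apex, AHA numbering
        lad_segments = np.array([1, 2, 7, 8, 13, 14, 17]) - 1
        seg_mean = np.nanmean(segs[lad_segments])
        vox_mean = clean_analysis.territory_mbf["LAD"]
        assert abs(seg_mean - vox_mean) / vox_mean < 0.05
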