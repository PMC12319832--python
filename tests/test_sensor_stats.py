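"""Scalp images, mass-univariate GLMs and permutation cluster inference."""

import numpy as np
import pandas as pd
import pytest

from mmnflow import sensor_stats as ss
from mmnflow import synthetic


@pytest.fixture(scope="module")
def mapper16(layout16):
    return ss.ScalpMapper(layout16, ss.ScalpGrid(16, 16))


@pytest.fixture(scope="module")
def times():
    return -100.0 + np.arange(154) * 1000.0 / 256.0


def random_stack(rng, n_units, mapper, times, scale=1.0):
    data = rng.normal(0, scale,
                      (n_units, mapper.layout.n_channels, len(times)))
    return ss.to_scalp_images(data, mapper.layout, times, mapper=mapper)


class TestDifferenceWaveform:
    def make(self, v, tt, ph, layout):
        trials = pd.DataFrame({"tone": 0, "trial_type": tt, "phase": ph,
                               "artifact": False})
        times = -100.0 + np.arange(v.shape[2]) * 1000.0 / 256.0
        return synthetic.EpochStack(voltages=v, times=times, layout=layout,
                                    trials=trials)

    def test_identical_sets_give_zero(self, layout16):
        v = np.random.default_rng(0).normal(size=(10, 16, 20))
        v[5:] = v[:5]
        st = self.make(v, ["deviant"] * 5 + ["standard"] * 5, "stable",
                       layout16)
        assert np.allclose(ss.difference_waveform(st), 0.0)

    def test_constant_offset_recovered(self, layout16):
        v = np.zeros((8, 16, 20))
        tt = ["standard"] * 4 + ["deviant"] * 4
        v[4:] -= 2.0
        st = self.make(v, tt, "stable", layout16)
        assert np.allclose(ss.difference_waveform(st), -2.0)

    def test_phase_restriction_and_errors(self, layout16):
        v = np.zeros((6, 16, 20))
        tt = ["standard", "deviant"] * 3
        ph = ["stable"] * 4 + ["volatile"] * 2
        st = self.make(v, tt, ph, layout16)
        ss.difference_waveform(st, phase="stable")
        st2 = self.make(v, ["other"] * 6, ph, layout16)
        with pytest.raises(ValueError, match="deviant"):
            ss.difference_waveform(st2)


class TestComponentMean:
    def test_constant_ramp_and_oracle(self, times):
        wf = np.full((4, len(times)), 3.0)
        out = ss.component_mean(wf, times, (150, 200))
        assert np.allclose(out, 3.0)
        sel = (times >= 150) & (times <= 200)
        ramp = np.tile(np.linspace(0, 10, len(times)), (2, 1))
        out2 = ss.component_mean(ramp, times, (150, 200))
        np.testing.assert_allclose(out2, ramp[:, sel].mean(axis=1))
        with pytest.raises(ValueError):
            ss.component_mean(wf, times, (900, 950))


class TestScalpImages:
    def test_constant_field(self, layout16, mapper16, times):
        data = np.full((16, 10), 7.0)
        stack = ss.to_scalp_images(data, layout16, times[:10],
                                   mapper=mapper16)
        assert np.allclose(stack.images[0][stack.mask], 7.0)
        assert np.isnan(stack.images[0][~stack.mask]).all()

    def test_single_channel_bump_peaks_at_channel(self, layout16, mapper16,
                                                  times):
        data = np.zeros((16, 1))
        ch = 5
        data[ch] = 1.0
        stack = ss.to_scalp_images(data, layout16, times[:1],
                                   mapper=mapper16)
        img = np.nan_to_num(stack.images[0][..., 0])
        ix, iy = np.unravel_index(np.argmax(img), img.shape)
        p = np.array([stack.grid.xs[ix], stack.grid.ys[iy]])
        d = np.linalg.norm(layout16.pos2d - p, axis=1)
        assert np.argmin(d) == ch

    def test_planar_field_exact(self, layout64, times):
        # linear interpolation reproduces a plane exactly inside the hull
        mapper = ss.ScalpMapper(layout64, ss.ScalpGrid(20, 20))
        pos = layout64.pos2d
        plane = 2.0 * pos[:, 0] - 1.5 * pos[:, 1] + 0.3
        stack = ss.to_scalp_images(plane[:, None], layout64, times[:1],
                                   mapper=mapper)
        gx, gy = np.meshgrid(stack.grid.xs, stack.grid.ys, indexing="ij")
        expected = 2.0 * gx - 1.5 * gy + 0.3
        got = stack.images[0][..., 0]
        np.testing.assert_allclose(got[stack.mask], expected[stack.mask],
                                   atol=1e-6)

    def test_degenerate_layout_rejected(self, times):
        pos2 = np.column_stack([np.linspace(-0.5, 0.5, 5), np.zeros(5)])
        layout = synthetic.SensorLayout(
            names=tuple(f"ch{i}" for i in range(5)),
            pos3d=np.column_stack([pos2, np.ones(5)]), pos2d=pos2)
        with pytest.raises(ValueError, match="degenerate"):
            ss.to_scalp_images(np.zeros((5, 3)), layout, times[:3])


class TestSmoothing:
    def test_fwhm_zero_identity(self, mapper16, times, layout16):
        stack = random_stack(np.random.default_rng(0), 2, mapper16,
                             times[:5])
        out = ss.smooth_images(stack, fwhm_mm=(0, 0))
        np.testing.assert_allclose(
            out.images[~np.isnan(out.images)],
            stack.images[~np.isnan(stack.images)])

    def test_constant_image_unchanged(self, layout16, mapper16, times):
        data = np.full((16, 5), 4.2)
        stack = ss.to_scalp_images(data, layout16, times[:5],
                                   mapper=mapper16)
        out = ss.smooth_images(stack)
        np.testing.assert_allclose(out.images[0][out.mask], 4.2, atol=1e-9)

    def test_delta_spreads_as_gaussian(self):
        # custom dense stack so the discrete delta is well resolved
        grid = ss.ScalpGrid(41, 41)
        mask = np.ones((41, 41), bool)
        img = np.zeros((1, 41, 41, 1))
        img[0, 20, 20, 0] = 1.0
        stack = ss.ScalpImageStack(images=img, mask=mask,
                                   times=np.array([0.0]), grid=grid)
        fwhm = 30.0
        out = ss.smooth_images(stack, fwhm_mm=(fwhm, fwhm))
        prof = out.images[0, :, 20, 0]
        sigma_vox = fwhm / 2.3548 / grid.mm_per_voxel[0]
        x = np.arange(41) - 20
        expected = np.exp(-0.5 * (x / sigma_vox) ** 2)
        expected /= expected.sum() ** 2  # 2-D kernel normalisation, 1 axis
        np.testing.assert_allclose(prof / prof.max(),
                                   expected / expected.max(), atol=0.02)

    def test_mask_aware_mean_preservation(self, layout16, mapper16, times):
        data = np.full((16, 3), 1.0)
        stack = ss.to_scalp_images(data, layout16, times[:3],
                                   mapper=mapper16)
        out = ss.smooth_images(stack, fwhm_mm=(40, 40))
        # no mass leaks out of the mask for a constant field
        assert np.nanmean(out.images[0]) == pytest.approx(1.0, abs=1e-9)


class TestFirstLevelGLM:
    def test_exact_noiseless_fit(self, layout16, mapper16, times):
        rng = np.random.default_rng(1)
        z = rng.normal(size=40)
        z = (z - z.mean()) / z.std()
        data = 2.0 * z[:, None, None] * np.ones((40, 16, 6))
        stack = ss.to_scalp_images(data, layout16, times[:6],
                                   mapper=mapper16)
        res = ss.SingleTrialGLM(stack, pd.DataFrame({"z": z})).fit()
        b = res.betas["z"]
        np.testing.assert_allclose(b[stack.mask], 2.0, atol=1e-10)
        # residuals vanish to float precision: t is flagged huge/infinite
        assert (np.abs(res.tmaps["z"][stack.mask]) > 1e6).all()

    def test_matches_normal_equation_oracle(self, layout16, mapper16,
                                            times):
        rng = np.random.default_rng(2)
        stack = random_stack(rng, 30, mapper16, times[:8])
        reg = pd.DataFrame(rng.normal(size=(30, 2)), columns=["a", "b"])
        res = ss.SingleTrialGLM(stack, reg).fit()
        Z = (reg - reg.mean()) / reg.std(ddof=0)
        X = np.column_stack([np.ones(30), Z])
        flat = stack.images.reshape(30, -1)
        valid = ~np.isnan(flat[0])
        beta_o, _, _, _ = np.linalg.lstsq(X, flat[:, valid], rcond=None)
        got = res.betas["a"].reshape(-1)[valid]
        np.testing.assert_allclose(got, beta_o[1], atol=1e-8)

    def test_orthogonal_regressor_zero_beta(self, layout16, mapper16,
                                            times):
        n = 24
        z = np.tile([1.0, 1.0, -1.0, -1.0], n // 4)   # regressor
        y = np.tile([1.0, -1.0, 1.0, -1.0], n // 4)   # data, z'y = 0 exactly
        data = y[:, None, None] * np.ones((n, 16, 4))
        stack = ss.to_scalp_images(data, layout16, times[:4],
                                   mapper=mapper16)
        res = ss.SingleTrialGLM(stack, pd.DataFrame({"z": z})).fit()
        np.testing.assert_allclose(res.betas["z"][stack.mask], 0.0,
                                   atol=1e-12)
        assert np.allclose(res.fmap("z")[stack.mask], 0.0, atol=1e-12)

    def test_rank_deficiency_and_zero_variance_errors(self, layout16,
                                                      mapper16, times):
        rng = np.random.default_rng(3)
        stack = random_stack(rng, 20, mapper16, times[:4])
        with pytest.raises(ValueError, match="zero-variance"):
            ss.SingleTrialGLM(stack,
                              pd.DataFrame({"c": np.ones(20)})).fit()
        x = rng.normal(size=20)
        with pytest.raises(ValueError):
            ss.SingleTrialGLM(stack, pd.DataFrame({"a": x,
                                                   "b": 2 * x})).fit()


class TestSecondLevel:
    def test_onesample_matches_textbook_t(self, layout16, mapper16, times):
        vals = np.array([1.2, 0.8, 1.5, 0.9, 1.1])
        data = vals[:, None, None] * np.ones((5, 16, 3))
        stack = ss.to_scalp_images(data, layout16, times[:3],
                                   mapper=mapper16)
        res = ss.second_level_onesample(stack)
        t_hand = vals.mean() / (vals.std(ddof=1) / np.sqrt(5))
        assert res.dof == 4
        np.testing.assert_allclose(res.tmap[stack.mask], t_hand, atol=1e-10)

    def test_zero_variance_flagged_infinite(self, layout16, mapper16,
                                            times):
        data = np.full((4, 16, 2), 3.0)
        stack = ss.to_scalp_images(data, layout16, times[:2],
                                   mapper=mapper16)
        res = ss.second_level_onesample(stack)
        assert np.isinf(res.tmap[stack.mask]).all()
        assert np.isfinite(res.tmap[stack.mask]).sum() == 0

    def test_covariate_matches_statsmodels(self, layout16, mapper16, times):
        import statsmodels.api as sm
        rng = np.random.default_rng(4)
        cov = np.array([6, 7, 8, 9, 10, 8.5])
        imgs = rng.normal(size=(6, 16, 2)) + 0.5 * cov[:, None, None]
        stack = ss.to_scalp_images(imgs, layout16, times[:2],
                                   mapper=mapper16)
        res = ss.second_level_covariate(stack, cov)
        flat = stack.images.reshape(6, -1)
        v = np.flatnonzero(~np.isnan(flat[0]))[7]
        fit = sm.OLS(flat[:, v], sm.add_constant(cov)).fit()
        got = res.tmap.reshape(-1)[v]
        assert got == pytest.approx(fit.tvalues[1], abs=1e-8)

    def test_perfect_covariate_link_infinite_t(self, layout16, mapper16,
                                               times):
        cov = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        imgs = cov[:, None, None] * np.ones((5, 16, 2))
        stack = ss.to_scalp_images(imgs, layout16, times[:2],
                                   mapper=mapper16)
        res = ss.second_level_covariate(stack, cov)
        assert (np.abs(res.tmap[stack.mask]) > 1e6).all()

    def test_input_validation(self, layout16, mapper16, times):
        stack = random_stack(np.random.default_rng(5), 4, mapper16,
                             times[:2])
        with pytest.raises(ValueError, match="constant covariate"):
            ss.GroupModel(stack, covariate=np.ones(4))
        with pytest.raises(ValueError, match="at least 3"):
            ss.GroupModel(stack.restrict((-100, 500)).images[:2]
                          if False else ss.ScalpImageStack(
                              images=stack.images[:2], mask=stack.mask,
                              times=stack.times, grid=stack.grid))


class TestClusterInference:
    def test_embedded_effect_found_once(self, layout16, times):
        rng = np.random.default_rng(6)
        mapper = ss.ScalpMapper(layout16, ss.ScalpGrid(12, 12))
        sel = (times >= 100) & (times <= 400)
        effect = np.zeros((16, len(times)))
        ch = 5
        it = np.argmin(np.abs(times - 200))
        effect[ch, it - 3:it + 3] = 3.0
        imgs = []
        for _ in range(10):
            data = rng.normal(0, 0.5, (16, len(times))) + effect
            imgs.append(ss.to_scalp_images(data, layout16, times,
                                           mapper=mapper).images[0])
        stack = ss.ScalpImageStack(images=np.array(imgs),
                                   mask=mapper.mask.copy(), times=times,
                                   grid=ss.ScalpGrid(12, 12),
                                   layout=layout16)
        smap = ss.GroupModel(stack).fit().cluster_inference(n_perm=200,
                                                            seed=0)
        sig = smap.significant(0.05)
        assert len(sig) == 1
        assert abs(sig.iloc[0]["peak_time_ms"] - 200) < 15
        p = np.array([stack.grid.xs[int(sig.iloc[0]["peak_x"])],
                      stack.grid.ys[int(sig.iloc[0]["peak_y"])]])
        # peak voxel within ~1.5 grid spacings of the embedded channel
        spacing = stack.grid.xs[1] - stack.grid.xs[0]
        assert np.linalg.norm(layout16.pos2d[ch] - p) < 1.5 * spacing

    def test_strict_cdt_gives_empty_table(self, layout16, mapper16, times):
        stack = random_stack(np.random.default_rng(7), 6, mapper16, times)
        smap = ss.GroupModel(stack).fit().cluster_inference(
            cdt_p=1e-12, n_perm=120, seed=1)
        assert smap.clusters.empty
        assert "no supra-threshold clusters" in smap.summary()

    def test_low_n_perm_warns(self, layout16, mapper16, times):
        stack = random_stack(np.random.default_rng(8), 6, mapper16, times)
        res = ss.GroupModel(stack).fit()
        with pytest.warns(UserWarning, match="coarse"):
            res.cluster_inference(n_perm=50, seed=2)

    def test_seed_determinism(self, layout16, mapper16, times):
        stack = random_stack(np.random.default_rng(9), 8, mapper16, times)
        res = ss.GroupModel(stack).fit()
        a = res.cluster_inference(cdt_p=0.05, n_perm=150, seed=3)
        b = res.cluster_inference(cdt_p=0.05, n_perm=150, seed=3)
        pd.testing.assert_frame_equal(a.clusters, b.clusters)


def test_channel_route_equals_image_route(layout16, times):
    """First-level betas via channel-level GLM + mapping equal the betas of
    the GLM on mapped-and-smoothed per-trial images."""
    from mmnflow.validation import first_level_beta_images
    import mmnflow.hgf as hgf
    rng = np.random.default_rng(10)
    n = 30
    u = rng.integers(0, 2, n)
    traj = hgf.filter_sequence(u)
    mapper = ss.ScalpMapper(layout16, ss.ScalpGrid(12, 12))
    v = rng.normal(0, 5, (n, 16, len(times)))
    trials = pd.DataFrame({"tone": u, "trial_type": "other",
                           "phase": "stable", "artifact": False})
    stack = synthetic.EpochStack(voltages=v, times=times, layout=layout16,
                                 trials=trials)
    fast = first_level_beta_images(stack, traj.table, "pwpe", mapper)
    imgs = ss.smooth_images(ss.to_scalp_images(v, layout16, times,
                                               mapper=mapper))
    glm = ss.SingleTrialGLM.from_design(imgs, traj.table, "pwpe").fit()
    for name in ("eps2", "eps3"):
        a, b = fast[name], glm.betas[name]
        np.testing.assert_allclose(a[~np.isnan(a)], b[~np.isnan(b)],
                                   atol=1e-8)
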