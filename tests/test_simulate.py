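import numpy as np
import pytest
from scipy import stats as sps

from mitonode import (
    ROI,
    apply_photoconversion,
    build_scene,
    export_ground_truth,
    render_movie,
)
from mitonode.simulate import OpticsModel, SceneParams
from tests.conftest import converted_scene


class TestBuildScene:
    def test_filament_count_matches_parameter(self):
        scene = build_scene(SceneParams(n_mito=5), seed=1)
        assert len(scene.filaments) == 5

    def test_same_seed_same_scene(self):
        p = SceneParams.puncta_movie()
        a, b = build_scene(p, seed=7), build_scene(p, seed=7)
        for fa, fb in zip(a.filaments, b.filaments):
            np.testing.assert_array_equal(fa.points, fb.points)
        assert [(q.role, q.position) for q in a.puncta] == \
               [(q.role, q.position) for q in b.puncta]
        assert [(e.time_s, e.kind) for e in a.events.entries] == \
               [(e.time_s, e.kind) for e in b.events.entries]

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            build_scene(SceneParams(mfn1_density_per_um=-1), seed=0)

    def test_scheduled_event_counts_match_poisson_mean(self):
        # fusion rate 0.25/mito/min, 20 mitochondria, 5 min -> mean 25
        p = SceneParams(n_mito=2, duration_s=300.0,
                        fusion_rate_tip_to_middle=0.19, fusion_rate_tip_to_tip=0.06)
        counts = []
        rng = np.random.default_rng(0)
        for seed in rng.integers(0, 2**31, size=200):
            # scheduling is seed-determined; geometry is not needed here
            sc = build_scene(SceneParams(n_mito=2, fov_um=12.0, duration_s=300.0,
                                         fusion_rate_tip_to_middle=0.19,
                                         fusion_rate_tip_to_tip=0.06), seed=int(seed))
            counts.append(sum(e.kind == "fusion" for e in sc.events.entries))
        counts = np.array(counts)
        expected = 0.25 * 2 * 5
        se = np.sqrt(expected / len(counts))
        assert abs(counts.mean() - expected) < 3 * se

    def test_event_counts_follow_poisson_law(self):
        """Chi-square goodness of fit of scheduled counts vs Poisson."""
        lam = 0.17 * 3 * 2  # fission rate x n_mito x minutes
        counts = []
        for seed in range(250):
            sc = build_scene(SceneParams(n_mito=3, fov_um=14.0, duration_s=120.0,
                                         fission_rate=0.17), seed=seed)
            counts.append(len(sc.events.entries))
        counts = np.array(counts)
        kmax = int(counts.max())
        obs = np.bincount(counts, minlength=kmax + 1).astype(float)
        probs = sps.poisson.pmf(np.arange(kmax + 1), lam)
        probs[-1] += sps.poisson.sf(kmax, lam)
        exp = probs * len(counts)
        # pool sparse tail bins so expected counts are reasonable
        keep = exp >= 5
        obs_p = np.append(obs[keep], obs[~keep].sum())
        exp_p = np.append(exp[keep], exp[~keep].sum())
        chi2 = ((obs_p - exp_p) ** 2 / exp_p).sum()
        p = sps.chi2.sf(chi2, df=len(obs_p) - 1)
        assert p > 0.01


class TestPhotoconversion:
    def test_largest_overlap_filament_selected(self):
        scene = build_scene(SceneParams(n_mito=3), seed=2)
        pts = scene.filaments[1].points
        mid = pts[len(pts) // 2]
        roi = ROI(origin=(int(mid[0] / 0.1) - 8, int(mid[1] / 0.1) - 8), size=(1.6, 1.6))
        out = apply_photoconversion(scene, roi)
        assert out.converted_filament == 1
        assert scene.converted_filament is None  # original untouched

    def test_background_roi_errors(self):
        scene = build_scene(SceneParams(n_mito=1, fov_um=20.0), seed=3)
        # find an empty corner at least 3 um from the filament
        pts = scene.filaments[0].points
        for corner in [(1, 1), (1, 170), (170, 1), (170, 170)]:
            c_um = np.array(corner) * 0.1
            if np.linalg.norm(pts - c_um, axis=1).min() > 3.5:
                with pytest.raises(ValueError):
                    apply_photoconversion(scene, ROI(origin=corner, size=(1.0, 1.0)))
                return
        pytest.skip("no empty corner in this realization")

    def test_converted_label_propagates_to_fusion_partner(self):
        scene = converted_scene(seed=3)
        tl = scene.timeline()
        gt = export_ground_truth(scene)
        fusions = gt.events[gt.events.kind == "fusion"]
        assert len(fusions) > 0
        for _, ev in fusions.iterrows():
            frame = int(round(ev.time_s / 5.0))
            donor_body = int(ev.participants.split(",")[0])
            pre = [fo for fo in tl.frames[frame - 1] if fo.body == donor_body]
            assert pre and not any(fo.converted for fo in pre)
            # from the event frame the donor body is gone: its material has
            # merged into the converted lineage
            post = tl.frames[frame + 1]
            assert not any(fo.body == donor_body for fo in post)
            n_conv_pre = sum(fo.converted for fo in tl.frames[frame - 1])
            n_conv_post = sum(fo.converted for fo in post)
            assert n_conv_post > n_conv_pre


class TestRender:
    def test_empty_scene_background_exact(self):
        scene = build_scene(SceneParams(n_mito=0, n_er_tubules=0, fov_um=3.0), seed=0)
        optics = OpticsModel(background=100.0, poisson_noise=False,
                             gaussian_read_noise_sd=0.0)
        stack = render_movie(scene, optics, seed=0)
        np.testing.assert_array_equal(stack.pixels, 100.0)

    def test_centerline_brighter_than_background(self, noise_free_optics):
        scene = build_scene(SceneParams(n_mito=1, n_er_tubules=0, fov_um=8.0), seed=5)
        stack = render_movie(scene, noise_free_optics, seed=0)
        img = stack.plane(role="mito")
        pts = scene.filaments[0].points
        mid_px = np.round(pts[len(pts) // 2] / 0.1).astype(int)
        assert img[mid_px[0], mid_px[1]] > noise_free_optics.background * 1.5
        # the global maximum lies on (or within a pixel of) the centreline
        peak = np.unravel_index(np.argmax(img), img.shape)
        dense = np.vstack([np.interp(np.linspace(0, 1, 400), np.linspace(0, 1, len(pts)),
                                     pts[:, k]) for k in (0, 1)]).T
        assert np.linalg.norm(dense / 0.1 - np.array(peak), axis=1).min() <= 1.5

    def test_poisson_noise_variance_matches_mean(self):
        scene = build_scene(SceneParams(n_mito=1, n_er_tubules=0, fov_um=3.0,
                                        mito_length_range=(1.5, 2.0)), seed=8)
        optics = OpticsModel(gaussian_read_noise_sd=0.0)
        samples = np.stack([
            render_movie(scene, optics, seed=s).plane(role="mito")
            for s in range(500)
        ])
        mean = samples.mean(axis=0)
        var = samples.var(axis=0)
        bright = mean > 150
        assert bright.any()
        ratio = var[bright].sum() / mean[bright].sum()
        assert abs(ratio - 1.0) < 0.1

    def test_constriction_renders_at_least_programmed_dip(self, noise_free_optics):
        from mitonode.simulate import ConstrictionSite
        scene = build_scene(SceneParams(n_mito=1, n_er_tubules=0, fov_um=10.0,
                                        mito_length_range=(6.0, 6.0)), seed=11)
        fil = scene.filaments[0]
        site = ConstrictionSite(arc_um=fil.length_um / 2, min_factor=0.5)
        fil.sites.append(site)
        stack = render_movie(scene, noise_free_optics, seed=0)
        img = stack.plane(role="mito") - noise_free_optics.background
        from mitonode.simulate import _point_at_arc
        at = lambda s: img[tuple(np.round(_point_at_arc(fil.points, s)[0] / 0.1).astype(int))]
        dip_val = at(site.arc_um)
        ref = max(at(site.arc_um - 1.5), at(site.arc_um + 1.5))
        assert 1 - dip_val / ref >= 1 - site.min_factor

    def test_seed_determinism_of_render(self, puncta_scene):
        a = render_movie(puncta_scene, seed=9).pixels
        b = render_movie(puncta_scene, seed=9).pixels
        np.testing.assert_array_equal(a, b)


class TestGroundTruth:
    def test_event_row_count_matches_schedule(self, photoconversion_scene):
        gt = export_ground_truth(photoconversion_scene)
        assert len(gt.events) == len(photoconversion_scene.events.realized())

    def test_zero_event_scene_has_zero_rates(self):
        scene = build_scene(SceneParams(n_mito=2, duration_s=60.0), seed=13)
        gt = export_ground_truth(scene)
        assert gt.rates["fusion"] == 0.0 and gt.rates["fission"] == 0.0

    def test_rates_recompute_from_event_list(self, photoconversion_scene):
        gt = export_ground_truth(photoconversion_scene)
        denom = gt.n_mito * gt.duration_min
        assert gt.rates["fusion"] == pytest.approx(
            (gt.events.kind == "fusion").sum() / denom)
        assert gt.rates["fusion_tip_to_middle"] + gt.rates["fusion_tip_to_tip"] == \
            pytest.approx(gt.rates["fusion"])

    def test_class_fraction_matches_schedule(self, photoconversion_scene):
        gt = export_ground_truth(photoconversion_scene)
        fus = gt.events[gt.events.kind == "fusion"]
        if len(fus):
            frac = (fus.fusion_class == "tip_to_middle").mean()
            sched = [e for e in photoconversion_scene.events.realized()
                     if e.kind == "fusion"]
            assert frac == pytest.approx(
                sum(e.fusion_class == "tip_to_middle" for e in sched) / len(sched))


def test_ddfp_channel_marks_er_mito_overlap(noise_free_optics):
    from mitonode.simulate import SceneParams
    scene = build_scene(SceneParams(n_mito=2, n_er_tubules=3, fov_um=10.0,
                                    with_ddfp=True), seed=6)
    stack = render_movie(scene, noise_free_optics, seed=0)
    ddfp = stack.plane(role="ddfp") - noise_free_optics.background
    mito = stack.plane(role="mito") - noise_free_optics.background
    er = stack.plane(role="er") - noise_free_optics.background
    # ddFP signal only where both organelles have signal, peaking at crossings
    assert ddfp.max() > 0
    both = np.minimum(mito, er)
    np.testing.assert_allclose(ddfp, 3.0 * both, atol=1e-2)  # float32 storage
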