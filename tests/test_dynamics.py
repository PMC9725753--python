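import numpy as np
import pytest

from mitonode import (
    BinaryMask,
    Calibration,
    classify_fusion_event,
    compute_event_rates,
    detect_fission_events,
    detect_fusion_events,
    export_ground_truth,
    render_movie,
    skeletonize_mask,
    track_components,
)
from mitonode.dynamics import (
    DegenerateSkeletonError,
    EventRecord,
    NoConvertedObjectError,
    score_movie,
)


def bar_labels(n_frames, bars):
    """Synthetic label movies: bars[label] = fn(frame) -> (r0, r1, c0, c1) or None."""
    out = []
    for f in range(n_frames):
        img = np.zeros((60, 60), dtype=int)
        for label, fn in bars.items():
            box = fn(f)
            if box is not None:
                r0, r1, c0, c1 = box
                img[r0:r1, c0:c1] = label
        out.append(img)
    return out


class TestTracking:
    def test_static_object_single_track(self):
        labels = bar_labels(60, {1: lambda f: (10, 15, 10, 40)})
        g = track_components(labels)
        assert len(g.tracks) == 1
        t = g.tracks[0]
        assert (t.birth, t.death) == (0, 59)

    def test_split_recorded_with_two_children(self):
        labels = bar_labels(40, {
            1: lambda f: (10, 15, 10, 40) if f < 20 else None,
            2: lambda f: (10, 15, 10, 22) if f >= 20 else None,
            3: lambda f: (10, 15, 28, 40) if f >= 20 else None,
        })
        g = track_components(labels)
        assert len(g.splits) == 1
        s = g.splits[0]
        assert s.frame == 20
        assert len(s.children) == 2

    def test_merge_recorded_with_two_parents(self):
        labels = bar_labels(40, {
            1: lambda f: (10, 15, 5, 25) if f < 30 else None,
            2: lambda f: (10, 15, 30, 50) if f < 30 else None,
            3: lambda f: (10, 15, 5, 50) if f >= 30 else None,
        })
        g = track_components(labels)
        assert len(g.merges) == 1
        assert len(g.merges[0].parents) == 2
        assert g.merges[0].frame == 30

    def test_overlap_matrix_matches_truth_on_simulated_labels(
            self, photoconversion_scene):
        from mitonode.simulate import render_true_labels
        gt = export_ground_truth(photoconversion_scene)
        frames = sorted({int(round(t / 5.0))
                         for t in gt.events.time_s} | {0, 5})
        labels = [render_true_labels(photoconversion_scene, frame=f)
                  for f in range(0, max(frames) + 2)]
        g = track_components(labels)
        # each fission contributes one extra object, each fusion removes one;
        # simultaneous fusions fold into one merge record with extra parents
        n_topology_changes = (sum(len(s.children) - 1 for s in g.splits)
                              + sum(len(m.parents) - 1 for m in g.merges))
        assert n_topology_changes == len(gt.events)


class TestFissionRules:
    def test_persisting_children_give_one_fission(self):
        labels = bar_labels(40, {
            1: lambda f: (10, 15, 10, 40) if f < 20 else None,
            2: lambda f: (10, 15, 10, 22) if f >= 20 else None,
            3: lambda f: (10, 15, 28, 40) if f >= 20 else None,
        })
        g = track_components(labels)
        events = detect_fission_events(g)
        assert len(events) == 1
        assert events[0].kind == "fission"

    def test_immediate_remerge_is_not_fission(self):
        labels = bar_labels(40, {
            1: lambda f: (10, 15, 10, 40) if f < 20 or f > 21 else None,
            2: lambda f: (10, 15, 10, 22) if f in (20, 21) else None,
            3: lambda f: (10, 15, 28, 40) if f in (20, 21) else None,
        })
        g = track_components(labels)
        assert detect_fission_events(g, min_persist_frames=3) == []

    def test_boundary_splits_excluded(self):
        labels = bar_labels(10, {
            1: lambda f: (10, 15, 10, 40) if f < 9 else None,
            2: lambda f: (10, 15, 10, 22) if f >= 9 else None,
            3: lambda f: (10, 15, 28, 40) if f >= 9 else None,
        })
        g = track_components(labels)
        assert detect_fission_events(g) == []


class TestFusionDetection:
    def test_no_converted_object_is_an_error(self):
        labels = bar_labels(10, {1: lambda f: (10, 15, 10, 40)})
        g = track_components(labels)
        conv = np.full((10, 60, 60), 100.0)
        with pytest.raises(NoConvertedObjectError):
            detect_fusion_events(g, conv)

    def test_movie_without_contacts_has_no_fusion(self):
        labels = bar_labels(20, {
            1: lambda f: (10, 15, 10, 25),
            2: lambda f: (40, 45, 10, 25),
        })
        g = track_components(labels)
        conv = np.full((20, 60, 60), 100.0)
        conv[:, 10:15, 10:25] = 800.0
        assert detect_fusion_events(g, conv) == []

    def test_mixing_confirms_fusion_and_no_mixing_rejects(self):
        def scenario(mixes):
            labels = bar_labels(30, {
                1: lambda f: (10, 15, 5, 25) if f < 12 else None,
                2: lambda f: (10, 15, 27, 45) if f < 12 else None,
                3: lambda f: (10, 15, 5, 45) if f >= 12 else None,
            })
            conv = np.full((30, 60, 60), 100.0)
            conv[:, 10:15, 5:25] = 900.0           # donor always red
            if mixes:
                conv[12:, 10:15, 25:45] = 900.0    # label spreads on contact
            g = track_components(labels)
            return detect_fusion_events(g, conv)

        fused = scenario(mixes=True)
        assert len(fused) == 1
        assert fused[0].kind == "fusion" and fused[0].frame == 12
        assert scenario(mixes=False) == []

    def test_simulated_fusion_times_within_one_frame(self, photoconversion_scene,
                                                     photoconversion_stack):
        gt = export_ground_truth(photoconversion_scene)
        events, rates = score_movie(photoconversion_stack)
        det = sorted(e.frame for e in events if e.kind == "fusion")
        true = sorted(int(round(t / 5.0))
                      for t in gt.events[gt.events.kind == "fusion"].time_s)
        assert len(det) == len(true)
        assert all(abs(a - b) <= 1 for a, b in zip(det, true))

    def test_kiss_and_run_contact_not_scored(self):
        from mitonode.simulate import SceneParams, build_scene, apply_photoconversion
        from mitonode.imgio import ROI
        scene = build_scene(SceneParams.photoconversion_movie(
            fusion_rate_tip_to_middle=0.0, fusion_rate_tip_to_tip=0.0,
            fission_rate=0.0, n_kiss=2), seed=17)
        pts = scene.filaments[0].points
        mid = pts[len(pts) // 2]
        scene = apply_photoconversion(scene, ROI(
            origin=(int(mid[0] / 0.1) - 10, int(mid[1] / 0.1) - 10), size=(2.0, 2.0)))
        stack = render_movie(scene, seed=517)
        events, rates = score_movie(stack)
        assert rates.n_fusion == 0


class TestClassification:
    def two_bar_masks(self, contact="tip"):
        """Donor bar approaching an acceptor bar end-on or broadside."""
        acceptor = np.zeros((80, 80), dtype=bool)
        acceptor[38:43, 10:60] = True
        donor = np.zeros((80, 80), dtype=bool)
        if contact == "tip":
            donor[38:43, 63:78] = True     # colinear, tip near acceptor's right end
            contact_px = (40.0, 60.0)
            donor_contact = (40.0, 63.0)
        else:
            donor[10:35, 33:38] = True     # perpendicular, tip near acceptor middle
            contact_px = (38.0, 35.0)
            donor_contact = (35.0, 35.0)
        return acceptor, donor, contact_px, donor_contact

    def classify(self, contact):
        acceptor, donor, cpx, dpx = self.two_bar_masks(contact)
        ev = EventRecord(time_s=0, frame=5, kind="fusion", contact_px=cpx)
        return classify_fusion_event(
            ev, skeletonize_mask(BinaryMask(donor)), skeletonize_mask(BinaryMask(acceptor)),
            donor_contact_px=dpx), ev

    def test_contact_at_both_tips_is_tip_to_tip(self):
        cls, _ = self.classify("tip")
        assert cls == "tip_to_tip"

    def test_tip_on_midbody_is_tip_to_middle(self):
        cls, ev = self.classify("middle")
        assert cls == "tip_to_middle"
        assert not ev.atypical

    def test_degenerate_skeleton_raises(self):
        blob = np.zeros((30, 30), dtype=bool)
        # a ring: the skeleton is a closed loop with no endpoints
        yy, xx = np.mgrid[0:30, 0:30]
        r = np.hypot(yy - 15, xx - 15)
        blob[(r > 6) & (r < 11)] = True
        ev = EventRecord(time_s=0, frame=5, kind="fusion", contact_px=(15.0, 4.0))
        with pytest.raises(DegenerateSkeletonError):
            classify_fusion_event(ev, skeletonize_mask(BinaryMask(blob)),
                                  skeletonize_mask(BinaryMask(blob)))


class TestRates:
    def test_rate_arithmetic(self):
        events = [EventRecord(time_s=0, frame=2, kind="fusion",
                              fusion_class="tip_to_middle")] * 5
        r = compute_event_rates(events, n_mitochondria=4, duration_min=5.0)
        assert r.fusion_rate == pytest.approx(0.25)

    def test_zero_events(self):
        r = compute_event_rates([], n_mitochondria=3, duration_min=5.0)
        assert r.fusion_rate == r.fission_rate == 0.0

    def test_class_rates_sum_exactly_to_total(self):
        rng = np.random.default_rng(0)
        events = [EventRecord(time_s=0, frame=2, kind="fusion",
                              fusion_class=rng.choice(["tip_to_tip", "tip_to_middle"]))
                  for _ in range(37)]
        r = compute_event_rates(events, n_mitochondria=7, duration_min=5.0)
        assert r.tip_to_tip_rate + r.tip_to_middle_rate == r.fusion_rate

    def test_invalid_denominators_rejected(self):
        with pytest.raises(ValueError):
            compute_event_rates([], n_mitochondria=0, duration_min=5.0)
        with pytest.raises(ValueError):
            compute_event_rates([], n_mitochondria=3, duration_min=0.0)
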