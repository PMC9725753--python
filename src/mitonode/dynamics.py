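"""Photoconversion time-lapse analysis.

Mitochondria are segmented per frame and linked by mask overlap into tracks
with explicit split/merge topology. Fusion is scored when a previously
unconverted mitochondrion, upon merging with the photoconverted one,
acquires converted-channel fluorescence (mixing); fission is scored at
splits whose daughters persist without re-merging. Fusion events are binned
into tip-to-tip (contact at a tip of both partners) and tip-to-middle
(a tip of the moving partner meets the other's mid-body), and rates are
events per mitochondrion per minute.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .imgio import BinaryMask, Calibration, ImageStack
from .morphology import LabeledObjects, SkeletonGraph, label_components, otsu_mask, skeletonize_mask

TIP_TO_TIP = "tip_to_tip"
TIP_TO_MIDDLE = "tip_to_middle"


@dataclass
class Track:
    """One mitochondrion's identity through time."""

    id: int
    frame_labels: dict[int, int]  # frame -> label in that frame's label image
    birth: int
    death: int  # inclusive
    parents: list[int] = field(default_factory=list)
    children: list[int] = field(default_factory=list)
    born_by_merge: bool = False
    born_by_split: bool = False


@dataclass
class SplitRecord:
    frame: int  # first frame with the children separate
    parent: int
    children: tuple[int, ...]


@dataclass
class MergeRecord:
    frame: int  # first frame with the merged object
    parents: tuple[int, ...]
    child: int


@dataclass
class TrackGraph:
    tracks: dict[int, Track]
    splits: list[SplitRecord]
    merges: list[MergeRecord]
    labels: list[np.ndarray]  # per-frame label images

    def mask(self, track_id: int, frame: int) -> np.ndarray:
        lbl = self.tracks[track_id].frame_labels[frame]
        return self.labels[frame] == lbl


def track_components(movie_labels: list[LabeledObjects] | list[np.ndarray],
                     min_overlap_frac: float = 0.3) -> TrackGraph:
    """Link per-frame labelled objects into tracks by maximal pixel overlap.

    Two objects in consecutive frames are linked when their overlap is at
    least `min_overlap_frac` of the smaller of the two. One-to-many links
    record a split, many-to-one a merge; in either case the involved tracks
    are closed and children started, so every object has a single identity
    per topology interval.
    """
    labels = [l.labels if isinstance(l, LabeledObjects) else np.asarray(l)
              for l in movie_labels]
    if len(labels) < 2:
        raise ValueError("need at least 2 frames to track")

    tracks: dict[int, Track] = {}
    splits: list[SplitRecord] = []
    merges: list[MergeRecord] = []
    next_id = 0

    def new_track(frame: int, label: int, **kw) -> int:
        nonlocal next_id
        tracks[next_id] = Track(id=next_id, frame_labels={frame: label},
                                birth=frame, death=frame, **kw)
        next_id += 1
        return next_id - 1

    active: dict[int, int] = {}  # label in current frame -> track id
    for lbl in np.unique(labels[0]):
        if lbl > 0:
            active[int(lbl)] = new_track(0, int(lbl))

    for f in range(1, len(labels)):
        prev, cur = labels[f - 1], labels[f]
        prev_ids = [l for l in np.unique(prev) if l > 0]
        cur_ids = [l for l in np.unique(cur) if l > 0]
        areas_prev = {l: int((prev == l).sum()) for l in prev_ids}
        areas_cur = {l: int((cur == l).sum()) for l in cur_ids}
        # overlap counts via joint histogram
        joint = prev.astype(np.int64) * (cur.max() + 1) + cur
        vals, counts = np.unique(joint[(prev > 0) & (cur > 0)], return_counts=True)
        links: dict[int, list[int]] = {l: [] for l in prev_ids}   # prev -> [cur]
        rlinks: dict[int, list[int]] = {l: [] for l in cur_ids}   # cur -> [prev]
        for v, n in zip(vals, counts):
            p, c = int(v // (cur.max() + 1)), int(v % (cur.max() + 1))
            if n >= min_overlap_frac * min(areas_prev[p], areas_cur[c]):
                links[p].append(c)
                rlinks[c].append(p)

        new_active: dict[int, int] = {}
        handled_cur: set[int] = set()
        # simple continuations first
        for p, cs in links.items():
            if len(cs) == 1 and len(rlinks[cs[0]]) == 1:
                t = active[p]
                tracks[t].frame_labels[f] = cs[0]
                tracks[t].death = f
                new_active[cs[0]] = t
                handled_cur.add(cs[0])
        # splits: one parent, several children
        for p, cs in links.items():
            if len(cs) >= 2 and all(len(rlinks[c]) == 1 for c in cs):
                parent = active[p]
                child_ids = []
                for c in cs:
                    t = new_track(f, c, parents=[parent], born_by_split=True)
                    child_ids.append(t)
                    new_active[c] = t
                    handled_cur.add(c)
                tracks[parent].children = child_ids
                splits.append(SplitRecord(frame=f, parent=parent,
                                          children=tuple(child_ids)))
        # merges and any remaining many-to-many topology
        for c in cur_ids:
            if c in handled_cur:
                continue
            ps = rlinks[c]
            parent_tracks = [active[p] for p in ps]
            t = new_track(f, c, parents=parent_tracks,
                          born_by_merge=len(parent_tracks) >= 2)
            for pt in parent_tracks:
                tracks[pt].children.append(t)
            if len(parent_tracks) >= 2:
                merges.append(MergeRecord(frame=f, parents=tuple(parent_tracks), child=t))
            new_active[c] = t
        active = new_active

    return TrackGraph(tracks=tracks, splits=splits, merges=merges, labels=labels)


@dataclass
class EventRecord:
    """A scored fission or fusion event."""

    time_s: float
    frame: int
    kind: str  # 'fission' | 'fusion'
    fusion_class: str = "none"
    participants: tuple[int, ...] = ()
    contact_px: tuple[float, float] | None = None
    evidence: float = 0.0  # mixing ratio (fusion) or post-split persistence frames
    atypical: bool = False

    def __post_init__(self) -> None:
        if self.kind == "fission" and self.fusion_class != "none":
            raise ValueError("fission events carry class 'none'")


class NoConvertedObjectError(ValueError):
    """No photoconverted mitochondrion is present at the start of the movie."""


def _track_mean(graph: TrackGraph, conv: np.ndarray, track: int, frame: int,
                bg: float) -> float:
    m = graph.mask(track, frame)
    return float(conv[frame][m].mean() - bg) if m.any() else 0.0


def detect_fusion_events(graph: TrackGraph, converted_movie: np.ndarray,
                         mixing_ratio_min: float = 0.1,
                         frame_interval_s: float = 5.0,
                         confirm_frames: int = 3) -> list[EventRecord]:
    """Score fusion by converted-fluorescence mixing at mask merges.

    The single photoconverted object is identified at the first frame. At
    each merge of a converted with an unconverted track, the event is
    confirmed when the mean converted-channel intensity over the unconverted
    partner's pre-merge footprint reaches `mixing_ratio_min` of the donor's
    mean within `confirm_frames` frames of contact — transient contacts
    without label transfer are thereby rejected. Merges touching the movie
    boundaries are excluded.
    """
    conv = np.asarray(converted_movie, dtype=float)
    n_frames = conv.shape[0]
    bg = float(np.median(conv[0]))
    noise = 1.4826 * float(np.median(np.abs(conv[0] - bg))) + 1e-9

    first = [t for t in graph.tracks.values() if t.birth == 0]
    if not first:
        raise NoConvertedObjectError("no objects at the first frame")
    means = {t.id: _track_mean(graph, conv, t.id, 0, bg) for t in first}
    source = max(means, key=means.get)
    if means[source] <= 5 * noise:
        raise NoConvertedObjectError("no photoconverted object found at movie start")

    converted: set[int] = {source}
    events: list[EventRecord] = []
    for merge in sorted(graph.merges, key=lambda m: m.frame):
        f = merge.frame
        if f <= 1 or f >= n_frames - 1:
            continue
        conv_parents = [p for p in merge.parents if p in converted]
        naive_parents = [p for p in merge.parents if p not in converted]
        # the merged object inherits the converted label regardless of mixing:
        # the donor's fluorophores are inside it either way
        if conv_parents:
            converted.add(merge.child)
        if not conv_parents or not naive_parents:
            continue
        donor = max(conv_parents,
                    key=lambda p: _track_mean(graph, conv, p, f - 1, bg))
        donor_mean = _track_mean(graph, conv, donor, f - 1, bg)
        if donor_mean <= 0:
            continue
        donor_mask = graph.mask(donor, f - 1)
        for q in naive_parents:
            foot = graph.mask(q, f - 1)
            for t in range(f, min(f + confirm_frames, n_frames)):
                ratio = float(conv[t][foot].mean() - bg) / donor_mean
                if ratio >= mixing_ratio_min:
                    contact = _contact_point(donor_mask, foot)
                    events.append(EventRecord(
                        time_s=t * frame_interval_s, frame=t, kind="fusion",
                        fusion_class="none", participants=(donor, q),
                        contact_px=contact, evidence=ratio,
                    ))
                    converted.add(q)
                    break
    return events


def closest_approach(mask_a: np.ndarray, mask_b: np.ndarray
                     ) -> tuple[tuple[float, float], tuple[float, float]]:
    """The closest pixel pair ``(point_on_a, point_on_b)`` between two masks.

    This is where two approaching mitochondria touch: each partner's contact
    point is its own pixel nearest the other partner.
    """
    if not mask_a.any() or not mask_b.any():
        raise ValueError("closest_approach requires two non-empty masks")
    dt, idx = ndimage.distance_transform_edt(~mask_a, return_indices=True)
    bpix = np.argwhere(mask_b)
    j = int(np.argmin(dt[bpix[:, 0], bpix[:, 1]]))
    pb = bpix[j]
    pa = idx[:, pb[0], pb[1]]
    return (float(pa[0]), float(pa[1])), (float(pb[0]), float(pb[1]))


def _contact_point(mask_a: np.ndarray, mask_b: np.ndarray) -> tuple[float, float]:
    """Midpoint of the closest approach between two masks."""
    pa, pb = closest_approach(mask_a, mask_b)
    return ((pa[0] + pb[0]) / 2.0, (pa[1] + pb[1]) / 2.0)


def detect_fission_events(graph: TrackGraph, min_persist_frames: int = 3,
                          frame_interval_s: float = 5.0) -> list[EventRecord]:
    """Score fission at splits whose daughters both persist.

    A split counts when both children live at least `min_persist_frames`
    frames without re-merging with each other, and the parent was not itself
    a transient contact (born from a merge fewer than `min_persist_frames`
    frames earlier). Splits within one frame of the movie boundaries are
    excluded.
    """
    n_frames = len(graph.labels)
    merges_by_parents = {}
    for m in graph.merges:
        merges_by_parents.setdefault(frozenset(m.parents), []).append(m.frame)

    def lineage_ids(track: int, upto: int) -> set[int]:
        """The track and its continuation chain up to frame `upto`."""
        out = {track}
        frontier = [track]
        while frontier:
            t = frontier.pop()
            for c in graph.tracks[t].children:
                if graph.tracks[c].birth <= upto:
                    out.add(c)
                    frontier.append(c)
        return out

    events: list[EventRecord] = []
    for split in graph.splits:
        f = split.frame
        if f <= 1 or f >= n_frames - 1:
            continue
        parent = graph.tracks[split.parent]
        if parent.born_by_merge and f - parent.birth < min_persist_frames:
            continue  # transient contact, not fission
        ok = True
        horizon = f + min_persist_frames
        kids = split.children
        for c in kids:
            life = graph.tracks[c].death - graph.tracks[c].birth + 1
            # a child that closes early because it split or merged again is
            # still a persisting mitochondrion; only a vanishing child (no
            # successors) breaks persistence
            if (graph.tracks[c].death < n_frames - 1 and life < min_persist_frames
                    and not graph.tracks[c].children):
                ok = False
        if ok and len(kids) == 2:
            # re-merge of the same pair (including continuations) within the window?
            la = lineage_ids(kids[0], horizon)
            lb = lineage_ids(kids[1], horizon)
            for m in graph.merges:
                if f < m.frame <= horizon and set(m.parents) & la and set(m.parents) & lb:
                    ok = False
                    break
        if ok:
            pm = graph.mask(split.parent, f - 1)
            com = ndimage.center_of_mass(pm)
            events.append(EventRecord(
                time_s=f * frame_interval_s, frame=f, kind="fission",
                participants=(split.parent,) + tuple(kids),
                contact_px=(float(com[0]), float(com[1])),
                evidence=float(min(graph.tracks[c].death - f + 1 for c in kids)),
            ))
    return events


class DegenerateSkeletonError(ValueError):
    """A fusion partner's skeleton has no endpoints; class is undecidable."""


def geodesic_tip_distance(skeleton: SkeletonGraph, point_px) -> float:
    """Arc distance (µm) along the skeleton from `point_px` to the nearest
    organelle end.

    The point is snapped to the nearest centreline pixel, then the shortest
    along-skeleton path to any endpoint node is measured. This asks "how far
    from the end of the organelle is this contact?" without being confused
    by mask caps or the medial axis stopping short of blunt tips.
    """
    if not skeleton.edges:
        raise DegenerateSkeletonError("empty skeleton")
    deg = skeleton._degrees()
    end_nodes = {n for n, dg in deg.items() if dg == 1}
    if not end_nodes:
        raise DegenerateSkeletonError("skeleton has no endpoints")
    point = np.asarray(point_px, dtype=float)
    px = skeleton.calibration.pixel_size
    best = None  # (pixel distance, edge index, path index)
    for ei, e in enumerate(skeleton.edges):
        dd = np.linalg.norm(e.path - point, axis=1)
        i = int(dd.argmin())
        if best is None or dd[i] < best[0]:
            best = (float(dd[i]), ei, i)
    _, ei, i = best
    edge = skeleton.edges[ei]
    steps = np.abs(np.diff(edge.path, axis=0))
    step_um = np.where(steps.sum(axis=1) == 2, np.sqrt(2.0), 1.0) * px
    arc_from_start = float(step_um[:i].sum())
    arc_to_end = edge.length_um - arc_from_start

    import networkx as nx
    g = nx.MultiGraph()
    for n in skeleton.nodes:
        g.add_node(n)
    for e in skeleton.edges:
        g.add_edge(e.nodes[0], e.nodes[1], weight=e.length_um)
    out = np.inf
    for node, offset in ((edge.nodes[0], arc_from_start), (edge.nodes[1], arc_to_end)):
        lengths = nx.single_source_dijkstra_path_length(g, node)
        reach = min((lengths[t] for t in end_nodes if t in lengths), default=np.inf)
        out = min(out, offset + reach)
    return float(out)


def _locate_contact(graph: TrackGraph, p1: int, p2: int, f: int,
                    m1: np.ndarray, m2: np.ndarray):
    """Per-partner contact points for a fusion at frame f+1.

    The new material bridging the partners (child mask minus the dilated
    union of the parent masks) marks where fusion happened; each partner's
    contact is its pixel nearest that bridge. Without a usable bridge the
    global closest approach between the parent masks is used.
    """
    fm = f + 1
    if fm < len(graph.labels):
        child_labels = set(graph.labels[fm][m1]) | set(graph.labels[fm][m2])
        child_labels.discard(0)
        if child_labels:
            child = np.isin(graph.labels[fm], list(child_labels))
            # truly new material: inside the child but near no object of the
            # previous frame (concurrent fusion partners included)
            occupied = ndimage.binary_dilation(graph.labels[f] > 0, iterations=2)
            growth = child & ~occupied
            # the bridge of THIS event touches both of its partners
            near_pair = (ndimage.binary_dilation(m1, iterations=4)
                         & ndimage.binary_dilation(m2, iterations=10))
            lab, n = ndimage.label(growth)
            best, best_size = None, 0
            for k in range(1, n + 1):
                comp = lab == k
                size = int(comp.sum())
                if size >= 6 and (comp & near_pair).any() and size > best_size:
                    best, best_size = comp, size
            if best is not None:
                ref = np.array(ndimage.center_of_mass(best))
                out = []
                for m in (m1, m2):
                    pix = np.argwhere(m)
                    p = pix[int(np.argmin(np.linalg.norm(pix - ref, axis=1)))]
                    out.append((float(p[0]), float(p[1])))
                return out[0], out[1]
    return closest_approach(m1, m2)


def classify_fusion_event(event: EventRecord, donor_skeleton: SkeletonGraph,
                          acceptor_skeleton: SkeletonGraph,
                          d_end: float = 0.5,
                          donor_contact_px: tuple[float, float] | None = None) -> str:
    """Bin a fusion event as tip-to-tip or tip-to-middle.

    Tip-to-tip: the contact point lies within `d_end` µm of a skeleton
    endpoint of both partners. Tip-to-middle: within `d_end` of a donor
    endpoint but at least `d_end` from every acceptor endpoint. Any other
    geometry is classified tip-to-middle with ``event.atypical`` set.

    When the two partners were still separated at the pre-event frame,
    `donor_contact_px` may give the donor-side closest-approach point (its
    pixel nearest the acceptor); the donor-endpoint distance is then
    measured from it instead of from the shared contact point.
    """
    if event.contact_px is None:
        raise ValueError("event carries no contact point")
    contact = np.array(event.contact_px, dtype=float)
    d_contact = (np.array(donor_contact_px, dtype=float)
                 if donor_contact_px is not None else contact)
    d_donor = geodesic_tip_distance(donor_skeleton, d_contact)
    d_acceptor = geodesic_tip_distance(acceptor_skeleton, contact)
    if d_donor <= d_end and d_acceptor <= d_end:
        event.fusion_class = TIP_TO_TIP
    elif d_donor <= d_end:
        event.fusion_class = TIP_TO_MIDDLE
    else:
        event.fusion_class = TIP_TO_MIDDLE
        event.atypical = True
    return event.fusion_class


@dataclass
class RateSummary:
    """Event counts and per-mitochondrion-per-minute rates (the movie-table
    layout: total mitochondria, total events, event types, rates)."""

    n_mitochondria: int
    duration_min: float
    n_fusion: int
    n_fission: int
    n_tip_to_tip: int
    n_tip_to_middle: int
    fusion_rate: float
    fission_rate: float
    tip_to_tip_rate: float
    tip_to_middle_rate: float


def compute_event_rates(events: list[EventRecord], n_mitochondria: int,
                        duration_min: float) -> RateSummary:
    """Rates = event count / (n_mitochondria × duration); class rates sum
    exactly to the total fusion rate."""
    if n_mitochondria < 1:
        raise ValueError("n_mitochondria must be >= 1")
    if duration_min <= 0:
        raise ValueError("duration_min must be > 0")
    fus = [e for e in events if e.kind == "fusion"]
    fis = [e for e in events if e.kind == "fission"]
    n_tt = sum(1 for e in fus if e.fusion_class == TIP_TO_TIP)
    n_tm = sum(1 for e in fus if e.fusion_class == TIP_TO_MIDDLE)
    denom = n_mitochondria * duration_min
    return RateSummary(
        n_mitochondria=n_mitochondria, duration_min=duration_min,
        n_fusion=len(fus), n_fission=len(fis),
        n_tip_to_tip=n_tt, n_tip_to_middle=n_tm,
        fusion_rate=len(fus) / denom, fission_rate=len(fis) / denom,
        tip_to_tip_rate=n_tt / denom, tip_to_middle_rate=n_tm / denom,
    )


def segment_movie(stack: ImageStack, role: str = "native",
                  min_size_px: int = 9) -> list[LabeledObjects]:
    """Per-frame Otsu segmentation + particle labelling of one channel."""
    out = []
    for f in range(stack.n_frames):
        plane = stack.plane(frame=f, role=role)
        mask = otsu_mask(plane, calibration=stack.calibration)
        objs = label_components(mask)
        lab = objs.labels.copy()
        for l in range(1, objs.count + 1):
            if objs.areas_px[l - 1] < min_size_px:
                lab[lab == l] = 0
        # relabel contiguously
        uniq = [u for u in np.unique(lab) if u > 0]
        relab = np.zeros_like(lab)
        for i, u in enumerate(uniq, start=1):
            relab[lab == u] = i
        areas = np.array([(relab == i).sum() for i in range(1, len(uniq) + 1)], dtype=float)
        out.append(LabeledObjects(labels=relab, areas_px=areas,
                                  calibration=stack.calibration))
    return out


def score_movie(stack: ImageStack, mixing_ratio_min: float = 0.1,
                min_persist_frames: int = 3, d_end: float = 0.5,
                min_overlap_frac: float = 0.3) -> tuple[list[EventRecord], RateSummary]:
    """End-to-end scoring of a photoconversion movie.

    Segments the native (total OMM label) channel, tracks objects, detects
    fusion by converted-channel mixing and fission by persistent splits,
    classifies fusion events by pre-event partner skeletons, and computes
    rates with the first-frame mitochondrion count as denominator.
    """
    cal = stack.calibration
    movie_labels = segment_movie(stack, role="native")
    graph = track_components(movie_labels, min_overlap_frac=min_overlap_frac)
    conv = stack.pixels[:, 0, stack.channel("converted")]
    fusions = detect_fusion_events(graph, conv, mixing_ratio_min=mixing_ratio_min,
                                   frame_interval_s=cal.frame_interval)
    fissions = detect_fission_events(graph, min_persist_frames=min_persist_frames,
                                     frame_interval_s=cal.frame_interval)
    for ev in fusions:
        p1, p2 = ev.participants
        # last frame at which both partners were still separate objects
        f = max(graph.tracks[p1].frame_labels.keys()
                & graph.tracks[p2].frame_labels.keys())
        m1, m2 = graph.mask(p1, f), graph.mask(p2, f)
        c1, c2 = _locate_contact(graph, p1, p2, f, m1, m2)
        # aggressive spur pruning: junction blobs in merged objects grow
        # short thinning artifacts whose endpoints would mimic tips
        sk1 = skeletonize_mask(BinaryMask(m1, calibration=cal), prune_um=0.8)
        sk2 = skeletonize_mask(BinaryMask(m2, calibration=cal), prune_um=0.8)
        try:
            # the moving partner fuses tip-first: call the partner whose
            # contact point is nearer its own organelle end the donor
            if geodesic_tip_distance(sk1, c1) <= geodesic_tip_distance(sk2, c2):
                sk_d, sk_a, cd, ca = sk1, sk2, c1, c2
            else:
                sk_d, sk_a, cd, ca = sk2, sk1, c2, c1
            ev.contact_px = ca
            classify_fusion_event(ev, sk_d, sk_a, d_end=d_end, donor_contact_px=cd)
        except DegenerateSkeletonError:
            ev.fusion_class = "none"
    events = sorted(fusions + fissions, key=lambda e: e.frame)
    n_mito = int(np.max(movie_labels[0].count)) if movie_labels[0].count else 0
    n_mito = max(n_mito, 1)
    duration_min = (stack.n_frames - 1) * cal.frame_interval / 60.0
    rates = compute_event_rates(events, n_mito, duration_min)
    return events, rates
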