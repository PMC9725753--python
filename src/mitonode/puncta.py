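"""Machinery-puncta analysis: spot detection in movies, persistence
filtering, density per µm of mitochondrion, ER-crossing occupancy, and node
density (Drp1+Mfn1 co-localisation).

The persistence filter operationalises "puncta present throughout a 2-min
movie": detections are linked frame-to-frame by greedy nearest-neighbour
matching and tracks detected in at least ``min_persistence`` of the movie's
frames (default 80%, tolerating single-frame dropouts) count as puncta.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.feature import blob_log

from .contacts import CrossingSet, NoResolvableCrossingsError
from .imgio import Calibration
from .morphology import SkeletonGraph


@dataclass
class PunctumDetection:
    position_px: tuple[float, float]  # sub-pixel (row, col)
    sigma_px: float
    intensity: float


@dataclass
class PersistentPunctum:
    role: str
    centroid_px: tuple[float, float]
    persistence: float  # fraction of movie frames with a detection
    frame_positions: dict[int, tuple[float, float]]


@dataclass
class PunctaSet:
    puncta: list[PersistentPunctum]
    calibration: Calibration = field(default_factory=Calibration)

    def __len__(self) -> int:
        return len(self.puncta)

    def centroids_px(self) -> np.ndarray:
        return np.array([p.centroid_px for p in self.puncta], dtype=float).reshape(-1, 2)


def detect_puncta_frame(image: np.ndarray, min_sigma_um: float = 0.08,
                        max_sigma_um: float = 0.3, snr_min: float = 5.0,
                        calibration: Calibration | None = None) -> list[PunctumDetection]:
    """Detect diffraction-limited spots in one plane.

    Candidates are scale-space (Laplacian-of-Gaussian) blob maxima whose
    background-subtracted peak exceeds `snr_min` times the robust image
    noise; positions are refined to sub-pixel precision by an
    intensity-weighted centroid. A blank image yields an empty list.
    """
    cal = calibration or Calibration()
    image = np.asarray(image, dtype=float)
    bg = float(np.median(image))
    noise = 1.4826 * float(np.median(np.abs(image - bg)))
    sub = image - bg
    vmax = sub.max()
    if vmax <= 0:
        return []
    blobs = blob_log(
        sub / vmax,
        min_sigma=max(cal.um_to_px(min_sigma_um), 1),
        max_sigma=max(cal.um_to_px(max_sigma_um), 2),
        num_sigma=5,
        threshold=0.08,
    )
    out: list[PunctumDetection] = []
    for (r, c, s) in blobs:
        ri, ci = int(round(r)), int(round(c))
        peak = sub[ri, ci]
        if noise > 0 and peak / noise < snr_min:
            continue
        if noise == 0 and peak <= 0:
            continue
        # sub-pixel refinement: weighted centroid over a small window
        w = max(2, int(round(s)))
        r0, r1 = max(ri - w, 0), min(ri + w + 1, image.shape[0])
        c0, c1 = max(ci - w, 0), min(ci + w + 1, image.shape[1])
        win = np.clip(sub[r0:r1, c0:c1], 0, None)
        tot = win.sum()
        if tot > 0:
            rr, cc = np.mgrid[r0:r1, c0:c1]
            r_ref = float((rr * win).sum() / tot)
            c_ref = float((cc * win).sum() / tot)
        else:
            r_ref, c_ref = float(r), float(c)
        out.append(PunctumDetection(position_px=(r_ref, c_ref),
                                    sigma_px=float(s), intensity=float(peak)))
    return out


def link_persistent_puncta(frames: list[list[PunctumDetection]],
                           link_radius_um: float = 0.4,
                           min_persistence: float = 0.8,
                           calibration: Calibration | None = None,
                           role: str = "") -> PunctaSet:
    """Link per-frame detections into tracks and keep the persistent ones.

    Linking is greedy nearest-neighbour per frame step within
    `link_radius_um`; a track is persistent when detected in at least
    `min_persistence` of all movie frames.
    """
    if len(frames) < 2:
        raise ValueError("need at least 2 frames to assess persistence")
    cal = calibration or Calibration()
    radius_px = link_radius_um / cal.pixel_size

    tracks: list[dict] = []  # {last: (r,c), positions: {frame: (r,c)}}
    for det in frames[0]:
        tracks.append({"last": det.position_px, "positions": {0: det.position_px}})
    for f in range(1, len(frames)):
        dets = frames[f]
        if tracks and dets:
            t_pos = np.array([t["last"] for t in tracks])
            d_pos = np.array([d.position_px for d in dets])
            dist = np.linalg.norm(t_pos[:, None] - d_pos[None, :], axis=2)
            pairs = sorted(
                ((dist[i, j], i, j) for i in range(len(tracks)) for j in range(len(dets))),
                key=lambda t: t[0],
            )
            used_t: set[int] = set()
            used_d: set[int] = set()
            for d, i, j in pairs:
                if d > radius_px:
                    break
                if i in used_t or j in used_d:
                    continue
                used_t.add(i)
                used_d.add(j)
                tracks[i]["last"] = dets[j].position_px
                tracks[i]["positions"][f] = dets[j].position_px
        else:
            used_d = set()
        for j, det in enumerate(dets):
            if j not in used_d:
                tracks.append({"last": det.position_px, "positions": {f: det.position_px}})

    n_frames = len(frames)
    puncta = []
    for t in tracks:
        persistence = len(t["positions"]) / n_frames
        if persistence >= min_persistence:
            pos = np.array(list(t["positions"].values()))
            puncta.append(PersistentPunctum(
                role=role,
                centroid_px=(float(pos[:, 0].mean()), float(pos[:, 1].mean())),
                persistence=persistence,
                frame_positions=dict(t["positions"]),
            ))
    return PunctaSet(puncta=puncta, calibration=cal)


def assign_to_skeleton(puncta: PunctaSet, skeleton: SkeletonGraph,
                       assignment_radius_um: float = 0.5) -> PunctaSet:
    """Puncta within `assignment_radius_um` of the skeleton centreline."""
    skel_px = skeleton.all_path_pixels()
    if len(skel_px) == 0:
        return PunctaSet(puncta=[], calibration=puncta.calibration)
    px = puncta.calibration.pixel_size
    keep = []
    for p in puncta.puncta:
        d = np.linalg.norm(skel_px - np.array(p.centroid_px), axis=1).min() * px
        if d <= assignment_radius_um:
            keep.append(p)
    return PunctaSet(puncta=keep, calibration=puncta.calibration)


def puncta_density(puncta: PunctaSet, mito_length_um: float,
                   skeleton: SkeletonGraph | None = None,
                   assignment_radius_um: float = 0.5) -> float:
    """Puncta per µm of mitochondrial length.

    When a skeleton is provided, only puncta within `assignment_radius_um`
    of the centreline are counted (the punctum-to-mitochondrion assignment
    rule); `mito_length_um` is the skeleton length of the organelle.
    """
    if mito_length_um <= 0:
        raise ValueError("mito_length_um must be > 0")
    if skeleton is not None:
        puncta = assign_to_skeleton(puncta, skeleton, assignment_radius_um)
    return len(puncta) / mito_length_um


def fraction_crossings_with_puncta(crossings: CrossingSet, puncta: PunctaSet,
                                   match_radius: float = 0.3) -> float:
    """Fraction of resolvable ER crossings with a persistent punctum within
    `match_radius` µm (the Drp1-at-crossings readout)."""
    res = crossings.resolvable()
    if not res:
        raise NoResolvableCrossingsError("no resolvable ER-mitochondria crossings")
    px = crossings.calibration.pixel_size
    pos = puncta.centroids_px()
    n_hit = 0
    for c in res:
        if len(pos):
            d = np.linalg.norm(pos - np.array(c.position_px), axis=1) * px
            if (d <= match_radius).any():
                n_hit += 1
    return n_hit / len(res)


def match_puncta_pairs(puncta_a: PunctaSet, puncta_b: PunctaSet,
                       coloc_radius_um: float = 0.3) -> list[tuple[int, int]]:
    """One-to-one nearest-first matching between two puncta sets.

    Pairs are formed in ascending distance order (ties broken by punctum
    index), each punctum used at most once, within `coloc_radius_um`.
    """
    a, b = puncta_a.centroids_px(), puncta_b.centroids_px()
    if len(a) == 0 or len(b) == 0:
        return []
    px = puncta_a.calibration.pixel_size
    dist = np.linalg.norm(a[:, None] - b[None, :], axis=2) * px
    pairs = sorted(((dist[i, j], i, j) for i in range(len(a)) for j in range(len(b))),
                   key=lambda t: (t[0], t[1], t[2]))
    used_a: set[int] = set()
    used_b: set[int] = set()
    out = []
    for d, i, j in pairs:
        if d > coloc_radius_um:
            break
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        out.append((i, j))
    return out


def node_density(puncta_a: PunctaSet, puncta_b: PunctaSet,
                 mito_length_um: float, coloc_radius_um: float = 0.3) -> float:
    """Nodes (puncta containing both markers) per µm of mitochondrial length.

    A node is a punctum of set A with a one-to-one matched punctum of set B
    within `coloc_radius_um`; symmetric in A and B by construction.
    """
    if mito_length_um <= 0:
        raise ValueError("mito_length_um must be > 0")
    return len(match_puncta_pairs(puncta_a, puncta_b, coloc_radius_um)) / mito_length_um


@dataclass
class PunctaAnalysis:
    mfn1_density_per_um: float | None
    drp1_crossing_fraction: float | None
    node_density_per_um: float | None
    mito_length_um: float
    n_resolvable_crossings: int


def analyze_puncta_movie(stack, snr_min: float = 5.0,
                         min_persistence: float = 0.8,
                         link_radius_um: float = 0.4,
                         coloc_radius_um: float = 0.3,
                         crossing_match_radius_um: float = 0.3,
                         max_parallel_run: float = 1.0) -> PunctaAnalysis:
    """Score machinery-puncta metrics on a 2-min movie.

    Mitochondrial length comes from the tip-corrected skeleton of the
    time-averaged matrix channel; persistent puncta are detected per channel
    and assigned to the network. Returns Mfn1 density per µm, the fraction
    of resolvable ER crossings with a persistent Drp1 punctum, and node
    density (one-to-one Drp1–Mfn1 pairs per µm), each ``None`` when the
    movie lacks that channel.
    """
    from skimage.morphology import closing, disk

    from .contacts import detect_crossings
    from .morphology import otsu_mask, skeleton_length_with_tips, skeletonize_mask
    from .imgio import BinaryMask

    cal = stack.calibration
    mito_avg = stack.pixels[:, 0, stack.channel("mito")].mean(axis=0)
    mask = otsu_mask(mito_avg, calibration=cal)
    closed = BinaryMask(closing(mask.pixels, disk(3)), calibration=cal)
    skel = skeletonize_mask(closed)
    length = skeleton_length_with_tips(skel, closed)

    def persistent(role: str) -> PunctaSet | None:
        try:
            ch = stack.channel(role)
        except KeyError:
            return None
        frames = [detect_puncta_frame(stack.pixels[f, 0, ch], snr_min=snr_min,
                                      calibration=cal)
                  for f in range(stack.n_frames)]
        ps = link_persistent_puncta(frames, link_radius_um=link_radius_um,
                                    min_persistence=min_persistence,
                                    calibration=cal, role=role)
        return assign_to_skeleton(ps, skel)

    mfn1 = persistent("mfn1")
    drp1 = persistent("drp1")

    mfn1_density = len(mfn1) / length if (mfn1 is not None and length > 0) else None
    node_dens = (node_density(drp1, mfn1, length, coloc_radius_um)
                 if (drp1 is not None and mfn1 is not None and length > 0) else None)
    drp1_frac = None
    n_resolvable = 0
    try:
        er_ch = stack.channel("er")
    except KeyError:
        er_ch = None
    if er_ch is not None and drp1 is not None:
        er_avg = stack.pixels[:, 0, er_ch].mean(axis=0)
        er_mask = otsu_mask(er_avg, calibration=cal)
        crossings = detect_crossings(skel, er_mask, max_parallel_run=max_parallel_run)
        n_resolvable = len(crossings.resolvable())
        if n_resolvable:
            drp1_frac = fraction_crossings_with_puncta(
                crossings, drp1, match_radius=crossing_match_radius_um)
    return PunctaAnalysis(
        mfn1_density_per_um=mfn1_density,
        drp1_crossing_fraction=drp1_frac,
        node_density_per_um=node_dens,
        mito_length_um=length,
        n_resolvable_crossings=n_resolvable,
    )
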