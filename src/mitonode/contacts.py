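"""ER–mitochondria contacts: crossing detection on the mitochondrial skeleton,
line-scan extraction, constriction calling by the >=40% intensity-dip rule,
and binary-mask overlap (Mander's coefficient).

A *crossing* is a maximal run of mitochondrial-skeleton pixels inside the ER
mask; runs longer than ``max_parallel_run`` are where the ER travels along
the mitochondrion rather than across it and are flagged unresolvable. A
*constriction* is a local minimum of the matrix-marker intensity along the
organelle axis that sits at least ``drop_threshold`` (default 40%) below the
larger of its two flanking fluorescence peaks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .imgio import BinaryMask, Calibration
from .morphology import SkeletonGraph

logger = logging.getLogger("mitonode")


@dataclass
class Crossing:
    position_px: tuple[float, float]  # run midpoint (row, col)
    resolvable: bool
    run_length_um: float
    edge_index: int
    arc_um: float  # arc position of the midpoint along its skeleton edge


@dataclass
class CrossingSet:
    crossings: list[Crossing]
    calibration: Calibration = field(default_factory=Calibration)

    def resolvable(self) -> list[Crossing]:
        return [c for c in self.crossings if c.resolvable]

    def __len__(self) -> int:
        return len(self.crossings)


def detect_crossings(mito_skeleton: SkeletonGraph, er_mask: BinaryMask,
                     max_parallel_run: float = 1.0,
                     merge_gap_um: float = 0.3,
                     require_two_sided: bool = True) -> CrossingSet:
    """Find ER crossings as maximal skeleton-pixel runs inside the ER mask.

    Runs separated by less than `merge_gap_um` of skeleton outside the mask
    are merged (mask noise would otherwise split one crossing into several).
    Each run is reported at its midpoint; runs longer than `max_parallel_run`
    (µm) are flagged unresolvable and excluded from downstream denominators.
    With `require_two_sided`, a run only counts when the ER mask is present
    on both sides of the mitochondrial axis at the run midpoint — an ER
    tubule grazing one flank of the organelle is a touch, not a crossing.
    """
    px = mito_skeleton.calibration.pixel_size
    gap_px = int(round(merge_gap_um / px))
    crossings: list[Crossing] = []
    for ei, edge in enumerate(mito_skeleton.edges):
        path = edge.path
        inside = er_mask.pixels[path[:, 0], path[:, 1]].copy()
        if gap_px > 0:
            run_start = None
            prev_end = None
            for i in range(len(inside)):
                if inside[i]:
                    if run_start is None:
                        run_start = i
                        if prev_end is not None and run_start - prev_end <= gap_px:
                            inside[prev_end:run_start] = True
                else:
                    if run_start is not None:
                        prev_end = i
                    run_start = None
        # step lengths between consecutive path pixels, in µm
        steps = np.zeros(len(path))
        if len(path) > 1:
            d = np.abs(np.diff(path, axis=0))
            steps[1:] = np.where(d.sum(axis=1) == 2, np.sqrt(2.0), 1.0) * px
        arcs = np.cumsum(steps)
        i = 0
        while i < len(path):
            if inside[i]:
                j = i
                while j + 1 < len(path) and inside[j + 1]:
                    j += 1
                run_len = float(arcs[j] - arcs[i])
                mid = (i + j) // 2
                if require_two_sided and not _er_on_both_sides(
                        er_mask.pixels, path, mid, px):
                    i = j + 1
                    continue
                crossings.append(Crossing(
                    position_px=(float(path[mid, 0]), float(path[mid, 1])),
                    resolvable=run_len <= max_parallel_run,
                    run_length_um=run_len,
                    edge_index=ei,
                    arc_um=float(arcs[mid]),
                ))
                i = j + 1
            else:
                i += 1
    return CrossingSet(crossings=crossings, calibration=mito_skeleton.calibration)


def _er_on_both_sides(er: np.ndarray, path: np.ndarray, mid: int, px: float,
                      probe_um: tuple[float, float] = (0.25, 0.8)) -> bool:
    """True if the ER mask appears on both sides of the mitochondrial axis
    near path index `mid`.

    ER pixels in an annulus `probe_um` around the run midpoint are split by
    the sign of their component along the local normal; a crossing tubule
    (even an oblique one) leaves mask on both sides, a grazing touch on one.
    """
    lo = max(mid - 3, 0)
    hi = min(mid + 3, len(path) - 1)
    tang = (path[hi] - path[lo]).astype(float)
    n = np.linalg.norm(tang)
    if n == 0:
        return True
    normal = np.array([-tang[1], tang[0]]) / n
    H, W = er.shape
    r_in, r_out = probe_um[0] / px, probe_um[1] / px
    c0 = path[mid].astype(float)
    r0, r1 = max(int(c0[0] - r_out), 0), min(int(c0[0] + r_out) + 2, H)
    c0_, c1_ = max(int(c0[1] - r_out), 0), min(int(c0[1] + r_out) + 2, W)
    sub = er[r0:r1, c0_:c1_]
    if not sub.any():
        return False
    pix = np.argwhere(sub) + np.array([r0, c0_]) - c0
    dist = np.linalg.norm(pix, axis=1)
    keep = (dist >= r_in) & (dist <= r_out)
    if not keep.any():
        return False
    comp = pix[keep] @ normal
    return bool((comp > 0.5).any() and (comp < -0.5).any())


# ---------------------------------------------------------------------------
# Line profiles and constriction calls


@dataclass
class LineProfile:
    """Fluorescence sampled along a centreline path.

    ``intensities`` is (N,) for a single plane or (Z, N) for a z-stack;
    ``arcs_um`` gives the arc-length coordinate of each sample and
    ``path_px`` the corresponding (row, col) pixel positions.
    """

    arcs_um: np.ndarray
    intensities: np.ndarray
    path_px: np.ndarray
    calibration: Calibration = field(default_factory=Calibration)

    @property
    def n_slices(self) -> int:
        return 1 if self.intensities.ndim == 1 else self.intensities.shape[0]


def extract_line_profile(image: np.ndarray, path_px: np.ndarray,
                         calibration: Calibration | None = None) -> LineProfile:
    """Sample `image` along a polyline, one sample per path pixel.

    `image` may be a (Y, X) plane or a (Z, Y, X) stack (one profile per
    slice). Sub-pixel vertices are interpolated bilinearly. Raises if the
    path leaves the image.
    """
    cal = calibration or Calibration()
    image = np.asarray(image, dtype=float)
    path = np.asarray(path_px, dtype=float)
    if path.ndim != 2 or path.shape[1] != 2 or len(path) < 1:
        raise ValueError("path must be an (N, 2) polyline in pixel coordinates")
    planes = image[None] if image.ndim == 2 else image
    if image.ndim not in (2, 3):
        raise ValueError(f"image must be 2-D or 3-D, got shape {image.shape}")
    H, W = planes.shape[-2:]
    if path[:, 0].min() < 0 or path[:, 1].min() < 0 or \
       path[:, 0].max() > H - 1 or path[:, 1].max() > W - 1:
        raise ValueError("line-profile path extends outside the image")

    # resample the polyline at 1-pixel arc spacing
    d = np.linalg.norm(np.diff(path, axis=0), axis=1) if len(path) > 1 else np.array([0.0])
    s = np.concatenate([[0.0], np.cumsum(d)])
    total = s[-1]
    n = max(1, int(round(total)) + 1)
    si = np.linspace(0.0, total, n) if total > 0 else np.array([0.0])
    rows = np.interp(si, s, path[:, 0])
    cols = np.interp(si, s, path[:, 1])
    samples = np.stack([
        ndimage.map_coordinates(p, np.stack([rows, cols]), order=1, mode="nearest")
        for p in planes
    ])
    if image.ndim == 2:
        samples = samples[0]
    return LineProfile(
        arcs_um=si * cal.pixel_size,
        intensities=samples,
        path_px=np.stack([rows, cols], axis=1),
        calibration=cal,
    )


@dataclass
class ConstrictionCall:
    """A called constriction: arc position, fractional dip, z support."""

    arc_um: float
    dip_fraction: float
    z_support: int
    position_px: tuple[float, float] | None = None


def _smooth(y: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return np.asarray(y, dtype=float)
    kernel = np.ones(window) / window
    pad = window // 2
    yp = np.pad(np.asarray(y, dtype=float), pad, mode="edge")
    return np.convolve(yp, kernel, mode="valid")[: len(y)]


def _dips_1d(y: np.ndarray) -> list[tuple[int, float]]:
    """(index, dip_fraction) for every strict local minimum with a local
    maximum on both sides; the reference peak is the larger flanking maximum.

    Profile boundary samples count as maxima when they exceed their single
    neighbour: a manually drawn line scan starts and ends on bright regions
    of the organelle, so its endpoints are legitimate reference peaks.
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    is_min = np.zeros(n, dtype=bool)
    is_max = np.zeros(n, dtype=bool)
    is_min[1:-1] = (y[1:-1] < y[:-2]) & (y[1:-1] < y[2:])
    is_max[1:-1] = (y[1:-1] > y[:-2]) & (y[1:-1] > y[2:])
    is_max[0] = y[0] > y[1]
    is_max[-1] = y[-1] > y[-2]
    max_idx = np.flatnonzero(is_max)
    out = []
    for m in np.flatnonzero(is_min):
        left = max_idx[max_idx < m]
        right = max_idx[max_idx > m]
        if len(left) == 0 or len(right) == 0:
            continue
        peak = max(y[left[-1]], y[right[0]])
        if peak <= 0:
            continue
        out.append((int(m), float(1.0 - y[m] / peak)))
    return out


def call_constrictions(profile: LineProfile, drop_threshold: float = 0.40,
                       min_z_support: int = 2, smooth_window: int = 3,
                       z_match_um: float = 0.3) -> list[ConstrictionCall]:
    """Call constrictions along a line profile.

    Profiles are pre-smoothed with a `smooth_window`-sample moving average.
    A call is a local intensity minimum whose dip relative to the larger of
    its two flanking peaks is at least `drop_threshold`. For multi-slice
    profiles, a call additionally requires the dip at `min_z_support`
    adjacent z-slices within `z_match_um` of the same arc position; the call
    is reported at its deepest slice.
    """
    y = profile.intensities
    if (y.shape[-1] if y.ndim else 0) < 3:
        raise ValueError("profile must have at least 3 samples")
    arcs = profile.arcs_um

    def slice_calls(y1d: np.ndarray) -> list[tuple[float, float, int]]:
        sm = _smooth(y1d, smooth_window)
        return [(float(arcs[i]), dip, i) for i, dip in _dips_1d(sm)
                if dip >= drop_threshold]

    def make_call(arc: float, dip: float, idx: int, support: int) -> ConstrictionCall:
        pos = profile.path_px[idx] if profile.path_px is not None else None
        return ConstrictionCall(
            arc_um=arc, dip_fraction=dip, z_support=support,
            position_px=(float(pos[0]), float(pos[1])) if pos is not None else None,
        )

    if y.ndim == 1:
        return [make_call(a, d, i, 1) for a, d, i in slice_calls(y)]

    per_slice = [slice_calls(y[z]) for z in range(y.shape[0])]
    # cluster calls across slices by arc position
    flat = [(a, d, i, z) for z, calls in enumerate(per_slice) for a, d, i in calls]
    flat.sort(key=lambda t: t[0])
    out: list[ConstrictionCall] = []
    used = np.zeros(len(flat), dtype=bool)
    for k, (a, d, i, z) in enumerate(flat):
        if used[k]:
            continue
        cluster = [k]
        for j in range(k + 1, len(flat)):
            if used[j]:
                continue
            if abs(flat[j][0] - a) <= z_match_um:
                cluster.append(j)
        zs = sorted({flat[j][3] for j in cluster})
        # longest run of adjacent slices
        best_run, run = 1, 1
        for p in range(1, len(zs)):
            run = run + 1 if zs[p] == zs[p - 1] + 1 else 1
            best_run = max(best_run, run)
        if best_run >= min_z_support:
            for j in cluster:
                used[j] = True
            aa, dd, ii, _zz = max((flat[j] for j in cluster), key=lambda t: t[1])
            out.append(make_call(aa, dd, ii, best_run))
    out.sort(key=lambda c: c.arc_um)
    return out


class NoResolvableCrossingsError(ValueError):
    """Zero resolvable crossings: the constriction fraction is undefined."""


def fraction_crossings_constricted(crossings: CrossingSet,
                                   calls: list[ConstrictionCall],
                                   match_radius: float = 0.5) -> float:
    """Fraction of resolvable ER crossings with a constriction call within
    `match_radius` µm. Adjacent calls at the same crossing count once."""
    res = crossings.resolvable()
    if not res:
        raise NoResolvableCrossingsError("no resolvable ER-mitochondria crossings")
    px = crossings.calibration.pixel_size
    call_pos = np.array([c.position_px for c in calls if c.position_px is not None],
                        dtype=float).reshape(-1, 2)
    n_hit = 0
    for c in res:
        if len(call_pos):
            d = np.linalg.norm(call_pos - np.array(c.position_px), axis=1) * px
            if (d <= match_radius).any():
                n_hit += 1
    return n_hit / len(res)


class EmptyReferenceMaskError(ValueError):
    """The reference mask is empty: the overlap fraction is undefined."""


def overlap_fraction(mask_a: BinaryMask, mask_b: BinaryMask) -> float:
    """Mander's-style overlap: the fraction of reference mask B covered by A.

    For the ER-over-mitochondria and ddFP-over-mitochondria readouts the
    caller passes the mitochondrial mask as B ("over total mitochondrial
    area").
    """
    a, b = mask_a.pixels, mask_b.pixels
    if a.shape != b.shape:
        raise ValueError(f"mask shapes differ: {a.shape} vs {b.shape}")
    nb = int(b.sum())
    if nb == 0:
        raise EmptyReferenceMaskError("reference mask B is empty")
    return float(np.logical_and(a, b).sum()) / nb


# ---------------------------------------------------------------------------
# Stack-level constriction workflow


@dataclass
class ConstrictionAnalysis:
    crossings: CrossingSet
    calls: list[ConstrictionCall]
    fraction_constricted: float
    skeleton: "object"  # SkeletonGraph of the (closed) mitochondrial mask


def analyze_constriction_stack(stack, drop_threshold: float = 0.40,
                               min_z_support: int = 2,
                               max_parallel_run: float = 1.0,
                               match_radius: float = 0.5,
                               close_radius_px: int = 2,
                               z_mode: str = "max") -> ConstrictionAnalysis:
    """Score ER-associated constrictions on a 2-channel z-stack.

    The line a scientist draws follows the organelle through its dim
    constrictions, so the skeleton mask uses hysteresis thresholding: bright
    pixels above the Otsu threshold seed the mask, and dim pixels above a
    low noise floor are kept only while connected to a seed. A light
    morphological closing (`close_radius_px`) then bridges any single-pixel
    breaks. Line profiles are read from the raw z-stack along each skeleton
    edge and constrictions called with the fractional-dip rule; the result
    is the fraction of resolvable ER crossings with a constriction within
    `match_radius` µm.
    """
    from skimage.filters import apply_hysteresis_threshold, threshold_otsu
    from skimage.morphology import closing, disk

    from .morphology import otsu_mask, skeletonize_mask

    cal = stack.calibration
    mito_z = stack.pixels[0, :, stack.channel("mito")]
    er_z = stack.pixels[0, :, stack.channel("er")]
    if z_mode == "max":
        mito_proj, er_proj = mito_z.max(axis=0), er_z.max(axis=0)
    else:
        mito_proj, er_proj = mito_z[int(z_mode)], er_z[int(z_mode)]
    logger.info("constriction analysis on z-mode %r, closing radius %d px",
                z_mode, close_radius_px)
    bg = float(np.median(mito_proj))
    noise = 1.4826 * float(np.median(np.abs(mito_proj - bg)))
    low = bg + 3.0 * noise
    high = float(threshold_otsu(mito_proj))
    hyst = apply_hysteresis_threshold(mito_proj, min(low, high), high)
    closed = BinaryMask(closing(hyst, disk(close_radius_px)), calibration=cal)
    skel = skeletonize_mask(closed)
    er_mask = otsu_mask(er_proj, calibration=cal)
    crossings = detect_crossings(skel, er_mask, max_parallel_run=max_parallel_run)
    # a dip can only be scored between two flanking fluorescence peaks, so a
    # crossing too close to the end of its line scan is not scorable: flag
    # it unresolvable (it leaves numerator and denominator together)
    end_margin_um = 0.7
    for c in crossings.crossings:
        edge_len = skel.edges[c.edge_index].length_um
        if c.arc_um < end_margin_um or c.arc_um > edge_len - end_margin_um:
            c.resolvable = False
    calls: list[ConstrictionCall] = []
    for edge in skel.edges:
        if len(edge.path) < 3:
            continue
        profile = extract_line_profile(mito_z, edge.path, calibration=cal)
        calls.extend(call_constrictions(profile, drop_threshold=drop_threshold,
                                        min_z_support=min_z_support))
    try:
        frac = fraction_crossings_constricted(crossings, calls,
                                              match_radius=match_radius)
    except NoResolvableCrossingsError:
        frac = float("nan")
    return ConstrictionAnalysis(crossings=crossings, calls=calls,
                                fraction_constricted=frac, skeleton=skel)
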