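"""Synthetic fluorescence-microscopy generator with exact ground truth.

Builds scenes of curvilinear mitochondrial filaments crossed by ER tubules,
decorates them with fission/fusion machinery puncta, schedules Poisson
fission/fusion events, photoconverts a single mitochondrion, and renders the
result into calibrated multi-channel stacks or time-lapse movies with
diffraction blur and Poisson + Gaussian camera noise.

The generator emulates three acquisition types used by the quantification
stages:

* 12-slice z-stacks of mitochondria + ER for constriction line scans
  (``SceneParams.constriction_stack``),
* 2-min / 5-s-interval movies of machinery puncta
  (``SceneParams.puncta_movie``),
* 5-min / 5-s-interval photoconversion movies with scheduled fusion
  (tip-to-tip and tip-to-middle) and fission events
  (``SceneParams.photoconversion_movie``).

All randomness flows from a single integer seed; identical ``(params, seed)``
give identical scenes, ground truth and noise realisations.
"""

from __future__ import annotations

import copy
import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from shapely.geometry import LineString, Point

from .imgio import Calibration, ImageStack, ROI

logger = logging.getLogger("mitonode")

TIP_TO_TIP = "tip_to_tip"
TIP_TO_MIDDLE = "tip_to_middle"


class InfeasibleGeometryError(RuntimeError):
    """Raised when filaments cannot be placed without overlap after bounded retries."""


# ---------------------------------------------------------------------------
# Scene data model


@dataclass
class ConstrictionSite:
    """A multiplicative Gaussian dip in tube radius centred at `arc_um`.

    ``min_factor`` is the radius factor at the dip centre (1.0 = no
    constriction); projected matrix intensity falls roughly with the square
    of the radius factor, so a 0.5 radius factor renders as a >50% dip.
    """

    arc_um: float
    min_factor: float
    width_um: float = 0.25


@dataclass
class Filament:
    """A mitochondrion centreline: polyline in µm, tube radius, constrictions."""

    points: np.ndarray  # (N, 2) as (y, x) µm
    radius_um: float = 0.15
    sites: list[ConstrictionSite] = field(default_factory=list)

    @property
    def length_um(self) -> float:
        return float(_arclengths(self.points)[-1])

    def radius_factor(self, s: np.ndarray) -> np.ndarray:
        """Radius factor profile along arc length (1 away from constrictions)."""
        f = np.ones_like(np.asarray(s, dtype=float))
        for site in self.sites:
            f *= 1.0 - (1.0 - site.min_factor) * np.exp(
                -0.5 * ((np.asarray(s, dtype=float) - site.arc_um) / site.width_um) ** 2
            )
        return f


@dataclass
class Punctum:
    role: str  # 'drp1' | 'mfn1'
    filament: int  # index into scene.filaments, -1 = free
    arc_um: float
    position: tuple[float, float]  # (y, x) µm
    frame_start: int = 0
    frame_stop: int | None = None  # exclusive; None = whole movie
    at_crossing: bool = False


@dataclass
class ScheduledEvent:
    time_s: float
    kind: str  # 'fission' | 'fusion'
    fusion_class: str  # TIP_TO_TIP | TIP_TO_MIDDLE | 'none'
    participants: tuple[int, ...] = ()
    contact_um: tuple[float, float] | None = None
    realized: bool = True

    def __post_init__(self) -> None:
        if self.kind == "fusion" and self.fusion_class not in (TIP_TO_TIP, TIP_TO_MIDDLE):
            raise ValueError("fusion events must carry a tip class")
        if self.kind == "fission" and self.fusion_class != "none":
            raise ValueError("fission events carry class 'none'")


@dataclass
class EventSchedule:
    entries: list[ScheduledEvent] = field(default_factory=list)

    def realized(self) -> list[ScheduledEvent]:
        return [e for e in self.entries if e.realized]


@dataclass
class TrueCrossing:
    filament: int
    tubule: int
    arc_um: float
    position: tuple[float, float]
    constricted: bool
    min_factor: float  # 1.0 when not constricted


@dataclass
class OpticsModel:
    """Confocal-like rendering parameters (counts = camera units)."""

    psf_sigma: float = 0.15  # µm
    background: float = 100.0
    photon_scale: float = 2000.0  # counts per unit emitter density
    gaussian_read_noise_sd: float = 3.0
    poisson_noise: bool = True
    axial_sigma_um: float = 0.35  # Gaussian axial attenuation for z-stacks

    def __post_init__(self) -> None:
        if self.psf_sigma <= 0 or self.photon_scale <= 0:
            raise ValueError("psf_sigma and photon_scale must be > 0")
        if self.background < 0 or self.gaussian_read_noise_sd < 0:
            raise ValueError("noise parameters must be >= 0")


@dataclass
class SceneParams:
    """Scene generation parameters. Defaults mirror the control condition.

    Densities and rates are the quantities the analysis estimates: puncta per
    µm of mitochondrial length, occupancy fractions of ER crossings, and
    fission/fusion events per mitochondrion per minute.
    """

    fov_um: float = 15.0
    n_mito: int = 6
    mito_length_range: tuple[float, float] = (4.0, 8.0)
    mito_radius_um: float = 0.15
    clearance_um: float = 1.2
    n_er_tubules: int = 4
    # ER-crossing constrictions
    crossing_constriction_prob: float = 0.0
    constriction_factor_range: tuple[float, float] = (0.3, 0.5)
    constriction_width_um: float = 0.25
    # puncta
    mfn1_density_per_um: float = 0.0
    drp1_crossing_occupancy: float = 0.0
    node_density_per_um: float = 0.0
    transient_puncta_per_um: float = 0.0
    transient_frames: int = 2
    # dynamics (events per mitochondrion per minute)
    fusion_rate_tip_to_middle: float = 0.0
    fusion_rate_tip_to_tip: float = 0.0
    fission_rate: float = 0.0
    n_kiss: int = 0
    with_ddfp: bool = False  # render the ER-mito contact (ddFP) channel
    # acquisition geometry
    duration_s: float = 0.0
    frame_interval_s: float = 5.0
    n_z: int = 1
    z_step_um: float = 0.2

    # -- acquisition-type factories (the study conditions) ------------------

    @classmethod
    def puncta_movie(cls, **overrides) -> "SceneParams":
        """2-min movie at 5-s intervals; control machinery densities."""
        base = dict(
            duration_s=120.0,
            frame_interval_s=5.0,
            mfn1_density_per_um=0.30,
            drp1_crossing_occupancy=0.47,
            transient_puncta_per_um=0.05,
        )
        base.update(overrides)
        return cls(**base)

    @classmethod
    def node_movie(cls, **overrides) -> "SceneParams":
        """2-min movie carrying co-localised Drp1+Mfn1 node puncta."""
        base = dict(duration_s=120.0, node_density_per_um=0.34)
        base.update(overrides)
        return cls(**base)

    @classmethod
    def constriction_stack(cls, **overrides) -> "SceneParams":
        """Single-timepoint 12-slice z-stack; 60% of crossings constricted.

        The ER field is dense (tubular ER networks have ~1-2 µm mesh
        spacing), giving each cell a realistic number of scoreable
        ER-mitochondria crossings.
        """
        base = dict(n_z=12, z_step_um=0.2, crossing_constriction_prob=0.60,
                    n_er_tubules=8)
        base.update(overrides)
        return cls(**base)

    @classmethod
    def photoconversion_movie(cls, **overrides) -> "SceneParams":
        """5-min movie at 5-s intervals; control fission/fusion rates.

        The field is sparser than the puncta scenes: photoconversion
        scoring follows one labelled mitochondrion and its partners, so the
        simulated cell keeps resolvable space between organelles for
        partners to approach through.
        """
        base = dict(
            fov_um=26.0,
            n_mito=6,
            clearance_um=2.8,
            duration_s=300.0,
            frame_interval_s=5.0,
            fusion_rate_tip_to_middle=0.19,
            fusion_rate_tip_to_tip=0.06,
            fission_rate=0.17,
            n_er_tubules=0,
        )
        base.update(overrides)
        return cls(**base)

    @property
    def n_frames(self) -> int:
        return max(1, int(round(self.duration_s / self.frame_interval_s)) + (1 if self.duration_s else 0))

    @property
    def duration_min(self) -> float:
        return self.duration_s / 60.0


@dataclass
class SceneGraph:
    """Ground-truth scene: geometry, puncta, event schedule and label states."""

    params: SceneParams
    seed: int
    filaments: list[Filament]
    tubules: list[np.ndarray]
    crossings: list[TrueCrossing]
    puncta: list[Punctum]
    events: EventSchedule
    converted_filament: int | None = None
    conversion_time_s: float = 0.0
    _timeline: "_Timeline | None" = field(default=None, repr=False)

    @property
    def fov_um(self) -> float:
        return self.params.fov_um

    @property
    def n_frames(self) -> int:
        return self.params.n_frames

    def timeline(self) -> "_Timeline":
        if self._timeline is None:
            self._timeline = _realize_timeline(self)
        return self._timeline


# ---------------------------------------------------------------------------
# Polyline helpers


def _arclengths(points: np.ndarray) -> np.ndarray:
    d = np.linalg.norm(np.diff(points, axis=0), axis=1)
    return np.concatenate([[0.0], np.cumsum(d)])


def _resample(points: np.ndarray, ds: float) -> tuple[np.ndarray, np.ndarray]:
    """Resample a polyline at spacing `ds`; returns (samples (M,2), arcs (M,))."""
    s = _arclengths(points)
    total = s[-1]
    if total == 0:
        return points[:1].copy(), np.array([0.0])
    n = max(2, int(math.ceil(total / ds)) + 1)
    si = np.linspace(0.0, total, n)
    ys = np.interp(si, s, points[:, 0])
    xs = np.interp(si, s, points[:, 1])
    return np.stack([ys, xs], axis=1), si


def _point_at_arc(points: np.ndarray, arc: float) -> tuple[np.ndarray, np.ndarray]:
    """Point and unit tangent at arc length `arc` along a polyline."""
    s = _arclengths(points)
    arc = float(np.clip(arc, 0.0, s[-1]))
    i = int(np.searchsorted(s, arc, side="right")) - 1
    i = min(max(i, 0), len(points) - 2)
    seg = points[i + 1] - points[i]
    seg_len = np.linalg.norm(seg)
    t = seg / seg_len if seg_len > 0 else np.array([1.0, 0.0])
    frac = (arc - s[i]) / seg_len if seg_len > 0 else 0.0
    return points[i] + frac * seg, t


def _sub_polyline(points: np.ndarray, s0: float, s1: float) -> np.ndarray:
    """The part of a polyline between arc lengths s0 and s1."""
    s = _arclengths(points)
    s0, s1 = max(0.0, s0), min(float(s[-1]), s1)
    p0, _ = _point_at_arc(points, s0)
    p1, _ = _point_at_arc(points, s1)
    inner = points[(s > s0) & (s < s1)]
    return np.vstack([p0[None], inner, p1[None]])


def _min_distance(a: np.ndarray, b: np.ndarray) -> float:
    if len(a) == 0 or len(b) == 0:
        return np.inf
    return float(cdist(a, b).min())


def _random_curve(rng: np.random.Generator, fov: float, length: float,
                  margin: float, step: float = 0.5, wiggle: float = 0.25,
                  start: np.ndarray | None = None,
                  direction: float | None = None) -> np.ndarray:
    """A smooth random polyline of given length inside [margin, fov-margin]²."""
    if start is None:
        start = rng.uniform(margin, fov - margin, size=2)
    theta = rng.uniform(0, 2 * np.pi) if direction is None else direction
    pts = [np.asarray(start, dtype=float)]
    n_steps = max(1, int(round(length / step)))
    for _ in range(n_steps):
        theta += rng.normal(0.0, wiggle)
        nxt = pts[-1] + step * np.array([np.sin(theta), np.cos(theta)])
        # steer back toward the interior when approaching the border
        for k in range(2):
            if nxt[k] < margin or nxt[k] > fov - margin:
                ctr = fov / 2
                theta = np.arctan2(*(ctr - pts[-1] + rng.normal(0, 0.2, 2)))
                nxt = pts[-1] + step * np.array([np.sin(theta), np.cos(theta)])
        nxt = np.clip(nxt, margin, fov - margin)
        pts.append(nxt)
    return np.array(pts)


# ---------------------------------------------------------------------------
# Scene construction


def _self_clear(dense: np.ndarray, arcs: np.ndarray, min_sep: float = 0.8,
                arc_gap: float = 1.2) -> bool:
    """Reject hairpins: non-adjacent points (arc distance > `arc_gap`) must
    stay `min_sep` apart so the rendered tube never overlaps itself."""
    if len(dense) < 3:
        return True
    d = cdist(dense, dense)
    a = np.abs(arcs[:, None] - arcs[None, :])
    return bool(d[a > arc_gap].min() >= min_sep) if (a > arc_gap).any() else True


def build_scene(params: SceneParams, seed: int) -> SceneGraph:
    """Generate a ground-truth scene.

    Filaments are placed with pairwise clearance by bounded rejection
    sampling (:class:`InfeasibleGeometryError` after too many retries).
    Event times for each kind/class are drawn as homogeneous Poisson
    processes with intensity ``rate × n_mito`` (per minute).
    """
    for name in ("mfn1_density_per_um", "drp1_crossing_occupancy", "node_density_per_um",
                 "fusion_rate_tip_to_middle", "fusion_rate_tip_to_tip", "fission_rate",
                 "transient_puncta_per_um"):
        if getattr(params, name) < 0:
            raise ValueError(f"{name} must be >= 0")
    rng = np.random.default_rng(seed)
    margin = 0.8
    filaments: list[Filament] = []
    dense_existing: list[np.ndarray] = []
    for _ in range(params.n_mito):
        placed = False
        for _attempt in range(300):
            length = rng.uniform(*params.mito_length_range)
            pts = _random_curve(rng, params.fov_um, length, margin)
            dense, arcs = _resample(pts, 0.2)
            if not _self_clear(dense, arcs):
                continue
            if all(_min_distance(dense, d) > params.clearance_um for d in dense_existing):
                filaments.append(Filament(points=pts, radius_um=params.mito_radius_um))
                dense_existing.append(dense)
                placed = True
                break
        if not placed:
            raise InfeasibleGeometryError(
                f"could not place {params.n_mito} filaments of length "
                f"{params.mito_length_range} in a {params.fov_um} µm field"
            )

    tubules: list[np.ndarray] = []
    for _ in range(params.n_er_tubules):
        # ER tubules span the field edge-to-edge with gentle wiggle
        side = rng.integers(0, 2)
        c0 = rng.uniform(margin, params.fov_um - margin)
        start = np.array([0.3, c0]) if side == 0 else np.array([c0, 0.3])
        direction = np.pi if side == 0 else np.pi / 2  # downward / rightward
        pts = _random_curve(rng, params.fov_um, params.fov_um - 0.6, margin=0.3,
                            wiggle=0.08, start=start, direction=direction)
        tubules.append(pts)

    crossings = _find_crossings(filaments, tubules)
    for c in crossings:
        if rng.random() < params.crossing_constriction_prob:
            mf = rng.uniform(*params.constriction_factor_range)
            filaments[c.filament].sites.append(
                ConstrictionSite(arc_um=c.arc_um, min_factor=mf,
                                 width_um=params.constriction_width_um)
            )
            c.constricted = True
            c.min_factor = mf

    puncta = _place_puncta(params, rng, filaments, crossings)
    events = _schedule_events(params, rng)
    return SceneGraph(
        params=params, seed=seed, filaments=filaments, tubules=tubules,
        crossings=crossings, puncta=puncta, events=events,
    )


def _find_crossings(filaments: list[Filament], tubules: list[np.ndarray]) -> list[TrueCrossing]:
    out: list[TrueCrossing] = []
    for fi, fil in enumerate(filaments):
        line = LineString(fil.points)
        for ti, tub in enumerate(tubules):
            inter = line.intersection(LineString(tub))
            if inter.is_empty:
                continue
            pts: list[Point] = []
            if inter.geom_type == "Point":
                pts = [inter]
            elif inter.geom_type == "MultiPoint":
                pts = list(inter.geoms)
            else:  # collapse collinear overlap to its midpoint
                pts = [inter.centroid]
            for p in pts:
                arc = float(line.project(p))
                # shapely's .x is the first stored coordinate = our row (y µm)
                out.append(TrueCrossing(
                    filament=fi, tubule=ti, arc_um=arc,
                    position=(float(p.x), float(p.y)),
                    constricted=False, min_factor=1.0,
                ))
    out.sort(key=lambda c: (c.filament, c.arc_um))
    return out


#: Machinery puncta are discrete, resolvable structures: same-role puncta are
#: placed with a hard-core minimum separation at the diffraction scale, so a
#: scored punctum corresponds to one countable spot.
MIN_PUNCTA_SEPARATION_UM = 0.45


def _place_puncta(params: SceneParams, rng: np.random.Generator,
                  filaments: list[Filament], crossings: list[TrueCrossing]) -> list[Punctum]:
    puncta: list[Punctum] = []
    placed: dict[str, list[np.ndarray]] = {"drp1": [], "mfn1": []}

    def _at(fi: int, arc: float, role: str, at_crossing=False, f0=0, f1=None) -> Punctum:
        pos, _ = _point_at_arc(filaments[fi].points, arc)
        placed[role].append(np.asarray(pos))
        return Punctum(role=role, filament=fi, arc_um=arc,
                       position=(float(pos[0]), float(pos[1])),
                       frame_start=f0, frame_stop=f1, at_crossing=at_crossing)

    def _clear(fi: int, arc: float, roles: tuple[str, ...]) -> bool:
        pos, _ = _point_at_arc(filaments[fi].points, arc)
        for role in roles:
            if any(np.linalg.norm(pos - q) < MIN_PUNCTA_SEPARATION_UM
                   for q in placed[role]):
                return False
        return True

    def _draw_arc(fi: int, roles: tuple[str, ...], L: float) -> float | None:
        for _try in range(40):
            arc = rng.uniform(0.2, L - 0.2)
            if _clear(fi, arc, roles):
                return arc
        return None

    for fi, fil in enumerate(filaments):
        L = fil.length_um
        for _ in range(rng.poisson(params.mfn1_density_per_um * L)):
            arc = _draw_arc(fi, ("mfn1",), L)
            if arc is not None:
                puncta.append(_at(fi, arc, "mfn1"))
        for _ in range(rng.poisson(params.node_density_per_um * L)):
            arc = _draw_arc(fi, ("mfn1", "drp1"), L)
            if arc is not None:
                puncta.append(_at(fi, arc, "drp1"))
                puncta.append(_at(fi, arc, "mfn1"))
        if params.transient_puncta_per_um > 0 and params.n_frames > params.transient_frames:
            for _ in range(rng.poisson(params.transient_puncta_per_um * L)):
                f0 = int(rng.integers(0, params.n_frames - params.transient_frames))
                role = "drp1" if rng.random() < 0.5 else "mfn1"
                arc = _draw_arc(fi, (role,), L)
                if arc is not None:
                    puncta.append(_at(fi, arc, role,
                                      f0=f0, f1=f0 + params.transient_frames))
    for c in crossings:
        if rng.random() < params.drp1_crossing_occupancy and \
                _clear(c.filament, c.arc_um, ("drp1",)):
            puncta.append(_at(c.filament, c.arc_um, "drp1", at_crossing=True))
    return puncta


def _schedule_events(params: SceneParams, rng: np.random.Generator) -> EventSchedule:
    entries: list[ScheduledEvent] = []
    if params.duration_s <= 0:
        return EventSchedule(entries)
    duration_min = params.duration_min
    buffer_s = 3 * params.frame_interval_s  # leave room for donor entry / persistence
    lo, hi = buffer_s, params.duration_s - buffer_s
    specs = [
        ("fusion", TIP_TO_MIDDLE, params.fusion_rate_tip_to_middle),
        ("fusion", TIP_TO_TIP, params.fusion_rate_tip_to_tip),
        ("fission", "none", params.fission_rate),
    ]
    for kind, cls, rate in specs:
        n = rng.poisson(rate * params.n_mito * duration_min)
        for t in np.sort(rng.uniform(lo, hi, size=n)):
            entries.append(ScheduledEvent(time_s=float(t), kind=kind, fusion_class=cls))
    entries.sort(key=lambda e: e.time_s)
    return EventSchedule(entries)


def apply_photoconversion(scene: SceneGraph, roi: ROI, t0: float = 0.0,
                          calibration: Calibration | None = None) -> SceneGraph:
    """Photoconvert the filament with the largest overlap with `roi`.

    Returns a new scene whose converted label propagates to fusion partners
    and partitions to both daughters at fission (handled by the timeline).
    Raises ``ValueError`` if no filament intersects the ROI.
    """
    if calibration is None:
        calibration = Calibration()
    h_px, w_px = roi.shape_px(calibration)
    r0, c0 = roi.origin
    y0, x0 = r0 * calibration.pixel_size, c0 * calibration.pixel_size
    y1, x1 = y0 + h_px * calibration.pixel_size, x0 + w_px * calibration.pixel_size
    best, best_overlap = None, 0.0
    for i, fil in enumerate(scene.filaments):
        dense, s = _resample(fil.points, 0.05)
        inside = ((dense[:, 0] >= y0) & (dense[:, 0] <= y1)
                  & (dense[:, 1] >= x0) & (dense[:, 1] <= x1))
        overlap = inside.sum() * 0.05
        if overlap > best_overlap:
            best, best_overlap = i, overlap
    if best is None or best_overlap == 0.0:
        raise ValueError("photoconversion ROI contains no filament")
    out = copy.deepcopy(scene)
    out.converted_filament = best
    out.conversion_time_s = float(t0)
    out._timeline = None
    return out


# ---------------------------------------------------------------------------
# Event realization: an explicit per-frame geometry timeline


@dataclass
class _Piece:
    """A static polyline segment rendered as a tube."""

    points: np.ndarray
    radius_um: float
    sites: list[ConstrictionSite]


@dataclass
class _FrameObject:
    piece: int  # piece id (render-cache key)
    body: int
    converted: bool


@dataclass
class _Timeline:
    """Frame-by-frame scene state after realizing the event schedule."""

    pieces: dict[int, _Piece]
    frames: list[list[_FrameObject]]  # per frame, visible pieces with body/label
    n_bodies_first_frame: int

    def bodies_at(self, frame: int) -> dict[int, list[int]]:
        out: dict[int, list[int]] = {}
        for fo in self.frames[frame]:
            out.setdefault(fo.body, []).append(fo.piece)
        return out


def _realize_timeline(scene: SceneGraph) -> _Timeline:
    """Turn the schedule into explicit per-frame geometry.

    Fusion partners enter the field shortly before their event (three frames
    ahead, resting one gap-length away from the contact point) and dock
    instantaneously at the scheduled frame; the merged object equilibrates
    the converted label within one frame. Fission splits a naive filament
    into two daughters separated by a resolvable gap. Events that cannot be
    realised geometrically after bounded retries are dropped from the
    realised schedule with a warning.
    """
    params = scene.params
    rng = np.random.default_rng((scene.seed * 2654435761 + 17) % (2**31))
    n_frames = scene.n_frames
    END = n_frames
    has_fusion = any(e.kind == "fusion" for e in scene.events.entries) or params.n_kiss > 0
    if has_fusion and scene.converted_filament is None:
        raise ValueError("scene schedules fusion events but no filament is photoconverted; "
                         "call apply_photoconversion first")

    pieces: dict[int, _Piece] = {}
    next_piece = 0

    def add_piece(points, radius, sites) -> int:
        nonlocal next_piece
        pieces[next_piece] = _Piece(points=np.asarray(points, float), radius_um=radius,
                                    sites=list(sites))
        next_piece += 1
        return next_piece - 1

    next_body = len(scene.filaments)

    def new_body() -> int:
        nonlocal next_body
        next_body += 1
        return next_body - 1

    # spans: (frame_start, frame_stop_exclusive, piece, body)
    spans: list[tuple[int, int, int, int]] = []
    # open state, mutated immediately as events are processed in time order
    naive: dict[int, tuple[int, int]] = {}          # body -> (piece, frame_opened)
    lineage_pieces: list[tuple[int, int]] = []      # (piece, frame_joined)
    lineage_body = scene.converted_filament
    lineage_tips: list[tuple[int, int, int]] = []   # (piece, end 0|-1, frame available)
    lineage_junctions: dict[int, list[float]] = {}
    # dense clearance geometry per piece; a donor must keep full clearance
    # from every piece except its own acceptor near the dock site
    piece_geoms: dict[int, np.ndarray] = {}
    contact_points: list[np.ndarray] = []

    for i, fil in enumerate(scene.filaments):
        pid = add_piece(fil.points, fil.radius_um, fil.sites)
        piece_geoms[pid] = _resample(fil.points, 0.2)[0]
        if i == lineage_body:
            lineage_pieces.append((pid, 0))
            lineage_tips = [(pid, 0, 0), (pid, -1, 0)]
            lineage_junctions[pid] = []
        else:
            naive[i] = (pid, 0)

    fov, margin = params.fov_um, 0.4

    DOCK_GAP = 1.1  # µm between contact point and the resting donor tip

    def try_make_donor(contact: np.ndarray, away: np.ndarray, acceptor_pid: int):
        """Build a static donor near `contact` docking onto piece `acceptor_pid`.

        Returns ``(pre_pts, docked_pts)``: the resting polyline whose tip
        sits `DOCK_GAP` µm from the contact point, and the docked polyline
        that extends the same body to slightly overlap the contact (so the
        donor never translates; its tip grows to the acceptor at the event
        frame and every pre-dock pixel stays inside the docked footprint).
        The donor keeps full clearance from every other piece so that the
        dock changes component topology by exactly one merge.
        """
        length = rng.uniform(2.0, 3.2)
        theta = math.atan2(away[0], away[1]) + rng.normal(0, 0.25)
        base = contact + DOCK_GAP * away
        pts = [base]
        step, th = 0.4, theta
        for _ in range(int(round(length / step))):
            th += rng.normal(0, 0.15)
            pts.append(pts[-1] + step * np.array([math.sin(th), math.cos(th)]))
        pre = np.array(pts)
        docked = np.vstack([contact - 0.08 * away, pre])
        if docked.min() < margin or docked.max() > fov - margin:
            return None
        dense = _resample(docked, 0.2)[0]
        others = [g for pid, g in piece_geoms.items() if pid != acceptor_pid]
        if others and cdist(dense, np.vstack(others)).min() < 1.1:
            return None
        d = cdist(dense, piece_geoms[acceptor_pid])
        near_contact = np.linalg.norm(dense - contact, axis=1) < 1.4
        if d[~near_contact].size and d[~near_contact].min() < 1.1:
            return None
        return pre, docked

    def pick_contact(cls: str, frame: int):
        """Choose a contact point + outward direction on the lineage.

        Only material that joined the lineage at least two frames before
        `frame` is eligible: the event-classification step reads the
        pre-event geometry, so the contact must sit on a piece that is
        already part of the rendered lineage there.
        """
        if cls == TIP_TO_TIP:
            avail = [t for t in lineage_tips if t[2] <= frame - 2]
            if not avail:
                return None
            k_av = int(rng.integers(0, len(avail)))
            pid, end, _af = avail[k_av]
            k = lineage_tips.index(avail[k_av])
            pp = pieces[pid].points
            contact = pp[0] if end == 0 else pp[-1]
            # a tip docking too close to an existing junction is swallowed
            # by the junction wedge in the rendered mask; keep tip contacts
            # well clear of every previous dock site
            if contact_points and min(
                    np.linalg.norm(contact - c) for c in contact_points) < 2.0:
                return None
            _, tang = _point_at_arc(pp, 0.0 if end == 0 else float(_arclengths(pp)[-1]))
            away = -tang if end == 0 else tang
            return contact.copy(), np.asarray(away, float), ("tip", k, pid, None)
        cand = [pid for pid, f0 in lineage_pieces
                if f0 <= frame - 2 and _arclengths(pieces[pid].points)[-1] > 2.2]
        if not cand:
            return None
        pid = int(rng.choice(cand))
        pp = pieces[pid].points
        L = float(_arclengths(pp)[-1])
        jxs = lineage_junctions.get(pid, [])
        tip_pos = np.array([
            pieces[tp].points[0] if e == 0 else pieces[tp].points[-1]
            for tp, e, _af in lineage_tips
        ]).reshape(-1, 2)
        for _try in range(20):
            arc = float(rng.uniform(0.9, L - 0.9))
            cand_pt, _ = _point_at_arc(pp, arc)
            # keep mid-body contacts clear of every free tip (so the tip
            # class is unambiguous at the classifier's 0.5 µm scale) and of
            # every previous dock site (so each fusion changes the component
            # topology on its own)
            if all(abs(arc - j) > 1.0 for j in jxs) and (
                    len(tip_pos) == 0
                    or np.linalg.norm(tip_pos - cand_pt, axis=1).min() > 1.8) and (
                    not contact_points
                    or min(np.linalg.norm(cand_pt - c) for c in contact_points) > 1.2):
                break
        else:
            return None
        pt, tang = _point_at_arc(pp, arc)
        normal = np.array([-tang[1], tang[0]])
        if rng.random() < 0.5:
            normal = -normal
        return pt.copy(), normal, ("middle", None, pid, arc)

    dropped = 0
    for ev in scene.events.entries:
        frame = int(round(ev.time_s / params.frame_interval_s))
        frame = min(max(frame, 2), n_frames - 3)
        if ev.kind == "fusion":
            ok = False
            for _attempt in range(400):
                picked = pick_contact(ev.fusion_class, frame)
                if picked is None:
                    continue
                contact, away, (mode, tip_k, target_pid, target_arc) = picked
                made = try_make_donor(np.asarray(contact, float), away, target_pid)
                if made is None:
                    continue
                pre_pts, docked_pts = made
                docked = add_piece(docked_pts, params.mito_radius_um, [])
                pre = add_piece(pre_pts, params.mito_radius_um, [])
                piece_geoms[docked] = _resample(docked_pts, 0.2)[0]
                contact_points.append(np.asarray(contact, float))
                donor_body = new_body()
                appear = max(0, frame - 3)
                spans.append((appear, frame, pre, donor_body))
                lineage_pieces.append((docked, frame))
                # update lineage topology immediately
                if mode == "tip":
                    lineage_tips.pop(tip_k)
                else:
                    lineage_junctions.setdefault(target_pid, []).append(target_arc)
                lineage_tips.append((docked, -1, frame))
                lineage_junctions[docked] = []
                ev.participants = (donor_body, lineage_body)
                ev.contact_um = (float(contact[0]), float(contact[1]))
                ev.time_s = frame * params.frame_interval_s
                ok = True
                break
            if not ok:
                ev.realized = False
                dropped += 1
        else:  # fission of a naive (non-lineage) body
            cand = [bid for bid, (pid, f0) in naive.items()
                    if f0 <= frame - 2
                    and _arclengths(pieces[pid].points)[-1] >= 3.2]
            if not cand:
                ev.realized = False
                dropped += 1
                continue
            bid = int(rng.choice(cand))
            pid, f0 = naive.pop(bid)
            pp = pieces[pid].points
            L = float(_arclengths(pp)[-1])
            cut = rng.uniform(0.4, 0.6) * L
            retract = 0.65  # µm trimmed from each daughter so masks separate
            d1 = add_piece(_sub_polyline(pp, 0.0, cut - retract), pieces[pid].radius_um,
                           [s for s in pieces[pid].sites if s.arc_um < cut - retract])
            d2 = add_piece(_sub_polyline(pp, cut + retract, L), pieces[pid].radius_um,
                           [replace(s, arc_um=s.arc_um - (cut + retract))
                            for s in pieces[pid].sites if s.arc_um > cut + retract])
            spans.append((f0, frame, pid, bid))
            piece_geoms[d1] = _resample(pieces[d1].points, 0.2)[0]
            piece_geoms[d2] = _resample(pieces[d2].points, 0.2)[0]
            naive[new_body()] = (d1, frame)
            naive[new_body()] = (d2, frame)
            cut_pt, _ = _point_at_arc(pp, cut)
            ev.participants = (bid,)
            ev.contact_um = (float(cut_pt[0]), float(cut_pt[1]))
            ev.time_s = frame * params.frame_interval_s
    if dropped:
        logger.warning("dropped %d of %d scheduled events that could not be realised "
                       "geometrically", dropped, len(scene.events.entries))

    # transient kiss-and-run contacts: dock for two frames, no label transfer
    for _ in range(params.n_kiss):
        for _attempt in range(150):
            frame = int(rng.integers(3, max(4, n_frames - 5)))
            picked = pick_contact(TIP_TO_MIDDLE if rng.random() < 0.5 else TIP_TO_TIP,
                                  frame)
            if picked is None:
                continue
            contact, away, (_mode, _k, target_pid, _arc) = picked
            made = try_make_donor(np.asarray(contact, float), away, target_pid)
            if made is None:
                continue
            pre_pts, docked_pts = made
            docked = add_piece(docked_pts, params.mito_radius_um, [])
            pre = add_piece(pre_pts, params.mito_radius_um, [])
            piece_geoms[docked] = _resample(docked_pts, 0.2)[0]
            contact_points.append(np.asarray(contact, float))
            b = new_body()
            spans.append((max(0, frame - 3), frame, pre, b))
            spans.append((frame, frame + 2, docked, b))
            spans.append((frame + 2, END, pre, b))
            break

    # close every still-open span
    for bid, (pid, f0) in naive.items():
        spans.append((f0, END, pid, bid))
    for pid, f0 in lineage_pieces:
        spans.append((f0, END, pid, lineage_body))

    conv_frame = (int(round(scene.conversion_time_s / params.frame_interval_s))
                  if scene.converted_filament is not None else None)
    frames: list[list[_FrameObject]] = []
    for f in range(n_frames):
        snapshot = [
            _FrameObject(piece=pid, body=bid,
                         converted=(bid == lineage_body and conv_frame is not None
                                    and f >= conv_frame))
            for (f0, f1, pid, bid) in spans if f0 <= f < f1
        ]
        frames.append(snapshot)
    return _Timeline(pieces=pieces, frames=frames,
                     n_bodies_first_frame=len(scene.filaments))


# ---------------------------------------------------------------------------
# Rendering


def _splat_tube(img: np.ndarray, piece: _Piece, psf_sigma: float, px: float,
                amp_scale: float = 1.0) -> None:
    """Accumulate the projected emitter density of a tube onto `img` (in px).

    The matrix marker fills the tube volume, so emitters per unit length scale
    with the local radius factor squared; the rendered cross-section is a
    Gaussian of width sqrt((r·f)² + psf²). A radius factor f therefore
    renders as a centreline intensity dip of at least 1 − f².
    """
    ds = 0.06
    samples, arcs = _resample(piece.points, ds)
    if len(samples) < 2:
        return
    step = arcs[1] - arcs[0]
    f = 1.0
    if piece.sites:
        f = np.ones(len(samples))
        for site in piece.sites:
            f = f * (1.0 - (1.0 - site.min_factor)
                     * np.exp(-0.5 * ((arcs - site.arc_um) / site.width_um) ** 2))
    amp = amp_scale * step / px * (f ** 2 if isinstance(f, np.ndarray) else f ** 2)
    sigma_um = np.sqrt((piece.radius_um * (f if isinstance(f, np.ndarray) else 1.0)) ** 2
                       + psf_sigma ** 2)
    _splat_gaussians(img, samples / px, np.broadcast_to(np.atleast_1d(amp), (len(samples),)),
                     np.atleast_1d(sigma_um / px) * np.ones(len(samples)))


def _splat_gaussians(img: np.ndarray, pos_px: np.ndarray, amps: np.ndarray,
                     sigmas_px: np.ndarray) -> None:
    """Add normalised 2-D Gaussians (integral = amp) at sub-pixel positions."""
    H, W = img.shape
    for (y, x), a, s in zip(pos_px, amps, sigmas_px):
        r = max(2, int(math.ceil(3.5 * s)))
        y0, y1 = int(math.floor(y)) - r, int(math.floor(y)) + r + 1
        x0, x1 = int(math.floor(x)) - r, int(math.floor(x)) + r + 1
        ya, yb = max(y0, 0), min(y1, H)
        xa, xb = max(x0, 0), min(x1, W)
        if ya >= yb or xa >= xb:
            continue
        yy = np.arange(ya, yb) - y
        xx = np.arange(xa, xb) - x
        g = np.exp(-0.5 * (yy[:, None] ** 2 + xx[None, :] ** 2) / s**2)
        img[ya:yb, xa:xb] += a / (2 * np.pi * s**2) * g


def render_movie(scene: SceneGraph, optics: OpticsModel | None = None,
                 calibration: Calibration | None = None, seed: int = 0) -> ImageStack:
    """Render the scene into a calibrated (T, Z, C, Y, X) stack.

    Channels present depend on scene content: ``mito`` and ``er`` always;
    ``drp1``/``mfn1`` when puncta of that role exist; ``native`` and
    ``converted`` when the scene carries events or a photoconverted
    filament; ``ddfp`` renders tethering-distance ER–mito overlap. The
    noise-free render is deterministic; Poisson shot noise and Gaussian read
    noise use `seed`.
    """
    if optics is None:
        optics = OpticsModel()
    if calibration is None:
        calibration = Calibration(z_step=scene.params.z_step_um,
                                  frame_interval=scene.params.frame_interval_s)
    px = calibration.pixel_size
    size = int(round(scene.fov_um / px))
    tl = scene.timeline()
    n_frames, n_z = scene.n_frames, scene.params.n_z

    roles = ["mito", "er"]
    if any(p.role == "drp1" for p in scene.puncta):
        roles.append("drp1")
    if any(p.role == "mfn1" for p in scene.puncta):
        roles.append("mfn1")
    dynamic = scene.converted_filament is not None or bool(scene.events.entries)
    if dynamic:
        roles += ["native", "converted"]
    if scene.params.with_ddfp:
        roles.append("ddfp")
    ch = {r: i for i, r in enumerate(roles)}

    rng = np.random.default_rng(seed)
    # cache: noise-free layer per piece id
    layer_cache: dict[int, np.ndarray] = {}

    def piece_layer(pid: int) -> np.ndarray:
        if pid not in layer_cache:
            img = np.zeros((size, size))
            _splat_tube(img, tl.pieces[pid], optics.psf_sigma, px)
            layer_cache[pid] = img
        return layer_cache[pid]

    er_layer = np.zeros((size, size))
    for tub in scene.tubules:
        _splat_tube(er_layer, _Piece(points=tub, radius_um=0.08, sites=[]),
                    optics.psf_sigma, px, amp_scale=0.7)

    sigma_p_px = max(optics.psf_sigma / px, 1.0)
    punc_sigma = math.sqrt((0.10 / px) ** 2 + sigma_p_px ** 2)

    out = np.zeros((n_frames, n_z, len(roles), size, size), dtype=np.float32)
    # axial focus profile for z-stacks; single-plane movies use weight 1
    if n_z > 1:
        zf = (n_z - 1) / 2.0
        zw = np.exp(-0.5 * (((np.arange(n_z) - zf) * calibration.z_step)
                            / optics.axial_sigma_um) ** 2)
    else:
        zw = np.ones(1)

    for f in range(n_frames):
        dens = {r: np.zeros((size, size)) for r in roles}
        dens["er"] += er_layer
        for fo in tl.frames[f]:
            lay = piece_layer(fo.piece)
            dens["mito"] += lay
            if dynamic:
                dens["native"] += lay
                if fo.converted:
                    dens["converted"] += lay
        for p in scene.puncta:
            stop = p.frame_stop if p.frame_stop is not None else n_frames
            if not (p.frame_start <= f < stop):
                continue
            pos = np.array(p.position) / px
            _splat_gaussians(dens[p.role], pos[None], np.array([2.0]),
                             np.array([punc_sigma]))
        if "ddfp" in dens:
            # the dimerisation-dependent reporter fluoresces only where both
            # membranes are within tethering distance: where ER and
            # mitochondrial densities overlap
            dens["ddfp"] = 3.0 * np.minimum(dens["mito"], dens["er"])
        for r in roles:
            for z in range(n_z):
                signal = optics.background + optics.photon_scale * dens[r] * zw[z]
                if optics.poisson_noise:
                    signal = rng.poisson(signal).astype(np.float64)
                if optics.gaussian_read_noise_sd > 0:
                    signal = signal + rng.normal(0, optics.gaussian_read_noise_sd, signal.shape)
                out[f, z, ch[r]] = np.clip(signal, 0, None)

    return ImageStack(pixels=out, channel_roles={i: r for r, i in ch.items()},
                      calibration=calibration)


def render_true_labels(scene: SceneGraph, frame: int = 0,
                       calibration: Calibration | None = None) -> np.ndarray:
    """Ground-truth body-label image for `frame` (0 = background)."""
    if calibration is None:
        calibration = Calibration()
    px = calibration.pixel_size
    size = int(round(scene.fov_um / px))
    tl = scene.timeline()
    lab = np.zeros((size, size), dtype=np.int32)
    yy, xx = np.mgrid[0:size, 0:size]
    for body, piece_ids in sorted(tl.bodies_at(frame).items()):
        for pid in piece_ids:
            piece = tl.pieces[pid]
            dense, _ = _resample(piece.points, 0.08)
            r_px = (piece.radius_um + 0.1) / px
            for (y, x) in dense / px:
                sel = (yy - y) ** 2 + (xx - x) ** 2 <= r_px ** 2
                lab[sel] = body + 1
    return lab


# ---------------------------------------------------------------------------
# Ground-truth export


@dataclass
class GroundTruthTable:
    """Tabular ground truth for a scene (the acceptance oracle)."""

    filaments: pd.DataFrame
    crossings: pd.DataFrame
    puncta: pd.DataFrame
    events: pd.DataFrame
    n_mito: int
    duration_min: float
    rates: dict[str, float]


def export_ground_truth(scene: SceneGraph) -> GroundTruthTable:
    """Flatten a scene into tables; true rates are recomputed from the
    realised event list as count / (n_mito × duration)."""
    p = scene.params
    if scene.events.entries:
        scene.timeline()  # realise the schedule so dropped events are excluded
    fil = pd.DataFrame([
        dict(filament=i, length_um=f.length_um, radius_um=f.radius_um,
             n_constrictions=len(f.sites),
             converted=(i == scene.converted_filament))
        for i, f in enumerate(scene.filaments)
    ])
    cross = pd.DataFrame([
        dict(filament=c.filament, tubule=c.tubule, arc_um=c.arc_um,
             y_um=c.position[0], x_um=c.position[1],
             constricted=c.constricted, min_factor=c.min_factor)
        for c in scene.crossings
    ], columns=["filament", "tubule", "arc_um", "y_um", "x_um", "constricted", "min_factor"])
    punc = pd.DataFrame([
        dict(role=q.role, filament=q.filament, arc_um=q.arc_um,
             y_um=q.position[0], x_um=q.position[1],
             frame_start=q.frame_start,
             frame_stop=q.frame_stop if q.frame_stop is not None else scene.n_frames,
             persistent=(q.frame_start == 0 and q.frame_stop is None),
             at_crossing=q.at_crossing)
        for q in scene.puncta
    ], columns=["role", "filament", "arc_um", "y_um", "x_um",
                "frame_start", "frame_stop", "persistent", "at_crossing"])
    evs = pd.DataFrame([
        dict(time_s=e.time_s, kind=e.kind, fusion_class=e.fusion_class,
             participants=",".join(map(str, e.participants)),
             y_um=(e.contact_um[0] if e.contact_um else np.nan),
             x_um=(e.contact_um[1] if e.contact_um else np.nan))
        for e in scene.events.realized()
    ], columns=["time_s", "kind", "fusion_class", "participants", "y_um", "x_um"])
    rates: dict[str, float] = {}
    if p.duration_min > 0:
        denom = p.n_mito * p.duration_min
        for kind in ("fusion", "fission"):
            rates[kind] = float((evs["kind"] == kind).sum()) / denom if len(evs) else 0.0
        for cls in (TIP_TO_MIDDLE, TIP_TO_TIP):
            rates[f"fusion_{cls}"] = (
                float(((evs["kind"] == "fusion") & (evs["fusion_class"] == cls)).sum()) / denom
                if len(evs) else 0.0
            )
    return GroundTruthTable(
        filaments=fil, crossings=cross, puncta=punc, events=evs,
        n_mito=p.n_mito, duration_min=p.duration_min, rates=rates,
    )
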