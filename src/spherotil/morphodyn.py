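"""Cell-couple morphodynamics: coupling, uropods, off-interface lamellae,
translocation, time-to-event survival and Fura-2 calcium ratios.

Tracks are sequences of outline polygons (T cell and target) sampled every
10 s, with a synapse chord recorded on frames where the cells are in contact.
All classifiers operate on polygon geometry only, so they are invariant under
rigid motions of the whole scene.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from shapely.geometry import Polygon
from shapely.ops import unary_union


@dataclass
class CoupleFrame:
    """One 10-s frame of a T-cell/target couple."""

    t_index: int
    tcell_xy: np.ndarray          # (N, 2) outline vertices, um
    target_xy: np.ndarray         # (M, 2) outline vertices, um
    contact: bool = False
    synapse_xy: np.ndarray | None = None   # (2, 2) chord endpoints, um

    def __post_init__(self) -> None:
        self.tcell_xy = np.asarray(self.tcell_xy, dtype=float)
        self.target_xy = np.asarray(self.target_xy, dtype=float)
        if self.synapse_xy is not None:
            self.synapse_xy = np.asarray(self.synapse_xy, dtype=float)

    @property
    def tcell_poly(self) -> Polygon:
        return Polygon(self.tcell_xy)

    @property
    def interface_length(self) -> float:
        if self.synapse_xy is None:
            return 0.0
        return float(np.linalg.norm(self.synapse_xy[1] - self.synapse_xy[0]))

    @property
    def synapse_mid(self) -> np.ndarray | None:
        if self.synapse_xy is None:
            return None
        return self.synapse_xy.mean(axis=0)


@dataclass
class CoupleTrack:
    track_id: str
    frames: list[CoupleFrame]
    frame_interval_s: float = 10.0

    def __post_init__(self) -> None:
        if not self.frames:
            raise ValueError("track must have at least one frame")

    @property
    def contact_frame(self) -> int | None:
        for f in self.frames:
            if f.contact:
                return f.t_index
        return None

    @property
    def duration_s(self) -> float:
        return self.frames[-1].t_index * self.frame_interval_s

    def frame(self, t_index: int) -> CoupleFrame:
        return self.frames[t_index]


@dataclass
class MorphoEvents:
    track_id: str
    uropod_intervals: list[tuple[int, int]]
    lamella_event_times_s: list[float]
    first_lamella_time_s: float | None
    censored: bool
    translocated: bool


# ---------------------------------------------------------------------------
# coupling


def find_coupling_frame(track: CoupleTrack, spread_fraction: float = 0.95) -> int:
    """First frame of tight coupling.

    Tight coupling = earlier of (a) the first contact frame whose interface
    length reaches ``spread_fraction`` of the track maximum ("maximally spread"),
    and (b) two frames after initial contact; clamped to the last frame.
    """
    cf = track.contact_frame
    if cf is None:
        raise ValueError(f"track {track.track_id}: no contact frame")
    last = track.frames[-1].t_index
    lengths = {f.t_index: f.interface_length for f in track.frames if f.contact}
    max_len = max(lengths.values())
    rule_a = None
    if max_len > 0:
        for t in sorted(lengths):
            if lengths[t] >= spread_fraction * max_len:
                rule_a = t
                break
    rule_b = min(cf + 2, last)
    return min(rule_a, rule_b) if rule_a is not None else rule_b


def interface_diameter(track: CoupleTrack, coupling_frame: int | None = None,
                       spread_fraction: float = 0.95) -> float:
    if coupling_frame is None:
        coupling_frame = find_coupling_frame(track, spread_fraction)
    d = track.frame(coupling_frame).interface_length
    if d <= 0:
        raise ValueError("interface diameter undefined at coupling frame")
    return d


# ---------------------------------------------------------------------------
# shape helpers


def _ensure_ccw(xy: np.ndarray) -> np.ndarray:
    x, y = xy[:, 0], xy[:, 1]
    area2 = np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y)
    return xy if area2 > 0 else xy[::-1]


def _concave_vertices(xy: np.ndarray) -> np.ndarray:
    """Boolean mask of reflex (locally concave) vertices of a CCW polygon."""
    xy = _ensure_ccw(xy)
    prev_e = xy - np.roll(xy, 1, axis=0)
    next_e = np.roll(xy, -1, axis=0) - xy
    cross = prev_e[:, 0] * next_e[:, 1] - prev_e[:, 1] * next_e[:, 0]
    return cross < -1e-9


def _angdiff(a: float, b: float) -> float:
    """Absolute angular difference in degrees, in [0, 180]."""
    d = np.degrees(np.abs(np.angle(np.exp(1j * (a - b)))))
    return float(d)


def _radial_arcs(xy: np.ndarray, rel_threshold: float = 1.15):
    """Contiguous vertex arcs protruding beyond ``rel_threshold`` x median radius.

    Returns (arcs, angles, radii, centroid): each arc is an index array into
    the (CCW-ordered) vertex list.
    """
    xy = _ensure_ccw(xy)
    c = np.asarray(Polygon(xy).centroid.coords[0])
    rel = xy - c
    radii = np.hypot(rel[:, 0], rel[:, 1])
    angles = np.arctan2(rel[:, 1], rel[:, 0])
    above = radii > rel_threshold * np.median(radii)
    if not above.any() or above.all():
        return [], angles, radii, c, xy
    # group contiguous runs with wraparound
    n = len(above)
    arcs = []
    idx = np.where(above)[0]
    runs = np.split(idx, np.where(np.diff(idx) > 1)[0] + 1)
    if len(runs) > 1 and runs[0][0] == 0 and runs[-1][-1] == n - 1:
        runs[0] = np.concatenate([runs[-1], runs[0]])
        runs.pop()
    arcs = runs
    return arcs, angles, radii, c, xy


# ---------------------------------------------------------------------------
# uropod


def detect_uropod(track: CoupleTrack, min_duration_frames: int = 6,
                  rel_threshold: float = 1.15, angle_tol_deg: float = 45.0,
                  spread_fraction: float = 0.95) -> list[tuple[int, int]]:
    """Pre-coupling uropod intervals (start, end frame indices, inclusive).

    A per-frame candidate is a boundary protrusion whose tip direction from the
    centroid lies within ``angle_tol_deg`` of the anti-motion vector and whose
    base has at least one vertex of inverse (reflex) curvature relative to the
    cell outline.  Only runs of >= ``min_duration_frames`` (1 min at 10-s
    frames) are reported.
    """
    try:
        coupling = find_coupling_frame(track, spread_fraction)
    except ValueError:
        coupling = track.frames[-1].t_index + 1
    pre = [f for f in track.frames if f.t_index < coupling]
    if len(pre) < min_duration_frames:
        warnings.warn(
            f"track {track.track_id}: only {len(pre)} pre-coupling frames",
            stacklevel=2)
        return []
    flags = np.zeros(len(pre), dtype=bool)
    centroids = [np.asarray(Polygon(f.tcell_xy).centroid.coords[0]) for f in pre]
    for i in range(1, len(pre)):
        motion = centroids[i] - centroids[i - 1]
        if np.linalg.norm(motion) < 1e-6:
            continue
        anti = np.arctan2(-motion[1], -motion[0])
        arcs, angles, radii, _, xy = _radial_arcs(pre[i].tcell_xy, rel_threshold)
        if not arcs:
            continue
        concave = _concave_vertices(xy)
        n = len(xy)
        for arc in arcs:
            tip = arc[np.argmax(radii[arc])]
            if _angdiff(angles[tip], anti) > angle_tol_deg:
                continue
            base = [(arc[0] - 1) % n, (arc[-1] + 1) % n]
            if concave[base].any():
                flags[i] = True
                break
    # runs of >= min_duration_frames consecutive flagged frames
    intervals = []
    start = None
    for i, fl in enumerate(np.append(flags, False)):
        if fl and start is None:
            start = i
        elif not fl and start is not None:
            if i - start >= min_duration_frames:
                intervals.append((pre[start].t_index, pre[i - 1].t_index))
            start = None
    return intervals


# ---------------------------------------------------------------------------
# lamellae


def detect_lamellae(track: CoupleTrack, sector_deg: float = 90.0,
                    area_frac: float = 0.10, retraction_frac: float = 0.5,
                    spread_fraction: float = 0.95,
                    coupling_frame: int | None = None) -> list[float]:
    """Onset times (s, relative to coupling) of off-interface lamellae.

    A protrusion is the region newly added between consecutive post-coupling
    outlines; it qualifies when its centroid direction from the cell centroid
    lies more than ``sector_deg`` away from the synapse direction and its area
    reaches ``area_frac`` of the cell area; the event is confirmed only if the
    region subsequently retracts (overlap drops below ``retraction_frac`` of
    the added area).
    """
    if coupling_frame is None:
        coupling_frame = find_coupling_frame(track, spread_fraction)
    post = [f for f in track.frames if f.t_index >= coupling_frame]
    if len(post) < 2:
        return []
    events: list[float] = []
    polys = [Polygon(f.tcell_xy) for f in post]
    for i in range(1, len(polys)):
        added = polys[i].difference(polys[i - 1])
        if added.is_empty or added.area < area_frac * polys[i].area:
            continue
        c = np.asarray(polys[i].centroid.coords[0])
        ac = np.asarray(added.centroid.coords[0])
        mid = post[i].synapse_mid
        if mid is None:
            continue
        dir_prot = np.arctan2(*(ac - c)[::-1])
        dir_syn = np.arctan2(*(mid - c)[::-1])
        if _angdiff(dir_prot, dir_syn) <= sector_deg:
            continue
        retracted = False
        for j in range(i + 1, len(polys)):
            if polys[j].intersection(added).area < retraction_frac * added.area:
                retracted = True
                break
        if retracted:
            t_s = (post[i].t_index - coupling_frame) * track.frame_interval_s
            events.append(float(t_s))
    return events


# ---------------------------------------------------------------------------
# translocation


def classify_translocation(track: CoupleTrack, spread_fraction: float = 0.95,
                           coupling_frame: int | None = None) -> bool:
    """True iff the synapse midpoint migrates, at any post-coupling frame,
    strictly further than the interface diameter measured at coupling."""
    if coupling_frame is None:
        coupling_frame = find_coupling_frame(track, spread_fraction)
    diam = interface_diameter(track, coupling_frame)
    ref = track.frame(coupling_frame).synapse_mid
    if ref is None:
        raise ValueError("no synapse recorded at the coupling frame")
    best = 0.0
    for f in track.frames:
        if f.t_index <= coupling_frame or f.synapse_mid is None:
            continue
        best = max(best, float(np.linalg.norm(f.synapse_mid - ref)))
    return best > diam


def classify_track(track: CoupleTrack, sector_deg: float = 90.0,
                   area_frac: float = 0.10, spread_fraction: float = 0.95,
                   movie_duration_s: float | None = None) -> MorphoEvents:
    """Run every classifier on a track and collect the event summary."""
    coupling = find_coupling_frame(track, spread_fraction)
    lam = detect_lamellae(track, sector_deg, area_frac,
                          spread_fraction=spread_fraction,
                          coupling_frame=coupling)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        uro = detect_uropod(track, spread_fraction=spread_fraction)
    return MorphoEvents(
        track_id=track.track_id,
        uropod_intervals=uro,
        lamella_event_times_s=lam,
        first_lamella_time_s=min(lam) if lam else None,
        censored=not lam,
        translocated=classify_translocation(track, spread_fraction,
                                            coupling_frame=coupling),
    )


# ---------------------------------------------------------------------------
# survival


@dataclass
class SurvivalCurve:
    times: np.ndarray        # distinct event times
    survival: np.ndarray     # S(t) just after each event time

    def at(self, t: float) -> float:
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


@dataclass
class LogRankResult:
    curve_a: SurvivalCurve
    curve_b: SurvivalCurve
    chi_square: float
    p_value: float


def km_curve(times, censored) -> SurvivalCurve:
    """Product-limit (Kaplan-Meier) estimator."""
    times = np.asarray(times, dtype=float)
    censored = np.asarray(censored, dtype=bool)
    if len(times) == 0:
        raise ValueError("empty group")
    if np.any(times < 0):
        raise ValueError("event times must be >= 0")
    event_times = np.unique(times[~censored])
    surv = []
    s = 1.0
    for t in event_times:
        n_at_risk = np.sum(times >= t)
        d = np.sum((times == t) & ~censored)
        s *= 1.0 - d / n_at_risk
        surv.append(s)
    return SurvivalCurve(times=event_times, survival=np.asarray(surv))


def logrank_statistic(times_a, censored_a, times_b, censored_b) -> float:
    """Two-group log-rank chi-square in the (O-E)^2/V form with the
    discrete-time tie convention."""
    ta = np.asarray(times_a, float); ca = np.asarray(censored_a, bool)
    tb = np.asarray(times_b, float); cb = np.asarray(censored_b, bool)
    all_events = np.unique(np.concatenate([ta[~ca], tb[~cb]]))
    o_minus_e = 0.0
    var = 0.0
    for t in all_events:
        n1 = np.sum(ta >= t)
        n2 = np.sum(tb >= t)
        n = n1 + n2
        d1 = np.sum((ta == t) & ~ca)
        d2 = np.sum((tb == t) & ~cb)
        d = d1 + d2
        if n == 0 or d == 0:
            continue
        e1 = d * n1 / n
        o_minus_e += d1 - e1
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    if var == 0:
        return 0.0
    return float(o_minus_e**2 / var)


def km_logrank(times_a, censored_a, times_b, censored_b) -> LogRankResult:
    """KM curves for both groups plus the two-group log-rank test
    (chi-square with 1 df)."""
    chi2 = logrank_statistic(times_a, censored_a, times_b, censored_b)
    p = float(stats.chi2.sf(chi2, df=1)) if chi2 > 0 else 1.0
    return LogRankResult(
        curve_a=km_curve(times_a, censored_a),
        curve_b=km_curve(times_b, censored_b),
        chi_square=chi2,
        p_value=p,
    )


# ---------------------------------------------------------------------------
# calcium


@dataclass
class CalciumTrace:
    """Fura-2 excitation pair with field backgrounds, aligned to coupling."""

    f340: np.ndarray
    f380: np.ndarray
    bg340: float
    bg380: float
    coupling_frame: int
    frame_interval_s: float = 10.0

    def __post_init__(self) -> None:
        self.f340 = np.asarray(self.f340, dtype=float)
        self.f380 = np.asarray(self.f380, dtype=float)
        if self.f340.shape != self.f380.shape:
            raise ValueError("excitation channels must have equal length")

    @property
    def times_s(self) -> np.ndarray:
        """Frame times in seconds with t=0 at the coupling frame."""
        idx = np.arange(len(self.f340))
        return (idx - self.coupling_frame) * self.frame_interval_s


def fura2_ratio(trace: CalciumTrace) -> np.ndarray:
    """Background-subtracted 340/380 ratio; NaN where the denominator <= 0."""
    num = trace.f340 - trace.bg340
    den = trace.f380 - trace.bg380
    out = np.full_like(num, np.nan, dtype=float)
    ok = den > 0
    out[ok] = num[ok] / den[ok]
    return out
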