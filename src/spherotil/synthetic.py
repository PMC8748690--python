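"""Synthetic-data generators with known ground truth for every pipeline stage.

Each generator is deterministic for a given seed and returns both the rendered
inputs and a truth object from which every downstream quantity can be
recovered without re-simulation.

Rendered scenes emulate the acquisition geometry: anisotropic z-stacks (3-um
z-steps) cropped at the spheroid's widest plane (half-spheroids, bottom slice
first), a point-like T-cell reporter channel and a concentric dead core whose
volume fraction grows linearly with saturation at 1.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from spherotil.cytotox import RedAreaSeries
from spherotil.flow_pca import MarkerMatrix
from spherotil.growth_stats import TumorCourse, elliptical_volume
from spherotil.io_config import VoxelGrid
from spherotil.morphodyn import CalciumTrace, CoupleFrame, CoupleTrack

from shapely.geometry import Polygon, box


# ---------------------------------------------------------------------------
# spheroid imaging scenes


@dataclass
class SpheroidSceneTruth:
    """Ground truth for a rendered spheroid scene."""

    centers_um: np.ndarray            # (n, 3) sphere centers (x, y, z)
    radii_um: np.ndarray              # (n,)
    volumes_um3: np.ndarray           # analytic (4/3) pi r^3
    touching_pairs: list[tuple[int, int]]
    timepoints_h: np.ndarray
    dead_fraction: np.ndarray         # (n_timepoints, n_spheroids), in [0, 1]
    tcell_centers_um: list[np.ndarray]   # per timepoint, (m, 3) in the half-stack
    tcell_count_mirrored: np.ndarray     # per timepoint: count after z-mirroring

    def to_json(self, path: str | Path) -> None:
        d = {
            "centers_um": self.centers_um.tolist(),
            "radii_um": self.radii_um.tolist(),
            "volumes_um3": self.volumes_um3.tolist(),
            "touching_pairs": [list(p) for p in self.touching_pairs],
            "timepoints_h": self.timepoints_h.tolist(),
            "dead_fraction": self.dead_fraction.tolist(),
            "tcell_centers_um": [a.tolist() for a in self.tcell_centers_um],
            "tcell_count_mirrored": self.tcell_count_mirrored.tolist(),
        }
        Path(path).write_text(json.dumps(d, indent=1))


def dead_fraction_curve(f0: float, kill_rate_per_h: float, times_h: np.ndarray
                        ) -> np.ndarray:
    """Linear-with-saturation dead-volume fraction: min(1, f0 + k t)."""
    return np.minimum(1.0, f0 + kill_rate_per_h * np.asarray(times_h, dtype=float))


def _render_ball(channel: np.ndarray, center_um, radius_um, voxel_size, value):
    dx, dy, dz = voxel_size
    nz, ny, nx = channel.shape
    cx, cy, cz = center_um
    zs = (np.arange(nz) * dz - cz)[:, None, None]
    ys = (np.arange(ny) * dy - cy)[None, :, None]
    xs = (np.arange(nx) * dx - cx)[None, None, :]
    inside = zs**2 + ys**2 + xs**2 <= radius_um**2
    channel[inside] = value


def make_spheroid_scene(
    n_spheroids: int = 1,
    radius_um: float | list[float] = 60.0,
    centers_xy_um: list[tuple[float, float]] | None = None,
    n_tcells: int = 0,
    kill_rate_per_h: float = 0.0,
    dead_fraction0: float = 0.0,
    n_timepoints: int = 1,
    interval_h: float = 2.0,
    noise: float = 0.0,
    blur_sigma_um: float = 0.0,
    seed: int | None = None,
    voxel_size: tuple[float, float, float] = (2.0, 2.0, 3.0),
    margin_um: float = 24.0,
    intensity: float = 200.0,
    tcell_radius_um: float = 4.0,
    tcell_z_mode: str = "plane",
) -> tuple[list[VoxelGrid], SpheroidSceneTruth]:
    """Render a spheroid scene as half-stacks (bottom to widest plane).

    All spheres share a common center plane (the widest plane, top slice of
    each stack).  T cells are point-like blobs placed inside the first sphere,
    well separated; ``tcell_z_mode='plane'`` puts them on the mirror plane so
    the mirrored detection count equals ``n_tcells`` exactly, ``'uniform'``
    samples z below the plane (each such cell counts twice after mirroring).
    The dead channel is a concentric core of volume fraction
    ``min(1, f0 + k t)``.
    """
    rng = np.random.default_rng(seed)
    if n_timepoints < 1:
        raise ValueError("n_timepoints must be >= 1")
    if kill_rate_per_h < 0 or dead_fraction0 < 0:
        raise ValueError("rates must be non-negative")
    radii = np.asarray(
        [radius_um] * n_spheroids if np.isscalar(radius_um) else radius_um,
        dtype=float)
    if len(radii) != n_spheroids:
        raise ValueError("radius list must match n_spheroids")
    dx, dy, dz = voxel_size
    if np.any(radii < 5 * max(dx, dy, dz)):
        raise ValueError("radii must span at least 5 voxels")

    rmax = radii.max()
    if centers_xy_um is None:
        xs = []
        x = margin_um + radii[0]
        for i, r in enumerate(radii):
            if i > 0:
                x += radii[i - 1] + 2 * margin_um + r
            xs.append(x)
        cy = margin_um + rmax
        centers_xy = [(xi, cy) for xi in xs]
    else:
        centers_xy = [tuple(c) for c in centers_xy_um]
        if len(centers_xy) != n_spheroids:
            raise ValueError("centers list must match n_spheroids")

    # common widest plane: center z sits exactly on the top slice
    nz_half = int(np.ceil(rmax / dz)) + 2
    cz = (nz_half - 1) * dz
    width = max(c[0] + r for c, r in zip(centers_xy, radii)) + margin_um
    height = max(c[1] + r for c, r in zip(centers_xy, radii)) + margin_um
    nx, ny = int(np.ceil(width / dx)), int(np.ceil(height / dy))
    for (x0, y0), r in zip(centers_xy, radii):
        if x0 - r < 0 or y0 - r < 0:
            raise ValueError("spheroid does not fit in the field")

    centers = np.array([(x0, y0, cz) for (x0, y0) in centers_xy])
    touching = [(i, j) for i in range(n_spheroids) for j in range(i + 1, n_spheroids)
                if np.linalg.norm(centers[i] - centers[j]) < radii[i] + radii[j]]

    times_h = np.arange(n_timepoints) * interval_h
    dead_frac = np.stack([dead_fraction_curve(dead_fraction0, kill_rate_per_h, times_h)
                          for _ in range(n_spheroids)], axis=1)

    # T-cell placement inside sphere 0, well separated in-plane
    tcell_centers = np.zeros((0, 3))
    if n_tcells > 0:
        r_host = radii[0] - tcell_radius_um - 2 * max(dx, dy, dz)
        host = centers[0]
        pts = []
        min_sep = 4 * tcell_radius_um
        for _ in range(20000):
            if len(pts) == n_tcells:
                break
            u = rng.uniform(0, 2 * np.pi)
            rad = r_host * np.sqrt(rng.uniform(0.05, 0.95))
            if tcell_z_mode == "plane":
                cand = np.array([host[0] + rad * np.cos(u),
                                 host[1] + rad * np.sin(u), cz])
            else:
                zr = rng.uniform(-r_host * 0.8, 0)
                in_plane = np.sqrt(max(r_host**2 - zr**2, 0))
                rad = in_plane * np.sqrt(rng.uniform(0.05, 0.95))
                cand = np.array([host[0] + rad * np.cos(u),
                                 host[1] + rad * np.sin(u), cz + zr])
            if all(np.linalg.norm(cand[:2] - p[:2]) >= min_sep for p in pts):
                pts.append(cand)
        if len(pts) < n_tcells:
            raise ValueError("could not place T cells with the required separation")
        tcell_centers = np.array(pts)

    on_plane = (np.abs(tcell_centers[:, 2] - cz) < 1e-9 if len(tcell_centers)
                else np.zeros(0, dtype=bool))
    mirrored_count = int(on_plane.sum() + 2 * (~on_plane).sum())

    series: list[VoxelGrid] = []
    shape = (nz_half, ny, nx)
    for ti, t_h in enumerate(times_h):
        sph = np.zeros(shape, dtype=np.float32)
        tc = np.zeros(shape, dtype=np.float32)
        dd = np.zeros(shape, dtype=np.float32)
        for ci, r in zip(centers, radii):
            _render_ball(sph, ci, r, voxel_size, intensity)
        for si, (ci, r) in enumerate(zip(centers, radii)):
            f = dead_frac[ti, si]
            if f > 0:
                _render_ball(dd, ci, r * f ** (1 / 3), voxel_size, intensity)
        for p in tcell_centers:
            _render_ball(tc, p, tcell_radius_um, voxel_size, intensity)
        channels = {"spheroid": sph, "tcell": tc, "dead": dd}
        if blur_sigma_um > 0:
            from scipy.ndimage import gaussian_filter
            sig = (blur_sigma_um / dz, blur_sigma_um / dy, blur_sigma_um / dx)
            channels = {k: gaussian_filter(v, sig) for k, v in channels.items()}
        if noise > 0:
            channels = {
                k: np.clip(v + rng.normal(0, noise, v.shape)
                           + rng.poisson(np.clip(v, 0, None) * 0.05) - v * 0.05,
                           0, None).astype(np.float32)
                for k, v in channels.items()}
        series.append(VoxelGrid(channels=channels, voxel_size=voxel_size,
                                timepoint_h=float(t_h)))

    truth = SpheroidSceneTruth(
        centers_um=centers, radii_um=radii,
        volumes_um3=(4 / 3) * np.pi * radii**3,
        touching_pairs=touching, timepoints_h=times_h,
        dead_fraction=dead_frac,
        tcell_centers_um=[tcell_centers.copy() for _ in times_h],
        tcell_count_mirrored=np.full(n_timepoints, mirrored_count),
    )
    return series, truth


# ---------------------------------------------------------------------------
# cytotoxicity curves


@dataclass
class CytotoxTruth:
    steepest_slope_um2_per_h: float     # most negative target slope
    t_steepest_h: float
    control_slope_at_steepest: float
    normalized_rate: float              # control - target slope at the window
    lag_h: float
    decline_end_h: float


def make_cytotox_curves(
    a0_um2: float = 1e5,
    g_control_per_h: float = 0.03,
    lag_h: float = 2.0,
    decline_duration_h: float = 6.0,
    floor_frac: float = 0.05,
    duration_h: float = 14.0,
    step_min: float = 15.0,
    noise: float = 0.0,
    seed: int | None = None,
) -> tuple[RedAreaSeries, RedAreaSeries, CytotoxTruth]:
    """Control grows exponentially; the target holds at ``a0`` through a lag,
    declines logistically to ``floor_frac * a0`` and stays at the floor.

    The logistic's steepest (inflection) slope is ``-s (A0 - floor)/4`` with
    ``s = 2 ln(99) / decline_duration`` (1% -> 99% progress across the
    decline window); it is the analytic killing-slope truth.
    """
    rng = np.random.default_rng(seed)
    t = np.arange(0, duration_h + 1e-9, step_min / 60.0)
    control = a0_um2 * np.exp(g_control_per_h * t)
    floor = floor_frac * a0_um2
    s = 2 * np.log(99.0) / decline_duration_h
    t_mid = lag_h + decline_duration_h / 2.0
    target = floor + (a0_um2 - floor) / (1.0 + np.exp(s * (t - t_mid)))
    target[t < lag_h] = a0_um2
    if noise > 0:
        control = np.clip(control + rng.normal(0, noise * a0_um2, t.shape), 0, None)
        target = np.clip(target + rng.normal(0, noise * a0_um2, t.shape), 0, None)
    slope = -s * (a0_um2 - floor) / 4.0
    ctrl_slope = g_control_per_h * a0_um2 * np.exp(g_control_per_h * t_mid)
    truth = CytotoxTruth(
        steepest_slope_um2_per_h=slope, t_steepest_h=t_mid,
        control_slope_at_steepest=ctrl_slope,
        normalized_rate=ctrl_slope - slope,
        lag_h=lag_h, decline_end_h=lag_h + decline_duration_h)
    return (RedAreaSeries(t, target, condition="target"),
            RedAreaSeries(t, control, condition="control"), truth)


# ---------------------------------------------------------------------------
# cell-couple tracks


@dataclass
class CoupleTrackTruth:
    track_id: str
    translocated: bool
    first_lamella_time_s: float | None    # relative to coupling; None = censored
    censored: bool
    has_uropod: bool
    uropod_frames: tuple[int, int] | None


def _couple_polygon(center, radius, clip_q=None, clip_dir=None,
                    bump=None, n_vertices=72) -> np.ndarray:
    """Circle outline with an optional radial finger bump and an optional
    half-plane clip (the flat synapse side).

    ``bump`` = (angle_rad, half_width_rad, height_um): radii inside the arc are
    raised by ``height``, producing reflex vertices at the bump base.
    """
    theta = np.linspace(0, 2 * np.pi, n_vertices, endpoint=False)
    r = np.full(n_vertices, float(radius))
    if bump is not None:
        b_ang, b_hw, b_h = bump
        d = np.angle(np.exp(1j * (theta - b_ang)))
        r[np.abs(d) <= b_hw] += b_h
    pts = np.stack([center[0] + r * np.cos(theta),
                    center[1] + r * np.sin(theta)], axis=1)
    if clip_q is None:
        return pts
    poly = Polygon(pts)
    u = np.asarray(clip_dir, dtype=float)
    u = u / np.linalg.norm(u)
    # keep the half-plane {x: (x - center) . u <= q}
    far = 10 * radius
    p0 = np.asarray(center) + clip_q * u
    perp = np.array([-u[1], u[0]])
    half = Polygon([p0 + far * perp, p0 - far * perp,
                    p0 - far * perp - far * u, p0 + far * perp - far * u])
    clipped = poly.intersection(half)
    return np.asarray(clipped.exterior.coords[:-1])


def make_couple_track(
    track_id: str = "t0",
    translocate: bool = False,
    lamella_time_s: float | None = None,
    uropod: bool = False,
    uropod_frames: int = 8,
    margin: float = 1.5,
    lamella_area_frac: float = 0.10,
    n_frames: int = 91,
    contact_frame: int = 12,
    spread_frames: int = 4,
    frame_interval_s: float = 10.0,
    tcell_radius_um: float = 7.0,
    target_radius_um: float = 10.0,
    jitter_um: float = 0.0,
    seed: int | None = None,
) -> tuple[CoupleTrack, CoupleTrackTruth]:
    """One parametric couple track with controllable injected events.

    Events exceed (or undershoot) classifier thresholds by ``margin``:
    translocation displacement = ``margin`` x interface diameter (or
    1/``margin`` when ``translocate`` is False but jitter motion exists),
    lamella protrusion area = ``margin`` x ``lamella_area_frac`` x cell area.
    ``lamella_time_s`` is relative to the coupling frame.
    """
    rng = np.random.default_rng(seed)
    rc, rt = tcell_radius_um, target_radius_um
    target_center = np.zeros(2)
    target_xy = _couple_polygon(target_center, rt)
    u = np.array([-1.0, 0.0])                 # approach direction (toward target)
    start_d = rt + rc + 18.0
    contact_d = rt + rc

    w_max = 0.8 * rc
    q_max = np.sqrt(rc**2 - w_max**2)

    coupling_frame = min(contact_frame + 2,
                         contact_frame + spread_frames, n_frames - 1)
    # translocation threshold is the interface diameter AT COUPLING, which may
    # be below the fully spread diameter when rule (b) fires first
    prog_c = min(1.0, (coupling_frame - contact_frame) / max(spread_frames, 1))
    diam_c = 2 * w_max * (0.25 + 0.75 * prog_c)
    d_target = margin * diam_c if translocate else diam_c / margin
    dphi_max = 2 * np.arcsin(min(d_target / (2 * rt), 1.0))
    ramp_start = coupling_frame + 3

    lam_frame = None
    if lamella_time_s is not None:
        lam_frame = coupling_frame + int(round(lamella_time_s / frame_interval_s))
        if not coupling_frame < lam_frame < n_frames - 4:
            raise ValueError("lamella time outside the post-coupling range")

    frames: list[CoupleFrame] = []
    for fi in range(n_frames):
        jit = rng.normal(0, jitter_um, 2) if jitter_um > 0 else np.zeros(2)
        if fi < contact_frame:
            frac = fi / contact_frame
            d = start_d + (contact_d - start_d) * frac
            center = target_center - u * d + jit
            bump = None
            if uropod and contact_frame - uropod_frames - 1 <= fi < contact_frame - 1:
                # rear finger: opposite the motion direction (motion is -u... the
                # cell moves along -u toward the target, so the rear points +u)
                bump = (0.0, np.radians(18.0), 0.45 * rc)
            pts = _couple_polygon(center, rc, bump=bump)
            frames.append(CoupleFrame(t_index=fi, tcell_xy=pts,
                                      target_xy=target_xy, contact=False))
            continue

        # in contact: interface grows linearly to w_max over spread_frames
        prog = min(1.0, (fi - contact_frame) / max(spread_frames, 1)) if \
            spread_frames > 0 else 1.0
        w = w_max * (0.25 + 0.75 * prog)
        q = np.sqrt(rc**2 - w**2)
        phi = 0.0
        if fi >= ramp_start and dphi_max > 0:
            phi = dphi_max * min(1.0, (fi - ramp_start) / max(n_frames - 1 - ramp_start, 1))
        dir_out = np.array([np.cos(np.pi - phi), np.sin(np.pi - phi)])  # contact normal
        contact_pt = target_center + rt * dir_out
        center = contact_pt + q * dir_out
        inward = -dir_out
        bump = None
        if lam_frame is not None and lam_frame <= fi < lam_frame + 3:
            cell_area = np.pi * rc**2
            b_hw = np.radians(20.0)
            area = margin * lamella_area_frac * cell_area
            h = np.sqrt(rc**2 + area / b_hw) - rc
            ang_away = np.arctan2(dir_out[1], dir_out[0])
            bump = (ang_away, b_hw, h)
        pts = _couple_polygon(center, rc, clip_q=q, clip_dir=inward, bump=bump)
        perp = np.array([-inward[1], inward[0]])
        chord_c = center + q * inward
        synapse = np.stack([chord_c + w * perp, chord_c - w * perp])
        frames.append(CoupleFrame(t_index=fi, tcell_xy=pts, target_xy=target_xy,
                                  contact=True, synapse_xy=synapse))

    track = CoupleTrack(track_id=track_id, frames=frames,
                        frame_interval_s=frame_interval_s)
    truth = CoupleTrackTruth(
        track_id=track_id, translocated=translocate,
        first_lamella_time_s=(None if lam_frame is None
                              else (lam_frame - coupling_frame) * frame_interval_s),
        censored=lam_frame is None,
        has_uropod=uropod,
        uropod_frames=((contact_frame - uropod_frames - 1, contact_frame - 2)
                       if uropod else None),
    )
    return track, truth


def make_couple_tracks(
    n_tracks: int = 10,
    translocation_frac: float = 0.5,
    lamella_times_s: list[float | None] | None = None,
    uropod_frac: float = 0.0,
    margin: float = 1.5,
    seed: int | None = None,
    **kwargs,
) -> tuple[list[CoupleTrack], list[CoupleTrackTruth]]:
    """A suite of couple tracks with known event labels.

    ``lamella_times_s`` gives the per-track injected lamella onset (relative
    to coupling, seconds); None entries are censored.  When omitted, a default
    staircase of times is used for the first half of the tracks.
    """
    rng = np.random.default_rng(seed)
    if lamella_times_s is None:
        lamella_times_s = [100.0 + 30.0 * i if i < n_tracks // 2 else None
                           for i in range(n_tracks)]
    if len(lamella_times_s) != n_tracks:
        raise ValueError("lamella_times_s must have one entry per track")
    n_trans = int(round(translocation_frac * n_tracks))
    n_uro = int(round(uropod_frac * n_tracks))
    tracks, truths = [], []
    for i in range(n_tracks):
        tr, th = make_couple_track(
            track_id=f"t{i}", translocate=i < n_trans,
            lamella_time_s=lamella_times_s[i], uropod=i < n_uro,
            margin=margin, seed=int(rng.integers(2**31)), **kwargs)
        tracks.append(tr)
        truths.append(th)
    return tracks, truths


def make_calcium_trace(
    n_frames: int = 91,
    coupling_frame: int = 20,
    baseline_ratio: float = 1.0,
    step_ratio: float = 2.0,
    f380_level: float = 150.0,
    bg340: float = 50.0,
    bg380: float = 50.0,
    noise: float = 0.0,
    seed: int | None = None,
) -> tuple[CalciumTrace, np.ndarray]:
    """Fura-2 trace whose background-subtracted ratio steps from
    ``baseline_ratio`` to ``step_ratio`` at the coupling frame.  Returns the
    trace and the true ratio series."""
    rng = np.random.default_rng(seed)
    ratio = np.full(n_frames, baseline_ratio)
    ratio[coupling_frame:] = step_ratio
    f380 = np.full(n_frames, f380_level + bg380)
    f340 = ratio * (f380 - bg380) + bg340
    if noise > 0:
        f340 = f340 + rng.normal(0, noise, n_frames)
        f380 = f380 + rng.normal(0, noise, n_frames)
    trace = CalciumTrace(f340=f340, f380=f380, bg340=bg340, bg380=bg380,
                         coupling_frame=coupling_frame)
    return trace, ratio


# ---------------------------------------------------------------------------
# tumor-growth cohorts


@dataclass
class GrowthCohortTruth:
    mouse: list[str]
    group: list[str]
    responder: list[bool]
    relapsed: list[bool]


def _dims_from_volume(v_mm3: float, aspect: float = 0.8) -> tuple[float, float]:
    """Invert V = 0.5 L W^2 with W = aspect * L."""
    length = (v_mm3 / (0.5 * aspect**2)) ** (1 / 3)
    return length, aspect * length


def make_growth_cohort(
    n_mice: int = 10,
    groups: dict[str, float] | None = None,
    responder_prob: float = 1.0,
    start_volume_mm3: float = 62.5,
    start_day: int = 12,
    end_day: int = 40,
    noise: float = 0.0,
    seed: int | None = None,
) -> tuple[list[TumorCourse], GrowthCohortTruth]:
    """Triphasic caliper courses: growth to day 18, response to day 26, then
    an open-ended relapse phase.

    ``groups`` maps group name -> relapse probability among responders
    (default one group "A" with probability 0.5).  Relapsing courses re-cross
    the day-``start_day`` volume; non-relapsing responders stay in deep
    remission (< 5 mm in both dimensions).  Non-responders grow monotonically.
    """
    rng = np.random.default_rng(seed)
    groups = groups or {"A": 0.5}
    days = np.arange(start_day, end_day + 1, 2, dtype=float)
    courses, truth = [], GrowthCohortTruth([], [], [], [])
    for gname, relapse_prob in groups.items():
        if not 0 <= relapse_prob <= 1:
            raise ValueError("relapse probability must lie in [0, 1]")
        for m in range(n_mice):
            mouse = f"{gname}{m:03d}"
            is_resp = rng.uniform() < responder_prob
            is_rel = bool(is_resp and rng.uniform() < relapse_prob)
            v = np.empty_like(days)
            for i, d in enumerate(days):
                if not is_resp:
                    v[i] = start_volume_mm3 * (1 + 0.15 * (d - start_day))
                elif d <= 18:                       # growth phase
                    v[i] = start_volume_mm3 * (1 + 0.12 * (d - start_day))
                elif d <= 26:                       # response phase: decay
                    peak = start_volume_mm3 * (1 + 0.12 * 6)
                    frac = (d - 18) / 8.0
                    low = 0.15 * start_volume_mm3
                    v[i] = peak * (low / peak) ** frac
                else:                               # relapse phase
                    low = 0.15 * start_volume_mm3
                    if is_rel:
                        v[i] = low * (1.35 ** (d - 26))
                    else:
                        v[i] = low * 0.98 ** (d - 26)
            if is_rel:
                v = np.minimum(v, 4.0 * start_volume_mm3)
                v[-1] = max(v[-1], 1.3 * start_volume_mm3)  # guarantee re-cross
            if noise > 0:
                v = v * np.exp(rng.normal(0, noise, v.shape))
            dims = np.array([_dims_from_volume(vi) for vi in v])
            courses.append(TumorCourse(mouse=mouse, group=gname, days=days,
                                       length_mm=dims[:, 0], width_mm=dims[:, 1],
                                       start_day=start_day))
            truth.mouse.append(mouse)
            truth.group.append(gname)
            truth.responder.append(bool(is_resp))
            truth.relapsed.append(is_rel)
    return courses, truth


# ---------------------------------------------------------------------------
# marker matrices


DEFAULT_MARKERS = ["CD39", "CD73", "TIM3", "TIGIT", "LAG3", "PD1", "CD44", "CD69"]


@dataclass
class MarkerCohortTruth:
    sample_id: list[str]
    group: list[str]
    suppression_score: list[float]


def make_marker_cells(
    n_mice_per_group: int = 10,
    n_cells: int = 1000,
    marker_names: list[str] | None = None,
    effect_axis: float = 1.0,
    marker_probs: list[float] | None = None,
    base_logit: float = -0.5,
    weight: float = 1.2,
    score_sd: float = 0.15,
    marker_noise: float = 0.05,
    seed: int | None = None,
) -> tuple[list[MarkerMatrix], MarkerCohortTruth]:
    """Per-cell marker positivity driven by a latent per-mouse suppression
    score; the treated group's score is shifted by ``-effect_axis`` so PC1 of
    the combination features separates the groups.

    When ``marker_probs`` is given, positivity is i.i.d. Bernoulli per marker
    (independent of the score) — the controlled regime for frequency oracles.
    Tumor volumes are log-normal and increase with the score.
    """
    rng = np.random.default_rng(seed)
    names = marker_names or list(DEFAULT_MARKERS)
    matrices, truth = [], MarkerCohortTruth([], [], [])
    for group, shift in (("control", 0.0), ("treated", -effect_axis)):
        for m in range(n_mice_per_group):
            sid = f"{group}{m:02d}"
            score = rng.normal(shift, score_sd)
            if marker_probs is not None:
                if len(marker_probs) != len(names):
                    raise ValueError("marker_probs must match marker count")
                pos = rng.uniform(size=(n_cells, len(names))) < np.asarray(marker_probs)
            else:
                logits = base_logit + weight * score \
                    + rng.normal(0, marker_noise, len(names))
                p = 1.0 / (1.0 + np.exp(-logits))
                pos = rng.uniform(size=(n_cells, len(names))) < p
            vol = 10 ** (1.5 + 0.35 * score + rng.normal(0, 0.08))
            matrices.append(MarkerMatrix(
                sample_id=sid, group=group, positivity=pos,
                marker_names=names, tumor_volume_mm3=float(vol)))
            truth.sample_id.append(sid)
            truth.group.append(group)
            truth.suppression_score.append(float(score))
    return matrices, truth
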