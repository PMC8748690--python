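"""3D spheroid segmentation: mirror-completion, thresholding, connected
components, alpha-shape gap filling, distance-based watershed splitting, and
per-spheroid T-cell / dead-volume quantification.

Half-stacks acquired from the spheroid bottom to its widest plane are mirrored
along z (widest plane kept once) to produce pseudo-complete spheroids before
segmentation.  All distance computations use physical voxel sizes, so the
3-um z-step anisotropy is accounted for.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.spatial import Delaunay, QhullError
from skimage.feature import peak_local_max
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label
from skimage.segmentation import watershed

from spherotil.io_config import Config, VoxelGrid

logger = logging.getLogger("spherotil")


@dataclass
class LabelVolume:
    labels: np.ndarray                       # (Z, Y, X) int, 0 = background
    voxel_size: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError("labels must be 3D")

    @property
    def n_objects(self) -> int:
        return int(self.labels.max())

    @property
    def voxel_volume_um3(self) -> float:
        dx, dy, dz = self.voxel_size
        return dx * dy * dz


@dataclass
class SpheroidRecord:
    label: int
    volume_um3: float
    centroid_um: tuple[float, float, float]   # (x, y, z)
    timepoint_h: float = 0.0
    tcell_count: int = 0
    sil_density_per_mm3: float = 0.0
    dead_volume_um3: float = 0.0


# ---------------------------------------------------------------------------
# mirror completion


def mirror_concatenate(grid: VoxelGrid) -> VoxelGrid:
    """Reflect a bottom-to-widest half-stack along z into a pseudo-complete
    stack of ``2Z - 1`` slices; the widest (top) plane appears exactly once."""
    channels = {}
    for name, vol in grid.channels.items():
        if vol.shape[0] == 1:
            channels[name] = vol.copy()
        else:
            channels[name] = np.concatenate([vol, vol[-2::-1]], axis=0)
    return VoxelGrid(channels=channels, voxel_size=grid.voxel_size,
                     timepoint_h=grid.timepoint_h)


# ---------------------------------------------------------------------------
# thresholding


def _binarise(vol: np.ndarray, method: float | str) -> np.ndarray:
    """Threshold a channel; 'otsu' guards against a foreground-free channel
    (a constant image, or foreground indistinguishable from background noise,
    yields an empty mask)."""
    if method == "otsu":
        if vol.max() == vol.min():
            return np.zeros(vol.shape, dtype=bool)
        thr = threshold_otsu(vol)
        mask = vol > thr
        bg = vol[~mask]
        fg = vol[mask]
        if fg.size == 0 or bg.size == 0:
            return np.zeros(vol.shape, dtype=bool)
        if fg.mean() - bg.mean() < 3.0 * max(bg.std(), 1e-12):
            return np.zeros(vol.shape, dtype=bool)
        return mask
    return vol > float(method)


# ---------------------------------------------------------------------------
# alpha-shape gap filling


def _tet_circumradii(points: np.ndarray, simplices: np.ndarray) -> np.ndarray:
    """Circumradius of every tetrahedron (vectorized)."""
    p0 = points[simplices[:, 0]]
    a = points[simplices[:, 1]] - p0
    b = points[simplices[:, 2]] - p0
    c = points[simplices[:, 3]] - p0
    # circumcenter offset m solves 2 M m = [|a|^2, |b|^2, |c|^2]
    m_rows = np.stack([a, b, c], axis=1)                    # (n, 3, 3)
    rhs = 0.5 * np.stack([(a * a).sum(1), (b * b).sum(1), (c * c).sum(1)], axis=1)
    det = np.linalg.det(m_rows)
    radii = np.full(len(simplices), np.inf)
    ok = np.abs(det) > 1e-12
    if ok.any():
        sol = np.linalg.solve(m_rows[ok], rhs[ok][..., None])[..., 0]
        radii[ok] = np.linalg.norm(sol, axis=1)
    return radii


class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))
        self.n_components = n

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[ri] = rj
            self.n_components -= 1


def _critical_alpha(radii: np.ndarray, simplices: np.ndarray, n_points: int) -> float:
    """Smallest circumradius cutoff at which the kept tetrahedra connect all
    points into one region (the per-object default alpha)."""
    order = np.argsort(radii)
    uf = _UnionFind(n_points)
    seen = np.zeros(n_points, dtype=bool)
    n_seen = 0
    for idx in order:
        tet = simplices[idx]
        for v in tet:
            if not seen[v]:
                seen[v] = True
                n_seen += 1
        for v in tet[1:]:
            uf.union(tet[0], v)
        if n_seen == n_points and uf.n_components == 1:
            return float(radii[idx])
    return float(radii[order[-1]])


def alpha_fill_component(mask: np.ndarray, voxel_size: tuple[float, float, float],
                         alpha: float | str = "auto",
                         max_points: int = 4000,
                         rng: np.random.Generator | None = None) -> np.ndarray:
    """Fill a (possibly fragmented) component with its alpha-shape interior.

    The component's voxel centers (physical units) are Delaunay-triangulated;
    tetrahedra with circumradius <= alpha are kept (alpha='auto' uses the
    per-object critical alpha, the smallest value yielding one connected
    region).  Voxels of the bounding box whose centers fall inside a kept
    tetrahedron are set.  The result is unioned with the input mask, so the
    fill is monotone (output is a superset of the input).

    Degenerate point clouds (coplanar/collinear, < 4 points) fall back to
    morphological closing plus hole filling.
    """
    coords = np.argwhere(mask)
    if len(coords) == 0:
        return mask.copy()
    scale = np.array(voxel_size[::-1])          # (dz, dy, dx) for (z, y, x) order
    pts_all = coords * scale
    if len(pts_all) > max_points:
        rng = rng or np.random.default_rng(0)
        sel = rng.choice(len(pts_all), size=max_points, replace=False)
        pts = pts_all[sel]
    else:
        pts = pts_all
    try:
        tri = Delaunay(pts)
    except QhullError:
        return _morph_fill(mask)
    radii = _tet_circumradii(tri.points, tri.simplices)
    if alpha == "auto":
        alpha_val = _critical_alpha(radii, tri.simplices, len(pts))
    else:
        alpha_val = float(alpha)
    keep = radii <= alpha_val * (1 + 1e-9)
    if not keep.any():
        return _morph_fill(mask)

    zmin, ymin, xmin = coords.min(axis=0)
    zmax, ymax, xmax = coords.max(axis=0)
    zz, yy, xx = np.meshgrid(np.arange(zmin, zmax + 1), np.arange(ymin, ymax + 1),
                             np.arange(xmin, xmax + 1), indexing="ij")
    cand = np.stack([zz.ravel(), yy.ravel(), xx.ravel()], axis=1)
    simplex = tri.find_simplex(cand * scale)
    inside = (simplex >= 0) & keep[np.clip(simplex, 0, None)]
    out = mask.copy()
    hit = cand[inside]
    out[hit[:, 0], hit[:, 1], hit[:, 2]] = True
    # the alpha complex may retain internal cavities (e.g. a hollow center);
    # the enclosed region is the filled interior
    return ndimage.binary_fill_holes(out)


def _morph_fill(mask: np.ndarray) -> np.ndarray:
    closed = ndimage.binary_closing(mask, structure=np.ones((3, 3, 3)), iterations=2)
    return ndimage.binary_fill_holes(closed) | mask


# ---------------------------------------------------------------------------
# segmentation


_CONN26 = np.ones((3, 3, 3), dtype=bool)


def segment_spheroids(grid: VoxelGrid, config: Config | None = None
                      ) -> tuple[LabelVolume, list[SpheroidRecord]]:
    """Binarise, label (26-connected), alpha-fill each component, split merged
    objects with an anisotropy-aware distance watershed, and measure volumes.

    Expects a mirror-concatenated grid.  Components below
    ``config.min_volume_um3`` are dropped.
    """
    config = config or Config()
    vol = grid.channels["spheroid"]
    vv = grid.voxel_volume_um3
    mask = _binarise(vol, config.spheroid_threshold)
    if not mask.any():
        warnings.warn("no spheroid foreground found", stacklevel=2)
        return LabelVolume(np.zeros(vol.shape, dtype=np.int32), grid.voxel_size), []

    comp = cc_label(mask, connectivity=3)
    filled = np.zeros(mask.shape, dtype=bool)
    for lab in range(1, comp.max() + 1):
        m = comp == lab
        if m.sum() * vv < config.min_volume_um3:
            continue
        filled |= alpha_fill_component(m, grid.voxel_size, config.alpha)
    if not filled.any():
        warnings.warn("all components below the minimum volume", stacklevel=2)
        return LabelVolume(np.zeros(vol.shape, dtype=np.int32), grid.voxel_size), []

    labels = _split_merged(filled, grid.voxel_size, config.marker_separation_um)

    # drop residual small fragments, relabel contiguously
    out = np.zeros(labels.shape, dtype=np.int32)
    records: list[SpheroidRecord] = []
    next_label = 0
    dx, dy, dz = grid.voxel_size
    for lab in range(1, labels.max() + 1):
        m = labels == lab
        count = int(m.sum())
        if count == 0 or count * vv < config.min_volume_um3:
            continue
        next_label += 1
        out[m] = next_label
        zc, yc, xc = ndimage.center_of_mass(m)
        records.append(SpheroidRecord(
            label=next_label, volume_um3=count * vv,
            centroid_um=(xc * dx, yc * dy, zc * dz),
            timepoint_h=grid.timepoint_h))
    return LabelVolume(out, grid.voxel_size), records


def _split_merged(mask: np.ndarray, voxel_size: tuple[float, float, float],
                  separation_um: float) -> np.ndarray:
    """Distance-based watershed splitting of merged objects.

    Seeds are local maxima of the physical-unit Euclidean distance map with a
    minimum in-plane separation of ``separation_um``; the watershed is
    restricted to each original connected component so it can only split,
    never merge, input objects.
    """
    dx, dy, dz = voxel_size
    comp = cc_label(mask, connectivity=3)
    dist = ndimage.distance_transform_edt(mask, sampling=(dz, dy, dx))
    min_dist_vox = max(1, int(round(separation_um / min(dx, dy))))
    peaks = peak_local_max(dist, labels=comp, min_distance=min_dist_vox,
                           exclude_border=False)
    markers = np.zeros(mask.shape, dtype=np.int32)
    for i, (z, y, x) in enumerate(peaks, start=1):
        markers[z, y, x] = i
    if markers.max() == 0:
        return comp
    return watershed(-dist, markers=markers, mask=mask)


def segment_cells(grid: VoxelGrid, labels: LabelVolume, config: Config | None = None
                  ) -> tuple[list[dict], dict[int, int]]:
    """Detect T cells by thresholding + 26-connected labeling (no alpha step).

    Components >= ``min_cell_volume_um3`` count as cells; each detection is
    assigned to the spheroid label containing its centroid (0 = outside any
    spheroid, counted toward the scene total only).  Returns the detection
    list and a per-spheroid-label count map.
    """
    config = config or Config()
    vol = grid.channels["tcell"]
    vv = grid.voxel_volume_um3
    mask = _binarise(vol, config.cell_threshold)
    comp = cc_label(mask, connectivity=3)
    detections: list[dict] = []
    counts: dict[int, int] = {}
    dx, dy, dz = grid.voxel_size
    for lab in range(1, comp.max() + 1):
        m = comp == lab
        v_um3 = m.sum() * vv
        if v_um3 < config.min_cell_volume_um3:
            continue
        zc, yc, xc = ndimage.center_of_mass(m)
        parent = int(labels.labels[int(round(zc)), int(round(yc)), int(round(xc))])
        detections.append({
            "centroid_um": (xc * dx, yc * dy, zc * dz),
            "volume_um3": float(v_um3),
            "spheroid_label": parent,
        })
        counts[parent] = counts.get(parent, 0) + 1
    return detections, counts


def segment_dead(grid: VoxelGrid, labels: LabelVolume, config: Config | None = None
                 ) -> dict[int, float]:
    """Dead (viability-dye) volume per spheroid label, um^3.

    The dead channel is thresholded and labeled; dead voxels are intersected
    with the spheroid label volume, so dye outside any spheroid contributes 0.
    """
    config = config or Config()
    mask = _binarise(grid.channels["dead"], config.dead_threshold)
    vv = grid.voxel_volume_um3
    out: dict[int, float] = {}
    for lab in range(1, labels.n_objects + 1):
        out[lab] = float(np.sum(mask & (labels.labels == lab)) * vv)
    return out


def quantify_timepoint(grid: VoxelGrid, config: Config | None = None
                       ) -> tuple[LabelVolume, list[SpheroidRecord]]:
    """mirror -> segment spheroids -> count cells -> dead volume, one stack."""
    config = config or Config()
    full = mirror_concatenate(grid)
    labels, records = segment_spheroids(full, config)
    _, counts = segment_cells(full, labels, config)
    dead = segment_dead(full, labels, config)
    for rec in records:
        rec.tcell_count = counts.get(rec.label, 0)
        rec.sil_density_per_mm3 = rec.tcell_count / (rec.volume_um3 * 1e-9)
        rec.dead_volume_um3 = dead.get(rec.label, 0.0)
    return labels, records


@dataclass
class TimeSeriesMetrics:
    timepoints_h: np.ndarray
    records: list[list[SpheroidRecord]]     # per timepoint
    total_volume_um3: np.ndarray
    total_tcell_count: np.ndarray
    scene_density_per_mm3: np.ndarray       # total count / total volume
    total_dead_um3: np.ndarray
    death_metric_um3: np.ndarray            # total dead at t minus at t0


def run_spheroid_pipeline(series: list[VoxelGrid], config: Config | None = None
                          ) -> TimeSeriesMetrics:
    """Quantify every timepoint; the death metric is the increase in summed
    dead volume relative to the first timepoint."""
    config = config or Config()
    if not series:
        raise ValueError("empty series")
    all_records, tot_v, tot_n, tot_d = [], [], [], []
    for i, grid in enumerate(series):
        try:
            _, recs = quantify_timepoint(grid, config)
        except Exception as exc:
            raise RuntimeError(f"timepoint {i} (t={grid.timepoint_h} h): {exc}") from exc
        all_records.append(recs)
        tot_v.append(sum(r.volume_um3 for r in recs))
        tot_n.append(sum(r.tcell_count for r in recs))
        tot_d.append(sum(r.dead_volume_um3 for r in recs))
    tot_v = np.asarray(tot_v)
    tot_n = np.asarray(tot_n, dtype=float)
    tot_d = np.asarray(tot_d)
    with np.errstate(divide="ignore", invalid="ignore"):
        dens = np.where(tot_v > 0, tot_n / (tot_v * 1e-9), 0.0)
    return TimeSeriesMetrics(
        timepoints_h=np.asarray([g.timepoint_h for g in series]),
        records=all_records,
        total_volume_um3=tot_v,
        total_tcell_count=tot_n.astype(int),
        scene_density_per_mm3=dens,
        total_dead_um3=tot_d,
        death_metric_um3=tot_d - tot_d[0],
    )
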