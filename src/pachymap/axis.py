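"""Medial-axis extraction and chromosome straightening.

The counterstain channel is thresholded (Otsu), reduced to its largest
connected component, and skeletonized; the skeleton's longest end-to-end
path is smoothed with a spline and becomes the chromosome axis. The
straightened image samples perpendicular cross-sections at equally spaced
arc-length stations, one column per pixel of arc.
"""

from __future__ import annotations

import heapq
import logging
from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
from scipy import ndimage
from scipy.interpolate import splev, splprep
from scipy.ndimage import map_coordinates
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label
from skimage.morphology import skeletonize

from .io import MultiChannelImage

log = logging.getLogger("pachymap")


class AxisError(ValueError):
    pass


@dataclass
class ChromosomePath:
    """Ordered (row, col) points in continuous pixel coordinates, running
    from one chromosome terminus to the other."""

    points: np.ndarray
    um_per_px: float
    short_arm_first: Optional[bool] = None

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 2:
            raise AxisError("path must be an (N, 2) array")
        if np.any(np.all(np.diff(self.points, axis=0) == 0, axis=1)):
            raise AxisError("path has repeated consecutive points")
        if self.arc_length_um <= 0:
            raise AxisError("path has zero length")

    @property
    def arc_length_px(self) -> float:
        return float(np.hypot(*np.diff(self.points, axis=0).T).sum())

    @property
    def arc_length_um(self) -> float:
        return self.arc_length_px * self.um_per_px


@dataclass
class StraightenedChromosome:
    """Straightened image: rows = perpendicular offset, cols = axial position."""

    pixels: np.ndarray  # [channel, row, col]
    axial_um_per_col: float
    half_width_um: float
    channel_labels: list[str]
    flipped: bool = False

    @property
    def n_cols(self) -> int:
        return int(self.pixels.shape[2])

    @property
    def length_um(self) -> float:
        return self.n_cols * self.axial_um_per_col

    def channel(self, index_or_label) -> np.ndarray:
        if isinstance(index_or_label, str):
            index_or_label = self.channel_labels.index(index_or_label)
        return self.pixels[index_or_label]


# --------------------------------------------------------------------------
# segmentation


def segment_foreground(
    img: MultiChannelImage,
    channel=0,
    blur_um: float = 0.3,
    close_um: float = 0.8,
) -> np.ndarray:
    """Binary chromosome mask: Otsu threshold, largest component, filled.

    The channel is Gaussian-blurred before thresholding so the beaded
    chromomere string thresholds as one tube, and the mask is morphologically
    closed so the dim centromeric constriction does not split it.
    """
    data = img.channel(channel).astype(float)
    if data.max() <= data.min():
        raise AxisError("no chromosome found: blank image")
    sigma_px = blur_um / img.um_per_px
    smooth = ndimage.gaussian_filter(data, sigma_px)
    mask = smooth > threshold_otsu(smooth)
    if not mask.any():
        raise AxisError("no chromosome found: empty mask")
    r = max(1, int(round(close_um / img.um_per_px)))
    yy, xx = np.mgrid[-r:r + 1, -r:r + 1]
    disk = (yy ** 2 + xx ** 2) <= r ** 2
    mask = ndimage.binary_closing(mask, structure=disk)
    labels = cc_label(mask, connectivity=2)
    sizes = np.bincount(labels.ravel())
    sizes[0] = 0
    mask = labels == int(np.argmax(sizes))
    mask = ndimage.binary_fill_holes(mask)
    log.info("segment_foreground: mask area %d px (blur %.2f μm, close %.2f μm)",
             int(mask.sum()), blur_um, close_um)
    return mask


# --------------------------------------------------------------------------
# skeleton graph helpers

_NEIGHBORS = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


def _skeleton_graph(skel: np.ndarray):
    coords = {tuple(p): i for i, p in enumerate(np.argwhere(skel))}
    adj: list[list[tuple[int, float]]] = [[] for _ in coords]
    for (r, c), i in coords.items():
        for dr, dc in _NEIGHBORS:
            j = coords.get((r + dr, c + dc))
            if j is not None:
                adj[i].append((j, float(np.hypot(dr, dc))))
    nodes = np.array(list(coords.keys()))
    return nodes, adj


def _dijkstra(adj, source: int):
    n = len(adj)
    dist = np.full(n, np.inf)
    prev = np.full(n, -1, dtype=int)
    dist[source] = 0.0
    heap = [(0.0, source)]
    while heap:
        d, u = heapq.heappop(heap)
        if d > dist[u]:
            continue
        for v, w in adj[u]:
            nd = d + w
            if nd < dist[v]:
                dist[v] = nd
                prev[v] = u
                heapq.heappush(heap, (nd, v))
    return dist, prev


def _longest_endpoint_path(skel: np.ndarray, intensity: Optional[np.ndarray]):
    nodes, adj = _skeleton_graph(skel)
    degrees = np.array([len(a) for a in adj])
    endpoints = np.flatnonzero(degrees <= 1)
    if endpoints.size < 2:
        raise AxisError("skeleton has no endpoints (cyclic): cannot trace axis")
    best = None
    for src in endpoints:
        dist, prev = _dijkstra(adj, int(src))
        finite = np.where(np.isfinite(dist[endpoints]), dist[endpoints], -1)
        tgt = endpoints[int(np.argmax(finite))]
        length = dist[tgt]
        path_idx = []
        u = int(tgt)
        while u != -1:
            path_idx.append(u)
            u = int(prev[u]) if u != src else -1
        path = nodes[path_idx[::-1]]
        score = (length, _path_mean_intensity(path, intensity))
        if best is None or score > best[0]:
            best = (score, path)
    return best[1]


def _path_mean_intensity(path: np.ndarray, intensity: Optional[np.ndarray]) -> float:
    if intensity is None:
        return 0.0
    return float(intensity[path[:, 0], path[:, 1]].mean())


# --------------------------------------------------------------------------
# axis extraction


def extract_axis(
    mask: np.ndarray,
    um_per_px: float,
    intensity: Optional[np.ndarray] = None,
    smooth_factor: float = 0.05,
    extend_to_boundary: bool = True,
    end_trim_factor: float = 0.5,
) -> ChromosomePath:
    """Medial axis of the mask as a smooth, end-to-end path.

    The skeleton is pruned to its single longest endpoint-to-endpoint path
    (ties broken by mean intensity), smoothed with a cubic spline whose
    smoothing factor grows with path length, extended along the end tangents
    to the mask boundary, and finally trimmed at each end by the local tube
    radius (distance-transform value at the skeleton endpoint) so the cap
    rounding does not inflate the arc length.
    """
    if cc_label(mask, connectivity=2).max() != 1:
        raise AxisError("mask must be a single connected component")
    skel = skeletonize(mask)
    path = _longest_endpoint_path(skel, intensity).astype(float)
    if path.shape[0] < 8:
        raise AxisError("skeleton path too short")
    # cubic smoothing spline; s scales with path length to iron pixel jaggedness
    s = smooth_factor * path.shape[0]
    tck, _ = splprep([path[:, 0], path[:, 1]], s=s, k=3)
    u = np.linspace(0, 1, max(200, 4 * path.shape[0]))
    rr, cc = splev(u, tck)
    pts = np.stack([rr, cc], axis=1)

    edt = ndimage.distance_transform_edt(mask)
    if extend_to_boundary:
        head = _extend_end(pts[1], pts[0], mask)
        tail = _extend_end(pts[-2], pts[-1], mask)
        pts = np.vstack([head[::-1], pts, tail])
    if end_trim_factor > 0:
        r0 = float(edt[tuple(np.round(path[0]).astype(int))])
        r1 = float(edt[tuple(np.round(path[-1]).astype(int))])
        pts = _trim_arc(pts, end_trim_factor * r0, end_trim_factor * r1)
    pts = _resample_uniform(pts, step_px=0.5)
    log.info("extract_axis: %d points, %.2f μm",
             pts.shape[0], float(np.hypot(*np.diff(pts, axis=0).T).sum()) * um_per_px)
    return ChromosomePath(points=pts, um_per_px=um_per_px)


def _extend_end(inner: np.ndarray, outer: np.ndarray, mask: np.ndarray,
                step: float = 0.5, max_steps: int = 400) -> np.ndarray:
    d = outer - inner
    norm = np.hypot(*d)
    if norm == 0:
        return np.empty((0, 2))
    d = d / norm
    out = []
    p = outer.copy()
    for _ in range(max_steps):
        p = p + step * d
        r, c = int(round(p[0])), int(round(p[1]))
        if not (0 <= r < mask.shape[0] and 0 <= c < mask.shape[1]) or not mask[r, c]:
            break
        out.append(p.copy())
    return np.asarray(out).reshape(-1, 2)


def _trim_arc(pts: np.ndarray, trim_start: float, trim_end: float) -> np.ndarray:
    seg = np.hypot(*np.diff(pts, axis=0).T)
    arc = np.concatenate([[0.0], np.cumsum(seg)])
    lo, hi = trim_start, arc[-1] - trim_end
    if hi <= lo:
        return pts
    keep = (arc >= lo) & (arc <= hi)
    head = np.array([np.interp(lo, arc, pts[:, 0]), np.interp(lo, arc, pts[:, 1])])
    tail = np.array([np.interp(hi, arc, pts[:, 0]), np.interp(hi, arc, pts[:, 1])])
    return np.vstack([head, pts[keep], tail])


def _resample_uniform(pts: np.ndarray, step_px: float) -> np.ndarray:
    seg = np.hypot(*np.diff(pts, axis=0).T)
    good = np.concatenate([[True], seg > 1e-9])
    pts = pts[good]
    seg = np.hypot(*np.diff(pts, axis=0).T)
    arc = np.concatenate([[0.0], np.cumsum(seg)])
    t = np.arange(0.0, arc[-1] + step_px / 2, step_px)
    return np.stack([np.interp(t, arc, pts[:, 0]),
                     np.interp(t, arc, pts[:, 1])], axis=1)


# --------------------------------------------------------------------------
# straightening


def straighten(
    img: MultiChannelImage,
    path: ChromosomePath,
    half_width_um: float = 1.2,
) -> StraightenedChromosome:
    """Resample perpendicular cross-sections at equal arc-length stations.

    One output column per pixel of arc length; rows span ±half_width_um.
    All channels are transformed identically (bilinear interpolation).
    """
    px = path.um_per_px
    stations = _resample_uniform(path.points, step_px=1.0)
    tangents = np.gradient(stations, axis=0)
    tangents /= np.hypot(*tangents.T)[:, None]
    normals = np.stack([-tangents[:, 1], tangents[:, 0]], axis=1)
    hw_px = int(round(half_width_um / px))
    offsets = np.arange(-hw_px, hw_px + 1)
    # coords[r, c] = station_c + offset_r * normal_c
    rows = stations[:, 0][None, :] + offsets[:, None] * normals[:, 0][None, :]
    cols = stations[:, 1][None, :] + offsets[:, None] * normals[:, 1][None, :]
    n_rows, n_cols = img.channel(0).shape
    if (rows.min() < -0.5 or rows.max() > n_rows - 0.5
            or cols.min() < -0.5 or cols.max() > n_cols - 0.5):
        raise AxisError("half_width too large: cross-sections leave the image")
    out = np.stack([
        map_coordinates(img.channel(k), [rows, cols], order=1, mode="nearest")
        for k in range(img.n_channels)
    ])
    return StraightenedChromosome(
        pixels=out,
        axial_um_per_col=px,
        half_width_um=hw_px * px,
        channel_labels=list(img.channel_labels),
    )


def orient(
    straightened: StraightenedChromosome,
    centromere_um: Optional[float] = None,
    marker_channel: Optional[str] = None,
    marker_arm: str = "S",
) -> StraightenedChromosome:
    """Flip so column 0 is the short-arm terminus.

    If an arm-specific marker channel is present its designated arm wins
    (needed when the designated short arm is physically the longer one);
    otherwise the side with less length from the centromere is "short".
    """
    flip = False
    if marker_channel is not None and marker_channel in straightened.channel_labels:
        trace = straightened.channel(marker_channel).max(axis=0)
        peak_frac = float(np.argmax(trace)) / max(len(trace) - 1, 1)
        flip = (peak_frac > 0.5) if marker_arm == "S" else (peak_frac <= 0.5)
    elif centromere_um is not None:
        flip = centromere_um > straightened.length_um / 2.0
    if not flip:
        return straightened
    return replace(
        straightened,
        pixels=straightened.pixels[:, :, ::-1].copy(),
        flipped=not straightened.flipped,
    )
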