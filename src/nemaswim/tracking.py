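"""Multi-animal tracking: segmentation, deformable centerline tracking,
keyframe merging, contact handling and quality control.

Segmentation locates dark swimmers on a light background: a local
standard-deviation filter (kernel ~ the animal's width) enhances edges and
suppresses sensor noise, the smoothed intensity image is thresholded, and
each animal's closed outline is extracted.  The inner Euclidean distance
transform of the outline gives the centerline (the inner ridge, the line of
lateral symmetry) and the body half-width at every ridge point.

Between segmentations, each animal is tracked frame-to-frame by a deformable
model: at 18 fps swim motion is mostly lateral and bodies overlap between
consecutive frames, so at least two *stationary anchor points* can be found
by comparing local intensity patches of the image pair.  Anchors are held
fixed while the remaining points relax under an energy combining image
support (the distance-transform ridge), curvature smoothness, and arc-length
preservation.  A fresh segmentation is merged in every 20 frames (key
frames) to bound drift.

Quality rules: a frame is flagged when the fitted body length drops two
(robust) standard deviations below the animal's whole-video typical length;
animals in
potential contact (overlapping motion envelopes that cannot be separated)
have those frames flagged; an animal with more than 20% flagged frames is
rejected outright, though manual overrides can flip individual frames or
the whole-animal verdict.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.ndimage import (
    distance_transform_edt,
    gaussian_filter,
    map_coordinates,
    uniform_filter,
)
from skimage.filters import threshold_otsu
from skimage.measure import find_contours, label, regionprops
from skimage.morphology import skeletonize

from .geometry import Centerline, body_length, resample_centerline

__all__ = [
    "TrackingParams",
    "FrameSegmentation",
    "AnimalTrack",
    "std_filter",
    "segment_frame",
    "track_step",
    "keyframe_merge",
    "handle_contacts",
    "quality_check",
    "orient_head_tail",
    "track_video",
]

FLAG_OK = "ok"
FLAG_CONTACT = "contact"
FLAG_QUALITY = "quality"
FLAG_LOST = "lost"


@dataclass
class TrackingParams:
    """Segmentation/tracking configuration.

    ``std_kernel`` should be about the animal's width in pixels.  The
    envelope bound is the maximum credible per-frame displacement of a body
    point: a quarter body length per frame at the reference 18 fps, scaled
    for other frame rates.
    """

    std_kernel: int = 5
    min_area: int = 120  # px, smallest credible animal blob
    min_skeleton_len: int = 15  # px
    n_track_points: int = 25  # deformable model control points
    keyframe_every: int = 20
    envelope_fraction: float = 0.25  # of body length per frame at 18 fps
    fit_iterations: int = 12
    w_image: float = 1.0
    w_smooth: float = 0.25
    w_length: float = 0.5
    contrast_sigmas: float = 4.0  # blob/background separation guard
    reject_fraction: float = 0.20
    length_sd_drop: float = 2.0


@dataclass
class FrameSegmentation:
    """Per-frame segmentation result: outlines, centerlines, half-widths."""

    outlines: List[np.ndarray]  # closed (x, y) polygons
    centerlines: List[Centerline]
    frame_index: int = 0


@dataclass
class AnimalTrack:
    """One animal's tracked centerline sequence with per-frame flags."""

    animal_id: int
    frames: List[Centerline]
    flags: List[str]  # FLAG_* per frame
    rejected: bool = False
    head_tail_swapped: bool = False

    @property
    def flagged_fraction(self) -> float:
        if not self.flags:
            return 0.0
        return float(np.mean([f != FLAG_OK for f in self.flags]))

    def apply_overrides(self, overrides: Dict[int, bool]) -> None:
        """Manual review: force frame validity (True = valid) per frame."""
        for t, ok in overrides.items():
            self.flags[t] = FLAG_OK if ok else FLAG_QUALITY
            self.frames[t].valid = ok


def std_filter(image: np.ndarray, size: int = 5) -> np.ndarray:
    """Local standard deviation (edge enhancer / noise suppressor)."""
    img = image.astype(float)
    m = uniform_filter(img, size)
    m2 = uniform_filter(img * img, size)
    return np.sqrt(np.clip(m2 - m * m, 0.0, None))


def _order_skeleton(skel: np.ndarray) -> Optional[np.ndarray]:
    """Order skeleton pixels end-to-end along the longest path.

    Returns an (N, 2) array of (row, col) coordinates or None if the
    skeleton is degenerate.  Uses a double BFS (farthest point from an
    arbitrary start, then farthest from that) over 8-connectivity.
    """
    coords = np.column_stack(np.nonzero(skel))
    if coords.shape[0] < 3:
        return None
    index = {tuple(c): i for i, c in enumerate(coords)}
    nbrs: List[List[int]] = [[] for _ in range(coords.shape[0])]
    for i, (r, c) in enumerate(coords):
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                if dr == 0 and dc == 0:
                    continue
                j = index.get((r + dr, c + dc))
                if j is not None:
                    nbrs[i].append(j)

    def bfs(start: int) -> Tuple[int, np.ndarray]:
        prev = np.full(coords.shape[0], -1, dtype=int)
        seen = np.zeros(coords.shape[0], dtype=bool)
        seen[start] = True
        frontier = [start]
        last = start
        while frontier:
            nxt = []
            for i in frontier:
                for j in nbrs[i]:
                    if not seen[j]:
                        seen[j] = True
                        prev[j] = i
                        nxt.append(j)
                        last = j
            frontier = nxt
        return last, prev

    a, _ = bfs(0)
    b, prev = bfs(a)
    path = [b]
    while prev[path[-1]] != -1:
        path.append(prev[path[-1]])
    if len(path) < 3:
        return None
    return coords[np.array(path[::-1])]


def _extend_to_tips(path_xy: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Extend an ordered centerline beyond the skeleton ends to the body
    tips (the skeleton of a tube stops about one half-width short)."""
    H, W = mask.shape
    out = [path_xy]
    for end, ref in ((0, min(5, len(path_xy) - 1)), (-1, max(-6, -len(path_xy)))):
        p = path_xy[end]
        d = p - path_xy[ref]
        norm = np.linalg.norm(d)
        if norm == 0:
            continue
        d = d / norm
        ext = []
        q = p.copy()
        for _ in range(60):
            q = q + d
            xi, yi = int(round(q[0])), int(round(q[1]))
            if not (0 <= xi < W and 0 <= yi < H) or not mask[yi, xi]:
                break
            ext.append(q.copy())
        if ext:
            if end == 0:
                out.insert(0, np.array(ext[::-1]))
            else:
                out.append(np.array(ext))
    return np.vstack(out)


def _spline_project(xy: np.ndarray, n_out: int, knot_fraction: float = 0.1) -> np.ndarray:
    """Project a (noisy) polyline onto a least-squares cubic spline with
    interior knots every ``knot_fraction`` of the arc length.

    The limited number of degrees of freedom (scale-free, in units of body
    length) removes pixel-grid jitter that would otherwise alias into the
    curvature estimate, while preserving genuine postures of up to about
    three wave cycles on the body.
    """
    from scipy.interpolate import LSQUnivariateSpline

    seg = np.linalg.norm(np.diff(xy, axis=0), axis=1)
    arc = np.concatenate([[0.0], np.cumsum(seg)])
    total = arc[-1]
    if total <= 0 or xy.shape[0] < 8:
        return xy
    u = arc / total
    # strictly increasing parameter required
    keep = np.concatenate([[True], np.diff(u) > 1e-12])
    u, pts = u[keep], xy[keep]
    n_knots = max(int(round(1.0 / knot_fraction)) - 1, 1)
    # Schoenberg-Whitney needs enough data between knots
    n_knots = min(n_knots, max((pts.shape[0] - 4) // 2, 1))
    t = np.linspace(0.0, 1.0, n_knots + 2)[1:-1]
    try:
        sx = LSQUnivariateSpline(u, pts[:, 0], t, k=3)
        sy = LSQUnivariateSpline(u, pts[:, 1], t, k=3)
    except Exception:
        return xy
    uu = np.linspace(0.0, 1.0, n_out)
    return np.column_stack([sx(uu), sy(uu)])


def _smooth_polyline(xy: np.ndarray, width: int = 5) -> np.ndarray:
    if xy.shape[0] < width:
        return xy
    kernel = np.ones(width) / width
    sm = xy.copy().astype(float)
    for k in (0, 1):
        sm[:, k] = np.convolve(np.pad(xy[:, k], width // 2, mode="edge"), kernel, "valid")
    sm[0], sm[-1] = xy[0], xy[-1]
    return sm


def _mask_to_centerline(
    mask: np.ndarray, params: TrackingParams, frame_index: int
) -> Optional[Centerline]:
    edt = distance_transform_edt(mask)
    skel = skeletonize(mask)
    ordered = _order_skeleton(skel)
    if ordered is None or ordered.shape[0] < params.min_skeleton_len:
        return None
    xy = ordered[:, ::-1].astype(float)  # (x, y)
    xy = _extend_to_tips(xy, mask)
    xy = _spline_project(_smooth_polyline(xy), 4 * params.n_track_points)
    hw = map_coordinates(edt, [xy[:, 1], xy[:, 0]], order=1, mode="nearest")
    c = Centerline(points=xy, half_widths=hw, frame_index=frame_index)
    return resample_centerline(c, params.n_track_points)


def segment_frame(
    image: np.ndarray,
    params: Optional[TrackingParams] = None,
    frame_index: int = 0,
) -> FrameSegmentation:
    """Locate all animals in one grayscale image.

    Pipeline: local std filter -> smoothed-intensity threshold (Otsu, with a
    contrast guard so featureless noise yields zero detections) -> connected
    components -> closed outline + inner distance transform per component ->
    skeleton ridge ordered end-to-end as the centerline, half-widths from
    the transform.  Returns an empty segmentation when nothing worm-like is
    found.
    """
    params = params or TrackingParams()
    img = image.astype(float)
    s = std_filter(img, params.std_kernel)
    sm = gaussian_filter(img, 1.0)
    thr = threshold_otsu(sm)
    mask = sm < thr
    # contrast guard: reject threshold splits that do not separate dark
    # animals from the background (e.g. pure-noise images)
    fg, bg = sm[mask], sm[~mask]
    if fg.size == 0 or bg.size == 0:
        return FrameSegmentation([], [], frame_index)
    if (bg.mean() - fg.mean()) < params.contrast_sigmas * max(bg.std(), 1e-6):
        return FrameSegmentation([], [], frame_index)
    # edge support: animals must carry std-filter energy
    if s[mask].mean() < s.mean():
        return FrameSegmentation([], [], frame_index)
    labels = label(mask)
    outlines, centerlines = [], []
    for region in regionprops(labels):
        if region.area < params.min_area:
            continue
        comp = labels == region.label
        cont = find_contours(comp.astype(float), 0.5)
        if not cont:
            continue
        outline = max(cont, key=len)[:, ::-1]  # (x, y)
        c = _mask_to_centerline(comp, params, frame_index)
        if c is None:
            continue
        outlines.append(outline)
        centerlines.append(c)
    return FrameSegmentation(outlines, centerlines, frame_index)


# ---------------------------------------------------------------------------
# frame-to-frame deformable tracking


def _local_body_evidence(
    image: np.ndarray, box: Tuple[int, int, int, int], params: TrackingParams
):
    """Threshold the ROI of one frame and return (mask, EDT) in ROI coords."""
    x0, y0, x1, y1 = box
    sigma = max(1.0, 0.005 * min(y1 - y0, x1 - x0))
    roi = gaussian_filter(image[y0:y1, x0:x1].astype(float), sigma)
    thr = threshold_otsu(roi) if np.ptp(roi) > 0 else roi.min()
    mask = roi < thr
    # signed distance: positive ridge inside the body, negative outside, so
    # gradient ascent attracts control points from either side
    edt = distance_transform_edt(mask) - distance_transform_edt(~mask)
    return mask, edt


def _roi_box(points: np.ndarray, shape: Tuple[int, int], margin: float):
    x0 = int(max(0, np.floor(points[:, 0].min() - margin)))
    y0 = int(max(0, np.floor(points[:, 1].min() - margin)))
    x1 = int(min(shape[1], np.ceil(points[:, 0].max() + margin)))
    y1 = int(min(shape[0], np.ceil(points[:, 1].max() + margin)))
    return x0, y0, x1, y1


def find_anchors(
    prev: Centerline, image_t1: np.ndarray, image_t2: np.ndarray, patch: int = 3
) -> np.ndarray:
    """Indices of body points whose local intensity patch is unchanged
    between consecutive frames (the stationary points), most stationary
    first.  At 18 fps at least two such points virtually always exist."""
    H, W = image_t1.shape
    diffs = []
    for i, (x, y) in enumerate(prev.points):
        xi, yi = int(round(x)), int(round(y))
        if not (patch <= xi < W - patch and patch <= yi < H - patch):
            diffs.append(np.inf)
            continue
        p1 = image_t1[yi - patch : yi + patch + 1, xi - patch : xi + patch + 1]
        p2 = image_t2[yi - patch : yi + patch + 1, xi - patch : xi + patch + 1]
        diffs.append(float(np.abs(p1.astype(float) - p2.astype(float)).mean()))
    order = np.argsort(diffs)
    return order[np.isfinite(np.array(diffs)[order])]


def track_step(
    prev: Centerline,
    image_t1: np.ndarray,
    image_t2: np.ndarray,
    params: Optional[TrackingParams] = None,
    frame_rate: float = 18.0,
    target_length: Optional[float] = None,
) -> Tuple[Centerline, str]:
    """Propagate one animal's centerline from frame t1 to frame t2.

    Stationary anchor points are pinned; the remaining control points relax
    for a few iterations under image support (uphill on the body's distance
    transform), curvature smoothness, and arc-length preservation, each step
    clipped to the motion envelope bound.  Half-widths are refreshed from
    the local distance transform.  Returns (centerline, flag).
    """
    params = params or TrackingParams()
    L = body_length(prev)
    if target_length is None:
        target_length = L
    bound = params.envelope_fraction * L * (18.0 / frame_rate)
    box = _roi_box(prev.points, image_t2.shape, margin=bound + 10)
    x0, y0, _, _ = box
    mask, edt = _local_body_evidence(image_t2, box, params)
    if not mask.any():
        return prev, FLAG_LOST

    anchors = find_anchors(prev, image_t1, image_t2)
    if anchors.size < 2:
        seg = segment_frame(image_t2, params, prev.frame_index + 1)
        match = _match_segment(prev, seg)
        if match is None:
            return prev, FLAG_LOST
        return match, FLAG_QUALITY
    anchor_set = set(anchors[: max(2, anchors.size // 4)].tolist())

    pts = prev.points.copy()
    free = np.array([i not in anchor_set for i in range(pts.shape[0])])

    def edt_at(p):
        return map_coordinates(edt, [p[:, 1] - y0, p[:, 0] - x0], order=1, mode="constant")

    def edt_grad(p):
        eps = 0.5
        gx = (
            map_coordinates(edt, [p[:, 1] - y0, p[:, 0] - x0 + eps], order=1, mode="constant")
            - map_coordinates(edt, [p[:, 1] - y0, p[:, 0] - x0 - eps], order=1, mode="constant")
        ) / (2 * eps)
        gy = (
            map_coordinates(edt, [p[:, 1] - y0 + eps, p[:, 0] - x0], order=1, mode="constant")
            - map_coordinates(edt, [p[:, 1] - y0 - eps, p[:, 0] - x0], order=1, mode="constant")
        ) / (2 * eps)
        return np.column_stack([gx, gy])

    def relax(pts, n_iter, anchored: bool):
        """Iterative deformable fit: normal-projected image force (the ridge
        carries no tangential information, and raw tangential pull drags the
        tips inward and collapses the body length) + curvature smoothness +
        arc-length preserving chain springs; displacements clipped to the
        motion envelope."""
        target_seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        target_seg *= L / max(target_seg.sum(), 1e-9)
        # the distance-field gradient has unit slope irrespective of scale,
        # so the image step must grow with the body for large animals; the
        # step anneals over iterations so the fit first catches up with the
        # motion, then settles onto the ridge without oscillation
        scale = max(L / 100.0, 1.0)
        for it in range(n_iter):
            anneal = scale * (1.0 - 0.85 * it / max(n_iter - 1, 1)) if scale > 1 else 1.0
            g = edt_grad(pts)
            tan = np.empty_like(pts)
            tan[1:-1] = pts[2:] - pts[:-2]
            tan[0] = pts[1] - pts[0]
            tan[-1] = pts[-1] - pts[-2]
            tan /= np.maximum(np.linalg.norm(tan, axis=1, keepdims=True), 1e-9)
            g = g - (np.sum(g * tan, axis=1, keepdims=True)) * tan
            step = params.w_image * anneal * g
            # smoothness: pull toward neighbor midpoint
            mid = np.empty_like(pts)
            mid[1:-1] = 0.5 * (pts[:-2] + pts[2:])
            mid[0], mid[-1] = pts[0], pts[-1]
            step += params.w_smooth * (mid - pts)
            # length preservation: spring along the chain toward target spacing
            d = np.diff(pts, axis=0)
            dist = np.linalg.norm(d, axis=1)
            unit = d / np.maximum(dist, 1e-9)[:, None]
            stretch_f = (dist - target_seg)[:, None] * unit
            spring = np.zeros_like(pts)
            spring[:-1] += stretch_f
            spring[1:] -= stretch_f
            step += params.w_length * spring
            if anchored:
                step[~free] = 0.0
            pts = pts + np.clip(step, -2.0 * anneal, 2.0 * anneal)
            # clip each point's total displacement to the envelope bound
            disp = pts - prev.points[: pts.shape[0]] if pts.shape[0] == prev.points.shape[0] else None
            if disp is not None:
                norms = np.linalg.norm(disp, axis=1)
                over = norms > bound
                if over.any():
                    pts[over] = prev.points[over] + disp[over] * (
                        bound / norms[over]
                    )[:, None]
        return pts

    pts = relax(pts, params.fit_iterations, anchored=True)

    # restore body length at the tips.  The binary mask boundary wobbles
    # with sensor noise, so tips are trimmed/grown against the smooth signed
    # distance with a tolerance band; the target is the (slowly adapting)
    # body length, which keeps the arc-length registration of the whole
    # body - and hence the curvature rows - stable over time.
    def sd_at(p) -> float:
        return float(
            map_coordinates(
                edt, [[p[1] - y0], [p[0] - x0]], order=1, mode="constant", cval=-10.0
            )[0]
        )

    tip_tol = -max(1.0, 0.005 * L)
    pts_list = [p for p in pts]
    for end in (0, -1):
        while len(pts_list) > 4 and sd_at(pts_list[end]) < tip_tol:
            pts_list.pop(end)
    pts = np.array(pts_list)
    for end, ref in ((0, 1), (-1, -2)):
        cur_len = np.linalg.norm(np.diff(pts, axis=0), axis=1).sum()
        deficit = target_length - cur_len
        if deficit <= 0.5:
            continue
        d = pts[end] - pts[ref]
        d /= max(np.linalg.norm(d), 1e-9)
        q = pts[end].copy()
        ext = []
        grown = 0.0
        while grown < min(deficit, bound):
            q2 = q + 0.5 * d
            if sd_at(q2) < tip_tol:
                break
            ext.append(q2.copy())
            grown += 0.5
            q = q2
        if ext:
            if end == 0:
                pts = np.vstack([np.array(ext[::-1]), pts])
            else:
                pts = np.vstack([pts, np.array(ext)])

    # settle the regrown tips onto the ridge
    c_tmp = Centerline(points=pts, half_widths=np.zeros(pts.shape[0]), frame_index=0)
    pts = resample_centerline(c_tmp, params.n_track_points).points
    pts = relax(pts, 4, anchored=False)
    # project onto the limited-dof spline so pixel jitter cannot alias into
    # the curvature map
    pts = _spline_project(pts, 4 * params.n_track_points)

    hw = edt_at(pts)
    c = Centerline(
        points=pts,
        half_widths=np.maximum(hw, 0.5),
        frame_index=prev.frame_index + 1,
    )
    c = resample_centerline(c, params.n_track_points)
    # sanity: fitted body must sit on image evidence
    if edt_at(c.points).mean() < 0.5:
        return c, FLAG_QUALITY
    return c, FLAG_OK


def _match_segment(
    prev: Centerline, seg: FrameSegmentation
) -> Optional[Centerline]:
    """Pick the segmented animal nearest to a tracked one; orient to match."""
    if not seg.centerlines:
        return None
    prev_c = prev.points.mean(axis=0)
    L = body_length(prev)
    best, best_d = None, np.inf
    for c in seg.centerlines:
        d = np.linalg.norm(c.points.mean(axis=0) - prev_c)
        if d < best_d:
            best, best_d = c, d
    if best is None or best_d > L:
        return None
    # orientation: align tail/head with the tracked predecessor using the
    # whole body (endpoint distances alone are ambiguous for U/C postures)
    a = resample_centerline(prev, 15).points
    b = resample_centerline(best, 15).points
    fwd = np.linalg.norm(a - b, axis=1).mean()
    rev = np.linalg.norm(a - b[::-1], axis=1).mean()
    out = best.reversed() if rev < fwd else best
    out.frame_index = prev.frame_index + 1
    return out


def keyframe_merge(
    tracked: Centerline,
    seg: FrameSegmentation,
    image: np.ndarray,
    params: Optional[TrackingParams] = None,
) -> Tuple[Centerline, str]:
    """Merge the propagated and freshly segmented centerlines at a key frame.

    Both candidates are resampled to the control grid and, pointwise, the
    candidate with the better local image support (deeper inside the body,
    i.e. larger distance-transform value) wins; the merged line is lightly
    smoothed.  Bounds tracker drift accumulated since the last key frame.
    """
    params = params or TrackingParams()
    match = _match_segment(tracked, seg)
    if match is None:
        return tracked, FLAG_QUALITY
    a = resample_centerline(tracked, params.n_track_points)
    b = resample_centerline(match, params.n_track_points)
    box = _roi_box(
        np.vstack([a.points, b.points]), image.shape, margin=10
    )
    x0, y0, _, _ = box
    _, edt = _local_body_evidence(image, box, params)

    def support(c):
        return map_coordinates(
            edt, [c.points[:, 1] - y0, c.points[:, 0] - x0], order=1, mode="constant"
        )

    sa, sb = support(a), support(b)
    take_b = sb > sa
    pts = np.where(take_b[:, None], b.points, a.points)
    hw = np.where(take_b, b.half_widths, a.half_widths)
    merged = Centerline(
        points=_smooth_polyline(pts, 3),
        half_widths=hw,
        frame_index=tracked.frame_index,
    )
    return resample_centerline(merged, params.n_track_points), FLAG_OK


def handle_contacts(
    centerlines: Sequence[Centerline],
    params: Optional[TrackingParams] = None,
    frame_rate: float = 18.0,
) -> List[bool]:
    """Per-animal contact flags for one frame.

    Each animal's motion envelope is the union of discs (radius = the
    per-frame displacement bound) around its body points.  Pairs whose
    envelopes intersect are candidate contacts; if the fitted bodies
    themselves come within touching distance (sum of local half-widths plus
    margin) the frames of both animals are flagged.  A single animal whose
    body approaches itself at large arc separation (curled/self-overlapping)
    is flagged through the same path.
    """
    params = params or TrackingParams()
    n = len(centerlines)
    flags = [False] * n
    bounds = []
    for c in centerlines:
        L = body_length(c)
        bounds.append(params.envelope_fraction * L * (18.0 / frame_rate))
    # pairwise animal contact
    for i in range(n):
        for j in range(i + 1, n):
            pi, pj = centerlines[i].points, centerlines[j].points
            d = np.linalg.norm(pi[:, None, :] - pj[None, :, :], axis=2)
            if d.min() > bounds[i] + bounds[j]:
                continue  # envelopes clear of each other
            touch = (
                centerlines[i].half_widths[:, None]
                + centerlines[j].half_widths[None, :]
                + 2.0
            )
            if (d < touch).any():
                flags[i] = flags[j] = True
    # self-overlap
    for i, c in enumerate(centerlines):
        pts = c.points
        L = body_length(c)
        m = pts.shape[0]
        arc = np.linspace(0, L, m)
        d = np.linalg.norm(pts[:, None, :] - pts[None, :, :], axis=2)
        sep = np.abs(arc[:, None] - arc[None, :])
        far = sep >= 0.3 * L
        touch = c.half_widths[:, None] + c.half_widths[None, :]
        if (d[far] < (touch[far])).any():
            flags[i] = True
    return flags


def quality_check(track: AnimalTrack, params: Optional[TrackingParams] = None) -> AnimalTrack:
    """Flag length-collapse frames and apply the rejection rule.

    A frame is flagged when its body length drops more than two robust
    standard deviations (1.4826 * MAD) below the animal's whole-video
    median length; the animal is rejected when more than 20% of its frames
    carry any flag.
    """
    params = params or TrackingParams()
    lengths = np.array([body_length(c) for c in track.frames])
    # robust moments: with plain mean/SD a sizeable block of collapsed
    # frames inflates the SD enough to mask itself (algebraically, >20%
    # contamination can never sit two SDs below the mean), defeating the
    # purpose of the rule; median/MAD keeps the threshold anchored to the
    # animal's typical length
    center = np.median(lengths)
    sd = max(1.4826 * np.median(np.abs(lengths - center)), 0.002 * center)
    for t, Lt in enumerate(lengths):
        if Lt < center - params.length_sd_drop * sd and track.flags[t] == FLAG_OK:
            track.flags[t] = FLAG_QUALITY
    for t, f in enumerate(track.flags):
        track.frames[t].valid = f == FLAG_OK
    track.rejected = track.flagged_fraction > params.reject_fraction
    return track


def orient_head_tail(track: AnimalTrack, reverse_fraction_first_pass: float) -> AnimalTrack:
    """Swap head/tail labels when the first measures pass says the animal
    swims in reverse more than half the time (strictly greater than 50%);
    measures must then be recomputed."""
    if reverse_fraction_first_pass > 50.0:
        track.frames = [c.reversed() for c in track.frames]
        track.head_tail_swapped = True
    return track


def track_video(
    frames: np.ndarray,
    frame_rate: float = 18.0,
    params: Optional[TrackingParams] = None,
) -> List[AnimalTrack]:
    """Track all animals through a (T, H, W) grayscale video.

    Deterministic: identical video + parameters give identical output.
    """
    params = params or TrackingParams()
    T = frames.shape[0]
    seg0 = segment_frame(frames[0], params, 0)
    tracks = [
        AnimalTrack(animal_id=i, frames=[c], flags=[FLAG_OK])
        for i, c in enumerate(seg0.centerlines)
    ]
    # slowly adapting per-animal length target stabilizes tip registration
    target_len = {tr.animal_id: body_length(tr.frames[0]) for tr in tracks}
    for t in range(1, T):
        # contact screening on the previous postures
        prev_lines = [tr.frames[-1] for tr in tracks]
        contact = (
            handle_contacts(prev_lines, params, frame_rate)
            if len(tracks) >= 1
            else [False] * len(tracks)
        )
        is_key = t % params.keyframe_every == 0
        seg = segment_frame(frames[t], params, t) if is_key else None
        for i, tr in enumerate(tracks):
            c, flag = track_step(
                tr.frames[-1],
                frames[t - 1],
                frames[t],
                params,
                frame_rate,
                target_length=target_len[tr.animal_id],
            )
            if flag == FLAG_OK:
                target_len[tr.animal_id] = 0.98 * target_len[tr.animal_id] + 0.02 * body_length(c)
            if is_key and seg is not None:
                c, mflag = keyframe_merge(c, seg, frames[t], params)
                if flag == FLAG_OK:
                    flag = mflag
            if contact[i] and flag == FLAG_OK:
                flag = FLAG_CONTACT
            c.frame_index = t
            tr.frames.append(c)
            tr.flags.append(flag)
    for tr in tracks:
        quality_check(tr, params)
    return tracks
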