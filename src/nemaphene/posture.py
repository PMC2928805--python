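"""Body-posture quantification: midline extraction and the head-bend angle.

The pipeline mirrors the classic single-worm posture assay: segment the animal
in each frame, skeletonize the mask, prune the skeleton to its longest
endpoint-to-endpoint geodesic path, smooth it, extend both ends to the true
mask tips, place 13 points at equal arc length from the tip of the nose to the
tail, and compute the *first supplementary angle* -- 180° minus the interior
angle at the second point formed by the three most anterior points
(equivalently, the turning angle between segments 1→2 and 2→3).  The reported
head-bend statistic is the maximum of that angle over the analysis window
(default 15-60 s, when stimulated animals bend most), i.e. the frame at which
the head swing reaches its maximal dorsoventral extension.

Coordinates are (x, y) = (column, row) subpixel positions throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import networkx as nx
import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.morphology import skeletonize

from .errors import (AnalysisWindowError, CoiledWormError, SegmentationError,
                     ValidationError)


@dataclass(frozen=True)
class PostureConfig:
    min_area_px: int = 50
    max_area_frac: float = 0.5        # of the frame
    smoothing: float = 1.5            # Gaussian sigma (px) along the path
    refine_iterations: int = 3        # grayscale subpixel refinement passes
    deadband: float = 0.25            # transverse weights below this -> 0
    resample_n: int = 400             # vertices of the final midline
    n_points: int = 13
    expected_length_px: Optional[float] = None  # sanity bounds 0.8-1.2x if set
    tip_step_px: float = 0.25
    max_tip_extension_px: float = 40.0
    min_net_motion_px: float = 2.0    # below this, head assignment is "unassigned"


@dataclass
class BinaryMask:
    mask: np.ndarray       # 2-D bool
    threshold: float
    area: int


@dataclass
class Midline:
    points: np.ndarray    # (M, 2) float, (x, y) px, head->tail once oriented
    arc_length: float     # px
    head_confidence: str = "unassigned"   # {"motion", "user", "unassigned"}

    def flipped(self) -> "Midline":
        return Midline(self.points[::-1].copy(), self.arc_length,
                       self.head_confidence)


@dataclass
class PosturePoints:
    points: np.ndarray    # (n, 2), point 1 = nose, point n = tail tip
    spacing: float        # arc length between consecutive points (px)


@dataclass
class FirstAngleResult:
    angle: float                    # degrees, unsigned magnitude
    frame_index: int
    time: float                     # s
    series: pd.DataFrame            # per-frame: time_s, angle_deg, ok, failure_reason
    signed_angle: Optional[float] = None  # image-frame sign, not dorsoventral


# ---------------------------------------------------------------------------
# segmentation

def segment_worm(frame: np.ndarray, config: PostureConfig = PostureConfig()) -> BinaryMask:
    """Segment the single worm: global threshold, hole fill, largest component.

    The threshold polarity is auto-detected (the worm may be darker or
    brighter than the plate); after an Otsu split the final cut is placed at
    the midpoint of the two class medians, which is robust to noise and
    recovers the renderer's own half-coverage mask exactly on noiseless input.
    """
    img = np.asarray(frame, dtype=float)
    if img.ndim != 2:
        raise ValidationError("frame: must be a single-channel 2-D image")
    if np.ptp(img) == 0:
        raise SegmentationError("uniform-intensity frame: no object to segment")
    try:
        t_otsu = threshold_otsu(img)
    except ValueError as exc:
        raise SegmentationError(f"threshold failed: {exc}") from exc
    lo, hi = img[img <= t_otsu], img[img > t_otsu]
    if lo.size == 0 or hi.size == 0:
        raise SegmentationError("degenerate intensity histogram")
    threshold = 0.5 * (np.median(lo) + np.median(hi))
    # the worm is the minority class; keep threshold ties on the worm side
    bright = img >= threshold
    fg = bright if bright.sum() <= bright.size / 2 else img <= threshold

    fg = ndimage.binary_fill_holes(fg)
    labels, n = ndimage.label(fg)
    if n == 0:
        raise SegmentationError("no foreground component")
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, np.arange(1, n + 1))
    best = int(np.argmax(sizes)) + 1
    mask = labels == best
    area = int(mask.sum())
    max_area = config.max_area_frac * img.size
    if not (config.min_area_px <= area <= max_area):
        raise SegmentationError(
            f"component area {area} px outside bounds "
            f"[{config.min_area_px}, {max_area:.0f}]")
    return BinaryMask(mask=mask, threshold=float(threshold), area=area)


# ---------------------------------------------------------------------------
# midline

_NEIGHBORS = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


def _skeleton_graph(skel: np.ndarray) -> nx.Graph:
    g = nx.Graph()
    coords = np.argwhere(skel)
    pix = set(map(tuple, coords))
    for (r, c) in pix:
        g.add_node((r, c))
        for dr, dc in _NEIGHBORS:
            nb = (r + dr, c + dc)
            if nb in pix:
                g.add_edge((r, c), nb, weight=float(np.hypot(dr, dc)))
    return g


def _longest_geodesic(g: nx.Graph) -> List[Tuple[int, int]]:
    endpoints = [n for n in g.nodes if g.degree(n) == 1]
    if len(endpoints) < 2:
        raise CoiledWormError(
            "coiled posture: skeleton has no endpoint-to-endpoint path")
    best_len, best_pair = -1.0, None
    for i, src in enumerate(endpoints):
        lengths = nx.single_source_dijkstra_path_length(g, src, weight="weight")
        for dst in endpoints[i + 1:]:
            if dst in lengths and lengths[dst] > best_len:
                best_len, best_pair = lengths[dst], (src, dst)
    if best_pair is None:
        raise CoiledWormError("coiled posture: skeleton endpoints are disconnected")
    return nx.dijkstra_path(g, *best_pair, weight="weight")


def _inside_mask(mask: np.ndarray, x: float, y: float) -> bool:
    r, c = int(round(y)), int(round(x))
    return 0 <= r < mask.shape[0] and 0 <= c < mask.shape[1] and bool(mask[r, c])


def _extend_to_tip(mask: np.ndarray, start: np.ndarray, direction: np.ndarray,
                   config: PostureConfig) -> np.ndarray:
    d = direction / (np.linalg.norm(direction) + 1e-12)
    p = start.astype(float).copy()
    traveled = 0.0
    while traveled < config.max_tip_extension_px:
        q = p + d * config.tip_step_px
        if not _inside_mask(mask, q[0], q[1]):
            break
        p, traveled = q, traveled + config.tip_step_px
    return p


def _arc_resample(pts: np.ndarray, n: int) -> np.ndarray:
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    s = np.linspace(0.0, cum[-1], n)
    return np.stack([np.interp(s, cum, pts[:, 0]),
                     np.interp(s, cum, pts[:, 1])], axis=1)


def _refine_to_ridge(path: np.ndarray, image: np.ndarray, mask: np.ndarray,
                     config: PostureConfig) -> np.ndarray:
    """Subpixel refinement of a midline path against the grayscale image.

    Each vertex moves to the intensity-weighted transverse centroid of the
    worm profile (normalized to [0, 1] between the background and foreground
    levels, with a deadband suppressing clipped noise tails); the window is
    the local mask half-width plus a small margin.  The pixelated skeleton is
    accurate to ~0.5 px; this recovers the remaining subpixel center.
    """
    bg = float(np.median(image[~mask]))
    fg = float(np.median(image[mask]))
    edt = ndimage.distance_transform_edt(mask)
    p = path.copy()
    for it in range(config.refine_iterations):
        d = np.gradient(p, axis=0)
        n = np.stack([-d[:, 1], d[:, 0]], axis=1)
        n /= np.linalg.norm(n, axis=1, keepdims=True) + 1e-12
        hw = ndimage.map_coordinates(edt, [p[:, 1], p[:, 0]], order=1,
                                     mode="nearest") + 2.5
        offs = np.arange(-hw.max(), hw.max() + 1e-9, 0.5)
        X = p[:, 0][None, :] + offs[:, None] * n[:, 0][None, :]
        Y = p[:, 1][None, :] + offs[:, None] * n[:, 1][None, :]
        v = ndimage.map_coordinates(image, [Y.ravel(), X.ravel()], order=1,
                                    mode="nearest")
        w = np.clip((v - bg) / (fg - bg), 0.0, 1.0).reshape(len(offs), -1)
        w[w < config.deadband] = 0.0
        w[np.abs(offs[:, None]) > hw[None, :]] = 0.0
        shift = (w * offs[:, None]).sum(axis=0) / (w.sum(axis=0) + 1e-12)
        p = p + shift[:, None] * n
        p = ndimage.gaussian_filter1d(p, config.smoothing, axis=0, mode="nearest")
    return p


def _grayscale_tip(image: np.ndarray, mask: np.ndarray, end: np.ndarray,
                   direction: np.ndarray, config: PostureConfig) -> np.ndarray:
    """Extend an endpoint along its tangent to the half-coverage crossing."""
    bg = float(np.median(image[~mask]))
    fg = float(np.median(image[mask]))
    d = direction / (np.linalg.norm(direction) + 1e-12)
    ts = np.arange(0.0, config.max_tip_extension_px, 0.1)
    xs, ys = end[0] + ts * d[0], end[1] + ts * d[1]
    v = ndimage.map_coordinates(image, [ys, xs], order=1, mode="nearest")
    w = np.clip((v - bg) / (fg - bg), 0.0, 1.0)
    below = np.where(w < 0.5)[0]
    if below.size == 0 or below[0] == 0:
        return end
    j = below[0]
    f = (w[j - 1] - 0.5) / (w[j - 1] - w[j]) if w[j - 1] != w[j] else 0.0
    return end + (ts[j - 1] + f * 0.1) * d


def extract_midline(mask: BinaryMask, config: PostureConfig = PostureConfig(),
                    image: Optional[np.ndarray] = None) -> Midline:
    """Skeletonize, prune to the longest geodesic, smooth, extend to tips.

    When the grayscale ``image`` is supplied the path is additionally refined
    to subpixel accuracy against the intensity profile (recommended; the
    driver :func:`analyze_movie` always does).  Raises
    :class:`CoiledWormError` for closed-loop (self-touching) skeletons.
    """
    skel = skeletonize(mask.mask)
    g = _skeleton_graph(skel)
    path = _longest_geodesic(g)
    # (row, col) -> (x, y)
    pts = np.array([(c, r) for r, c in path], dtype=float)
    m = len(pts)
    if m < 4:
        raise SegmentationError(f"skeleton path too short ({m} px)")

    smooth = ndimage.gaussian_filter1d(pts, config.smoothing, axis=0,
                                       mode="nearest")
    smooth = _arc_resample(smooth, max(m, 100))

    if image is not None:
        img = np.asarray(image, dtype=float)
        smooth = _refine_to_ridge(smooth, img, mask.mask, config)
        tip0 = _grayscale_tip(img, mask.mask, smooth[0], smooth[0] - smooth[4],
                              config)
        tip1 = _grayscale_tip(img, mask.mask, smooth[-1], smooth[-1] - smooth[-5],
                              config)
    else:
        # mask-only route: march along the terminal tangents to the boundary
        tip0 = _extend_to_tip(mask.mask, smooth[0], smooth[0] - smooth[4], config)
        tip1 = _extend_to_tip(mask.mask, smooth[-1], smooth[-1] - smooth[-5], config)
    full = np.vstack([tip0, smooth, tip1])

    out = _arc_resample(full, config.resample_n)
    arc = float(np.linalg.norm(np.diff(out, axis=0), axis=1).sum())
    if config.expected_length_px is not None:
        if not (0.8 * config.expected_length_px <= arc <= 1.2 * config.expected_length_px):
            raise SegmentationError(
                f"midline arc length {arc:.1f} px outside 0.8-1.2x of expected "
                f"{config.expected_length_px:.1f} px")
    return Midline(points=out, arc_length=arc)


def assign_body_points(midline: Midline, n: int = 13) -> PosturePoints:
    """``n`` points at equal arc length along the midline (default 13).

    Point 1 is the nose, point ``n`` the tail tip; positions are linearly
    interpolated between polyline vertices.
    """
    if n < 3:
        raise ValidationError("n: at least 3 body points are required")
    if midline.arc_length <= 0:
        raise ValidationError("midline: arc length must be > 0")
    pts = _arc_resample(midline.points, n)
    return PosturePoints(points=pts, spacing=midline.arc_length / (n - 1))


def first_supplementary_angle(points: PosturePoints, signed: bool = False) -> float:
    """First supplementary angle (degrees) from the three most anterior points.

    180° minus the interior angle at point 2, i.e. the turning angle between
    segment 1→2 and segment 2→3.  Unsigned magnitude in [0, 180] by default;
    with ``signed=True`` the sign is the image-frame turn direction (positive
    = counter-clockwise in array coordinates), *not* a dorsoventral label.
    """
    p = np.asarray(points.points, dtype=float)
    if len(p) < 3:
        raise ValidationError("points: need at least 3 points")
    v1, v2 = p[1] - p[0], p[2] - p[1]
    n1, n2 = np.linalg.norm(v1), np.linalg.norm(v2)
    if n1 == 0 or n2 == 0:
        raise ValidationError("points: coincident points, angle undefined")
    cross = v1[0] * v2[1] - v1[1] * v2[0]
    dot = float(np.dot(v1, v2))
    ang = np.degrees(np.arctan2(cross, dot))
    return float(ang) if signed else float(abs(ang))


# ---------------------------------------------------------------------------
# head assignment and the per-movie statistic

def assign_head(midlines: Sequence[Optional[Midline]],
                centroids: Optional[np.ndarray] = None,
                override: Optional[str] = None,
                config: PostureConfig = PostureConfig()) -> List[Optional[Midline]]:
    """Orient midlines consistently and label the nose end.

    Orientation is made consistent across frames by endpoint proximity
    matching; the nose is the endpoint that leads the centroid motion
    (projection of endpoint offsets onto per-frame motion direction).  With
    net motion below ``min_net_motion_px`` and no ``override`` ("first" or
    "last"), the orientation is kept but flagged ``unassigned``.
    """
    mids: List[Optional[Midline]] = [m for m in midlines]
    valid = [i for i, m in enumerate(mids) if m is not None]
    if not valid and override is None:
        raise ValidationError("midlines: no valid frames to orient")

    # consistent orientation frame-to-frame
    prev = None
    for i in valid:
        m = mids[i]
        if prev is not None:
            same = (np.linalg.norm(m.points[0] - prev.points[0])
                    + np.linalg.norm(m.points[-1] - prev.points[-1]))
            swap = (np.linalg.norm(m.points[0] - prev.points[-1])
                    + np.linalg.norm(m.points[-1] - prev.points[0]))
            if swap < same:
                mids[i] = m = m.flipped()
        prev = m

    if override is not None:
        if override not in ("first", "last"):
            raise ValidationError("override: must be 'first' or 'last'")
        flip = override == "last"
        out = []
        for m in mids:
            if m is None:
                out.append(None)
                continue
            m2 = m.flipped() if flip else Midline(m.points.copy(), m.arc_length)
            m2.head_confidence = "user"
            out.append(m2)
        return out

    if centroids is None:
        centroids = np.array([
            mids[i].points.mean(axis=0) if mids[i] is not None else (np.nan, np.nan)
            for i in range(len(mids))])
    centroids = np.asarray(centroids, dtype=float)

    cv = centroids[valid]
    net = np.linalg.norm(cv[-1] - cv[0]) if len(cv) >= 2 else 0.0
    score = 0.0
    if len(cv) >= 2:
        vel = np.diff(cv, axis=0)
        for j, i in enumerate(valid[:-1]):
            v = vel[j]
            nv = np.linalg.norm(v)
            if nv == 0:
                continue
            vhat = v / nv
            m = mids[i]
            score += float(np.dot(m.points[0] - cv[j], vhat)
                           - np.dot(m.points[-1] - cv[j], vhat))
    if net < config.min_net_motion_px or score == 0.0:
        for m in mids:
            if m is not None:
                m.head_confidence = "unassigned"
        return mids
    flip = score < 0
    out = []
    for m in mids:
        if m is None:
            out.append(None)
            continue
        m2 = m.flipped() if flip else Midline(m.points.copy(), m.arc_length)
        m2.head_confidence = "motion"
        out.append(m2)
    return out


def max_extension_first_angle(series: pd.DataFrame,
                              window: Tuple[float, float] = (15.0, 60.0)) -> FirstAngleResult:
    """The maximal |first angle| over valid frames inside the time window.

    ``series`` needs columns ``time_s``, ``angle_deg``, ``ok`` (and optionally
    ``failure_reason`` and ``signed_angle_deg``).  This is the frame at which
    the head swing reaches its maximal dorsoventral extension.
    """
    t0, t1 = window
    sel = series[(series["time_s"] >= t0) & (series["time_s"] <= t1)]
    ok = sel[sel["ok"]]
    if ok.empty:
        reasons = sel.get("failure_reason")
        detail = "; ".join(str(r) for r in reasons.dropna()) if reasons is not None else ""
        raise AnalysisWindowError(
            f"no valid frames in window [{t0}, {t1}] s" + (f" ({detail})" if detail else ""))
    i = ok["angle_deg"].idxmax()
    row = ok.loc[i]
    return FirstAngleResult(
        angle=float(row["angle_deg"]),
        frame_index=int(i),
        time=float(row["time_s"]),
        series=series,
        signed_angle=float(row["signed_angle_deg"]) if "signed_angle_deg" in row else None,
    )


# ---------------------------------------------------------------------------
# high-level driver

@dataclass
class PostureAnalysis:
    result: FirstAngleResult
    points: List[Optional[PosturePoints]]   # per frame
    midlines: List[Optional[Midline]]


def analyze_movie(stack: np.ndarray, frame_interval: float,
                  config: PostureConfig = PostureConfig(),
                  window: Tuple[float, float] = (15.0, 60.0),
                  head_override: Optional[str] = None) -> PostureAnalysis:
    """Segment → midline → head assignment → 13 points → first angle per frame.

    Per-frame failures (segmentation, coiling) are recorded and skipped, not
    fatal; the summary statistic is the windowed maximum-extension angle.
    """
    midlines: List[Optional[Midline]] = []
    reasons: List[Optional[str]] = []
    centroids = np.full((len(stack), 2), np.nan)
    for k, frame in enumerate(stack):
        try:
            m = segment_worm(frame, config)
            centroids[k] = ndimage.center_of_mass(m.mask)[::-1]  # (x, y)
            midlines.append(extract_midline(m, config, image=frame))
            reasons.append(None)
        except (SegmentationError, CoiledWormError) as exc:
            midlines.append(None)
            reasons.append(str(exc))

    oriented = assign_head(midlines, centroids, override=head_override, config=config)

    rows, pts_list = [], []
    for k, m in enumerate(oriented):
        t = k * frame_interval
        if m is None:
            rows.append({"frame": k, "time_s": t, "angle_deg": np.nan,
                         "signed_angle_deg": np.nan, "ok": False,
                         "failure_reason": reasons[k]})
            pts_list.append(None)
            continue
        pts = assign_body_points(m, config.n_points)
        rows.append({"frame": k, "time_s": t,
                     "angle_deg": first_supplementary_angle(pts),
                     "signed_angle_deg": first_supplementary_angle(pts, signed=True),
                     "ok": True, "failure_reason": None})
        pts_list.append(pts)
    series = pd.DataFrame(rows).set_index("frame")
    result = max_extension_first_angle(series, window)
    return PostureAnalysis(result=result, points=pts_list, midlines=oriented)
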