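"""Synthetic crawling-worm movies with analytic ground truth.

The centerline is built from cumulative turning angles over equal arc-length
steps, so the total arc length equals ``body_length`` by construction.  The
head bend is injected as a circular arc over the first 2/12 of arc length:
the tangent ramps linearly from +θ to −θ, and because the chord of a circular
arc is parallel to its midpoint tangent, the first supplementary angle of the
13 equidistant midline points equals ``head_bend_angle`` exactly.  The
sinusoidal undulation is tapered to zero over that anterior region so it
cannot contaminate the head statistic.

Rendering: a pixel belongs to the worm when its distance to the centerline is
at most the local half-width; implemented as a union of disks stamped along a
densely resampled centerline on a 4x supersampled grid, then block-averaged to
grayscale coverage (subpixel-stable masks).  The worm centroid (width-weighted,
i.e. the centroid of the analytic body) translates at ``speed`` along
``heading``; undulation contributes zero net centroid drift by construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..errors import FieldOfViewError
from .specs import WormSpec
from .truth import GroundTruth

# 12 * 64 segments: the 13 equidistant points land exactly on vertices
_N_SEG = 768
_SUPERSAMPLE = 4
_MARGIN_PX = 10


def _smoothstep(x: np.ndarray) -> np.ndarray:
    x = np.clip(x, 0.0, 1.0)
    return x * x * (3.0 - 2.0 * x)


def make_centerline(spec: WormSpec, t: float = 0.0) -> np.ndarray:
    """Analytic centerline at time ``t`` as a (769, 2) array of (x, y) in µm.

    Ordered nose→tail; arc length equals ``spec.body_length`` exactly
    (sum of 768 equal straight segments).
    """
    L = spec.body_length
    ds = L / _N_SEG
    u_mid = (np.arange(_N_SEG) + 0.5) / _N_SEG  # segment midpoints

    heading = np.deg2rad(spec.heading)
    base = heading + np.pi  # body extends tail-ward; nose leads the motion

    # circular-arc head bend over the first 2/12 of arc length: tangent ramps
    # linearly from +theta to -theta.  The chord of a circular arc is parallel
    # to its midpoint tangent, so the two anterior chords differ by exactly
    # theta and the 13-point first angle equals head_bend_angle by construction.
    theta = np.deg2rad(spec.head_bend_deg(t))
    bend = np.where(u_mid < 1.0 / 6.0, theta * (1.0 - 12.0 * u_mid), -theta)

    # undulation tapered in after the head region so the first-angle chords
    # stay exactly straight
    ramp = _smoothstep((u_mid - 1.0 / 6.0) / (1.0 / 6.0))
    omega = 2 * np.pi * spec.undulation_frequency
    phase = 2 * np.pi * u_mid / spec.undulation_wavelength - omega * t
    undul = np.deg2rad(spec.undulation_amplitude) * ramp * np.sin(phase)

    ang = base + bend + undul
    steps = ds * np.stack([np.cos(ang), np.sin(ang)], axis=1)
    pts = np.vstack([[0.0, 0.0], np.cumsum(steps, axis=0)])

    # place the width-weighted (body-mass) centroid on the prescribed path
    u = np.arange(_N_SEG + 1) / _N_SEG
    w = spec.half_width_um(u)
    centroid = (pts * w[:, None]).sum(axis=0) / w.sum()
    pos = spec.speed * t * np.array([np.cos(heading), np.sin(heading)])
    return pts - centroid + pos


def analytic_posture_points(spec: WormSpec, t: float = 0.0) -> np.ndarray:
    """The 13 equidistant points of the analytic centerline, (13, 2) µm."""
    pts = make_centerline(spec, t)
    return pts[:: _N_SEG // 12]


@dataclass
class SyntheticWormMovie:
    """Rendered movie plus its analytic ground truth."""

    frames: np.ndarray          # (T, H, W) uint16
    masks: np.ndarray           # (T, H, W) bool, coverage >= 0.5
    truth: GroundTruth
    pixel_size: float           # µm/px
    frame_interval: float       # s
    origin: np.ndarray          # world µm of pixel (0, 0)


def _resample_polyline(pts: np.ndarray, step: float):
    """Resample a polyline to ~equal steps; returns points and normalized arc."""
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    total = cum[-1]
    n = max(int(np.ceil(total / step)) + 1, 2)
    s = np.linspace(0.0, total, n)
    x = np.interp(s, cum, pts[:, 0])
    y = np.interp(s, cum, pts[:, 1])
    return np.stack([x, y], axis=1), s / total


def _paint_tube(canvas: np.ndarray, pts_ss: np.ndarray, radii_ss: np.ndarray) -> None:
    """Union of disks along the centerline, in place on a boolean canvas."""
    H, W = canvas.shape
    for (x, y), r in zip(pts_ss, radii_ss):
        if r <= 0:
            continue
        i0 = max(int(np.floor(y - r)), 0)
        i1 = min(int(np.ceil(y + r)) + 1, H)
        j0 = max(int(np.floor(x - r)), 0)
        j1 = min(int(np.ceil(x + r)) + 1, W)
        if i0 >= i1 or j0 >= j1:
            continue
        yy = np.arange(i0, i1)[:, None] - y
        xx = np.arange(j0, j1)[None, :] - x
        canvas[i0:i1, j0:j1] |= (yy * yy + xx * xx) <= r * r


def render_movie(spec: WormSpec) -> SyntheticWormMovie:
    """Render a movie of one crawling worm and its ground-truth sidecar.

    Raises :class:`FieldOfViewError` when a fixed ``canvas_shape`` cannot
    contain the full trajectory.
    """
    rng = np.random.default_rng(spec.seed)
    dt = spec.frame_interval
    times = np.arange(spec.n_frames) * dt

    centerlines = [make_centerline(spec, t) for t in times]
    allpts = np.vstack(centerlines)
    pad = spec.max_half_width + _MARGIN_PX * spec.pixel_size
    lo = allpts.min(axis=0) - pad
    hi = allpts.max(axis=0) + pad

    if spec.canvas_shape is None:
        W = int(np.ceil((hi[0] - lo[0]) / spec.pixel_size))
        H = int(np.ceil((hi[1] - lo[1]) / spec.pixel_size))
        origin = lo
    else:
        H, W = spec.canvas_shape
        # center the trajectory bounding box on the requested canvas
        origin = (lo + hi) / 2.0 - np.array([W, H]) * spec.pixel_size / 2.0
        if (hi[0] - lo[0]) > W * spec.pixel_size or (hi[1] - lo[1]) > H * spec.pixel_size:
            raise FieldOfViewError(
                "worm leaves the field of view; use a larger canvas_shape "
                f"(trajectory needs at least {int(np.ceil((hi[1]-lo[1])/spec.pixel_size))}x"
                f"{int(np.ceil((hi[0]-lo[0])/spec.pixel_size))} px)")

    ss = _SUPERSAMPLE
    frames = np.empty((spec.n_frames, H, W), dtype=np.uint16)
    masks = np.empty((spec.n_frames, H, W), dtype=bool)
    contrast = spec.foreground_intensity - spec.background_intensity

    per_frame = []
    heading = np.deg2rad(spec.heading)
    for k, t in enumerate(times):
        pts_px = (centerlines[k] - origin) / spec.pixel_size
        dense, u = _resample_polyline(pts_px, step=0.2)
        radii_px = spec.half_width_um(u) / spec.pixel_size
        canvas = np.zeros((H * ss, W * ss), dtype=bool)
        # supersampled pixel (I, J) has center ((J+0.5)/ss - 0.5, (I+0.5)/ss - 0.5)
        pts_ss = ss * (dense + 0.5) - 0.5
        _paint_tube(canvas, pts_ss, radii_px * ss)
        coverage = canvas.reshape(H, ss, W, ss).mean(axis=(1, 3))
        img = spec.background_intensity + coverage * contrast
        if spec.noise_sd > 0:
            img = img + rng.normal(0.0, spec.noise_sd, img.shape)
        frames[k] = np.clip(np.round(img), 0, 65535).astype(np.uint16)
        masks[k] = coverage >= 0.5

        pts13 = centerlines[k][:: _N_SEG // 12]
        centroid_world = spec.speed * t * np.array([np.cos(heading), np.sin(heading)])
        per_frame.append({
            "time_s": float(t),
            "first_angle_deg": abs(spec.head_bend_deg(t)),
            "points13_px": (pts13 - origin) / spec.pixel_size,
            "centroid_px": (centroid_world - origin) / spec.pixel_size,
        })

    truth = GroundTruth("worm", {
        "speed_um_per_s": spec.speed,
        "heading_deg": spec.heading,
        "pixel_size_um": spec.pixel_size,
        "frame_interval_s": spec.frame_interval,
        "body_length_um": spec.body_length,
        "body_area_um2": spec.body_area_um2(),
        "per_frame": per_frame,
        "displacement_px_per_frame":
            spec.speed * spec.frame_interval / spec.pixel_size,
    })
    return SyntheticWormMovie(frames, masks, truth, spec.pixel_size,
                              spec.frame_interval, np.asarray(origin, float))


def random_midline(rng: np.random.Generator, length_px: float = 200.0,
                   n_vertices: int = 400, n_modes: int = 4,
                   max_turn_deg: float = 120.0) -> np.ndarray:
    """A random smooth open polyline, used as a test substrate for midlines.

    Tangent angle is a random low-order Fourier series; the result is a
    (n_vertices, 2) array of (x, y) pixel coordinates with equal chord steps.
    """
    n_seg = n_vertices - 1
    u = (np.arange(n_seg) + 0.5) / n_seg
    ang = np.zeros(n_seg)
    for m in range(1, n_modes + 1):
        amp = rng.uniform(0, np.deg2rad(max_turn_deg) / n_modes)
        ang += amp * np.sin(2 * np.pi * m * u + rng.uniform(0, 2 * np.pi))
    ds = length_px / n_seg
    steps = ds * np.stack([np.cos(ang), np.sin(ang)], axis=1)
    return np.vstack([[0.0, 0.0], np.cumsum(steps, axis=0)])
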