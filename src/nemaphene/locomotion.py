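"""Centroid tracking and average locomotory speed.

Speed is the mean *path length* per unit time: total distance travelled over
consecutive valid-frame pairs divided by the summed elapsed time of those
pairs.  A head-bending worm with little net displacement still has locomotory
speed, which is what the assay compares.  Frames where segmentation fails are
flagged invalid and excluded from both numerator and denominator; they are
never interpolated.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import SegmentationError, ValidationError
from .posture import PostureConfig, segment_worm


@dataclass
class Track:
    """Per-frame centroid positions with calibration metadata."""

    frame: pd.DataFrame        # columns: time_s, x_px, y_px, valid
    pixel_size: Optional[float]   # µm/px; None = uncalibrated (speeds in px/s)
    frame_interval: float      # s

    def __post_init__(self):
        t = self.frame["time_s"].to_numpy()
        if len(t) >= 2 and not np.all(np.diff(t) > 0):
            raise ValidationError("time_s: times must be strictly increasing")


def track_centroids(stack: np.ndarray, frame_interval: float,
                    pixel_size: Optional[float] = None,
                    config: PostureConfig = PostureConfig()) -> Track:
    """Centroid of the segmented worm in every frame.

    Invalid frames (no acceptable component) are flagged, not interpolated.
    Raises :class:`ValidationError` with fewer than 2 valid frames.
    """
    if len(stack) < 2:
        raise ValidationError("stack: need at least 2 frames to track")
    rows = []
    for k, frame in enumerate(stack):
        t = k * frame_interval
        try:
            m = segment_worm(frame, config)
            cy, cx = ndimage.center_of_mass(m.mask)
            rows.append({"time_s": t, "x_px": cx, "y_px": cy, "valid": True})
        except SegmentationError:
            rows.append({"time_s": t, "x_px": np.nan, "y_px": np.nan,
                         "valid": False})
    df = pd.DataFrame(rows)
    if int(df["valid"].sum()) < 2:
        raise ValidationError("stack: fewer than 2 valid frames")
    return Track(frame=df, pixel_size=pixel_size, frame_interval=frame_interval)


def average_speed(track: Track) -> float:
    """Average speed in µm/s (px/s when the track is uncalibrated).

    Path length over adjacent valid-frame pairs divided by their summed
    elapsed time; gaps around invalid frames contribute to neither.
    """
    df = track.frame
    valid = df["valid"].to_numpy()
    if valid.sum() < 2:
        raise ValidationError("track: need at least 2 valid frames")
    xy = df[["x_px", "y_px"]].to_numpy()
    t = df["time_s"].to_numpy()
    pair = valid[:-1] & valid[1:]
    if not pair.any():
        raise ValidationError("track: no adjacent valid-frame pairs")
    steps = np.linalg.norm(np.diff(xy, axis=0), axis=1)[pair]
    dts = np.diff(t)[pair]
    speed_px = float(steps.sum() / dts.sum())
    return speed_px * track.pixel_size if track.pixel_size else speed_px
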