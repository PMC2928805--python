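"""Synthetic punctate-fluorescence images (Gaussian spots on noisy background)."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .specs import PunctaSpec
from .truth import GroundTruth


@dataclass
class SyntheticPunctaImage:
    image: np.ndarray          # (H, W) float
    truth: GroundTruth
    path: np.ndarray           # (2, 2) linescan polyline through the centers


def render_puncta(spec: PunctaSpec) -> SyntheticPunctaImage:
    """Render ``n_puncta`` Gaussian spots of known net height on a background.

    The spots sit on the middle image row, ``spacing`` px apart.  The ground
    truth records each center and net height; a ready-made linescan path along
    the spot row is returned for convenience.
    """
    rng = np.random.default_rng(spec.seed)
    margin = max(16.0, 4.0 * spec.psf_sigma + 8.0)
    n = spec.n_puncta
    W = int(np.ceil(2 * margin + max(n - 1, 0) * spec.spacing))
    H = spec.image_height
    yc = H / 2.0
    centers_x = margin + spec.spacing * np.arange(n)
    heights = np.asarray(spec.heights(), dtype=float)

    yy = np.arange(H)[:, None]
    xx = np.arange(W)[None, :]
    img = np.full((H, W), spec.background_level, dtype=float)
    for xc, h in zip(centers_x, heights):
        img += h * np.exp(-((xx - xc) ** 2 + (yy - yc) ** 2)
                          / (2.0 * spec.psf_sigma ** 2))
    if spec.noise_sd > 0:
        img = img + rng.normal(0.0, spec.noise_sd, img.shape)

    truth = GroundTruth("puncta", {
        "centers_px": np.stack([centers_x, np.full(n, yc)], axis=1) if n else
                      np.zeros((0, 2)),
        "net_heights": heights,
        "background_level": spec.background_level,
        "psf_sigma_px": spec.psf_sigma,
        "noise_sd": spec.noise_sd,
    })
    path = np.array([[0.0, yc], [W - 1.0, yc]])
    return SyntheticPunctaImage(img, truth, path)
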