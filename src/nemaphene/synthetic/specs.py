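"""Parameter specifications for the synthetic generators.

Each spec is an immutable dataclass validated on construction; invalid values
raise :class:`~nemaphene.errors.ValidationError` naming the offending field.
Defaults follow the assay conditions the pipeline is built for: single adult
hermaphrodites (~1 mm) crawling on agar filmed at 500 ms intervals for 2 min,
confocal puncta images, and whole-cell voltage-clamp traces digitized at
2.9 kHz with a -60 mV holding potential.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np

from ..errors import ValidationError


def _require(cond: bool, name: str, msg: str) -> None:
    if not cond:
        raise ValidationError(f"{name}: {msg}")


@dataclass(frozen=True)
class WormSpec:
    """Geometry, motion and imaging parameters of one synthetic crawling worm.

    The worm is a tapered tube around a centerline built from cumulative
    turning angles over equal arc-length steps.  ``head_bend_angle`` is the
    ground-truth *first supplementary angle* of the 13 equidistant midline
    points (degrees); the generator injects it as extra turning over the first
    2/12 of arc length so the 13-point statistic equals it by construction.
    """

    body_length: float = 1000.0        # µm, nose to tail along the midline
    max_half_width: float = 35.0       # µm, mid-body half-width
    width_profile: Optional[Sequence[Tuple[float, float]]] = None
    # optional (u, half_width_um) control points, u in [0, 1]; tapered default
    undulation_amplitude: float = 30.0  # deg, tangent-angle oscillation
    undulation_wavelength: float = 0.65  # fraction of body length
    undulation_frequency: float = 0.3    # Hz, wave propagation
    head_bend_angle: float = 0.0        # deg, ground-truth first angle
    head_bend_frequency: float = 0.0    # Hz; 0 = static bend
    head_bend_phase: float = 90.0       # deg; 90 -> bend at peak at t=0
    speed: float = 100.0                # µm/s translation along heading
    heading: float = 0.0                # deg, world frame
    pixel_size: float = 5.0             # µm/px
    frame_interval: float = 0.5         # s (assay standard)
    n_frames: int = 240                 # 2 min at 500 ms
    noise_sd: float = 8.0               # intensity units
    background_intensity: float = 100.0
    foreground_intensity: float = 500.0
    canvas_shape: Optional[Tuple[int, int]] = None  # (H, W) px; None = auto
    seed: int = 0

    def __post_init__(self):
        _require(self.body_length > 0, "body_length", "must be > 0")
        _require(0 <= self.undulation_amplitude < 90,
                 "undulation_amplitude", "must be in [0, 90) degrees")
        _require(self.undulation_wavelength > 0,
                 "undulation_wavelength", "must be > 0")
        _require(self.n_frames >= 1, "n_frames", "must be >= 1")
        _require(self.frame_interval > 0, "frame_interval", "must be > 0")
        _require(self.pixel_size > 0, "pixel_size", "must be > 0")
        _require(self.max_half_width > 0, "max_half_width", "must be > 0")
        _require(0 <= abs(self.head_bend_angle) <= 150,
                 "head_bend_angle", "magnitude must be <= 150 degrees")
        _require(self.noise_sd >= 0, "noise_sd", "must be >= 0")
        _require(self.foreground_intensity > self.background_intensity,
                 "foreground_intensity", "must exceed background_intensity")

    # -- derived helpers -------------------------------------------------

    def head_bend_deg(self, t: float) -> float:
        """Instantaneous head-bend angle (signed, degrees) at time ``t``."""
        if self.head_bend_frequency == 0:
            return float(self.head_bend_angle)
        ph = np.deg2rad(self.head_bend_phase)
        return float(self.head_bend_angle
                     * np.sin(2 * np.pi * self.head_bend_frequency * t + ph))

    def half_width_um(self, u) -> np.ndarray:
        """Half-width (µm) at normalized arc position ``u`` in [0, 1].

        Tapers to zero at both the nose and the tail tip.
        """
        u = np.asarray(u, dtype=float)
        if self.width_profile is not None:
            ctrl = np.asarray(self.width_profile, dtype=float)
            return np.interp(u, ctrl[:, 0], ctrl[:, 1])
        return self.max_half_width * np.sin(np.pi * np.clip(u, 0, 1)) ** 0.5

    def body_area_um2(self) -> float:
        """Analytic plan area of the worm, ∫ 2·half_width(s) ds."""
        u = np.linspace(0.0, 1.0, 100_001)
        return float(np.trapezoid(2.0 * self.half_width_um(u), u) * self.body_length)


@dataclass(frozen=True)
class PunctaSpec:
    """Punctate fluorescence substrate: Gaussian spots on a noisy background."""

    n_puncta: int = 5
    spacing: float = 40.0              # px between neighbouring centers
    peak_heights: Optional[Sequence[float]] = None  # default 150 each
    psf_sigma: float = 2.0             # px
    background_level: float = 100.0
    noise_sd: float = 5.0
    image_height: int = 64             # px; puncta lie on the middle row
    seed: int = 0

    def __post_init__(self):
        _require(self.n_puncta >= 0, "n_puncta", "must be >= 0")
        _require(self.psf_sigma > 0, "psf_sigma", "must be > 0")
        if self.n_puncta > 1:
            _require(self.spacing > 4 * self.psf_sigma, "spacing",
                     "must exceed 4*psf_sigma so puncta are resolvable")
        h = self.heights()
        _require(len(h) == self.n_puncta, "peak_heights",
                 "length must equal n_puncta")
        _require(all(x > 0 for x in h), "peak_heights", "must all be > 0")
        _require(self.noise_sd >= 0, "noise_sd", "must be >= 0")

    def heights(self) -> list:
        if self.peak_heights is None:
            return [150.0] * self.n_puncta
        return [float(x) for x in self.peak_heights]


@dataclass(frozen=True)
class TraceSpec:
    """Evoked postsynaptic current: difference-of-exponentials kinetics.

    ``tau_rise = 0`` selects a pure monoexponential decay.  The kinetic kernel
    is rescaled so the analytic peak deviation equals ``amplitude`` exactly.
    Inward currents deflect negative from baseline (voltage clamp at -60 mV).
    """

    amplitude: float = 2.0       # nA, peak deviation magnitude
    tau_rise: float = 1.0        # ms
    tau_decay: float = 5.0       # ms
    onset: float = 20.0          # ms, stimulus onset
    duration: float = 150.0      # ms
    sampling_rate: float = 2.9   # kHz (assay standard)
    baseline_current: float = -0.2  # nA holding current
    noise_sd: float = 0.02       # nA
    polarity: str = "inward"     # {"inward", "outward"}
    seed: int = 0

    def __post_init__(self):
        _require(self.tau_rise >= 0, "tau_rise", "must be >= 0")
        _require(self.tau_decay > self.tau_rise, "tau_decay",
                 "must exceed tau_rise")
        _require(self.sampling_rate > 0, "sampling_rate", "must be > 0")
        _require(self.amplitude > 0, "amplitude", "must be > 0")
        _require(self.polarity in ("inward", "outward"), "polarity",
                 "must be 'inward' or 'outward'")
        _require(self.onset >= 0, "onset", "must be >= 0")
        _require(self.duration > self.onset, "duration",
                 "must exceed onset")
        _require(self.noise_sd >= 0, "noise_sd", "must be >= 0")
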