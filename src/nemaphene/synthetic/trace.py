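"""Synthetic evoked postsynaptic current traces.

Kinetics are a difference of exponentials
``k(t) = exp(-t/tau_decay) - exp(-t/tau_rise)`` (or a pure monoexponential
decay when ``tau_rise = 0``), rescaled so the analytic peak deviation equals
``amplitude`` exactly.  With that convention the analytic charge transfer is
``amplitude * (tau_decay - tau_rise) / k(t_peak)`` in nA·ms = pC, which for a
monoexponential reduces to ``amplitude * tau_decay``.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import brentq

from .specs import TraceSpec
from .truth import GroundTruth
from ..ephys import CurrentTrace


def kernel_peak_time(tau_rise: float, tau_decay: float) -> float:
    """Time-to-peak of the difference-of-exponentials kernel (ms)."""
    if tau_rise == 0:
        return 0.0
    return float(np.log(tau_decay / tau_rise)
                 * tau_decay * tau_rise / (tau_decay - tau_rise))


def _unit_kernel(t: np.ndarray, tau_rise: float, tau_decay: float) -> np.ndarray:
    t = np.asarray(t, dtype=float)
    if tau_rise == 0:
        return np.where(t >= 0, np.exp(-np.maximum(t, 0) / tau_decay), 0.0)
    k = np.exp(-np.maximum(t, 0) / tau_decay) - np.exp(-np.maximum(t, 0) / tau_rise)
    return np.where(t >= 0, k, 0.0)


def analytic_half_decay(tau_rise: float, tau_decay: float) -> float:
    """Time (ms) from the kernel peak to 50% of peak; tau_decay*ln2 if tau_rise=0."""
    if tau_rise == 0:
        return float(tau_decay * np.log(2.0))
    tp = kernel_peak_time(tau_rise, tau_decay)
    peak = _unit_kernel(np.array([tp]), tau_rise, tau_decay)[0]

    def f(t):
        return _unit_kernel(np.array([t]), tau_rise, tau_decay)[0] - 0.5 * peak

    t_half = brentq(f, tp, tp + 50.0 * tau_decay)
    return float(t_half - tp)


def analytic_decay_to(frac: float, tau_rise: float, tau_decay: float) -> float:
    """Time (ms) from kernel onset until the kernel falls to ``frac`` of peak."""
    tp = kernel_peak_time(tau_rise, tau_decay)
    peak = _unit_kernel(np.array([tp]), tau_rise, tau_decay)[0]

    def f(t):
        return _unit_kernel(np.array([t]), tau_rise, tau_decay)[0] - frac * peak

    return float(brentq(f, tp, tp + 100.0 * tau_decay))


def make_trace(spec: TraceSpec):
    """Generate a trace and its analytic ground truth.

    Returns ``(CurrentTrace, GroundTruth)``.  A warning is recorded in the
    ground truth when the duration is too short for the response to decay to
    5% of peak.
    """
    rng = np.random.default_rng(spec.seed)
    dt = 1.0 / spec.sampling_rate  # ms
    t = np.arange(0.0, spec.duration, dt)

    tp = kernel_peak_time(spec.tau_rise, spec.tau_decay)
    peak = _unit_kernel(np.array([max(tp, 0.0)]), spec.tau_rise, spec.tau_decay)[0] \
        if spec.tau_rise > 0 else 1.0
    sgn = -1.0 if spec.polarity == "inward" else 1.0
    k = _unit_kernel(t - spec.onset, spec.tau_rise, spec.tau_decay)
    current = spec.baseline_current + sgn * spec.amplitude * k / peak
    if spec.noise_sd > 0:
        current = current + rng.normal(0.0, spec.noise_sd, current.shape)

    charge = spec.amplitude * (spec.tau_decay - spec.tau_rise) / peak \
        if spec.tau_rise > 0 else spec.amplitude * spec.tau_decay

    warnings = []
    t95 = analytic_decay_to(0.05, spec.tau_rise, spec.tau_decay)
    if spec.onset + t95 > spec.duration:
        warnings.append("duration too short for the response to decay to 5% of peak")

    truth = GroundTruth("trace", {
        "amplitude_nA": spec.amplitude,
        "peak_time_ms": spec.onset + tp,
        "half_decay_ms": analytic_half_decay(spec.tau_rise, spec.tau_decay),
        "charge_pC": charge,
        "baseline_nA": spec.baseline_current,
        "polarity": spec.polarity,
        "sampling_rate_khz": spec.sampling_rate,
        "stimulus_onset_ms": spec.onset,
    }, warnings=warnings)

    trace = CurrentTrace(time_ms=t, current_na=current,
                         sampling_rate_khz=spec.sampling_rate,
                         stimulus_onset_ms=spec.onset)
    return trace, truth
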