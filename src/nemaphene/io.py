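"""File I/O: multi-page TIFF stacks with JSON sidecars, trace CSVs, tables.

Conventions:
  * image stacks: 16-bit unsigned multi-page TIFF, with ``<stem>.json``
    carrying ``pixel_size_um`` and ``frame_interval_s`` (plus any acquisition
    metadata);
  * ground truth: ``<stem>.truth.json``;
  * current traces: CSV with header ``time_ms,current_nA`` and a JSON sidecar
    with ``stimulus_onset_ms``, ``sampling_rate_khz``, ``holding_mv``.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Tuple

import numpy as np
import pandas as pd
import tifffile

from .ephys import CurrentTrace
from .synthetic.truth import GroundTruth


def save_stack(stem, frames: np.ndarray, pixel_size_um: float,
               frame_interval_s: float, truth: Optional[GroundTruth] = None,
               **metadata) -> Path:
    stem = Path(stem)
    stem.parent.mkdir(parents=True, exist_ok=True)
    tif = stem.with_suffix(".tif")
    tifffile.imwrite(tif, np.asarray(frames, dtype=np.uint16),
                     photometric="minisblack")
    meta = {"pixel_size_um": pixel_size_um,
            "frame_interval_s": frame_interval_s, **metadata}
    stem.with_suffix(".json").write_text(json.dumps(meta, indent=1))
    if truth is not None:
        truth.save(stem.with_suffix(".truth.json"))
    return tif


def load_stack(path) -> Tuple[np.ndarray, dict]:
    """Read a TIFF stack and its JSON sidecar (empty dict when absent)."""
    path = Path(path)
    frames = tifffile.imread(path)
    if frames.ndim == 2:
        frames = frames[None]
    sidecar = path.with_suffix(".json")
    meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    return frames, meta


def save_trace(stem, trace: CurrentTrace,
               truth: Optional[GroundTruth] = None) -> Path:
    stem = Path(stem)
    stem.parent.mkdir(parents=True, exist_ok=True)
    csv = stem.with_suffix(".csv")
    pd.DataFrame({"time_ms": trace.time_ms,
                  "current_nA": trace.current_na}).to_csv(csv, index=False)
    meta = {"stimulus_onset_ms": trace.stimulus_onset_ms,
            "sampling_rate_khz": trace.sampling_rate_khz,
            "holding_mv": trace.holding_mv}
    stem.with_suffix(".meta.json").write_text(json.dumps(meta, indent=1))
    if truth is not None:
        truth.save(stem.with_suffix(".truth.json"))
    return csv


def load_trace(csv_path, meta_path=None) -> CurrentTrace:
    csv_path = Path(csv_path)
    df = pd.read_csv(csv_path)
    if not {"time_ms", "current_nA"} <= set(df.columns):
        raise ValueError("trace CSV must have columns time_ms,current_nA")
    if meta_path is None:
        cand = csv_path.with_suffix(".meta.json")
        meta = json.loads(cand.read_text()) if cand.exists() else {}
    else:
        meta = json.loads(Path(meta_path).read_text())
    return CurrentTrace(
        time_ms=df["time_ms"].to_numpy(float),
        current_na=df["current_nA"].to_numpy(float),
        sampling_rate_khz=meta.get("sampling_rate_khz", 2.9),
        stimulus_onset_ms=meta.get("stimulus_onset_ms", 0.0),
        holding_mv=meta.get("holding_mv", -60.0),
    )


def load_path_csv(path) -> np.ndarray:
    """Polyline vertices from a CSV with columns ``x_px,y_px``."""
    df = pd.read_csv(path)
    return df[["x_px", "y_px"]].to_numpy(float)
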