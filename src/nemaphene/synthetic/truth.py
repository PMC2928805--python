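"""Analytic ground-truth sidecars for synthetic datasets.

Every generated dataset carries exactly one :class:`GroundTruth` holding the
values implied by the generating specification (angles, speeds, punctum
heights, trace kinetics).  These values are computed from the analytic form of
the object being rendered -- never read back from rendered pixels or samples --
so downstream recovery tests compare against an independent reference.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


@dataclass
class GroundTruth:
    """Modality-keyed record of analytic values for one synthetic dataset."""

    modality: str  # "worm" | "puncta" | "trace"
    data: dict
    warnings: list = field(default_factory=list)

    def __getitem__(self, key):
        return self.data[key]

    def save(self, path) -> None:
        payload = {
            "modality": self.modality,
            "data": _jsonable(self.data),
            "warnings": list(self.warnings),
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def load(cls, path) -> "GroundTruth":
        payload = json.loads(Path(path).read_text())
        return cls(payload["modality"], payload["data"], payload.get("warnings", []))
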