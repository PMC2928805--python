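"""Exception types shared across the pipeline."""


class ValidationError(ValueError):
    """A specification or argument violates a documented invariant.

    The message always names the offending field.
    """


class SegmentationError(RuntimeError):
    """No acceptable worm object could be segmented in a frame."""


class CoiledWormError(RuntimeError):
    """Skeleton has no endpoint-to-endpoint path (self-touching / coiled posture)."""


class FieldOfViewError(RuntimeError):
    """The rendered worm leaves the requested canvas; a larger canvas is needed."""


class TruncatedDecayError(RuntimeError):
    """The trace ends before the response decays through the requested level."""


class AnalysisWindowError(RuntimeError):
    """No valid frames inside the requested analysis window."""
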