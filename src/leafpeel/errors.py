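"""Exception types shared across the pipeline."""


class StackReadError(IOError):
    """A stack file could not be read or its axes could not be resolved."""


class DetectionError(RuntimeError):
    """Surface detection failed (no contrast, or no surface crossing found)."""


class EmptyLayerError(ValueError):
    """A layer mask selected zero voxels where a non-empty layer is required."""
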