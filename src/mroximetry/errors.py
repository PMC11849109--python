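"""Exception types shared across the pipeline stages."""


class EmptyRegionError(ValueError):
    """A region of interest contains no usable voxels."""


class InsufficientBreathsError(ValueError):
    """Too few respiratory cycles to estimate an end-tidal value."""
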