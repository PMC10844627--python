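"""Exception types shared across the package."""


class DentspikeError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(DentspikeError, ValueError):
    """Invalid or inconsistent configuration values."""


class FormatError(DentspikeError, ValueError):
    """Malformed on-disk artifact (binary recording, sidecar, event CSV)."""


class DegenerateInputError(DentspikeError, ValueError):
    """Input is structurally valid but degenerate for the requested operation
    (e.g. z-scoring a constant waveform)."""
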