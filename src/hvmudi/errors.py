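"""Exception hierarchy for the hvmudi pipeline."""


class HvmudiError(Exception):
    """Base class for all pipeline errors."""


class ConfigError(HvmudiError):
    """Invalid acquisition or algorithm configuration."""


class DataError(HvmudiError):
    """Input data violates a contract (non-finite values, bad extents)."""


class FormatError(HvmudiError):
    """On-disk container is malformed or missing metadata."""


class SceneError(HvmudiError):
    """Phantom scene is degenerate (e.g. zero tube diameter)."""


class ThresholdError(HvmudiError):
    """Singular-value threshold range is empty or inverted."""
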