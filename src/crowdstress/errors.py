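"""Exception hierarchy shared across the pipeline."""


class CrowdStressError(Exception):
    """Base class for all pipeline errors."""


class ConfigError(CrowdStressError):
    """Invalid configuration; message names the offending field."""


class FormatError(CrowdStressError):
    """Malformed input file; message carries file/line context."""


class FusionError(CrowdStressError):
    """Streams cannot be joined (no overlap, implausible clock offset...)."""


class ModelError(CrowdStressError):
    """Model cannot be fitted (insufficient data, rank deficiency, non-convergence)."""
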