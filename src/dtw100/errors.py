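"""Exception hierarchy shared across the package."""


class Dtw100Error(Exception):
    """Base class for all package-specific errors."""


class ValidationError(Dtw100Error, ValueError):
    """Invalid parameter, configuration value, or domain-type invariant breach."""


class DataFormatError(ValidationError):
    """Malformed on-disk data (ragged columns, non-numeric cells, bad manifest)."""


class PipelineError(Dtw100Error, RuntimeError):
    """A pipeline stage failed; message carries the stage and sample id."""
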