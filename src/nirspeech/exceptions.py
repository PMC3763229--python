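"""Exception hierarchy.

Every error raised by the package derives from :class:`NirspeechError`, split by
the stage that detects it: configuration, input data, physical model, metric
computation, statistics, and file parsing.
"""


class NirspeechError(Exception):
    """Base class for all package errors."""


class ConfigurationError(NirspeechError):
    """Inconsistent or invalid configuration / design parameters."""


class DataError(NirspeechError):
    """Input data violates a precondition (shape, sign, coverage)."""


class ModelError(NirspeechError):
    """Physical model cannot be applied (e.g. ill-conditioned extinction matrix)."""


class MetricError(NirspeechError):
    """A hemodynamic metric is undefined for the given input."""


class AnalysisError(NirspeechError):
    """Statistical analysis cannot be carried out (unbalanced table, degenerate data)."""


class FileFormatError(NirspeechError):
    """A file does not conform to the package's text formats."""
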