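"""Exception hierarchy shared across the package."""


class GlucodynError(Exception):
    """Base class for all package errors."""


class ParameterError(GlucodynError, ValueError):
    """An argument violates a documented precondition."""


class FormatError(GlucodynError, ValueError):
    """An input file does not conform to the documented CSV dialect."""


class QCError(GlucodynError, ValueError):
    """A series fails a quality-control rule (validity screen, gap policy)."""


class ComputationError(GlucodynError, ValueError):
    """A metric is undefined for the supplied data (e.g. non-positive mean)."""


class ConfigError(GlucodynError, ValueError):
    """A pipeline run configuration is invalid."""
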