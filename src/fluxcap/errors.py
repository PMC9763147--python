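"""Typed exceptions raised by the flux-analysis pipeline.

Every validation failure raises one of these, never a bare ``ValueError``,
so callers (and the CLI) can distinguish malformed files from inconsistent
designs and from quantities that are mathematically undefined.
"""


class FluxcapError(Exception):
    """Base class for all package errors."""


class FormatError(FluxcapError):
    """A file does not conform to the documented CSV dialect."""


class ConsistencyError(FluxcapError):
    """Two inputs disagree (e.g. wells present in traces but not layout)."""


class ValidationError(FluxcapError):
    """A value violates a domain invariant (e.g. non-positive sperm count)."""


class ConfigurationError(FluxcapError):
    """A run is not analysable as configured (e.g. no background wells)."""


class UndefinedPanelError(FluxcapError):
    """A panel quantity is undefined for this well (e.g. basal rate <= 0)."""


class UsageError(FluxcapError):
    """An operation was invoked with incompatible arguments."""
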