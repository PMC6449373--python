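"""Exception hierarchy.

Configuration problems (bad simulation or trajectory parameters) raise
:class:`ConfigurationError`; malformed or inconsistent *data* passed to an
analysis operation raises :class:`InputError`.  Both derive from
:class:`AdrnMesError` so callers can catch everything from this package with
one clause.
"""


class AdrnMesError(ValueError):
    """Base class for all errors raised by this package."""


class ConfigurationError(AdrnMesError):
    """A simulation or pipeline configuration violates its invariants."""


class InputError(AdrnMesError):
    """Input data handed to an analysis operation is malformed."""
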