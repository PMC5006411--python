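"""Exception hierarchy.

Structural problems (bad schema, invalid values, impossible configurations)
raise; numerical fitting failures never do — they surface as a
``converged=False`` fit so simulation loops can count them.
"""


class RdgeeError(Exception):
    """Base class for all package errors."""


class SchemaError(RdgeeError):
    """An input file or mapping is missing a required column."""


class DataError(RdgeeError):
    """Input values violate the data model (non-binary outcome, events > total, ...)."""


class ConfigError(RdgeeError):
    """An invalid model/scenario/analysis configuration."""


class NotConvergedError(RdgeeError):
    """A downstream computation was asked to use a non-converged fit."""
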