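"""Exception hierarchy.

All pipeline errors derive from :class:`ForestDynError` so callers can
catch the package's failures with a single except clause; the subclasses
distinguish bad measurements, malformed files, violated bookkeeping
identities, and invalid configuration.
"""


class ForestDynError(Exception):
    """Base class for all forestdyn errors."""


class InvalidMeasurementError(ForestDynError, ValueError):
    """A DBH or basal-area input is outside its physical domain."""


class FormatError(ForestDynError, ValueError):
    """An input file does not conform to the expected dialect."""


class IntegrityError(ForestDynError, ValueError):
    """Data violate a bookkeeping invariant (duplicates, impossible counts)."""


class ConfigurationError(ForestDynError, ValueError):
    """A survey/run parameter is outside its stated domain."""


class UndefinedStatisticError(ForestDynError, ValueError):
    """A statistic is requested on a degenerate input (e.g. S < 2)."""
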