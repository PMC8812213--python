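"""Exception hierarchy for tpdscan."""


class TpdError(Exception):
    """Base class for all tpdscan errors."""


class InputError(TpdError):
    """A required input file is missing or unreadable."""


class SchemaError(TpdError):
    """An input table is missing a column or contains an unparseable value."""


class ConfigurationError(TpdError):
    """A simulation or run configuration is internally inconsistent."""


class StaleCacheError(TpdError):
    """A baseline-count cache does not match the cohort, mode or windows."""


class UndefinedExpectedError(TpdError):
    """The expected count is undefined because the baseline count C is zero.

    Distinct from an expected count of zero, which is a valid value.
    """
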