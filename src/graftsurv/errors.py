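"""Exception hierarchy.

Configuration errors signal a caller mistake (bad spec/config values);
data errors signal inconsistencies inside a cohort table (e.g. a dialysis
date preceding the transplant date). The CLI maps them to distinct exit
codes.
"""


class GraftsurvError(Exception):
    """Base class for all package errors."""


class ConfigurationError(GraftsurvError, ValueError):
    """Invalid specification or configuration values."""


class DataError(GraftsurvError, ValueError):
    """Inconsistent or unusable input data."""
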