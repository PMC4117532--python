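"""Exception hierarchy for xcistr.

All user-facing failures derive from :class:`XcistrError` so the CLI can map
them onto exit codes (input problems → 2, QC failures in strict mode → 3).
"""


class XcistrError(Exception):
    """Base class for all xcistr errors."""


class InputError(XcistrError, ValueError):
    """Malformed or inconsistent user input (bad alphabet, missing column...)."""


class ConfigError(XcistrError, ValueError):
    """Invalid configuration, e.g. a malformed enzyme table."""


class EstimationError(XcistrError):
    """A quantity could not be estimated from the data provided."""


class InsufficientDataError(XcistrError):
    """Too few observations for the requested statistic."""


class MendelianInconsistencyError(XcistrError):
    """A child allele is absent from both parents."""


class QCFailure(XcistrError):
    """A quality-control check failed (e.g. incomplete digestion)."""
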