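"""Exception hierarchy shared across the pipeline."""


class OsteoMRError(Exception):
    """Base class for all pipeline errors."""


class InputError(OsteoMRError):
    """Invalid or empty data supplied to an operation."""


class ConfigurationError(OsteoMRError):
    """Missing columns, unknown SNPs, or other configuration problems."""


class ContractViolation(OsteoMRError):
    """An operation was called outside its documented precondition."""
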