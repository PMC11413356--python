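"""Exception hierarchy for the omnimr pipeline."""


class OmnimrError(Exception):
    """Base class for all omnimr-specific errors."""


class ParameterError(OmnimrError, ValueError):
    """Invalid parameter or configuration value."""


class FormatError(OmnimrError, ValueError):
    """Malformed input file (missing columns, bad sidecar, ...)."""


class EmptyInputError(OmnimrError, ValueError):
    """An input yielded zero usable records."""


class EmptyOverlapError(OmnimrError, ValueError):
    """No SNPs shared between a summary table and the reference panel."""


class InsufficientOverlapError(OmnimrError, ValueError):
    """Fewer SNPs retained after QC than the configured floor."""


class SingularityError(OmnimrError, ValueError):
    """An LD or covariance matrix could not be factorized."""


class EmptyInstrumentError(OmnimrError, ValueError):
    """Instrument selection produced no SNPs at the given threshold."""
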