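"""Exception hierarchy shared across pipeline stages."""


class SalmoArrayError(Exception):
    """Base class for all pipeline errors."""


class InvalidDesignError(SalmoArrayError):
    """Experimental design violates a structural constraint."""


class InconsistentArchitectureError(SalmoArrayError):
    """A planted transcript architecture is self-contradictory."""


class EmptyInputError(SalmoArrayError):
    """An operation received no data to work on."""


class InsufficientDataError(SalmoArrayError):
    """Too few arrays/replicates/finite values for the requested statistic."""


class DimensionError(SalmoArrayError):
    """Matrix dimensions or labels do not line up."""


class ParseError(SalmoArrayError):
    """A text input file is malformed."""


class ValidationError(SalmoArrayError):
    """A configuration parameter is outside its allowed range."""
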