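"""Exception hierarchy for the combiscreen pipeline."""


class CombiscreenError(Exception):
    """Base class for all combiscreen errors."""


class SchemaError(CombiscreenError):
    """An input table is missing a required column or has an unusable layout."""


class ValidationError(CombiscreenError):
    """A value violates a field or record invariant (negative signal, bad unit, duplicate key...)."""


class InsufficientDataError(CombiscreenError):
    """Not enough observations to run the requested analysis."""


class DegenerateFitError(CombiscreenError):
    """Dose-response data carry no information about an IC50 (e.g. constant responses)."""


class UnconvergedFitError(CombiscreenError):
    """A downstream step refused to consume a non-converged curve fit."""


class MissingArmError(CombiscreenError):
    """A four-arm combination experiment lacks one of its arms."""
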