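"""Package-wide exception types."""


class ScatdietError(Exception):
    """Base class for all scatdiet errors."""


class ValidationError(ScatdietError):
    """Invalid input data or configuration."""


class DuplicateSpeciesError(ValidationError):
    """A taxon pool or reference database contains a repeated species name."""


class TagCapacityError(ValidationError):
    """More PCR tags requested than the distance-constrained tag space allows."""


class SimulationError(ScatdietError):
    """A read-simulation precondition failed (e.g. missing primer site)."""


class ConfigurationError(ScatdietError):
    """Inconsistent run configuration (e.g. ambiguous tag scheme)."""


class TaxonLookupError(ScatdietError, KeyError):
    """A taxon name could not be resolved in the taxonomy tree."""


class EnumerationBudgetError(ScatdietError):
    """An exact test's enumeration would exceed the configured budget."""
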