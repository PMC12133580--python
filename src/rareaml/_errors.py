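"""Exception types shared across the package."""


class RareAMLError(Exception):
    """Base class for package errors."""


class InsufficientDataError(RareAMLError, ValueError):
    """A statistic was requested on fewer observations than it needs."""


class DimensionError(RareAMLError, ValueError):
    """Mismatched vector/matrix dimensions."""


class CohortError(RareAMLError, ValueError):
    """A required sample group is missing or too small."""


class SimConfigError(RareAMLError, ValueError):
    """A simulation configuration violates one of its invariants."""


class ChromosomeNamingError(RareAMLError, ValueError):
    """Peak and promoter files use incompatible chromosome naming schemes."""


class NamespaceError(RareAMLError, ValueError):
    """Gene identifier namespaces disagree between inputs."""
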