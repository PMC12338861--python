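"""Exception hierarchy shared across the package."""


class AnisopyError(Exception):
    """Base class for all package-specific errors."""


class InvalidReadingError(AnisopyError):
    """A polarized intensity reading violates its preconditions."""

    def __init__(self, message: str, channel: str | None = None):
        super().__init__(message)
        self.channel = channel


class PhotophysicsLookupError(AnisopyError, KeyError):
    """Requested (probe, wavelength) pair is absent from the table."""


class ValidationError(AnisopyError, ValueError):
    """A table or configuration failed validation."""


class DomainError(AnisopyError, ValueError):
    """A numeric argument lies outside the mathematically valid domain."""


class SingularityError(DomainError):
    """An expression hits a pole (zero denominator) for these arguments."""


class RankDeficiencyError(AnisopyError, ValueError):
    """Regression design has no spread in the regressor."""


class InsufficientDataError(AnisopyError, ValueError):
    """Not enough usable observations to perform the requested fit."""


class ScenarioError(AnisopyError, ValueError):
    """Synthetic scenario parameters produce unphysical observables."""


class GridMismatchError(AnisopyError, ValueError):
    """Two gradient surfaces are not defined on the same grid/mode."""
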