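"""Exception hierarchy for the dosing engine."""

from __future__ import annotations


class VancalcError(Exception):
    """Base class for all domain errors raised by this package."""


class OutOfRangeError(VancalcError):
    """A patient value falls outside the range covered by a nomogram axis.

    The nomograms carry no guidance outside their printed bands, so values
    below the first band or at/above the upper edge of the last band are
    rejected rather than extrapolated.
    """

    def __init__(self, axis_name: str, value: float, lower: float, upper: float):
        self.axis_name = axis_name
        self.value = value
        self.lower = lower
        self.upper = upper
        super().__init__(
            f"{axis_name}={value:g} is outside the covered range "
            f"[{lower:g}, {upper:g}) of this nomogram"
        )


class MissingPostnatalAgeError(VancalcError):
    """An age-conditional maintenance cell was hit without a postnatal age.

    The smallest pediatric weight band chooses between q8h and q12h based on
    postnatal age; the engine refuses to guess when the age is absent.
    """

    def __init__(self) -> None:
        super().__init__(
            "postnatal age in days is required: the resolved maintenance cell "
            "uses q8h for postnatal age > 7 days and q12h for age < 7 days"
        )


class NomogramFormatError(VancalcError):
    """A nomogram document failed schema or structural validation."""
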