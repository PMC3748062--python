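"""Exception types shared across the package."""

__all__ = ["DomainError", "InfeasibleSigmaError", "FormatError"]


class DomainError(ValueError):
    """An input is outside the mathematical domain of an operation."""


class InfeasibleSigmaError(DomainError):
    """A sigma-transform would drive a cell count negative.

    Raised instead of truncating the cell to zero, because truncation would
    silently break the closed-form identities the transform is meant to obey.
    """


class FormatError(ValueError):
    """A batch input file is malformed (missing columns, non-numeric cells)."""
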