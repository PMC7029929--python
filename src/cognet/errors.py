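"""Exception hierarchy shared across the package."""


class CognetError(Exception):
    """Base class for all package-specific errors."""


class FormatError(CognetError):
    """Malformed input file (missing columns, bad cell values...)."""


class ValidationError(CognetError):
    """A wordlist or matrix violates a hard structural rule."""


class UndefinedDistanceError(CognetError):
    """A pair of taxa has no comparable characters under pairwise deletion."""

    def __init__(self, taxon_a: str, taxon_b: str):
        self.pair = (taxon_a, taxon_b)
        super().__init__(
            f"distance undefined for pair ({taxon_a!r}, {taxon_b!r}): "
            "no characters are scored in both taxa"
        )


class SizeError(CognetError):
    """Too few taxa (or characters) for the requested operation."""


class EmptySelectionError(CognetError):
    """A period filter removed every taxon."""


class SolverError(CognetError):
    """Numerical solver failed to converge."""
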