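"""Exception hierarchy shared across the package."""


class PkuNmrError(Exception):
    """Base class for all package errors."""


class InvalidParameterError(PkuNmrError, ValueError):
    """A caller-supplied parameter violates a precondition."""


class DegenerateSpectrumError(PkuNmrError, ValueError):
    """A spectrum has no usable signal (e.g. zero creatinine integral)."""


class CoverageError(PkuNmrError, ValueError):
    """A spectrum's ppm axis does not cover the requested region."""


class DegenerateDataError(PkuNmrError, ValueError):
    """A data matrix carries no variance / is singular beyond repair."""


class UndefinedRatioError(InvalidParameterError):
    """Fold change requested against a zero denominator."""


class RankDeficiencyError(PkuNmrError, ValueError):
    """Design matrix is rank deficient; offending columns are reported."""

    def __init__(self, columns):
        self.columns = list(columns)
        super().__init__(f"collinear predictor columns: {', '.join(self.columns)}")


class FormatError(PkuNmrError, ValueError):
    """A file does not conform to the expected dialect/schema."""
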