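"""Exception types shared across the package."""


class PrstrataError(Exception):
    """Base class for package errors."""


class ValidationError(PrstrataError, ValueError):
    """Invalid user input (configuration, parameter ranges, malformed tables)."""


class CollinearityError(PrstrataError, ValueError):
    """Rank-deficient regression design; carries the offending column names."""

    def __init__(self, columns):
        self.columns = list(columns)
        super().__init__(
            "design matrix is rank deficient; collinear columns: "
            + ", ".join(map(str, self.columns))
        )


class DegenerateDataError(PrstrataError, ValueError):
    """Data degenerate for the requested operation (zero variance, single sex, ...)."""
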