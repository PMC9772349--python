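"""Exception types raised by pipeline stages."""


class SncausalError(Exception):
    """Base class for all package errors."""


class InvalidDesignError(SncausalError, ValueError):
    """A synthetic design violates its invariants."""


class InvalidArmError(SncausalError, ValueError):
    """An unknown genotype/treatment/cell-type arm label was requested."""


class MissingArmError(SncausalError, ValueError):
    """A required experimental arm has no cells."""


class ConfigurationError(SncausalError, ValueError):
    """Required configuration (e.g. a metadata column) is missing or invalid."""


class DegenerateCellError(SncausalError, ValueError):
    """A cell with zero library size reached normalization."""


class FormatError(SncausalError, ValueError):
    """An on-disk file does not match the expected format."""


class CollinearityError(SncausalError, ValueError):
    """A regression design matrix is rank-deficient."""

    def __init__(self, aliased_columns):
        self.aliased_columns = list(aliased_columns)
        super().__init__(
            f"design matrix is rank-deficient; aliased columns: {self.aliased_columns}"
        )


class PipelineError(SncausalError, RuntimeError):
    """A pipeline stage failed; the message names the stage."""
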