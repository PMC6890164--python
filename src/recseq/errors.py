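"""Exception hierarchy shared across the package."""


class RecseqError(Exception):
    """Base class for all package-specific errors."""


class ConstraintError(RecseqError):
    """A genome specification cannot be satisfied (e.g. motif longer than unit)."""


class InputError(RecseqError):
    """Invalid user input (bad alphabet, empty region, zero bin size...)."""


class ParseError(RecseqError):
    """Malformed FASTQ/SAM/BED/config input; carries file context where known."""


class DesignInfeasibleError(RecseqError):
    """No enzyme triple satisfies the panel constraints.

    ``best_partial`` holds the triple satisfying the most constraints, to help
    the user relax the design.
    """

    def __init__(self, message, best_partial=None):
        super().__init__(message)
        self.best_partial = best_partial


class NormalizationError(RecseqError):
    """A library cannot be normalized (zero totals, missing anchor counts)."""


class AnchorMissingError(NormalizationError):
    """The 2-micron anchor has zero reads; cross-sample scaling is undefined."""


class ConfigError(RecseqError):
    """Unknown or invalid key in a run configuration."""


class EstimationError(RecseqError):
    """Dispersion estimation failed (no bin with sufficient counts)."""
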