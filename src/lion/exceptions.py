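"""Exception taxonomy used across the package."""


class LionError(Exception):
    """Base class for all package-specific errors."""


class InputError(LionError):
    """A required input file is missing or unreadable."""


class ParseError(LionError):
    """A line of an input file violates the expected format."""


class LookupError_(LionError):
    """A requested identifier does not exist in the network."""


class ExtractionError(LionError):
    """A disease subnetwork could not be constructed (e.g. no seeds in the PPI)."""


class NormalizationError(LionError):
    """The walk matrix cannot be column-normalized (degree-0 node)."""


class ConvergenceError(LionError):
    """The diffusion iteration hit max_iter before reaching tolerance."""


class EvaluationError(LionError):
    """ROC/AUC is undefined for the requested label set."""


class ConfigError(LionError):
    """A synthetic-benchmark configuration is invalid or unsatisfiable."""
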