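"""Exception hierarchy shared across the package."""


class GenophenoError(Exception):
    """Base class for all package errors."""


class OboParseError(GenophenoError):
    """Malformed OBO input (e.g. a [Term] stanza without an id)."""


class CycleError(GenophenoError):
    """The is_a graph contains a cycle."""

    def __init__(self, cycle):
        self.cycle = list(cycle)
        super().__init__("is_a graph contains a cycle: " + " -> ".join(self.cycle))


class UnknownTermError(GenophenoError, KeyError):
    """A term id could not be resolved in the loaded ontology."""


class FormatError(GenophenoError):
    """Structurally invalid input file (VCF/TSV)."""


class SchemaError(GenophenoError):
    """A tabular input is missing required columns."""


class RowValidationError(GenophenoError):
    """A row of a tabular input violates a value invariant."""

    def __init__(self, message, line=None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class ConfigError(GenophenoError):
    """Invalid configuration value."""


class ParameterError(GenophenoError):
    """Invalid simulation parameters."""


class UndefinedFrequencyError(GenophenoError):
    """Genotype frequency requested for a variant with AN == 0."""


class UndefinedScoreError(GenophenoError):
    """A score was requested on a degenerate (empty) heatmap."""


class UnknownGeneError(GenophenoError, KeyError):
    """Gene symbol absent from the cohort gene index."""
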