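"""Exception hierarchy.

Data errors (bad input files, infeasible configs) are kept distinct from
usage errors so the CLI can map them to different exit codes.
"""


class PhenodrugError(Exception):
    """Base class for all package errors."""


class ParseError(PhenodrugError):
    """Malformed input file; carries the offending line number when known."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class ValidationError(PhenodrugError):
    """Structurally valid input that violates a semantic contract."""


class FormatError(PhenodrugError):
    """Tabular input missing required columns or containing illegal values."""


class LookupError_(PhenodrugError):
    """Reference to an unknown ontology term, gene, or drug."""


class ConfigError(PhenodrugError):
    """Infeasible synthetic-data or run configuration."""


class UndefinedMetricError(PhenodrugError):
    """An evaluation metric has no defined value (e.g. empty overlap).

    Distinct from a zero score: callers may render it as NA.
    """
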