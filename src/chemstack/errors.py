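"""Exception hierarchy shared across the package."""


class ChemstackError(Exception):
    """Base class for all package errors."""


class ConfigurationError(ChemstackError):
    """Invalid configuration: unknown family, missing column, bad cutoffs."""


class InputError(ChemstackError):
    """Malformed or empty input data."""


class DomainError(ChemstackError):
    """Value outside the mathematical domain of an operation."""


class SmilesParseError(InputError):
    """SMILES string could not be parsed.  Carries the offending string."""

    def __init__(self, smiles: str, detail: str = ""):
        self.smiles = smiles
        msg = f"unparsable SMILES: {smiles!r}"
        if detail:
            msg += f" ({detail})"
        super().__init__(msg)


class EmptyDatasetError(InputError):
    """No usable records remain after filtering."""


class StratificationError(InputError):
    """A class is too small to stratify or fold."""


class InfeasibleSubsetsError(InputError):
    """Requested more balanced subsets than majority members."""


class InvariantViolationError(ChemstackError):
    """A structural invariant (disjointness, alignment, widths) is broken."""


class IncompleteMatrixError(ChemstackError):
    """A base model required for the probability-feature matrix is missing."""


class UndefinedMetricError(ChemstackError):
    """Metric undefined for the given inputs (e.g. single-class AUC)."""
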