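"""Exception hierarchy shared across the package."""


class NpekError(Exception):
    """Base class for all package-specific errors."""


class SmilesParseError(NpekError):
    """A SMILES string could not be parsed into a valid structure."""

    def __init__(self, smiles: str, detail: str = ""):
        self.smiles = smiles
        msg = f"unparsable SMILES: {smiles!r}"
        if detail:
            msg += f" ({detail})"
        super().__init__(msg)


class ConfigurationError(NpekError):
    """Invalid loader or run configuration (e.g. missing SMILES column)."""


class EmptySetError(NpekError):
    """An operation produced or received an empty molecule/feature set."""


class ParameterError(NpekError):
    """An operation was called with out-of-range or mismatched parameters."""


class InfeasibleCVError(NpekError):
    """Too few positives/negatives to run the requested stratified CV."""


class UndefinedMetricError(NpekError):
    """A metric is undefined for the given inputs (e.g. single-class AUC)."""


class FeatureLookupError(NpekError):
    """A fingerprint feature was not found where it was required."""


class GenerationError(NpekError):
    """A synthetic-data template could not yield valid structures."""


class PipelineIOError(NpekError):
    """Saving/loading a trained pipeline failed or versions mismatch."""
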