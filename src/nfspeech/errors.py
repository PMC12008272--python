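"""Exception hierarchy shared across the pipeline."""


class NfspeechError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(NfspeechError):
    """An input file is missing a required column/key."""


class ValidationError(NfspeechError):
    """A row or record violates a domain invariant (with location info)."""


class RegistryError(NfspeechError):
    """An unknown backend name was requested."""


class UndefinedSimilarityError(NfspeechError):
    """Cosine similarity requested for a zero vector."""


class FitError(NfspeechError):
    """A model or vectorizer cannot be fitted on the given data."""


class PoolError(NfspeechError):
    """A retrieval pool is empty after patient exclusion."""


class CapabilityError(NfspeechError):
    """A backend lacks an optional capability (e.g. token probabilities)."""


class AbstainError(NfspeechError):
    """Every paraphrase of an ensemble failed to parse; no prediction emitted."""
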