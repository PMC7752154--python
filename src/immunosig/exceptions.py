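"""Exception hierarchy for the immunosig pipeline."""


class ImmunosigError(Exception):
    """Base class for all pipeline errors."""


class ConfigurationError(ImmunosigError):
    """A configuration value violates its contract; the message names the field."""


class DimensionError(ImmunosigError):
    """Inputs that must share a gene or observation universe do not."""


class GeneOverlapError(ImmunosigError):
    """Too few genes shared between a matrix and a model's gene universe."""


class DegenerateStratificationError(ImmunosigError):
    """A high/low split produced an empty group (e.g. constant scores)."""


class TrainingDivergenceError(ImmunosigError):
    """Autoencoder training produced a non-finite loss."""


class SeparationError(ImmunosigError):
    """Perfect separation detected in a logistic fit."""
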