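"""Exception hierarchy shared across the pipeline stages."""


class LiposortError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(LiposortError):
    """A configuration value violates its contract (bad fractions, weights...)."""


class PlacementError(LiposortError):
    """A field of view is too crowded to satisfy the minimum center spacing."""


class InputError(LiposortError):
    """An operation received input that violates its preconditions."""


class DegenerateInputError(InputError):
    """Input is formally valid but analysis on it is meaningless (e.g. saturated image)."""
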