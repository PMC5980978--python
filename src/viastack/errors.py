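"""Exception hierarchy for viastack."""


class ViastackError(Exception):
    """Base class for all viastack errors."""


class ConfigurationError(ViastackError):
    """A run configuration file is missing, unparseable, or lacks a required key."""


class ValidationError(ViastackError):
    """A parameter or precondition is violated (e.g. threshold_min >= threshold_max)."""


class StackReadError(ViastackError):
    """A channel z-stack on disk is incomplete or inconsistent."""


class GenerationError(ViastackError):
    """A synthetic scene could not be placed within the retry budget."""
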