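"""Exception types shared across the package."""


class ModelError(Exception):
    """Base class for model construction and simulation errors."""


class InvalidStateSpaceError(ModelError):
    """The state roster violates a structural invariant."""


class InvalidScheduleError(ModelError):
    """A hazard schedule is malformed (value outside [0,1] or row sum > 1)."""


class InvalidScenarioError(ModelError):
    """A policy scenario cannot be applied to the baseline schedule."""


class UnknownSubgroupError(ModelError):
    """A preference subgroup label is not one of the known labels."""


class ConfigError(ModelError):
    """A run configuration file is missing, malformed or contains unknown keys."""


class MissingArtifactError(ModelError):
    """A pipeline stage requires an upstream artifact that does not exist."""
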