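"""Exception hierarchy.

``ValidationError`` maps to CLI exit code 2 (bad inputs / config),
``ComputeError`` to exit code 3 (a stage failed on valid inputs).
"""


class ScovnetError(Exception):
    """Base class for all package errors."""


class ValidationError(ScovnetError, ValueError):
    """Invalid inputs, configuration, or preconditions."""


class ComputeError(ScovnetError, RuntimeError):
    """A computation could not be completed on otherwise valid inputs."""
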