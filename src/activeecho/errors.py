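"""Exception hierarchy shared across the package."""


class ActiveEchoError(Exception):
    """Base class for all package errors."""


class ConfigError(ActiveEchoError, ValueError):
    """Invalid configuration value (geometry, device limits, scenario keys)."""


class GeometryError(ActiveEchoError, ValueError):
    """A point or path lies outside the modelled acoustic region."""


class PlanError(ActiveEchoError, ValueError):
    """A firing plan is inconsistent with the probe's line schedule."""


class InsufficientDataError(ActiveEchoError, ValueError):
    """Not enough observations to run the requested estimate."""


class NoSignalError(ActiveEchoError, ValueError):
    """An operation that requires a nonzero signal received none."""


class MetricError(ActiveEchoError, ValueError):
    """An image metric is undefined for the given inputs."""
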