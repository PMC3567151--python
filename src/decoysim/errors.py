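"""Exception hierarchy shared across the package."""


class DecoysimError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(DecoysimError, ValueError):
    """A parameter set or control file is invalid or infeasible."""


class SimulationError(DecoysimError, RuntimeError):
    """A simulation run cannot proceed (e.g. no males, no mated females)."""


class InputError(DecoysimError, ValueError):
    """Malformed user-supplied data (tables, trajectories, arguments)."""
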