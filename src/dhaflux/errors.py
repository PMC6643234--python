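"""Exception hierarchy.

Input problems (bad files, bad arguments) raise :class:`InputError`;
numerical failures (integrator blow-up, infeasible LP) raise
:class:`NumericalError`. The CLI maps them to exit codes 1 and 2.
"""


class DhafluxError(Exception):
    """Base class for all package errors."""


class InputError(DhafluxError, ValueError):
    """Invalid user input: malformed file, bad parameter, unknown name."""


class ConfigurationError(InputError):
    """Invalid configuration, e.g. an exchange reaction missing from a model."""


class NumericalError(DhafluxError, RuntimeError):
    """A numerical routine failed (non-convergence, infeasibility)."""
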