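"""Exception hierarchy.

Everything raised deliberately by this package derives from :class:`TreeGRNError`
so callers (and the CLI, which maps these onto distinct exit codes) can
discriminate data problems from configuration problems from evaluation
problems.
"""


class TreeGRNError(Exception):
    """Base class for all errors raised by treegrn."""


class DataIntegrityError(TreeGRNError, ValueError):
    """Input data violate an invariant (non-finite values, duplicate genes...)."""


class ParseError(DataIntegrityError):
    """A file could not be parsed; the message names the offending line."""


class ConfigurationError(TreeGRNError, ValueError):
    """An invalid parameter combination or an empty candidate-regulator set."""


class EvaluationError(TreeGRNError, ValueError):
    """An evaluation that is undefined for the given inputs (e.g. no positives)."""


class SimulationError(TreeGRNError, RuntimeError):
    """The steady-state simulator failed to converge after its retry budget."""
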