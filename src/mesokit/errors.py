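"""Exception hierarchy.

All package-raised errors derive from :class:`MesokitError` so CLI commands can
map them to exit code 1 (data/model error) while genuine usage errors keep
click's exit code 2.
"""


class MesokitError(Exception):
    """Base class for all mesokit errors."""


class DomainError(MesokitError, ValueError):
    """An input violates a mathematical or physical precondition."""


class ParseError(MesokitError, ValueError):
    """A data file does not conform to the expected dialect."""


class ConvergenceError(MesokitError, RuntimeError):
    """A numerical solver or least-squares fit failed to converge."""


class FitError(MesokitError, ValueError):
    """A model fit is ill-posed on the given data (e.g. no signal)."""
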