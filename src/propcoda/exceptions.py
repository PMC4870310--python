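"""Exception hierarchy.

All errors raised by propcoda derive from :class:`PropcodaError` so callers
can catch the whole family.  The subclasses distinguish the failure modes
that matter operationally: bad values in the data (``DataDomainError``),
incompatible shapes (``ShapeError``), statistics that are mathematically
undefined on the given input (``UndefinedStatisticError``), bad user
parameters (``ParameterError``), and the isolated pole of the exact
reference-change relation (``PoleError``).
"""


class PropcodaError(Exception):
    """Base class for all propcoda errors."""


class DataDomainError(PropcodaError, ValueError):
    """Input values outside the mathematical domain (e.g. nonpositive
    entries where a logarithm is required)."""


class ShapeError(PropcodaError, ValueError):
    """Mismatched lengths or matrix dimensions."""


class UndefinedStatisticError(PropcodaError, ValueError):
    """The requested statistic is undefined on this input
    (e.g. zero variance in a denominator)."""


class DegenerateResidualError(UndefinedStatisticError):
    """Residual variance vanished while partialling on a covariate."""


class ParameterError(PropcodaError, ValueError):
    """A user-supplied parameter is out of range."""


class PoleError(PropcodaError, ArithmeticError):
    """Evaluation at the pole F = -2 of the exact reference-change
    relation, where the distortion formula is discontinuous."""
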