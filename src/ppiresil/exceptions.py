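"""Exception types shared across the package."""


class PPIResilError(Exception):
    """Base class for all package errors."""


class EmptyInputError(PPIResilError, ValueError):
    """An edge-list file yielded no nodes and no edges."""


class DisconnectedGraphError(PPIResilError, ValueError):
    """An operation defined only on connected graphs received a disconnected one."""


class ParameterError(PPIResilError, ValueError):
    """Infeasible or out-of-range parameters."""


class MembershipError(PPIResilError, KeyError):
    """A node identifier is not a member of the graph."""


class AlignmentError(PPIResilError, ValueError):
    """Two node tables do not cover the same node set."""


class ConvergenceError(PPIResilError, RuntimeError):
    """An iterative solver failed to reach its tolerance within the cap."""


class InsufficientDataError(PPIResilError, ValueError):
    """Too few data points for the requested fit."""
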