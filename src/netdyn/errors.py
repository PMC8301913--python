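"""Exception hierarchy for netdyn."""


class NetdynError(Exception):
    """Base class for all netdyn errors."""


class ParseError(NetdynError):
    """A structure or trajectory file could not be parsed."""


class EmptyStructureError(NetdynError):
    """A structure contains no atoms."""


class TopologyError(NetdynError):
    """Trajectory frames are inconsistent with the supplied topology."""


class SelectionError(NetdynError):
    """A selection expression is malformed or cannot be resolved."""


class EmptySelectionError(SelectionError):
    """A selection resolved to zero atoms."""


class InsufficientFramesError(NetdynError):
    """An operation needs more trajectory frames than are available."""


class DegenerateGeometryError(NetdynError):
    """Point sets are too small or collinear for superposition."""


class ParameterError(NetdynError):
    """A numerical parameter is outside its valid range."""


class LookupFailure(NetdynError):
    """A requested residue or atom does not exist in the structure."""


class NoPathError(NetdynError):
    """Source and sink are in different connected components."""


class UndefinedCorrelationError(NetdynError):
    """A residue has zero displacement variance; its correlations are undefined."""


class RadiusTableError(NetdynError):
    """No van der Waals radius is known for an element."""


class GroupingError(NetdynError):
    """Chain groups for an interface calculation are invalid."""


class UndefinedStatisticError(NetdynError):
    """A statistic is undefined for the given input (e.g. empty interface)."""


class ClashError(NetdynError):
    """An assembled model contains inter-protomer steric clashes."""


class NamingError(NetdynError):
    """Chain renaming would produce duplicate chain identifiers."""


class NotPositiveSemidefiniteError(NetdynError):
    """A covariance factor is not positive semidefinite."""

    def __init__(self, smallest_eigenvalue: float):
        self.smallest_eigenvalue = smallest_eigenvalue
        super().__init__(
            f"covariance is not positive semidefinite "
            f"(smallest eigenvalue {smallest_eigenvalue:.3e})"
        )
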