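"""Exception hierarchy for the wholeheart toolkit."""


class WholeHeartError(Exception):
    """Base class for all toolkit errors."""


class ConfigurationError(WholeHeartError):
    """Invalid or inconsistent configuration (unknown ids, bad parameters)."""


class TopologyError(WholeHeartError):
    """A topological invariant is violated (open shell, bad nesting, ...).

    Carries the full list of violations in ``violations``.
    """

    def __init__(self, message, violations=None):
        super().__init__(message)
        self.violations = list(violations or [])


class SizeError(WholeHeartError):
    """A node/size cap would be exceeded; the message suggests a remedy."""


class LesionError(WholeHeartError):
    """A lesion region does not intersect any conducting tissue."""


class FormatError(WholeHeartError):
    """A mesh or sidecar file cannot be interpreted."""


class GeometryError(WholeHeartError):
    """Geometry unsuitable for the requested operation (open/non-nested shells)."""


class ConditioningError(WholeHeartError):
    """A linear system is numerically singular or near-singular."""


class RankError(WholeHeartError):
    """Unregularized inversion requested on a rank-deficient transfer matrix."""


class InsufficiencyError(WholeHeartError):
    """Too few usable samples/nodes for a statistical estimate."""
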