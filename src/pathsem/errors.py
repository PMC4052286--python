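"""Exception types shared across the package."""


class PathsemError(Exception):
    """Base class for all pathsem errors."""


class ParseError(PathsemError, ValueError):
    """A pathway/expression/evidence file could not be parsed."""


class IdentificationError(PathsemError, ValueError):
    """A path model violates an identifiability condition."""


class ConvergenceError(PathsemError, RuntimeError):
    """The ML optimizer failed to converge.

    Carries ``best_theta`` and ``best_objective`` with the best point found,
    so callers (e.g. the stepwise refiner) can inspect or discard it.
    """

    def __init__(self, message, best_theta=None, best_objective=None):
        super().__init__(message)
        self.best_theta = best_theta
        self.best_objective = best_objective
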