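"""Exception hierarchy shared across the package.

Every error raised by the library derives from :class:`TrpcalcError`, so
callers (notably the CLI) can map failures to distinct exit codes without
string matching.
"""


class TrpcalcError(Exception):
    """Base class for all trpcalc errors."""


class ParameterError(TrpcalcError, ValueError):
    """A scenario parameter is outside its mathematical domain.

    Raised for probabilities outside their open/closed intervals, odd or
    non-positive sample sizes, odds ratios below one, empty grids, and the
    like — anything that makes the requested quantity undefined rather than
    merely unreachable.
    """


class InfeasibleError(TrpcalcError):
    """The requested target cannot be reached with the given design.

    Carries optional structured context so planners can report *why* a
    target is out of reach (e.g. the smallest number of studies that would
    make it feasible, or the best TRP achievable within the search bound).
    """

    def __init__(self, message, *, min_feasible_k=None, best_trp=None):
        super().__init__(message)
        self.min_feasible_k = min_feasible_k
        self.best_trp = best_trp
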