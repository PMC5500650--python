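"""Exception hierarchy.

Exit-code mapping used by the CLI: ConfigError -> 2, DataError -> 3,
NumericalError -> 4.
"""


class NetfalffError(Exception):
    """Base class for all package errors."""


class ConfigError(NetfalffError):
    """Invalid configuration: bad band, bad dimensions, malformed config file."""


class DataError(NetfalffError):
    """Invalid or degenerate input data."""


class DegenerateInputError(DataError):
    """Input is formally valid but carries no usable signal (all-zero,
    zero-variance, all-missing)."""


class StageError(DataError):
    """A preprocessing stage was asked to re-apply itself to data already
    carrying its stage tag."""


class NumericalError(NetfalffError):
    """Numerical failure (non-convergence, singular system)."""


class IcaConvergenceError(NumericalError):
    """Spatial ICA failed to converge; retriable with a different seed.

    Attributes
    ----------
    seed : int
        Seed the failed decomposition was started from.
    n_iter : int
        Iterations consumed before giving up.
    """

    def __init__(self, message: str, seed: int, n_iter: int):
        super().__init__(message)
        self.seed = seed
        self.n_iter = n_iter
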