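"""Exception hierarchy shared across the pipeline stages."""


class IrriheatError(Exception):
    """Base class for all package errors."""


class ConfigurationError(IrriheatError):
    """Invalid configuration (bad world config, unvalidated factor table,
    missing rate window, bad filter window, ...)."""


class InputError(IrriheatError):
    """Invalid runtime input (unknown experiment label, grid mismatch,
    missing variable, empty pool, ...)."""


class InsufficientDataError(InputError):
    """Too few observations for the requested statistic."""


class DegenerateInputError(InputError):
    """Input with no usable variation (constant column, min == max baseline)."""


class DomainError(InputError):
    """Value outside the physical domain of a formula."""


class NoHeadroomError(IrriheatError):
    """Flood irrigation cannot decrease: no drip- or sprinkler-suitable crops."""


class ConsistencyError(IrriheatError):
    """Internal invariant violated (shares off the simplex, caps broken)."""


class EmptySelectionError(InputError):
    """A mask or region selected no grid cells."""
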