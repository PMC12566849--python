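"""Exception hierarchy shared across the package."""


class NanomillError(Exception):
    """Base class for all errors raised by this package."""


class GridError(NanomillError):
    """Invalid size-grid construction or grid/data mismatch."""


class PSDError(NanomillError):
    """Invalid particle size distribution record or conversion."""


class KernelOverflowError(NanomillError):
    """A kernel power term left the representable floating-point range."""


class SolverError(NanomillError):
    """Population balance integration failed or violated conservation."""


class FitError(NanomillError):
    """Parameter estimation could not produce a usable result."""


class IOFormatError(NanomillError):
    """A file did not match the expected CSV/YAML/JSON dialect."""
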