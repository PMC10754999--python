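"""Exception hierarchy.

The CLI maps these onto exit codes: ConfigError -> 2, DataError -> 3,
NumericError -> 4.  Everything raised by the library derives from
FtirnetError so callers can catch one base class.
"""


class FtirnetError(Exception):
    """Base class for all errors raised by ftirnet."""


class ConfigError(FtirnetError):
    """Invalid configuration (bad preset name, band outside grid, ...)."""


class DataError(FtirnetError):
    """Malformed or inconsistent input data."""


class AxisMismatchError(DataError):
    """Spectra in one file/dataset do not share a wavenumber axis."""


class SpectrumParseError(DataError):
    """A spectrum row/record could not be parsed."""


class LabelConflictError(DataError):
    """Replicates of one sample carry different class labels."""


class NumericError(FtirnetError):
    """Numerical failure (divergent training, undefined metric, ...)."""
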