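"""Exception types shared across the pipeline.

The CLI maps these onto exit codes: configuration problems exit with 2,
data problems with 3.
"""


class NeurosccaError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(NeurosccaError):
    """Invalid configuration: bad parameter values, missing keys, infeasible grids."""


class DataError(NeurosccaError):
    """Invalid data: shape mismatches, constant columns, NaNs, out-of-range values."""
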