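"""Exception hierarchy shared across the pipeline.

Configuration problems (bad column mapping, unknown attribute, malformed
config file) and data-contract violations (fatal log structure, empty
variant table, out-of-range indices) are kept distinct so the command-line
layer can map them to different exit codes.
"""


class EquiflowError(Exception):
    """Base class for all errors raised by this package."""


class ConfigError(EquiflowError):
    """A configuration value or file is missing, malformed, or inconsistent."""


class DataContractError(EquiflowError):
    """Input data violates a precondition of the requested operation."""
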