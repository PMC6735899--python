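"""Coded exceptions shared across the pipeline.

``ConfigError`` covers bad parameters and malformed configuration;
``DataError`` covers malformed or inconsistent input data. The CLI maps
them to exit codes 2 and 3 respectively.
"""


class PoolscreenError(Exception):
    """Base class for all package errors."""


class ConfigError(PoolscreenError):
    """Invalid parameter or configuration value."""


class DataError(PoolscreenError):
    """Malformed or internally inconsistent input data."""
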