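"""Exception hierarchy shared across the package.

The CLI maps these onto exit codes: input/schema/config problems exit
with 2, analysis-stage problems with 3.
"""


class CpirankError(Exception):
    """Base class for all package errors."""


class InputError(CpirankError):
    """An input file is missing, unreadable, or not parseable."""


class SchemaError(InputError):
    """A table is readable but lacks a mandatory column or field."""


class ConfigError(CpirankError):
    """A configuration value is invalid or infeasible."""


class AnalysisError(CpirankError):
    """A statistical or modelling step cannot run on the given data."""
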