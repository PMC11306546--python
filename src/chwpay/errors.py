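"""Exception hierarchy with distinct process exit codes.

Exit codes: 2 configuration, 3 input schema, 4 input validation, 5 I/O.
Click reserves 2 for usage errors, which are configuration errors here too.
"""


class ChwPayError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class ConfigError(ChwPayError):
    """Invalid run configuration (flags, config file, staffing/service params)."""

    exit_code = 2


class SchemaError(ChwPayError):
    """Input file does not match the documented column schema."""

    exit_code = 3


class ValidationError(ChwPayError):
    """Input values violate domain invariants (located by geo_id and field)."""

    exit_code = 4


class OutputError(ChwPayError):
    """Results could not be written."""

    exit_code = 5
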