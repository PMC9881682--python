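"""Exception hierarchy with stable CLI exit codes.

Exit-code contract: 0 success, 2 input error, 3 database error, 4 internal.
"""


class EnzSelectError(Exception):
    """Base class for all package errors."""

    exit_code = 4


class InputError(EnzSelectError):
    """Any problem with user-supplied query input."""

    exit_code = 2


class ReactionParseError(InputError):
    """Malformed SMILES/SMARTS/molfile content."""


class ReactionFormatError(InputError):
    """Structurally invalid .rxn file (counts, headers, V3000...)."""


class ValidationError(InputError):
    """Input violates a documented contract (empty side, bad residue...)."""


class NotFoundError(InputError):
    """EC number or external reference absent from the database."""


class ConfigError(InputError):
    """Invalid scoring or similarity configuration."""


class DatabaseError(EnzSelectError):
    """Missing or inconsistent database files."""

    exit_code = 3


class FixtureError(EnzSelectError):
    """Synthetic fixture generation cannot satisfy the requested spec."""

    exit_code = 3
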