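"""Exception hierarchy.

Every error raised on a user-facing code path derives from
:class:`BindsurfError` so the CLI can catch one type and exit non-zero.
"""


class BindsurfError(Exception):
    """Base class for all package errors."""


class PDBParseError(BindsurfError):
    """A PDB file could not be parsed into a usable structure."""


class ChainAmbiguityError(PDBParseError):
    """No chain was requested but the file contains several."""

    def __init__(self, chains):
        self.chains = sorted(chains)
        super().__init__(
            "multiple chains present, pass an explicit chain id; "
            f"available: {', '.join(self.chains)}"
        )


class InterfaceFileError(BindsurfError):
    """The interface file is malformed."""


class ValidationError(BindsurfError):
    """An input violates a documented precondition or invariant."""


class EmptyFilterError(BindsurfError):
    """Coverage filtering removed every interface."""


class MissingResidueError(BindsurfError):
    """A residue required by an operation is absent from the structure."""
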