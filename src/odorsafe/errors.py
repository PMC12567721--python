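"""Exception hierarchy for odorsafe.

Every error raised by the package derives from :class:`OdorsafeError` so
callers can catch the whole family in batch loops.
"""

from __future__ import annotations


class OdorsafeError(Exception):
    """Base class for all odorsafe errors."""


class StructureError(OdorsafeError):
    """A SMILES string could not be turned into a usable single-fragment molecule.

    Carries the offending string so batch error reports can name it.
    """

    def __init__(self, smiles: str, reason: str = "could not be parsed"):
        self.smiles = smiles
        self.reason = reason
        super().__init__(f"SMILES {smiles!r} {reason}")


class OutOfDomainError(OdorsafeError):
    """Molecule falls outside the element coverage of the decision tree.

    Raised for e.g. organometallics rather than silently returning the
    most conservative class.
    """

    def __init__(self, smiles: str, detail: str):
        self.smiles = smiles
        self.detail = detail
        super().__init__(f"SMILES {smiles!r} is outside the model domain: {detail}")


class InputError(OdorsafeError):
    """A numeric input violates its physical constraints (negative VP, T <= 0, ...)."""


class ConfigurationError(OdorsafeError):
    """Bad run configuration, e.g. an unknown hazard label in a TTC table."""


class LoadError(OdorsafeError):
    """A file could not be loaded; message itemizes the offending rows/columns."""
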