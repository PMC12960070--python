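"""Exception hierarchy for ionclust.

All package-raised errors derive from :class:`IonclustError` so callers can
catch one type at pipeline boundaries while tests can assert the specific
failure mode.
"""


class IonclustError(Exception):
    """Base class for all ionclust errors."""


class FormatError(IonclustError):
    """A coordinate file could not be parsed (names file and, where known, line)."""


class StructureError(IonclustError):
    """Frames of one trajectory disagree structurally (e.g. atom counts)."""


class RoleMapError(IonclustError):
    """The atom -> molecule/role mapping is missing, inconsistent or incomplete."""


class GenerationError(IonclustError):
    """A synthetic fixture could not be generated under its constraints."""


class IntegrityError(IonclustError):
    """A derived object violates an internal consistency contract."""
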