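"""Exception hierarchy for the de-identification pipeline."""


class WiseDeidError(Exception):
    """Base class for all package errors."""


class UnparseableInput(WiseDeidError):
    """Input is neither valid JSON nor well-formed XML."""


class UnknownSchema(WiseDeidError):
    """Valid JSON/XML, but neither FHIR-shaped nor CDA-rooted."""


class SchemaViolation(WiseDeidError):
    """Structurally invalid document (e.g. a Bundle without an entry list)."""


class MalformedPath(WiseDeidError):
    """A flat-record path that cannot be interpreted."""


class UnknownMode(WiseDeidError):
    """Unknown rule-registry mode."""


class UnparseableValue(WiseDeidError):
    """A value does not parse as the kind a generalization ladder expects."""


class VaultLocked(WiseDeidError):
    """Vault cannot be opened: wrong key material or corrupted store."""


class VaultWriteFailure(WiseDeidError):
    """Vault could not be persisted."""


class UnknownPseudonym(WiseDeidError):
    """Pseudonym not present in the vault."""


class OutOfRange(WiseDeidError):
    """Risk value outside (0, 1]."""


class EmptySelection(WiseDeidError):
    """Section/resource filtering removed every entry."""


class MissingLegalBasis(WiseDeidError):
    """Pipeline invoked without asserting a legal basis for processing."""


class PublicShareRefusal(WiseDeidError):
    """Re-identification refused: the document was shared with a general audience."""
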