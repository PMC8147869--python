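"""Exception types shared across the package."""


class PromsetsError(Exception):
    """Base class for all package-specific errors."""


class FormatError(PromsetsError):
    """A file does not conform to the expected dialect."""


class ConsistencyError(PromsetsError):
    """Input data violates an internal consistency requirement."""


class ContractError(PromsetsError):
    """An operation was called outside its precondition."""


class ConfigurationError(PromsetsError):
    """A configuration value or rule file is invalid."""


class SmilesParseError(PromsetsError):
    """A SMILES string could not be parsed.

    Carries the offending string as ``.smiles``.
    """

    def __init__(self, smiles: str):
        super().__init__(f"unparsable SMILES: {smiles!r}")
        self.smiles = smiles
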