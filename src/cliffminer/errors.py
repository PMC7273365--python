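"""Exception hierarchy.

Each error family maps to a distinct CLI exit code (see ``cliffminer.cli``).
"""


class CliffMinerError(Exception):
    """Base class for all cliffminer errors."""


class ConfigurationError(CliffMinerError):
    """Invalid configuration: missing columns, bad pattern files, bad specs."""


class StructureError(CliffMinerError):
    """A structure string could not be parsed or standardized."""

    def __init__(self, smiles: str, message: str = "unparseable structure"):
        self.smiles = smiles
        super().__init__(f"{message}: {smiles!r}")


class UnitError(CliffMinerError):
    """A potency value carries units that cannot be converted to molar."""

    def __init__(self, units: str):
        self.units = units
        super().__init__(f"unknown potency units: {units!r}")


class DataIntegrityError(CliffMinerError):
    """Cross-stage inconsistency, e.g. a pair member without a potency."""


class FixtureSpecError(ConfigurationError):
    """A synthetic-fixture specification is internally inconsistent."""
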