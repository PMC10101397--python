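"""Exception hierarchy.

Everything raised on bad user input derives from :class:`PhantomradError`;
the subclasses that signal invalid values also derive from :class:`ValueError`
so generic validation code can catch them uniformly.
"""


class PhantomradError(Exception):
    """Base class for all package-specific errors."""


class InvalidInputError(PhantomradError, ValueError):
    """A value violates an operation's preconditions (empty map, zero mass...)."""


class FormulaParseError(InvalidInputError):
    """Malformed chemical formula; carries the offending position."""

    def __init__(self, message: str, formula: str, position: int):
        super().__init__(f"{message} in formula {formula!r} at position {position}")
        self.formula = formula
        self.position = position


class UnknownElementError(PhantomradError, KeyError):
    """An element symbol is not present in the packaged element table."""

    def __init__(self, symbol: str, context: str = ""):
        suffix = f" ({context})" if context else ""
        super().__init__(f"unknown element symbol {symbol!r}{suffix}")
        self.symbol = symbol


class UnknownCompoundError(PhantomradError, KeyError):
    """A recipe component cannot be resolved in the compound database."""

    def __init__(self, name: str):
        super().__init__(f"compound {name!r} not found in the compound database")
        self.name = name


class UnknownTissueError(PhantomradError, KeyError):
    """A tissue slug is not present in the packaged reference tables."""

    def __init__(self, tissue: str):
        super().__init__(f"unknown tissue {tissue!r}")
        self.tissue = tissue


class MissingDensityError(InvalidInputError):
    """An operation requires a mass density that the composition lacks."""

    def __init__(self, material: str):
        super().__init__(f"material {material!r} has no mass density set")
        self.material = material


class EnergyRangeError(PhantomradError, ValueError):
    """A photon energy falls outside the tabulated support."""


class DataLoadError(PhantomradError, OSError):
    """A packaged or user fixture file is missing or corrupt."""
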