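"""Exception hierarchy for gutnet.

Every error raised by the package derives from :class:`GutnetError` so
callers can catch the whole family with one clause.
"""


class GutnetError(Exception):
    """Base class for all gutnet errors."""


# --- network model -----------------------------------------------------------

class ConflictError(GutnetError):
    """Opposite-sign associations collide for the same (organism, compound, activity)."""


class MissingRuleError(GutnetError):
    """A degraded macromolecule has no degradation rule."""


# --- i/o ---------------------------------------------------------------------

class SchemaError(GutnetError):
    """A JSON object does not carry the expected keys; names the offending id."""


class CrossRefError(GutnetError):
    """A network object references an organism/compound absent from the side files."""


class ParseError(GutnetError):
    """A tabular input could not be parsed; carries a line number when known."""


class NegativeValueError(GutnetError):
    """An abundance or concentration value is negative."""


# --- taxa selection ----------------------------------------------------------

class RankError(GutnetError):
    """Operation requires a table at a different taxonomic rank."""


class EmptySelectionError(GutnetError):
    """A coverage summary was requested for an empty species selection."""


# --- degree-distribution fitting --------------------------------------------

class DegenerateError(GutnetError):
    """The degree sample is degenerate (constant, or too few usable entries)."""


class ConvergenceError(GutnetError):
    """Likelihood maximisation failed to converge."""


# --- concordance validation --------------------------------------------------

class UnknownCompoundError(GutnetError):
    """The requested metabolite is not a compound of the network."""


class GroupMismatchError(GutnetError):
    """Abundance and metabolite tables declare different experimental groups."""


class ZeroDenominatorError(GutnetError):
    """A fold change has a zero group-mean denominator."""


class NoRecordsError(GutnetError):
    """Match rate requested on no usable fold-change records."""


class NoQualifyingPairsError(GutnetError):
    """No (f, g) pair qualifies (both >= 1 or both <= 1) for the permutation test."""


class SeedRequiredError(GutnetError):
    """A seed is required in strict mode for reproducible permutation tests."""


# --- synthetic data ----------------------------------------------------------

class InfeasibleDegreeError(GutnetError):
    """Organism and compound stub totals could not be reconciled."""
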