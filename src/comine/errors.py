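"""Exception hierarchy for comine.

All errors derive from :class:`ComineError` so callers can catch the
package's failures with a single except clause; each subclass also derives
from the closest builtin (ValueError/KeyError/RuntimeError) so that generic
handling keeps working.
"""


class ComineError(Exception):
    """Base class for all comine errors."""


class InvalidTermError(ComineError, ValueError):
    """A MeSH term was empty or whitespace-only after normalization."""


class EmptyLexiconError(ComineError, ValueError):
    """Building a lexicon left zero surviving entries."""


class DuplicatePMIDError(ComineError, ValueError):
    """A corpus contained the same PMID more than once."""


class UnknownDiseaseError(ComineError, KeyError):
    """A requested disease term is not in the lexicon / collection."""


class InconsistentCountsError(ComineError, ValueError):
    """Contingency counts produce a negative 2x2 cell under the chosen convention."""


class DegenerateTableError(ComineError, ValueError):
    """All-zero 2x2 table: the hypergeometric distribution is undefined."""


class OracleScaleError(ComineError, ValueError):
    """The enumeration oracle was asked for a table too large to enumerate."""


class GMTParseError(ComineError, ValueError):
    """A GMT line was malformed (fewer than three tab-separated fields)."""


class DuplicateSetError(ComineError, ValueError):
    """A GMT stream declared the same gene-set name twice."""


class InsufficientCollectionError(ComineError, ValueError):
    """Multimorbidity analysis needs the index set plus at least two others."""


class SpecError(ComineError, ValueError):
    """A simulation specification is invalid (probabilities, universe size...)."""


class ConfigError(ComineError, ValueError):
    """A pipeline configuration is missing inputs or has invalid values."""
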