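"""Exception hierarchy.

Input-shaped problems (malformed tables, violated invariants, unknown
labels) derive from :class:`InputError`; the CLI maps these to exit code 2.
Numerical problems (non-convergent quadrature, degenerate model domains)
derive from :class:`AnalysisError` and map to exit code 3.
"""


class KaryorateError(Exception):
    """Base class for all package errors."""


class InputError(KaryorateError):
    """Invalid or inconsistent input data."""


class FormatError(InputError):
    """Malformed file content (wrong columns, non-consecutive positions...)."""


class UniquenessError(InputError):
    """A syntenic block triple occurs more than once within one karyotype."""


class ChronologyError(InputError):
    """A node in a dated tree is older than its parent."""


class MappingError(InputError):
    """A taxon or branch label cannot be matched to the tree."""


class HomologyError(InputError):
    """A derived block has no home in the ancestral karyotype."""


class AnalysisError(KaryorateError):
    """Base for numerical/model failures."""


class DomainError(AnalysisError):
    """Arguments outside the mathematical domain of a model."""


class NumericalError(AnalysisError):
    """Quadrature or root finding failed to converge."""
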