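"""Exception hierarchy shared across the package."""


class StrandgateError(Exception):
    """Base class for all package errors."""


class FormatError(StrandgateError):
    """Malformed structure or table file (e.g. inconsistent PDB models)."""


class TopologyError(StrandgateError):
    """Strand topology does not resolve against the structure."""


class FixtureError(StrandgateError):
    """Synthetic fixture specification is internally inconsistent."""


class DegenerateGeometryError(StrandgateError):
    """Geometric operation on degenerate input (collinear/coincident atoms)."""


class CoverageError(StrandgateError):
    """Umbrella windows leave a gap inside the sampled region."""


class ConvergenceError(StrandgateError):
    """Iterative solver exceeded its iteration budget."""
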