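"""Exception hierarchy shared across symsurf modules."""


class SymsurfError(Exception):
    """Base class for all symsurf errors."""


class InputError(SymsurfError, ValueError):
    """Unreadable, malformed or inconsistent input."""


class EmptyStructureError(InputError):
    """A structure file with no ATOM records."""


class FormatError(InputError):
    """A tabulated file violating its schema (axes file, scale file, tables)."""


class DegenerateGeometryError(SymsurfError):
    """Geometry unfit for the requested operation (collinear points, near-identity rotation)."""


class HeteromerError(InputError):
    """Chains are not sequence-identical; point-group detection is defined for homomers."""


class AsymmetricStructureError(SymsurfError):
    """No consistent point group found within tolerance."""


class NotApplicableError(SymsurfError):
    """A descriptor variant requested on a symmetry class it is not defined for."""


class ContractViolationError(SymsurfError):
    """An internal invariant was violated (e.g. negative plane distance)."""
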