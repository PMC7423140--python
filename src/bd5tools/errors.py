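"""Exception hierarchy for bd5tools."""


class BD5Error(Exception):
    """Base class for all bd5tools errors."""


class DimensionMismatchError(BD5Error):
    """A record's coordinate fields disagree with the declared dimensionality."""


class EntityArityError(BD5Error, ValueError):
    """Vertex count or radius presence is wrong for the entity kind."""


class MalformedEntityError(BD5Error):
    """Rows of one entity cannot be reassembled (duplicate or gapped sID run)."""


class StructureError(BD5Error):
    """A BD5 file is missing a required group or dataset, or is not HDF5."""


class ValidationFailedError(BD5Error):
    """A document failed validation where a valid document is required."""

    def __init__(self, violations):
        self.violations = list(violations)
        lines = "; ".join(str(v) for v in self.violations[:5])
        more = "" if len(self.violations) <= 5 else f" (+{len(self.violations) - 5} more)"
        super().__init__(f"document has {len(self.violations)} violation(s): {lines}{more}")


class TrackError(BD5Error):
    """Track graph inconsistency (dangling endpoint, time ordering, cycle)."""


class DanglingEdgeError(TrackError):
    """A trackInfo edge names an object ID absent from every time group."""


class BDMLParseError(BD5Error):
    """BDML XML could not be parsed or lacks a quantitative payload."""


class CSVImportError(BD5Error):
    """A CSV table could not be mapped onto spatial records."""
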