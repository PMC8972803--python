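"""Exception hierarchy shared across the package.

All domain errors derive from :class:`GlobalDynError` so the CLI can map
them to exit status 1 while genuine usage errors exit with status 2.
"""


class GlobalDynError(Exception):
    """Base class for all globaldyn domain errors."""


class PDBParseError(GlobalDynError):
    """A fixed-width PDB record could not be parsed; message names the line."""


class EmptySelectionError(GlobalDynError):
    """An atom selection matched nothing."""


class ShapeError(GlobalDynError, ValueError):
    """Inputs have inconsistent sizes (node counts, vector lengths, ...)."""


class AlignmentKeyError(GlobalDynError, KeyError):
    """An alignment table references a residue a member does not have."""


class SingularGeometryError(GlobalDynError):
    """Coincident nodes (or similar) make an elastic model undefined."""


class UnsupportedKindError(GlobalDynError):
    """A mode-set operation was asked for on the wrong kind of modes."""


class DensityFormatError(GlobalDynError):
    """A density-map file is malformed; message names the offending field."""


class DegenerateGeometryWarning(UserWarning):
    """Collinear/degenerate geometry: the result is valid but not unique."""


class ZeroModeCountWarning(UserWarning):
    """Zero-mode count differs from the count expected for a connected system."""
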