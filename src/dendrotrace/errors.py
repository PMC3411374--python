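"""Exception hierarchy shared by all recognition stages."""


class DendrotraceError(Exception):
    """Base class for all package errors."""


class FormatError(DendrotraceError):
    """Unsupported or unreadable image format."""


class BoundsError(DendrotraceError):
    """A coordinate or rectangle falls outside the image."""


class ParameterError(DendrotraceError):
    """An operation parameter is invalid (wrong kind, even window, ...)."""


class SeedError(DendrotraceError):
    """Flood seed does not lie on a foreground pixel."""


class EditError(DendrotraceError):
    """A node or branch edit refers to a missing id or duplicates a branch."""


class PositionError(DendrotraceError):
    """A node position does not lie on the component mask."""


class MappingError(DendrotraceError):
    """A tip-name mapping targets a node that is not a tip."""


class RootingError(DendrotraceError):
    """The requested root is not a valid inner node."""


class CapacityError(DendrotraceError):
    """A tree does not fit into the requested render canvas."""


class ConfigError(DendrotraceError):
    """Pipeline configuration is invalid."""
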