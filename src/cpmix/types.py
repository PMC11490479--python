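"""Shared enums and exceptions."""

from __future__ import annotations

import enum


class CellType(enum.IntEnum):
    """Cell type codes used in per-cell arrays and contact-energy lookups."""

    WALL = 0
    MOTILE = 1
    NON_MOTILE = 2


class Experiment(enum.Enum):
    MIXING = "mixing"
    INVASION = "invasion"


class MixingClass(enum.Enum):
    WELL_MIXED = "well_mixed"
    PARTIAL = "partial"
    NONE = "none"


class Winner(enum.Enum):
    MOTILE = "motile"
    NON_MOTILE = "non_motile"
    COEXIST = "coexist"
    UNDECIDED = "undecided"


class CpmixError(Exception):
    """Base class for package errors."""


class ConfigError(CpmixError):
    """Invalid or unknown configuration values."""


class SnapshotError(CpmixError):
    """Corrupt or inconsistent lattice snapshot files."""


class UnknownCellError(CpmixError):
    """A cell id was requested that does not exist in the registry."""
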