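"""Physicochemical property groups backing the 188D encoder.

Each of the eight properties partitions the 20 standard amino acids into
three groups (e.g. for secondary-structure propensity: helix-formers,
strand-formers, coil-formers).  Composition, transition and distribution
descriptors are computed per property over these groups, so the partition
invariant (disjoint cover of the alphabet) is enforced whenever a table is
constructed or loaded.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import yaml

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
AA_SET = frozenset(AMINO_ACIDS)
AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}

# Canonical property order; frozen so that feature indices are portable
# across runs and configuration files.
PROPERTY_ORDER = (
    "secondary_structure",
    "solvent_accessibility",
    "vdw_volume",
    "hydrophobicity",
    "charge",
    "polarity",
    "polarizability",
    "surface_tension",
)

# Standard three-way CTD groupings from the 188D descriptor literature.
_DEFAULT_GROUPS: dict[str, tuple[str, str, str]] = {
    "secondary_structure": ("EALMQKRH", "VIYCWFT", "GNPSD"),
    "solvent_accessibility": ("ALFCGIVW", "RKQEND", "MSPTHY"),
    "vdw_volume": ("GASTPDC", "NVEQIL", "MHKFRYW"),
    "hydrophobicity": ("RKEDQN", "GASTPHY", "CLVIMFW"),
    "charge": ("KR", "ANCQGHILMFPSTWYV", "DE"),
    "polarity": ("LIFWCMVY", "PATGS", "HQRKNED"),
    "polarizability": ("GASDT", "CPNVEQIL", "KMHFRYW"),
    "surface_tension": ("GQDNAHR", "KTSEC", "ILMFPWYV"),
}


class GroupTableError(ValueError):
    """Raised when a property-group table violates the partition invariant."""


@dataclass(frozen=True)
class PropertyGroupTable:
    """Eight named physicochemical properties, each splitting the 20
    standard residues into three disjoint, exhaustive groups.

    Parameters
    ----------
    properties : sequence of str
        Property names in descriptor order.
    groups : dict
        Mapping property name -> 3-tuple of residue strings.
    """

    properties: tuple[str, ...] = PROPERTY_ORDER
    groups: dict[str, tuple[str, str, str]] = field(
        default_factory=lambda: dict(_DEFAULT_GROUPS)
    )

    def __post_init__(self) -> None:
        if len(self.properties) != 8:
            raise GroupTableError(
                f"expected exactly 8 properties, got {len(self.properties)}"
            )
        for prop in self.properties:
            if prop not in self.groups:
                raise GroupTableError(f"no groups given for property {prop!r}")
            gs = self.groups[prop]
            if len(gs) != 3:
                raise GroupTableError(
                    f"property {prop!r} must have exactly 3 groups, got {len(gs)}"
                )
            seen: set[str] = set()
            for g in gs:
                letters = set(g.upper())
                if not letters <= AA_SET:
                    bad = "".join(sorted(letters - AA_SET))
                    raise GroupTableError(
                        f"property {prop!r} contains non-standard letters {bad!r}"
                    )
                if letters & seen:
                    dup = "".join(sorted(letters & seen))
                    raise GroupTableError(
                        f"property {prop!r}: residues {dup!r} appear in two groups"
                    )
                seen |= letters
            if seen != AA_SET:
                missing = "".join(sorted(AA_SET - seen))
                raise GroupTableError(
                    f"property {prop!r}: residues {missing!r} unassigned"
                )

    def group_index(self, prop: str) -> list[int]:
        """Return, for each alphabet position, the 0-based group id (0/1/2)
        of that residue under ``prop``."""
        idx = [0] * 20
        for j, g in enumerate(self.groups[prop]):
            for aa in g.upper():
                idx[AA_INDEX[aa]] = j
        return idx

    @classmethod
    def default(cls) -> "PropertyGroupTable":
        return cls()

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PropertyGroupTable":
        """Load a table from a YAML mapping ``property: [g1, g2, g3]``.

        Property order follows the file; the partition invariant is
        enforced regardless of edits.
        """
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if not isinstance(raw, dict):
            raise GroupTableError(f"{path}: expected a mapping of property -> groups")
        props = tuple(raw.keys())
        groups = {
            p: tuple(str(g).upper() for g in gs) for p, gs in raw.items()
        }
        return cls(properties=props, groups=groups)  # type: ignore[arg-type]

    def to_yaml(self, path: str | Path) -> None:
        data = {p: list(self.groups[p]) for p in self.properties}
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)
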