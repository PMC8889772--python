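"""Lipid species shorthand nomenclature: parsing, formatting, class taxonomy.

Species are written in sum-composition shorthand, e.g. ``"MGDG 34:3"``:
a head-group class code, one space, then total acyl carbons and total
double bonds summed over all acyl chains. No sn-position or individual
chain resolution is attempted — the notation carries class, C and DB only.

The class taxonomy covers the 14 head-group classes quantified in rice
leaf lipidomes: three chloroplast galactolipids, six diacyl phospholipid
classes, two lyso-phospholipids, the two neutral glycerolipids (DG, TG)
and the free fatty acid pool.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from enum import Enum

__all__ = [
    "LipidCategory",
    "LipidClassInfo",
    "LIPID_CLASSES",
    "SpeciesDescriptor",
    "LipidNameError",
    "UnknownLipidClassError",
    "MalformedSpeciesError",
    "parse_species",
    "format_species",
    "classify_saturation",
]


class LipidCategory(str, Enum):
    """Head-group category a lipid class belongs to."""

    GALACTOLIPID = "galactolipid"
    PHOSPHOLIPID = "phospholipid"
    LYSOPHOSPHOLIPID = "lysophospholipid"
    NEUTRAL = "neutral"
    FREE_FATTY_ACID = "free_fatty_acid"


@dataclass(frozen=True)
class LipidClassInfo:
    """A head-group class: its code, category and acyl-chain count."""

    code: str
    category: LipidCategory
    n_acyl_chains: int


def _classes(category: LipidCategory, n_chains: int, *codes: str) -> dict[str, LipidClassInfo]:
    return {c: LipidClassInfo(c, category, n_chains) for c in codes}


#: The 14 head-group classes, keyed by case-sensitive code.
LIPID_CLASSES: dict[str, LipidClassInfo] = {
    **_classes(LipidCategory.GALACTOLIPID, 2, "MGDG", "DGDG", "SQDG"),
    **_classes(LipidCategory.PHOSPHOLIPID, 2, "PA", "PC", "PE", "PG", "PI", "PMeOH"),
    **_classes(LipidCategory.LYSOPHOSPHOLIPID, 1, "LPE", "LPC"),
    **_classes(LipidCategory.NEUTRAL, 2, "DG"),
    **_classes(LipidCategory.NEUTRAL, 3, "TG"),
    **_classes(LipidCategory.FREE_FATTY_ACID, 1, "FA"),
}

#: Class codes grouped by category (iteration order = definition order).
CATEGORY_CLASSES: dict[LipidCategory, tuple[str, ...]] = {
    cat: tuple(c for c, info in LIPID_CLASSES.items() if info.category is cat)
    for cat in LipidCategory
}


class LipidNameError(ValueError):
    """Base error for species-name parsing and validation."""


class UnknownLipidClassError(LipidNameError):
    """The class-code token is not one of the 14 known codes."""


class MalformedSpeciesError(LipidNameError):
    """The name does not match ``<CLASS> <carbons>:<double_bonds>``."""


@dataclass(frozen=True, order=True)
class SpeciesDescriptor:
    """A lipid species as (class code, total acyl carbons, total double bonds).

    ``double_bonds`` is the N that enters the double-bond index; invariants
    ``carbons >= double_bonds >= 0`` and ``carbons >= 1`` are enforced on
    construction.
    """

    class_code: str
    carbons: int
    double_bonds: int

    def __post_init__(self) -> None:
        if self.class_code not in LIPID_CLASSES:
            raise UnknownLipidClassError(
                f"unknown lipid class: {self.class_code!r}"
            )
        if self.carbons < 1:
            raise MalformedSpeciesError(
                f"malformed species: carbons must be >= 1, got {self.carbons}"
            )
        if self.double_bonds < 0:
            raise MalformedSpeciesError(
                f"malformed species: double bonds must be >= 0, got {self.double_bonds}"
            )
        if self.double_bonds > self.carbons:
            raise MalformedSpeciesError(
                f"malformed species: {self.double_bonds} double bonds exceed "
                f"{self.carbons} carbons"
            )

    @property
    def info(self) -> LipidClassInfo:
        return LIPID_CLASSES[self.class_code]

    @property
    def category(self) -> LipidCategory:
        return LIPID_CLASSES[self.class_code].category

    def __str__(self) -> str:
        return format_species(self)


_STRICT_RE = re.compile(r"^(?P<cls>\S+) (?P<c>\d+):(?P<db>\d+)$")
# lenient mode additionally accepts "MGDG(34:3)" and tolerates extra whitespace
_LENIENT_RE = re.compile(r"^\s*(?P<cls>\S+?)\s*\(?\s*(?P<c>\d+)\s*:\s*(?P<db>\d+)\s*\)?\s*$")


def parse_species(name: str, *, strict: bool = True) -> SpeciesDescriptor:
    """Parse shorthand like ``"MGDG 34:3"`` into a :class:`SpeciesDescriptor`.

    Strict mode (default) requires exactly one ASCII space between the
    class code and ``carbons:double_bonds``. Lenient mode also accepts the
    parenthesised dialect ``"MGDG(34:3)"`` and stray whitespace.

    Raises
    ------
    UnknownLipidClassError
        If the class token is not one of the 14 known codes.
    MalformedSpeciesError
        If the carbons:double_bonds part is missing or non-numeric, or the
        descriptor invariants fail.
    """
    if not isinstance(name, str):
        raise MalformedSpeciesError(f"malformed species: expected a string, got {type(name).__name__}")
    m = (_STRICT_RE if strict else _LENIENT_RE).match(name)
    if m is None:
        raise MalformedSpeciesError(
            f"malformed species: {name!r} does not match '<CLASS> <carbons>:<double_bonds>'"
        )
    cls = m.group("cls")
    if cls not in LIPID_CLASSES:
        raise UnknownLipidClassError(f"unknown lipid class: {cls!r} in {name!r}")
    return SpeciesDescriptor(cls, int(m.group("c")), int(m.group("db")))


def format_species(d: SpeciesDescriptor) -> str:
    """Canonical shorthand ``"<CLASS> <carbons>:<double_bonds>"``.

    Round-trips: ``parse_species(format_species(d)) == d``.
    """
    return f"{d.class_code} {d.carbons}:{d.double_bonds}"


def classify_saturation(d: SpeciesDescriptor) -> str:
    """Classify a free fatty acid as ``"SFA"`` (0 double bonds) or ``"UFA"``.

    Only defined for the FA class; any esterified class raises ``ValueError``.
    """
    if d.class_code != "FA":
        raise LipidNameError(
            "saturation classification applies to free fatty acids; "
            f"got class {d.class_code!r}"
        )
    return "SFA" if d.double_bonds == 0 else "UFA"
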