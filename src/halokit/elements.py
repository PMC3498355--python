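"""Element tables, van der Waals radii and acceptor taxonomy.

Two radius sets are shipped:

``"bondi"``
    The standard Bondi compilation, under which r(Br) + r(O) = 3.37 Å.
``"paper"``
    The Bondi set uniformly rescaled so that r(Br) + r(O) = 3.70 Å, the
    donor–acceptor sum used as the halogen-bond distance ceiling in CK2α
    contact surveys.  This is the default for survey reproduction.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

__all__ = [
    "AcceptorClass",
    "ElementInfo",
    "HALOGENS",
    "RADIUS_SETS",
    "vdw_radius",
    "vdw_sum",
]

#: Halogens that act as sigma-hole donors in the contact scan.
HALOGENS = frozenset({"CL", "BR", "I"})

_BONDI = {
    "H": 1.20,
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "F": 1.47,
    "P": 1.80,
    "S": 1.80,
    "CL": 1.75,
    "BR": 1.85,
    "I": 1.98,
}

# Rescale so the dominant Br…O donor-acceptor pair sums to 3.70 Å.
_PAPER_SCALE = 3.70 / (_BONDI["BR"] + _BONDI["O"])
_PAPER = {sym: r * _PAPER_SCALE for sym, r in _BONDI.items()}

RADIUS_SETS: dict[str, dict[str, float]] = {"bondi": _BONDI, "paper": _PAPER}


@dataclass(frozen=True)
class ElementInfo:
    """An element symbol with its van der Waals radius in Å."""

    symbol: str
    vdw_radius: float

    def __post_init__(self) -> None:
        if self.vdw_radius <= 0:
            raise ValueError(f"vdw_radius must be positive, got {self.vdw_radius}")


class AcceptorClass(enum.Enum):
    """Taxonomy of halogen-bond acceptor sites.

    Electron donors available to a covalently bound halogen's sigma hole:
    backbone carbonyl oxygens, side-chain O/N/S atoms, water oxygens, and
    aromatic pi systems (represented by ring centroids).
    """

    BACKBONE_CARBONYL_O = "backbone_carbonyl_O"
    SIDECHAIN_O = "sidechain_O"
    SIDECHAIN_N = "sidechain_N"
    SIDECHAIN_S = "sidechain_S"
    WATER_O = "water_O"
    PI_SYSTEM = "pi_system"


def vdw_radius(element: str, radius_set: str = "paper") -> float:
    """Look up the van der Waals radius of *element* in Å."""
    try:
        table = RADIUS_SETS[radius_set]
    except KeyError:
        raise KeyError(
            f"unknown radius set {radius_set!r}; choose from {sorted(RADIUS_SETS)}"
        ) from None
    try:
        return table[element.upper()]
    except KeyError:
        raise KeyError(
            f"element {element!r} not in radius set {radius_set!r}"
        ) from None


def vdw_sum(elem1: str, elem2: str, radius_set: str = "paper") -> float:
    """Sum of van der Waals radii of two elements in Å (symmetric)."""
    return vdw_radius(elem1, radius_set) + vdw_radius(elem2, radius_set)
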