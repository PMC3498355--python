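"""Structure parsing and halogen–acceptor contact extraction.

PDB content is parsed with gemmi into flat :class:`AtomRecord` lists; the
scan then pairs every ligand halogen (Cl, Br, I — sigma-hole donors) with
every candidate acceptor (backbone carbonyl O, side-chain O/N/S, water O,
aromatic ring centroid) within a distance threshold and reports the
contact distance together with the two flanking angles, C–X…Acc at the
halogen and X…Acc–C at the acceptor.

Conventions: coordinates in Å, angles in degrees, residue numbering as in
the source file.  Hydrogens are ignored.  For alternate conformations the
highest-occupancy conformer is kept (ties broken by altloc letter).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Iterable, Optional, Sequence, Union

import gemmi
import numpy as np
import pandas as pd

from .elements import HALOGENS, AcceptorClass
from .errors import (
    EmptyStructureError,
    GeometryError,
    ParameterError,
    ParseError,
)

__all__ = [
    "AtomRecord",
    "HalogenSite",
    "Acceptor",
    "ContactRecord",
    "parse_structure",
    "find_halogen_sites",
    "find_acceptors",
    "scan_contacts",
    "compute_angle",
    "distance",
    "contacts_to_frame",
]

_WATER_NAMES = {"HOH", "WAT", "H2O", "DOD"}
_BACKBONE_NAMES = {"N", "CA", "C", "O", "OXT"}

#: Aromatic side-chain ring atom names used for pi-system centroids.
_RING_ATOMS = {
    "HIS": [("CG", "ND1", "CD2", "CE1", "NE2")],
    "PHE": [("CG", "CD1", "CD2", "CE1", "CE2", "CZ")],
    "TYR": [("CG", "CD1", "CD2", "CE1", "CE2", "CZ")],
    "TRP": [
        ("CG", "CD1", "NE1", "CE2", "CD2"),
        ("CE2", "CD2", "CE3", "CZ3", "CH2", "CZ2"),
    ],
}

_MAX_XC_BOND = 2.1  # Å, halogen-carbon covalent bond ceiling
_MAX_ANCHOR_BOND = 1.8  # Å, acceptor-carbon covalent bond ceiling


@dataclass
class AtomRecord:
    """One atom (or ring-centroid pseudo-atom) with resolved element."""

    serial: int
    name: str
    element: str
    residue_name: str
    residue_number: int
    chain: str
    xyz: np.ndarray
    record_kind: str  # "polymer" | "hetero" | "water"
    occupancy: float = 1.0
    altloc: str = ""

    @property
    def residue_id(self) -> tuple[str, int, str]:
        return (self.chain, self.residue_number, self.residue_name)


@dataclass
class HalogenSite:
    """A covalently bound halogen with its carbon, the sigma-hole donor."""

    x_atom: AtomRecord
    c_atom: Optional[AtomRecord]
    ligand_id: str
    #: False when no carbon was found within the covalent bond ceiling;
    #: such sites are kept for the distance census but carry no C-X...Acc angle.
    bonded: bool = True


@dataclass
class Acceptor:
    atom: AtomRecord
    acceptor_class: AcceptorClass
    anchor: Optional[AtomRecord]


@dataclass
class ContactRecord:
    """One halogen...acceptor pair within the scan threshold."""

    structure_id: str
    site: HalogenSite
    acceptor: AtomRecord
    acceptor_class: AcceptorClass
    acc_anchor: Optional[AtomRecord]
    d: float
    theta_cxa: Optional[float]  # degrees, at the halogen
    theta_xac: Optional[float]  # degrees, at the acceptor; None for water/pi

    @property
    def is_halogen_bond_candidate(self) -> bool:
        return self.d > 0


def _element_from_name(name: str, residue_name: str) -> str:
    """Heuristic element assignment when the element column is absent."""
    stripped = name.strip()
    if residue_name.upper() in _WATER_NAMES:
        return "O"
    for two in ("CL", "BR"):
        if stripped.upper().startswith(two):
            return two
    head = stripped.lstrip("0123456789")
    return head[:1].upper() if head else "X"


def distance(a: AtomRecord, b: AtomRecord) -> float:
    """Euclidean distance between two atoms in Å."""
    return float(np.linalg.norm(a.xyz - b.xyz))


def compute_angle(a: Sequence[float], b: Sequence[float], c: Sequence[float]) -> float:
    """Interior angle at vertex *b* of the triple (a, b, c), in degrees.

    Raises
    ------
    GeometryError
        If either arm (a-b or c-b) has zero length.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    c = np.asarray(c, dtype=float)
    u = a - b
    v = c - b
    nu = np.linalg.norm(u)
    nv = np.linalg.norm(v)
    if nu == 0.0 or nv == 0.0:
        raise GeometryError("angle undefined: zero-length arm at the vertex")
    cosang = float(np.dot(u, v) / (nu * nv))
    return math.degrees(math.acos(max(-1.0, min(1.0, cosang))))


def parse_structure(text: str) -> list[AtomRecord]:
    """Parse PDB-format text into atom records.

    Element symbols come from the element column when present, otherwise
    from atom-name heuristics.  Waters are classified by residue name,
    hydrogens are dropped, and only the highest-occupancy alternate
    conformer of each atom is retained.
    """
    for lineno, line in enumerate(text.splitlines(), start=1):
        if line.startswith(("ATOM ", "HETATM")) and len(line.rstrip()) < 54:
            raise ParseError(f"malformed coordinate record at line {lineno}")
    try:
        st = gemmi.read_pdb_string(text)
    except (RuntimeError, ValueError) as exc:
        raise ParseError(f"PDB parse failure: {exc}") from exc
    if len(st) == 0:
        raise EmptyStructureError("structure contains no atoms")

    atoms: list[AtomRecord] = []
    model = st[0]
    for chain in model:
        for residue in chain:
            resname = residue.name.upper()
            if resname in _WATER_NAMES:
                kind = "water"
            else:
                info = gemmi.find_tabulated_residue(residue.name)
                if info is not None and info.is_amino_acid():
                    kind = "polymer"
                elif residue.het_flag == "A":
                    kind = "polymer"
                else:
                    kind = "hetero"
            # keep one conformer per atom name: highest occupancy, tie -> altloc order
            best: dict[str, gemmi.Atom] = {}
            for atom in residue:
                prev = best.get(atom.name)
                if (
                    prev is None
                    or atom.occ > prev.occ
                    or (atom.occ == prev.occ and (atom.altloc or "~") < (prev.altloc or "~"))
                ):
                    best[atom.name] = atom
            for atom in best.values():
                elem = atom.element.name.upper() if atom.element else ""
                if elem in ("", "X"):
                    elem = _element_from_name(atom.name, residue.name)
                if elem == "H" or elem == "D":
                    continue
                xyz = np.array([atom.pos.x, atom.pos.y, atom.pos.z], dtype=float)
                if not np.all(np.isfinite(xyz)):
                    raise ParseError(f"non-finite coordinates for atom {atom.serial}")
                atoms.append(
                    AtomRecord(
                        serial=atom.serial,
                        name=atom.name,
                        element=elem,
                        residue_name=residue.name,
                        residue_number=residue.seqid.num,
                        chain=chain.name,
                        xyz=xyz,
                        record_kind=kind,
                        occupancy=float(atom.occ),
                        altloc=atom.altloc or "",
                    )
                )
    if not atoms:
        raise EmptyStructureError("structure contains no atoms")
    return atoms


LigandSelector = Union[None, str, Iterable[str], Callable[[AtomRecord], bool]]


def _ligand_predicate(selector: LigandSelector) -> Callable[[AtomRecord], bool]:
    if selector is None:
        return lambda a: a.record_kind == "hetero"
    if isinstance(selector, str):
        return lambda a: a.residue_name.upper() == selector.upper()
    if callable(selector):
        return selector
    names = {s.upper() for s in selector}
    return lambda a: a.residue_name.upper() in names


def find_halogen_sites(
    atoms: Sequence[AtomRecord], ligand_selector: LigandSelector = None
) -> list[HalogenSite]:
    """One site per Cl/Br/I atom in the selected ligand residues.

    The bonded carbon is the nearest carbon of the same residue within
    2.1 Å; a halogen with no such carbon is still emitted (``bonded =
    False``) so it enters the distance census but not angle statistics.
    """
    pred = _ligand_predicate(ligand_selector)
    sites = []
    by_residue: dict[tuple, list[AtomRecord]] = {}
    for a in atoms:
        by_residue.setdefault(a.residue_id, []).append(a)
    for a in atoms:
        if a.element.upper() not in HALOGENS or not pred(a):
            continue
        carbons = [c for c in by_residue[a.residue_id] if c.element.upper() == "C"]
        c_best, d_best = None, _MAX_XC_BOND
        for c in carbons:
            d = distance(a, c)
            if d <= d_best:
                c_best, d_best = c, d
        ligand_id = f"{a.residue_name}_{a.chain}_{a.residue_number}"
        sites.append(
            HalogenSite(x_atom=a, c_atom=c_best, ligand_id=ligand_id, bonded=c_best is not None)
        )
    return sites


def find_acceptors(
    atoms: Sequence[AtomRecord], include_pi: bool = True
) -> list[Acceptor]:
    """Enumerate halogen-bond acceptor sites in the structure.

    Backbone O of amino-acid residues (anchor: the same-residue carbonyl
    C), side-chain O/N/S (anchor: nearest covalently bonded carbon),
    water O, and — when *include_pi* — one centroid pseudo-atom per
    aromatic side-chain ring of His/Phe/Tyr/Trp.
    """
    acceptors: list[Acceptor] = []
    by_residue: dict[tuple, list[AtomRecord]] = {}
    for a in atoms:
        by_residue.setdefault(a.residue_id, []).append(a)

    for rid, res_atoms in by_residue.items():
        kind = res_atoms[0].record_kind
        resname = rid[2].upper()
        if kind == "water":
            for a in res_atoms:
                if a.element.upper() == "O":
                    acceptors.append(Acceptor(a, AcceptorClass.WATER_O, None))
            continue
        if kind != "polymer":
            continue
        named = {a.name: a for a in res_atoms}
        carbons = [a for a in res_atoms if a.element.upper() == "C"]
        for a in res_atoms:
            elem = a.element.upper()
            if a.name in ("O", "OXT") and elem == "O":
                acceptors.append(
                    Acceptor(a, AcceptorClass.BACKBONE_CARBONYL_O, named.get("C"))
                )
            elif a.name not in _BACKBONE_NAMES and elem in ("O", "N", "S"):
                cls = {
                    "O": AcceptorClass.SIDECHAIN_O,
                    "N": AcceptorClass.SIDECHAIN_N,
                    "S": AcceptorClass.SIDECHAIN_S,
                }[elem]
                anchor, d_best = None, _MAX_ANCHOR_BOND
                for c in carbons:
                    d = distance(a, c)
                    if d <= d_best:
                        anchor, d_best = c, d
                acceptors.append(Acceptor(a, cls, anchor))
        if include_pi and resname in _RING_ATOMS:
            for ring in _RING_ATOMS[resname]:
                if all(n in named for n in ring):
                    centroid = np.mean([named[n].xyz for n in ring], axis=0)
                    pseudo = AtomRecord(
                        serial=-1,
                        name="PI",
                        element="PI",
                        residue_name=rid[2],
                        residue_number=rid[1],
                        chain=rid[0],
                        xyz=centroid,
                        record_kind="polymer",
                    )
                    acceptors.append(Acceptor(pseudo, AcceptorClass.PI_SYSTEM, None))
    return acceptors


def scan_contacts(
    atoms: Sequence[AtomRecord],
    threshold: float = 4.0,
    ligand_selector: LigandSelector = None,
    include_pi: bool = True,
    structure_id: str = "",
) -> list[ContactRecord]:
    """All halogen...acceptor pairs with d <= *threshold* (Å).

    Acceptors belonging to a ligand residue are excluded (no intra-ligand
    contacts).  Angles are reported where the defining anchors exist:
    C-X...Acc needs a bonded carbon at the halogen, X...Acc-C an anchor
    carbon at the acceptor (absent for water and pi centroids).
    """
    if threshold <= 0:
        raise ParameterError(f"threshold must be positive, got {threshold}")
    sites = find_halogen_sites(atoms, ligand_selector)
    acceptors = find_acceptors(atoms, include_pi=include_pi)
    ligand_residues = {s.x_atom.residue_id for s in sites}
    contacts = []
    for site in sites:
        x = site.x_atom
        for acc in acceptors:
            if acc.atom.residue_id in ligand_residues:
                continue
            d = float(np.linalg.norm(x.xyz - acc.atom.xyz))
            if d > threshold or d == 0.0:
                continue
            theta_cxa = None
            if site.bonded:
                theta_cxa = compute_angle(site.c_atom.xyz, x.xyz, acc.atom.xyz)
            theta_xac = None
            if acc.anchor is not None:
                theta_xac = compute_angle(x.xyz, acc.atom.xyz, acc.anchor.xyz)
            contacts.append(
                ContactRecord(
                    structure_id=structure_id,
                    site=site,
                    acceptor=acc.atom,
                    acceptor_class=acc.acceptor_class,
                    acc_anchor=acc.anchor,
                    d=d,
                    theta_cxa=theta_cxa,
                    theta_xac=theta_xac,
                )
            )
    contacts.sort(key=lambda c: (c.site.ligand_id, c.site.x_atom.name, c.d))
    return contacts


def contacts_to_frame(contacts: Sequence[ContactRecord]) -> pd.DataFrame:
    """Contacts as a flat table (TSV/JSON-ready)."""
    rows = []
    for c in contacts:
        rows.append(
            {
                "structure_id": c.structure_id,
                "chain": c.site.x_atom.chain,
                "ligand_id": c.site.ligand_id,
                "x_name": c.site.x_atom.name,
                "x_element": c.site.x_atom.element,
                "acc_residue": f"{c.acceptor.residue_name}{c.acceptor.residue_number}",
                "acc_name": c.acceptor.name,
                "acceptor_class": c.acceptor_class.value,
                "d": c.d,
                "theta_cxa": c.theta_cxa,
                "theta_xac": c.theta_xac,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "structure_id",
            "chain",
            "ligand_id",
            "x_name",
            "x_element",
            "acc_residue",
            "acc_name",
            "acceptor_class",
            "d",
            "theta_cxa",
            "theta_xac",
        ],
    )
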