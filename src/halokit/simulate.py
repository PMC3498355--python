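"""Synthetic inputs for every analysis stage.

Four generators, each a pure function of its arguments (identical seed →
identical bytes) returning data plus a manifest that records the truth:

* dose-response counts on the assay's 7-point concentration grid
  (0.016–250 µM) with multiplicative noise;
* contact distances from the truncated two-component normal mixture that
  emulates the crystallographic survey (broad ~N(3.34, 0.28²) van der
  Waals population, narrow ~N(2.90, 0.04²) halogen-bond population);
* minimal 3D protein–ligand complexes in PDB format with halogen–acceptor
  contacts planted at exact requested geometry — the constructive oracle
  for the contact scanner;
* descriptor tables with a known linear structure–activity relationship
  for regression recovery.

Synthetic complexes use glycine-only backbones plus one Ser/Lys/Cys/
water/Phe per required acceptor class, keeping each file under a hundred
atoms.  Crystallographic disorder (B-factors, altlocs, occupancy) is not
emulated.
"""

from __future__ import annotations

import math
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .elements import AcceptorClass
from .errors import ConstructionError, ParameterError
from .structure import compute_angle

__all__ = [
    "gen_dose_response",
    "gen_contact_distances",
    "mixture_truncated_cdf",
    "build_synthetic_complex",
    "build_synthetic_ck2_complex",
    "gen_qsar_table",
    "DEFAULT_CONCENTRATIONS",
]

#: Assay grid: 7 geometrically spaced concentrations spanning 0.016-250 µM.
DEFAULT_CONCENTRATIONS = tuple(np.geomspace(0.016, 250.0, 7))

#: Descriptor ranges bracketing the measured benzotriazole series.
_DESCRIPTOR_RANGES = {
    "Vmol": (127.1, 213.0),
    "pKa": (4.78, 8.56),
    "dG_diss": (49.7, 59.5),
    "dG_solv_anion": (-59.9, -38.0),
}


def gen_dose_response(
    ic50: float,
    c_max: float,
    c_min: float,
    concentrations: Optional[Sequence[float]] = None,
    cv: float = 0.05,
    replicates: int = 3,
    seed: int = 0,
    noise: str = "cv",
):
    """Simulate scintillation counts under one-site inhibition.

    Counts are model value × (1 + ε), ε ~ N(0, cv²), floored at zero;
    ``noise="poisson"`` draws Poisson counts around the model value
    instead.  The default of three replicates per concentration mirrors
    the assay protocol (minimum three independent experiments).  Returns
    (DataFrame[concentration_uM, counts, replicate], manifest).
    """
    if cv < 0:
        raise ParameterError("cv must be nonnegative")
    if concentrations is None:
        concentrations = DEFAULT_CONCENTRATIONS
    x = np.asarray(list(concentrations), dtype=float)
    if np.any(x <= 0):
        raise ParameterError("concentrations must be positive")
    rng = np.random.default_rng(seed)
    model = c_min + (c_max - c_min) / (1.0 + x / ic50)
    rows = []
    for rep in range(replicates):
        if noise == "cv":
            counts = np.maximum(model * (1.0 + rng.normal(0.0, cv, size=x.size)), 0.0)
        elif noise == "poisson":
            counts = rng.poisson(model).astype(float)
        else:
            raise ParameterError(f"unknown noise model {noise!r}")
        for xi, ci in zip(x, counts):
            rows.append({"concentration_uM": xi, "counts": ci, "replicate": rep})
    df = pd.DataFrame(rows)
    manifest = {
        "generator": "dose_response",
        "seed": seed,
        "true": {"ic50": ic50, "c_max": c_max, "c_min": c_min},
        "cv": cv,
        "noise": noise,
        "replicates": replicates,
        "concentrations": list(map(float, x)),
    }
    return df, manifest


def mixture_truncated_cdf(x, mu1, sigma1, mu2, sigma2, w2, window):
    """CDF of the two-component normal mixture truncated to *window*."""
    lo, hi = window
    comp = lambda q: (1 - w2) * stats.norm.cdf(q, mu1, sigma1) + w2 * stats.norm.cdf(
        q, mu2, sigma2
    )
    mass = comp(hi) - comp(lo)
    xx = np.clip(np.asarray(x, dtype=float), lo, hi)
    return (comp(xx) - comp(lo)) / mass


def gen_contact_distances(
    n: int,
    mu1: float = 3.34,
    sigma1: float = 0.28,
    mu2: float = 2.90,
    sigma2: float = 0.04,
    w2: float = 0.15,
    window: tuple[float, float] = (2.5, 4.0),
    seed: int = 0,
):
    """Draw contact distances from the truncated survey mixture.

    Defaults emulate the crystallographic survey: an 85/15 superposition
    of the broad van der Waals population and the narrow halogen-bond
    population, truncated to the 2.5–4.0 Å scan window.
    """
    if not 0 <= w2 <= 1:
        raise ParameterError("w2 must lie in [0, 1]")
    lo, hi = window
    if not lo < hi:
        raise ParameterError("window must satisfy lo < hi")
    comp = lambda q: (1 - w2) * stats.norm.cdf(q, mu1, sigma1) + w2 * stats.norm.cdf(
        q, mu2, sigma2
    )
    mass = comp(hi) - comp(lo)
    if mass < 1e-9:
        raise ParameterError("mixture has (near-)zero mass inside the window")
    rng = np.random.default_rng(seed)
    out = np.empty(0)
    while out.size < n:
        m = max(int((n - out.size) / mass * 1.2) + 16, 32)
        which = rng.random(m) < w2
        draw = np.where(
            which, rng.normal(mu2, sigma2, m), rng.normal(mu1, sigma1, m)
        )
        out = np.concatenate([out, draw[(draw >= lo) & (draw <= hi)]])
    distances = out[:n]
    manifest = {
        "generator": "contact_distances",
        "seed": seed,
        "n": n,
        "true": {"mu1": mu1, "sigma1": sigma1, "mu2": mu2, "sigma2": sigma2, "w2": w2},
        "window": [lo, hi],
    }
    return distances, manifest


# ---------------------------------------------------------------------------
# synthetic complexes

_ACCEPTOR_BOND = {
    AcceptorClass.BACKBONE_CARBONYL_O: 1.23,
    AcceptorClass.SIDECHAIN_O: 1.42,
    AcceptorClass.SIDECHAIN_N: 1.47,
    AcceptorClass.SIDECHAIN_S: 1.78,  # kept inside the scanner's 1.8 Å anchor ceiling
}


def _pdb_line(record, serial, name, resname, chain, resnum, xyz, element):
    nm = name if len(name) >= 4 else f" {name:<3s}"
    return (
        f"{record:<6s}{serial:>5d} {nm:<4s}{resname:>4s} {chain}{resnum:>4d}    "
        f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}{1.00:6.2f}{0.00:6.2f}"
        f"          {element:>2s}"
    )


def _rot2d(v, deg):
    """Rotate the xy-components of a 3-vector by *deg* degrees."""
    th = math.radians(deg)
    c, s = math.cos(th), math.sin(th)
    return np.array([c * v[0] - s * v[1], s * v[0] + c * v[1], v[2]])


class _Builder:
    def __init__(self):
        self.lines = []
        self.serial = 0
        self.resnum = 0
        self.halogen_xyz = []

    def atom(self, record, name, resname, chain, resnum, xyz, element):
        # quantize to the PDB's 3-decimal coordinate precision so the
        # in-memory geometry equals the parsed text bit-for-bit
        xyz = np.round(np.asarray(xyz, dtype=float), 3) + 0.0
        self.serial += 1
        self.lines.append(
            _pdb_line(record, self.serial, name, resname, chain, resnum, xyz, element)
        )
        return xyz

    def next_resnum(self):
        self.resnum += 1
        return self.resnum


def _chain_away(builder, start, x_origin, names, resname, chain, resnum, elements, bond=1.52):
    """Place a chain of atoms stepping radially away from the halogen."""
    prev = np.asarray(start, dtype=float)
    placed = []
    for name, elem in zip(names, elements):
        direction = prev - x_origin
        nrm = np.linalg.norm(direction)
        direction = direction / nrm if nrm > 0 else np.array([1.0, 0.0, 0.0])
        prev = prev + bond * direction
        builder.atom("ATOM", name, resname, chain, resnum, prev, elem)
        placed.append(prev)
    return placed


def build_synthetic_complex(
    planted: Sequence[tuple], seed: int = 0, decoys: int = 2
):
    """Emit PDB text with halogen–acceptor contacts at exact geometry.

    Each planted contact is (d, theta_cxa, theta_xac, acceptor_class)
    with d the Br…acceptor distance in Å, theta_cxa the C–X…Acc angle
    and theta_xac the X…Acc–C angle in degrees (pass None for water/pi
    acceptors, whose anchor angle is undefined).  Contacts are built in
    well-separated clusters so each is recovered independently; decoy
    waters are placed beyond 4.5 Å of every halogen.

    Returns (pdb_text, manifest); the manifest's planted list is what
    the contact scanner must reproduce exactly.
    """
    rng = np.random.default_rng(seed)
    b = _Builder()
    manifest_planted = []
    ligand_resnum = 9000
    for k, spec in enumerate(planted):
        d, theta_cxa, theta_xac, acc_class = spec
        if isinstance(acc_class, str):
            acc_class = AcceptorClass(acc_class)
        if d <= 1.5:
            raise ConstructionError(f"contact {k}: distance {d} not realizable (need > 1.5 Å)")
        if not 0.0 < theta_cxa < 180.0:
            raise ConstructionError(f"contact {k}: theta_cxa must lie in (0, 180)")
        anchored = acc_class in _ACCEPTOR_BOND
        if anchored:
            if theta_xac is None or not 0.0 < theta_xac < 180.0:
                raise ConstructionError(f"contact {k}: theta_xac must lie in (0, 180)")
        elif theta_xac is not None:
            raise ConstructionError(
                f"contact {k}: theta_xac undefined for {acc_class.value} acceptors"
            )

        off = np.array([40.0 * k, 0.0, 0.0])
        x_pos = off  # halogen
        c_pos = off + np.array([1.90, 0.0, 0.0])
        # acceptor on the ray making theta_cxa with X->C at the halogen
        acc_dir = _rot2d(np.array([1.0, 0.0, 0.0]), theta_cxa)
        a_pos = x_pos + d * acc_dir

        # ligand: one Br + its carbon per cluster, single hetero residue each
        x_q = b.atom("HETATM", f"BR{k + 1}", "LIG", "L", ligand_resnum + k, x_pos, "BR")
        c_q = b.atom("HETATM", f"C{k + 1}", "LIG", "L", ligand_resnum + k, c_pos, "C")

        chain = "A"
        resnum = k + 1
        anchor = anchor_q = None
        if anchored:
            u = (x_pos - a_pos) / d  # acceptor -> halogen
            w = np.array([-u[1], u[0], 0.0])
            bond = _ACCEPTOR_BOND[acc_class]
            th = math.radians(theta_xac)
            anchor = a_pos + bond * (math.cos(th) * u + math.sin(th) * w)
        if acc_class is AcceptorClass.BACKBONE_CARBONYL_O:
            a_q = b.atom("ATOM", "O", "GLY", chain, resnum, a_pos, "O")
            anchor_q = b.atom("ATOM", "C", "GLY", chain, resnum, anchor, "C")
            _chain_away(b, anchor, x_pos, ["CA", "N"], "GLY", chain, resnum, ["C", "N"])
        elif acc_class is AcceptorClass.SIDECHAIN_O:
            a_q = b.atom("ATOM", "OG", "SER", chain, resnum, a_pos, "O")
            anchor_q = b.atom("ATOM", "CB", "SER", chain, resnum, anchor, "C")
            _chain_away(
                b, anchor, x_pos, ["CA", "C", "O", "N"], "SER", chain, resnum,
                ["C", "C", "O", "N"], bond=1.9,
            )
        elif acc_class is AcceptorClass.SIDECHAIN_N:
            a_q = b.atom("ATOM", "NZ", "LYS", chain, resnum, a_pos, "N")
            anchor_q = b.atom("ATOM", "CE", "LYS", chain, resnum, anchor, "C")
            _chain_away(
                b, anchor, x_pos, ["CD", "CG", "CB", "CA", "C", "O", "N"], "LYS",
                chain, resnum, ["C", "C", "C", "C", "C", "O", "N"], bond=1.9,
            )
        elif acc_class is AcceptorClass.SIDECHAIN_S:
            a_q = b.atom("ATOM", "SG", "CYS", chain, resnum, a_pos, "S")
            anchor_q = b.atom("ATOM", "CB", "CYS", chain, resnum, anchor, "C")
            _chain_away(
                b, anchor, x_pos, ["CA", "C", "O", "N"], "CYS", chain, resnum,
                ["C", "C", "O", "N"], bond=1.9,
            )
        elif acc_class is AcceptorClass.WATER_O:
            wat_num = 500 + k
            a_q = b.atom("HETATM", "O", "HOH", "W", wat_num, a_pos, "O")
        elif acc_class is AcceptorClass.PI_SYSTEM:
            # Phe ring, centroid at the planted position, face-on to the halogen
            axis = (a_pos - x_pos) / d
            e1 = np.cross(axis, [0.0, 0.0, 1.0])
            if np.linalg.norm(e1) < 1e-8:
                e1 = np.cross(axis, [0.0, 1.0, 0.0])
            e1 /= np.linalg.norm(e1)
            e2 = np.cross(axis, e1)
            ring_names = ["CG", "CD1", "CE1", "CZ", "CE2", "CD2"]
            ring_q = []
            for j, nm in enumerate(ring_names):
                ang = math.radians(60.0 * j)
                pos = a_pos + 1.39 * (math.cos(ang) * e1 + math.sin(ang) * e2)
                ring_q.append(b.atom("ATOM", nm, "PHE", chain, resnum, pos, "C"))
            a_q = np.mean(ring_q, axis=0)  # centroid of the quantized ring
            cg = a_pos + 1.39 * e1
            _chain_away(
                b, cg, x_pos, ["CB", "CA", "C", "O", "N"], "PHE", chain, resnum,
                ["C", "C", "C", "O", "N"], bond=1.9,
            )
        else:  # pragma: no cover
            raise ConstructionError(f"unsupported acceptor class {acc_class}")

        # achieved geometry after coordinate quantization: this is what the
        # scanner must reproduce exactly
        d_ach = float(np.linalg.norm(x_q - a_q))
        cxa_ach = compute_angle(c_q, x_q, a_q)
        xac_ach = compute_angle(x_q, a_q, anchor_q) if anchor_q is not None else None
        manifest_planted.append(
            {
                "d": d_ach,
                "theta_cxa": float(cxa_ach),
                "theta_xac": None if xac_ach is None else float(xac_ach),
                "acceptor_class": acc_class.value,
                "requested": {
                    "d": float(d),
                    "theta_cxa": float(theta_cxa),
                    "theta_xac": None if theta_xac is None else float(theta_xac),
                },
            }
        )

    # decoy waters well clear of every halogen
    n_halogens = max(len(planted), 1)
    for j in range(decoys):
        base = np.array([40.0 * rng.integers(0, n_halogens), -12.0 - 3.0 * j, 8.0])
        jitter = rng.uniform(-1.0, 1.0, 3)
        b.atom("HETATM", "O", "HOH", "W", 800 + j, base + jitter, "O")

    text = "\n".join(b.lines + ["END"]) + "\n"
    manifest = {
        "generator": "synthetic_complex",
        "seed": seed,
        "planted": manifest_planted,
        "n_atoms": b.serial,
        "ligand_resnames": ["LIG"],
    }
    return text, manifest


def build_synthetic_ck2_complex():
    """Synthetic stand-in for the kinase–tetrabromobenzotriazole complex.

    This is a constructed miniature, not a crystal structure: a planar
    tetrabromo-benzotriazole-like ligand whose triazole N–N bonds are
    built at exactly 1.242 and 1.419 Å (the asymmetry diagnostic of the
    neutral protomer), plus an arginine side-chain fragment whose Nε sits
    exactly 2.99 Å from a peripheral bromine — the short Br…Nε contact
    geometry reported for the real complex.  It exercises the same
    parsing/scanning/measurement path a real structure would.

    Returns (pdb_text, manifest).
    """
    b = _Builder()
    r = 1.39  # aromatic ring radius
    center = np.zeros(3)
    # benzene ring: C3A, C4, C5, C6, C7, C7A anticlockwise, fused bond on top
    names = ["C3A", "C4", "C5", "C6", "C7", "C7A"]
    angles = [60.0, 0.0, -60.0, -120.0, -180.0, -240.0]
    ring = {}
    for nm, ang in zip(names, angles):
        th = math.radians(ang)
        ring[nm] = center + np.array([r * math.cos(th), r * math.sin(th), 0.0])
    # triazole: N3 on C3A, N1 on C7A, N2 at the circle intersection giving
    # the exact 1.242 / 1.419 Å N-N bond lengths
    def _out(nm, dist):
        p = ring[nm]
        d = p - center
        return p + dist * d / np.linalg.norm(d)

    # N1/N3 bond directions are bent toward each other so the pentagon
    # closes: |N1-N3| = 2.15 Å leaves room for both N-N bonds
    half_sep = 2.15 / 2.0
    bend = math.degrees(math.acos((half_sep - r * math.cos(math.radians(60.0))) / 1.37))
    n3 = ring["C3A"] + 1.37 * np.array(
        [math.cos(math.radians(bend)), math.sin(math.radians(bend)), 0.0]
    )
    n1 = ring["C7A"] + 1.37 * np.array(
        [math.cos(math.radians(180.0 - bend)), math.sin(math.radians(180.0 - bend)), 0.0]
    )
    # place N2 so that |N2-N1| = 1.242 and |N2-N3| = 1.419
    d12, d23 = 1.242, 1.419
    base = n3 - n1
    dd = np.linalg.norm(base)
    ex = base / dd
    ey = np.array([-ex[1], ex[0], 0.0])
    ax = (d12**2 - d23**2 + dd**2) / (2 * dd)
    h = math.sqrt(max(d12**2 - ax**2, 0.0))
    # choose the intersection pointing away from the benzene ring
    cand1 = n1 + ax * ex + h * ey
    cand2 = n1 + ax * ex - h * ey
    n2 = cand1 if np.linalg.norm(cand1 - center) > np.linalg.norm(cand2 - center) else cand2

    resnum = 501
    for nm in names:
        b.atom("HETATM", nm, "TBT", "L", resnum, ring[nm], "C")
    n1_q = b.atom("HETATM", "N1", "TBT", "L", resnum, n1, "N")
    n2_q = b.atom("HETATM", "N2", "TBT", "L", resnum, n2, "N")
    n3_q = b.atom("HETATM", "N3", "TBT", "L", resnum, n3, "N")
    br = {}
    for i, nm in enumerate(["C4", "C5", "C6", "C7"]):
        pos = _out(nm, 1.88)
        br[nm] = b.atom("HETATM", f"BR{i + 4}", "TBT", "L", resnum, pos, "BR")

    # arginine fragment: Nε exactly 2.99 Å from the peripheral Br on C7
    target_br = br["C7"]
    direction = (target_br - center) / np.linalg.norm(target_br - center)
    ne = target_br + 2.99 * direction
    cd = ne + 1.46 * _rot2d(direction, 140.0)
    cz = ne + 1.33 * _rot2d(direction, -35.0)
    nh1 = cz + 1.33 * _rot2d(direction, -80.0)
    nh2 = cz + 1.33 * _rot2d(direction, 10.0)
    ne_q = b.atom("ATOM", "NE", "ARG", "A", 47, ne, "N")
    b.atom("ATOM", "CD", "ARG", "A", 47, cd, "C")
    b.atom("ATOM", "CZ", "ARG", "A", 47, cz, "C")
    b.atom("ATOM", "NH1", "ARG", "A", 47, nh1, "N")
    b.atom("ATOM", "NH2", "ARG", "A", 47, nh2, "N")
    _chain_away(b, cd, target_br, ["CG", "CB", "CA", "C", "O", "N"], "ARG", "A", 47,
                ["C", "C", "C", "C", "O", "N"], bond=1.9)

    text = "\n".join(b.lines + ["END"]) + "\n"
    manifest = {
        "generator": "synthetic_ck2_complex",
        "planted": {
            "br_ne_distance": 2.99,
            "nn_bonds": [1.242, 1.419],
            "ligand_resname": "TBT",
            "n_bromines": 4,
        },
        "achieved": {
            "br_ne_distance": float(np.linalg.norm(br["C7"] - ne_q)),
            "nn_bonds": [
                float(np.linalg.norm(n1_q - n2_q)),
                float(np.linalg.norm(n2_q - n3_q)),
            ],
        },
        "n_atoms": b.serial,
    }
    return text, manifest


def gen_qsar_table(
    n: int,
    coefficients: Optional[dict] = None,
    noise_sd: float = 0.0,
    seed: int = 0,
    descriptors: Sequence[str] = ("Vmol", "pKa"),
):
    """Descriptor table with a known linear activity relationship.

    Descriptors are drawn uniformly over the ranges spanned by the
    measured benzotriazole series; the response is
    intercept + Σ coef·descriptor + N(0, noise_sd²).
    """
    if n < 5:
        raise ParameterError("need n >= 5 compounds")
    if coefficients is None:
        coefficients = {"intercept": 30.0, "Vmol": -0.12, "pKa": -2.1}
    rng = np.random.default_rng(seed)
    data = {}
    for dsc in descriptors:
        lo, hi = _DESCRIPTOR_RANGES[dsc]
        data[dsc] = rng.uniform(lo, hi, n)
    df = pd.DataFrame(data, index=[f"cpd{i + 1:02d}" for i in range(n)])
    y = np.full(n, float(coefficients.get("intercept", 0.0)))
    for dsc in descriptors:
        y = y + coefficients.get(dsc, 0.0) * df[dsc].values
    y = y + rng.normal(0.0, noise_sd, n)
    df["log_ic50"] = y
    manifest = {
        "generator": "qsar_table",
        "seed": seed,
        "n": n,
        "true": dict(coefficients),
        "noise_sd": noise_sd,
        "descriptors": list(descriptors),
    }
    return df, manifest
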