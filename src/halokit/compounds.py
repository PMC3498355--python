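"""The brominated-benzotriazole compound table.

Ten benzotriazole (Bt) derivatives — the parent, two mono-, four di-, two
tri-bromo isomers and tetrabromobenzotriazole (TBBt) — with measured acid
dissociation constants (pKa of the triazole N–H proton), aqueous
solubilities, CK2α inhibitory activities (IC50), computed molecular
volumes, ab initio free energies of proton dissociation and anion
solvation, docking-derived binding free energies, and MD mobility metrics.

The parent Bt is inactive; its IC50 is a lower bound (> 2000 µM) and is
stored with ``ic50_censored = True`` so downstream models must choose an
explicit censoring policy.
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from importlib import resources

import pandas as pd

__all__ = ["CompoundRecord", "load_table1", "read_compound_tsv", "write_compound_tsv"]

_COLUMNS = [
    "ligand",
    "pKa",
    "Cw_M",
    "IC50_uM",
    "IC50_sd_uM",
    "IC50_censored",
    "Vmol_A3",
    "dG_diss_kcal",
    "dG_solv_anion_kcal",
    "dG_bind_neutral_kcal",
    "dG_bind_anion_kcal",
    "RMSF_A",
    "RMSD_A",
]


@dataclass(frozen=True)
class CompoundRecord:
    """One compound: physicochemical descriptors plus inhibitory activity.

    Units: ``Cw`` mol/L, ``ic50`` µM, ``Vmol`` Å³, free energies kcal/mol,
    RMSF/RMSD Å.  ``ic50_censored`` marks an activity reported only as a
    lower bound, with ``ic50`` holding that bound.
    """

    name: str
    pKa: float
    Cw: float
    ic50: float
    ic50_sd: float
    ic50_censored: bool
    Vmol: float
    dG_diss: float
    dG_solv_anion: float
    dG_bind_neutral: float
    dG_bind_anion: float
    rmsf: float
    rmsd: float

    def __post_init__(self) -> None:
        if self.ic50 <= 0:
            raise ValueError(f"{self.name}: ic50 must be positive")
        if self.Vmol <= 0:
            raise ValueError(f"{self.name}: Vmol must be positive")
        if self.Cw <= 0:
            raise ValueError(f"{self.name}: Cw must be positive")
        if not 0 < self.pKa < 14:
            raise ValueError(f"{self.name}: pKa outside (0, 14)")


def _records_from_frame(df: pd.DataFrame) -> list[CompoundRecord]:
    recs = []
    for row in df.itertuples(index=False):
        recs.append(
            CompoundRecord(
                name=row.ligand,
                pKa=float(row.pKa),
                Cw=float(row.Cw_M),
                ic50=float(row.IC50_uM),
                ic50_sd=float(row.IC50_sd_uM),
                ic50_censored=bool(int(row.IC50_censored)),
                Vmol=float(row.Vmol_A3),
                dG_diss=float(row.dG_diss_kcal),
                dG_solv_anion=float(row.dG_solv_anion_kcal),
                dG_bind_neutral=float(row.dG_bind_neutral_kcal),
                dG_bind_anion=float(row.dG_bind_anion_kcal),
                rmsf=float(row.RMSF_A),
                rmsd=float(row.RMSD_A),
            )
        )
    return recs


def read_compound_tsv(path) -> list[CompoundRecord]:
    """Read a compound table from TSV (same schema as the packaged fixture)."""
    df = pd.read_csv(path, sep="\t")
    missing = set(_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"compound table missing columns: {sorted(missing)}")
    return _records_from_frame(df)


def write_compound_tsv(records: list[CompoundRecord], path) -> None:
    """Write compound records as TSV, round-trippable with `read_compound_tsv`."""
    rows = []
    for r in records:
        rows.append(
            {
                "ligand": r.name,
                "pKa": r.pKa,
                "Cw_M": r.Cw,
                "IC50_uM": r.ic50,
                "IC50_sd_uM": r.ic50_sd,
                "IC50_censored": int(r.ic50_censored),
                "Vmol_A3": r.Vmol,
                "dG_diss_kcal": r.dG_diss,
                "dG_solv_anion_kcal": r.dG_solv_anion,
                "dG_bind_neutral_kcal": r.dG_bind_neutral,
                "dG_bind_anion_kcal": r.dG_bind_anion,
                "RMSF_A": r.rmsf,
                "RMSD_A": r.rmsd,
            }
        )
    pd.DataFrame(rows, columns=_COLUMNS).to_csv(path, sep="\t", index=False)


def load_table1() -> list[CompoundRecord]:
    """Load the packaged 10-compound benzotriazole descriptor/activity table.

    Returns the records in the canonical row order (Bt first, TBBt last),
    with the parent Bt carrying ``ic50_censored = True`` and its 2000 µM
    lower bound in ``ic50``.
    """
    with resources.files("halokit.data").joinpath("table1.tsv").open() as fh:
        records = read_compound_tsv(fh)
    if len(records) != 10:
        raise RuntimeError(f"compound fixture corrupted: {len(records)} records, expected 10")
    names = [r.name for r in records]
    if len(set(names)) != 10:
        raise RuntimeError("compound fixture corrupted: duplicate names")
    if not records[0].ic50_censored or any(r.ic50_censored for r in records[1:]):
        raise RuntimeError("compound fixture corrupted: censoring flags")
    return records


def as_frame(records: list[CompoundRecord]) -> pd.DataFrame:
    """Compound records as a DataFrame indexed by name."""
    df = pd.DataFrame([{f.name: getattr(r, f.name) for f in fields(r)} for r in records])
    return df.set_index("name")
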