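"""Packaged printed-table fixtures: class totals, per-class DBI, fatty acids.

Three published summary tables from a two-cultivar rice cold-stress
lipidome comparison ship with the package as TSVs: per-class
concentrations (nmol g⁻¹ FW), per-class double-bond index, and the 16
free-fatty-acid species. Each stores, per genotype×treatment cell, the
printed mean, SD and post-hoc letter, plus the printed percent relative
change (RC) per genotype. Values are transcribed as printed; the source
tables contain occasional last-digit inconsistencies between each other
(e.g. the FA class row vs the TFA row) which are preserved, not
reconciled.

The helpers below turn table columns into in-memory objects: a cell's
class means become a single pseudo-replicate ``LipidomeSample`` with one
representative species per class, and the fatty-acid table becomes an
FA-species → amount map.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .metrics import LipidomeSample
from .nomenclature import SpeciesDescriptor, parse_species

__all__ = [
    "CELLS",
    "CELL_PREFIX",
    "lipid_class_table",
    "dbi_table",
    "fatty_acid_table",
    "class_mean_sample",
    "fa_mean_amounts",
]

#: (genotype, treatment) cells in table column order.
CELLS: tuple[tuple[str, str], ...] = (
    ("KY131", "control"),
    ("KY131", "cold"),
    ("DN422", "control"),
    ("DN422", "cold"),
)

#: Column prefix per cell, e.g. ky_control_mean / ky_control_sd / ky_control_letter.
CELL_PREFIX: dict[tuple[str, str], str] = {
    ("KY131", "control"): "ky_control",
    ("KY131", "cold"): "ky_cold",
    ("DN422", "control"): "dn_control",
    ("DN422", "cold"): "dn_cold",
}

# one arbitrary but fixed representative species per class, used when a
# table row carries only a class total (the C:DB of the stand-in does not
# enter any class-level statistic)
_REPRESENTATIVE = {
    "MGDG": "MGDG 34:3", "DGDG": "DGDG 36:6", "SQDG": "SQDG 34:3",
    "PA": "PA 34:2", "PC": "PC 36:4", "PE": "PE 36:4", "PG": "PG 34:2",
    "PI": "PI 34:2", "PMeOH": "PMeOH 36:4", "LPE": "LPE 18:1",
    "LPC": "LPC 18:2", "DG": "DG 36:6", "TG": "TG 54:9", "FA": "FA 18:3",
}


def _load(name: str) -> pd.DataFrame:
    with resources.files("coldomics.data").joinpath(name).open("r") as fh:
        return pd.read_csv(fh, sep="\t", keep_default_na=False, na_values=[])


def lipid_class_table() -> pd.DataFrame:
    """Per-class concentration table (14 classes + Total row)."""
    return _load("class_concentrations.tsv")


def dbi_table() -> pd.DataFrame:
    """Per-class double-bond index table (14 classes + Total row)."""
    return _load("class_dbi.tsv")


def fatty_acid_table() -> pd.DataFrame:
    """Free-fatty-acid species table (16 species + TFA/UFA/SFA/UFA:SFA rows)."""
    return _load("fatty_acids.tsv")


def class_mean_sample(genotype: str, treatment: str) -> LipidomeSample:
    """One cell's printed class means as a single pseudo-replicate sample."""
    prefix = CELL_PREFIX[(genotype, treatment)]
    df = lipid_class_table()
    conc = {
        parse_species(_REPRESENTATIVE[row["lipid_class"]]): float(row[f"{prefix}_mean"])
        for _, row in df.iterrows()
        if row["lipid_class"] != "Total"
    }
    return LipidomeSample(
        sample_id=f"{prefix}_means",
        genotype=genotype,
        treatment=treatment,
        replicate=1,
        concentrations=conc,
    )


def fa_mean_amounts(genotype: str, treatment: str) -> dict[SpeciesDescriptor, float]:
    """One cell's printed FA-species means as a species → amount map."""
    prefix = CELL_PREFIX[(genotype, treatment)]
    df = fatty_acid_table()
    summary_rows = {"TFA", "UFA", "SFA", "UFA/SFA"}
    return {
        parse_species(row["fatty_acid"]): float(row[f"{prefix}_mean"])
        for _, row in df.iterrows()
        if row["fatty_acid"] not in summary_rows
    }
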