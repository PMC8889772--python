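"""Per-sample lipidome aggregation statistics.

Implements the table arithmetic of a class-resolved membrane lipidome:
class and category totals (nmol g⁻¹ FW), mol-percent composition, the
double-bond index (DBI), percent relative change between treatment means,
and the free-fatty-acid saturation summary (TFA/UFA/SFA and their ratio).

DBI conventions
---------------
The double-bond index weights each species' double-bond count N by its
mol % and sums:  DBI = Σ N × mol%.  Two knobs are exposed:

* ``scope`` — the mol-% denominator: ``"total"`` (whole lipidome) or
  ``"within_class"`` (each class renormalised to 100).
* ``scale`` — ``"per_formula"`` divides the sum by 100, giving the mean
  number of double bonds per molecule; ``"table_magnitude"`` leaves it
  undivided, matching the convention under which published per-class DBI
  values add up to the published total (~100× the per-molecule mean).

The default ``(scope="total", scale="table_magnitude")`` makes the total
DBI exactly additive over classes. The total DBI reported under
``within_class`` scope is still computed with whole-lipidome mol % so it
remains a property of the whole sample (within-class percentages do not
aggregate).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping

from .nomenclature import (
    CATEGORY_CLASSES,
    LIPID_CLASSES,
    LipidCategory,
    SpeciesDescriptor,
)

__all__ = [
    "LipidomeSample",
    "ClassProfile",
    "MolFractionTable",
    "DBIProfile",
    "FattyAcidSummary",
    "UndefinedStatisticError",
    "class_totals",
    "mol_percent",
    "dbi",
    "relative_change",
    "fatty_acid_summary",
    "category_fraction",
    "dg_tg_ratio",
]

logger = logging.getLogger(__name__)

SCOPES = ("total", "within_class")
SCALES = ("per_formula", "table_magnitude")


class UndefinedStatisticError(ValueError):
    """A statistic's denominator is zero or a precondition fails."""


@dataclass
class LipidomeSample:
    """One replicate: species → concentration (nmol g⁻¹ FW) plus labels."""

    sample_id: str
    genotype: str
    treatment: str
    replicate: int
    concentrations: dict[SpeciesDescriptor, float]

    def __post_init__(self) -> None:
        if not self.concentrations:
            raise ValueError(f"sample {self.sample_id!r}: at least one species required")
        for sp, amt in self.concentrations.items():
            if amt < 0 or not math.isfinite(amt):
                raise ValueError(
                    f"sample {self.sample_id!r}: negative or non-finite amount "
                    f"{amt} for {sp}"
                )


@dataclass
class ClassProfile:
    """Per-class total concentration and the grand total."""

    per_class: dict[str, float]
    grand_total: float


@dataclass
class MolFractionTable:
    """Per-species mol % under a named denominator scope."""

    fractions: dict[SpeciesDescriptor, float]
    scope: str


@dataclass
class DBIProfile:
    """Per-class and total double-bond index under a stated convention."""

    per_class: dict[str, float]
    total: float
    scope: str
    scale: str


@dataclass
class FattyAcidSummary:
    """Free fatty acid pools: total, unsaturated, saturated, and their ratio.

    ``ratio`` is NaN (``ratio_defined=False``) when SFA is zero.
    """

    tfa: float
    ufa: float
    sfa: float
    ratio: float = field(default=math.nan)
    ratio_defined: bool = field(default=True)


def class_totals(sample: LipidomeSample) -> ClassProfile:
    """Sum species concentrations into the 14 class totals and a grand total.

    Classes with no species in the sample report 0 (a fixed panel with a
    missing class is a real analytical outcome, not an error).
    """
    totals = {code: 0.0 for code in LIPID_CLASSES}
    for sp, amt in sample.concentrations.items():
        totals[sp.class_code] += amt
    return ClassProfile(per_class=totals, grand_total=sum(totals.values()))


def mol_percent(sample: LipidomeSample, scope: str = "total") -> MolFractionTable:
    """Per-species mol %: 100 × amount / denominator.

    ``scope="total"`` divides by the grand total; ``scope="within_class"``
    divides each species by its own class total, so each non-empty class
    sums to 100.
    """
    _check_enum("scope", scope, SCOPES)
    profile = class_totals(sample)
    fractions: dict[SpeciesDescriptor, float] = {}
    if scope == "total":
        if profile.grand_total <= 0:
            raise UndefinedStatisticError(
                f"empty denominator scope 'total' in sample {sample.sample_id!r}"
            )
        for sp, amt in sample.concentrations.items():
            fractions[sp] = 100.0 * amt / profile.grand_total
    else:
        for sp, amt in sample.concentrations.items():
            denom = profile.per_class[sp.class_code]
            if denom <= 0:
                raise UndefinedStatisticError(
                    f"empty denominator scope 'within_class' for class "
                    f"{sp.class_code} in sample {sample.sample_id!r}"
                )
            fractions[sp] = 100.0 * amt / denom
    return MolFractionTable(fractions=fractions, scope=scope)


def dbi(
    sample: LipidomeSample,
    scope: str = "total",
    scale: str = "table_magnitude",
) -> DBIProfile:
    """Double-bond index per class and overall: Σ N × mol % (÷100 if per_formula).

    Under the default ``(total, table_magnitude)`` convention the total is
    exactly the sum of the per-class values. The total under
    ``within_class`` scope always uses whole-lipidome mol %, so it equals
    the total-scope total on the same scale.
    """
    _check_enum("scope", scope, SCOPES)
    _check_enum("scale", scale, SCALES)
    fr = mol_percent(sample, scope=scope)
    fr_total = fr if scope == "total" else mol_percent(sample, scope="total")
    divisor = 100.0 if scale == "per_formula" else 1.0

    per_class = {code: 0.0 for code in LIPID_CLASSES}
    for sp, pct in fr.fractions.items():
        per_class[sp.class_code] += sp.double_bonds * pct
    per_class = {c: v / divisor for c, v in per_class.items()}
    total = sum(sp.double_bonds * pct for sp, pct in fr_total.fractions.items()) / divisor
    return DBIProfile(per_class=per_class, total=total, scope=scope, scale=scale)


def relative_change(control_mean: float, treated_mean: float) -> float:
    """Percent relative change: 100 × (treated − control) / control."""
    if control_mean == 0:
        raise UndefinedStatisticError("undefined relative change: control mean is zero")
    return 100.0 * (treated_mean - control_mean) / control_mean


def fatty_acid_summary(fa_amounts: Mapping[SpeciesDescriptor, float]) -> FattyAcidSummary:
    """TFA / UFA / SFA pools and the UFA:SFA ratio from FA-class amounts.

    UFA collects species with ≥ 1 double bond, SFA the fully saturated
    ones; TFA is their sum. A zero SFA pool flags the ratio undefined
    rather than raising.
    """
    tfa = ufa = sfa = 0.0
    for sp, amt in fa_amounts.items():
        if sp.class_code != "FA":
            raise ValueError(
                f"fatty_acid_summary expects only FA-class species, got {sp}"
            )
        tfa += amt
        if sp.double_bonds == 0:
            sfa += amt
        else:
            ufa += amt
    if sfa > 0:
        return FattyAcidSummary(tfa=tfa, ufa=ufa, sfa=sfa, ratio=ufa / sfa)
    logger.warning("SFA pool is zero; UFA/SFA ratio undefined")
    return FattyAcidSummary(tfa=tfa, ufa=ufa, sfa=sfa, ratio=math.nan, ratio_defined=False)


def category_fraction(sample: LipidomeSample, category: str | LipidCategory) -> float:
    """Percent of total lipid carried by one head-group category."""
    try:
        cat = LipidCategory(category)
    except ValueError:
        raise ValueError(f"unknown lipid category: {category!r}") from None
    profile = class_totals(sample)
    if profile.grand_total <= 0:
        raise UndefinedStatisticError(
            f"empty denominator scope 'total' in sample {sample.sample_id!r}"
        )
    cat_sum = sum(profile.per_class[c] for c in CATEGORY_CLASSES[cat])
    return 100.0 * cat_sum / profile.grand_total


def dg_tg_ratio(sample: LipidomeSample) -> tuple[float, bool]:
    """DG:TG class-total ratio, an index of triacylglycerol turnover.

    Returns ``(ratio, defined)``; a zero TG pool yields ``(nan, False)``.
    """
    profile = class_totals(sample)
    tg = profile.per_class["TG"]
    if tg <= 0:
        logger.warning("TG total is zero; DG/TG ratio undefined")
        return math.nan, False
    return profile.per_class["DG"] / tg, True


def _check_enum(name: str, value: str, allowed: tuple[str, ...]) -> None:
    if value not in allowed:
        raise ValueError(f"{name} must be one of {allowed}, got {value!r}")
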