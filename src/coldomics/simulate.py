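"""Seeded synthetic-data generators for every pipeline input.

Two generators cover the pipeline's inputs so all stages are testable
without any external download:

* a species-level lipidome with class structure: per genotype×treatment
  cell, each species' replicate concentration is its cell mean times a
  mean-one log-normal factor (multiplicative replicate noise, matching
  positive concentrations with a few-percent CV);
* paired differential-expression result tables for two contrasts with
  planted common / contrast-exclusive / fold-change-ratio structure and a
  uniform-p null background, returned together with the ground truth.

All randomness flows from the explicit ``seed`` in each spec; there is no
hidden global state.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .fixtures import CELLS, lipid_class_table, CELL_PREFIX
from .genesets import DERecord
from .metrics import LipidomeSample
from .nomenclature import SpeciesDescriptor, parse_species

__all__ = [
    "LipidomeSimSpec",
    "DESimSpec",
    "DESimTruth",
    "default_species_panel",
    "table_based_sim_spec",
    "simulate_lipidome",
    "simulate_de_tables",
]

# species named in the source tables/text, always present in the panel
_NAMED = {
    "MGDG": ["MGDG 34:3", "MGDG 36:6"],
    "TG": ["TG 52:4", "TG 52:5", "TG 52:6", "TG 54:8", "TG 54:9"],
    "FA": [
        "FA 14:0", "FA 16:0", "FA 17:0", "FA 18:0", "FA 18:1", "FA 18:2",
        "FA 18:3", "FA 19:1", "FA 20:0", "FA 20:1", "FA 20:2", "FA 22:0",
        "FA 22:1", "FA 22:2", "FA 23:0", "FA 24:0",
    ],
}

# species per class; sums to 218, the panel size of the emulated platform
_PANEL_SIZES = {
    "MGDG": 20, "DGDG": 20, "SQDG": 12, "PA": 16, "PC": 24, "PE": 24,
    "PG": 16, "PI": 14, "PMeOH": 8, "LPE": 8, "LPC": 8, "DG": 18,
    "TG": 14, "FA": 16,
}

_CARBON_GRID = {
    1: (16, 18, 20, 22),          # lyso classes: one acyl chain
    2: (32, 34, 36, 38, 40),      # diacyl classes
    3: (48, 50, 52, 54, 56),      # triacyl (TG)
}


def default_species_panel() -> list[SpeciesDescriptor]:
    """The fixed 218-species synthetic panel.

    Species named in the packaged tables are included verbatim; each class
    is completed to its panel size with plausible C:DB combinations from a
    deterministic carbon/double-bond grid. The completion is synthetic —
    the full species list of the emulated platform is not published.
    """
    panel: list[SpeciesDescriptor] = []
    for code, size in _PANEL_SIZES.items():
        chosen = [parse_species(s) for s in _NAMED.get(code, [])]
        if code != "FA":
            n_chains = 3 if code == "TG" else (1 if code in ("LPE", "LPC") else 2)
            for carbons in _CARBON_GRID[n_chains]:
                for db in range(0, min(carbons, 3 * n_chains) + 1):
                    d = SpeciesDescriptor(code, carbons, db)
                    if d not in chosen:
                        chosen.append(d)
        panel.extend(chosen[:size])
    assert len(panel) == 218
    return panel


@dataclass
class LipidomeSimSpec:
    """Simulation design for a replicated genotype×treatment lipidome.

    ``cell_means`` maps each (genotype, treatment) cell to a species-mean
    vector aligned with ``panel``; replicate noise is log-normal with
    coefficient of variation ``cv`` and expectation equal to the mean.
    """

    panel: list[SpeciesDescriptor]
    cell_means: dict[tuple[str, str], np.ndarray]
    cv: float = 0.05
    n_replicates: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cv <= 0:
            raise ValueError(f"cv must be > 0, got {self.cv}")
        for cell, means in self.cell_means.items():
            means = np.asarray(means, dtype=float)
            if means.shape != (len(self.panel),):
                raise ValueError(f"cell {cell}: means must align with the panel")
            if np.any(means <= 0):
                raise ValueError(f"cell {cell}: species means must be > 0")
            self.cell_means[cell] = means


def table_based_sim_spec(
    seed: int = 0, cv: float = 0.05, n_replicates: int = 3
) -> LipidomeSimSpec:
    """Default simulation: the packaged class-total table spread over the panel.

    Each cell's printed class totals are distributed across that class's
    panel species with fixed geometrically decaying weights, so class and
    grand totals (in expectation) match the printed table while species
    structure stays synthetic.
    """
    panel = default_species_panel()
    table = lipid_class_table()
    table = table[table["lipid_class"] != "Total"]
    by_class: dict[str, list[int]] = {}
    for i, sp in enumerate(panel):
        by_class.setdefault(sp.class_code, []).append(i)

    cell_means: dict[tuple[str, str], np.ndarray] = {}
    for cell in CELLS:
        col = f"{CELL_PREFIX[cell]}_mean"
        means = np.empty(len(panel))
        for _, row in table.iterrows():
            idx = by_class[row["lipid_class"]]
            w = 0.7 ** np.arange(len(idx))
            means[idx] = float(row[col]) * w / w.sum()
        cell_means[cell] = means
    return LipidomeSimSpec(panel, cell_means, cv=cv, n_replicates=n_replicates, seed=seed)


def simulate_lipidome(spec: LipidomeSimSpec) -> list[LipidomeSample]:
    """Draw replicate samples for every cell of the design.

    Each amount is ``mean × exp(ε)`` with ``ε ~ Normal(−σ²/2, σ²)`` and
    ``σ² = log(1 + cv²)``, so E[amount] equals the specified mean exactly.
    """
    rng = np.random.default_rng(spec.seed)
    sigma = math.sqrt(math.log1p(spec.cv**2))
    samples: list[LipidomeSample] = []
    for (genotype, treatment), means in spec.cell_means.items():
        for rep in range(1, spec.n_replicates + 1):
            eps = rng.normal(-(sigma**2) / 2, sigma, size=len(spec.panel))
            amounts = means * np.exp(eps)
            samples.append(
                LipidomeSample(
                    sample_id=f"{genotype}_{treatment}_r{rep}",
                    genotype=genotype,
                    treatment=treatment,
                    replicate=rep,
                    concentrations=dict(zip(spec.panel, amounts.tolist())),
                )
            )
    return samples


@dataclass
class DESimSpec:
    """Simulation design for a pair of DE result tables.

    ``frac_de_a``/``frac_de_b`` set the planted-DEG fraction per contrast;
    ``frac_shared`` of the smaller planted set is common to both;
    ``frac_ratio`` of the shared (direction-concordant) genes receive a
    linear fold-change ratio ≥ ``ratio_min`` between contrasts, the rest a
    ratio in [1, ratio_min). Planted |log2fc| is drawn from a normal
    truncated below ``min_abs_log2fc``; null genes get small log2fc noise
    and Uniform(0, 1) FDR.
    """

    n_genes: int = 2000
    frac_de_a: float = 0.15
    frac_de_b: float = 0.12
    frac_shared: float = 0.6
    frac_ratio: float = 0.3
    frac_discordant: float = 0.0
    ratio_min: float = 1.5
    lfc_mean: float = 2.5
    lfc_sd: float = 0.6
    min_abs_log2fc: float = 1.0
    null_lfc_sd: float = 0.2
    planted_fdr_max: float = 0.04
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("frac_de_a", "frac_de_b", "frac_shared", "frac_ratio", "frac_discordant"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")


@dataclass
class DESimTruth:
    """Planted ground truth accompanying a simulated DE table pair."""

    de_a: frozenset[str]
    de_b: frozenset[str]
    common: frozenset[str]
    only_a: frozenset[str]
    only_b: frozenset[str]
    ratio_passed: frozenset[str]
    candidates: frozenset[str]
    discordant: frozenset[str]


def simulate_de_tables(
    spec: DESimSpec,
) -> tuple[list[DERecord], list[DERecord], DESimTruth]:
    """Generate two contrasts' DE records plus the planted truth labels."""
    rng = np.random.default_rng(spec.seed)
    genes = [f"g{i:05d}" for i in range(spec.n_genes)]
    n_a = int(round(spec.frac_de_a * spec.n_genes))
    n_b = int(round(spec.frac_de_b * spec.n_genes))
    n_shared = int(round(spec.frac_shared * min(n_a, n_b)))

    perm = rng.permutation(spec.n_genes)
    shared = [genes[i] for i in perm[:n_shared]]
    only_a = [genes[i] for i in perm[n_shared : n_shared + (n_a - n_shared)]]
    only_b = [genes[i] for i in perm[n_shared + (n_a - n_shared) : n_a + n_b - n_shared]]

    def planted_mag(size: int) -> np.ndarray:
        draw = rng.normal(spec.lfc_mean, spec.lfc_sd, size)
        return np.maximum(draw, spec.min_abs_log2fc + 0.1)

    def planted_fdr(size: int) -> np.ndarray:
        return rng.uniform(0.0, spec.planted_fdr_max, size)

    lfc_a: dict[str, float] = {}
    lfc_b: dict[str, float] = {}
    fdr_a: dict[str, float] = {}
    fdr_b: dict[str, float] = {}

    n_disc = int(round(spec.frac_discordant * n_shared))
    n_conc = n_shared - n_disc
    n_ratio = int(round(spec.frac_ratio * n_conc))
    log2_min = math.log2(spec.ratio_min)
    signs = rng.choice([-1.0, 1.0], size=n_shared)
    mag_b = planted_mag(n_shared)
    # ratio-planted genes: |lfc_a| exceeds |lfc_b| by >= log2(ratio_min)
    delta = np.empty(n_shared)
    delta[:n_ratio] = log2_min + np.abs(rng.normal(0.3, 0.2, n_ratio))
    delta[n_ratio:] = rng.uniform(0.0, 0.95 * log2_min, n_shared - n_ratio)
    ratio_genes = shared[:n_ratio]
    disc_genes = shared[n_conc:]
    for i, g in enumerate(shared):
        s = signs[i]
        lfc_b[g] = s * mag_b[i]
        lfc_a[g] = (-s if g in disc_genes else s) * (mag_b[i] + delta[i])
        fdr_a[g], fdr_b[g] = planted_fdr(2)
    for g, m, q in zip(only_a, planted_mag(len(only_a)), planted_fdr(len(only_a))):
        lfc_a[g] = rng.choice([-1.0, 1.0]) * m
        fdr_a[g] = q
    for g, m, q in zip(only_b, planted_mag(len(only_b)), planted_fdr(len(only_b))):
        lfc_b[g] = rng.choice([-1.0, 1.0]) * m
        fdr_b[g] = q

    records_a, records_b = [], []
    for g in genes:
        records_a.append(
            DERecord(g, lfc_a.get(g, float(rng.normal(0, spec.null_lfc_sd)) if spec.null_lfc_sd else 0.0),
                     fdr_a.get(g, float(rng.uniform())), contrast="cold_vs_control_a")
        )
        records_b.append(
            DERecord(g, lfc_b.get(g, float(rng.normal(0, spec.null_lfc_sd)) if spec.null_lfc_sd else 0.0),
                     fdr_b.get(g, float(rng.uniform())), contrast="cold_vs_control_b")
        )

    truth = DESimTruth(
        de_a=frozenset(shared) | frozenset(only_a),
        de_b=frozenset(shared) | frozenset(only_b),
        common=frozenset(shared),
        only_a=frozenset(only_a),
        only_b=frozenset(only_b),
        ratio_passed=frozenset(ratio_genes) - frozenset(disc_genes),
        candidates=(frozenset(ratio_genes) - frozenset(disc_genes)) | frozenset(only_a),
        discordant=frozenset(disc_genes),
    )
    return records_a, records_b, truth
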