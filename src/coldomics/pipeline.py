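"""Pipeline orchestration: file IO, grouped summary tables, PCA, reports.

Ties the nomenclature, metrics, statistics and gene-set modules into the
two standard reports:

* the lipidome report — per-class concentration, per-class DBI and
  fatty-acid summary tables (mean ± SD per genotype×treatment cell,
  post-hoc letters, percent relative change per genotype), category
  fractions, and a PCA of per-sample species composition;
* the transcriptome report — DEG Venn partition, tolerance candidate
  list, TF-family tally and term enrichment.

All outputs are plain TSV. Rendered tables round to 2 decimals; each has
a full-precision companion (``*_full.tsv``). Outputs are deterministic:
identical inputs and config give byte-identical files.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from . import metrics
from .genesets import AnnotationMap, DERecord, call_deg, enrich, family_tally, tolerance_set
from .metrics import LipidomeSample
from .nomenclature import LIPID_CLASSES, LipidCategory, format_species, parse_species
from .stats import compact_letter_display, pairwise_posthoc

__all__ = [
    "RunConfig",
    "read_lipidome",
    "write_lipidome",
    "read_de_table",
    "read_annotation_map",
    "read_family_map",
    "lipidome_report",
    "run_lipidome_report",
    "transcriptome_report",
    "run_transcriptome_report",
]

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Analysis options shared by the report runners."""

    dbi_scope: str = "total"
    dbi_scale: str = "table_magnitude"
    posthoc_method: str = "tukey_hsd"
    alpha: float = 0.05
    control_label: str = "control"
    treated_label: str = "cold"
    fdr_max: float = 0.05
    min_abs_log2fc: float = 1.0
    ratio_min: float = 1.5
    ratio_basis: str = "linear_fc"
    enrich_fdr_max: float = 0.05
    letters: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("alpha", "fdr_max", "min_abs_log2fc", "ratio_min", "enrich_fdr_max"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, object]) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        stray = set(mapping) - known
        if stray:
            raise ValueError(f"unknown config keys: {sorted(stray)}")
        return cls(**mapping)  # type: ignore[arg-type]


# ---------------------------------------------------------------------------
# IO

def read_lipidome(table_path: str | Path, metadata_path: str | Path) -> list[LipidomeSample]:
    """Read a species × sample concentration table plus its metadata sheet.

    The table's first column holds species shorthand; remaining columns are
    sample ids. Metadata columns: sample_id, genotype, treatment, replicate.
    Sample ids must match one-to-one between the two files.
    """
    sep = "," if str(table_path).endswith(".csv") else "\t"
    table = pd.read_csv(table_path, sep=sep)
    meta = pd.read_csv(metadata_path, sep="\t" if not str(metadata_path).endswith(".csv") else ",")
    species = [parse_species(s) for s in table.iloc[:, 0]]
    sample_ids = list(table.columns[1:])
    unmatched = sorted(set(sample_ids) ^ set(meta["sample_id"].astype(str)))
    if unmatched:
        raise ValueError(f"sample ids unmatched between table and metadata: {unmatched}")
    meta = meta.set_index(meta["sample_id"].astype(str))
    samples = []
    for sid in sample_ids:
        row = meta.loc[sid]
        samples.append(
            LipidomeSample(
                sample_id=sid,
                genotype=str(row["genotype"]),
                treatment=str(row["treatment"]),
                replicate=int(row["replicate"]),
                concentrations=dict(zip(species, table[sid].astype(float).tolist())),
            )
        )
    return samples


def write_lipidome(
    samples: Sequence[LipidomeSample], table_path: str | Path, metadata_path: str | Path
) -> None:
    """Write samples in the table + metadata dialect ``read_lipidome`` reads."""
    panel = list(samples[0].concentrations)
    table = pd.DataFrame({"species": [format_species(sp) for sp in panel]})
    for s in samples:
        table[s.sample_id] = [s.concentrations.get(sp, 0.0) for sp in panel]
    table.to_csv(table_path, sep="\t", index=False)
    meta = pd.DataFrame(
        {
            "sample_id": [s.sample_id for s in samples],
            "genotype": [s.genotype for s in samples],
            "treatment": [s.treatment for s in samples],
            "replicate": [s.replicate for s in samples],
        }
    )
    meta.to_csv(metadata_path, sep="\t", index=False)


def read_de_table(path: str | Path) -> dict[str, list[DERecord]]:
    """Read a DE result TSV (gene_id, contrast, log2fc, fdr) grouped by contrast."""
    df = pd.read_csv(path, sep="\t")
    out: dict[str, list[DERecord]] = {}
    for _, row in df.iterrows():
        rec = DERecord(str(row["gene_id"]), float(row["log2fc"]), float(row["fdr"]),
                       contrast=str(row["contrast"]))
        out.setdefault(rec.contrast, []).append(rec)
    return out


def read_annotation_map(
    term_gene_path: str | Path,
    universe: Sequence[str],
    labels_path: str | Path | None = None,
) -> AnnotationMap:
    """Read a two-column (term_id, gene_id) TSV into an :class:`AnnotationMap`."""
    df = pd.read_csv(term_gene_path, sep="\t")
    terms: dict[str, set[str]] = {}
    for _, row in df.iterrows():
        terms.setdefault(str(row["term_id"]), set()).add(str(row["gene_id"]))
    labels = {}
    if labels_path is not None:
        ldf = pd.read_csv(labels_path, sep="\t")
        labels = dict(zip(ldf["term_id"].astype(str), ldf["label"].astype(str)))
    return AnnotationMap(
        terms={t: frozenset(g) for t, g in terms.items()},
        universe=frozenset(str(g) for g in universe),
        labels=labels,
    )


def read_family_map(path: str | Path) -> dict[str, str]:
    """Read a two-column (gene_id, family) TSV."""
    df = pd.read_csv(path, sep="\t")
    return dict(zip(df["gene_id"].astype(str), df["family"].astype(str)))


# ---------------------------------------------------------------------------
# lipidome report

def _per_replicate_stats(sample: LipidomeSample, config: RunConfig) -> dict[str, dict[str, float]]:
    """All row-statistics of the three summary tables for one replicate."""
    profile = metrics.class_totals(sample)
    dbi_profile = metrics.dbi(sample, scope=config.dbi_scope, scale=config.dbi_scale)
    fa = {sp: amt for sp, amt in sample.concentrations.items() if sp.class_code == "FA"}
    rows: dict[str, dict[str, float]] = {"class": {}, "dbi": {}, "fa": {}, "category": {}}
    rows["class"].update(profile.per_class)
    rows["class"]["Total"] = profile.grand_total
    rows["dbi"].update(dbi_profile.per_class)
    rows["dbi"]["Total"] = dbi_profile.total
    for sp in sorted(fa):
        rows["fa"][format_species(sp)] = fa[sp]
    if fa:
        summary = metrics.fatty_acid_summary(fa)
        rows["fa"]["TFA"] = summary.tfa
        rows["fa"]["UFA"] = summary.ufa
        rows["fa"]["SFA"] = summary.sfa
        rows["fa"]["UFA/SFA"] = summary.ratio
    for cat in LipidCategory:
        rows["category"][cat.value] = metrics.category_fraction(sample, cat)
    ratio, defined = metrics.dg_tg_ratio(sample)
    rows["category"]["DG/TG"] = ratio if defined else math.nan
    return rows


def _letters_for(
    values: dict[tuple[str, str], dict[str, list[float]]],
    row: str,
    config: RunConfig,
) -> dict[tuple[str, str], tuple[str, str]]:
    """Two letter tracks per cell: across treatments within genotype, and
    across genotypes within treatment. Empty strings when a family lacks
    replication (n < 2) or variation is degenerate for every group."""
    cells = list(values)
    out = {cell: ["", ""] for cell in cells}
    families = [
        (0, lambda c, g=g: c[0] == g) for g in sorted({c[0] for c in cells})
    ] + [
        (1, lambda c, t=t: c[1] == t) for t in sorted({c[1] for c in cells})
    ]
    for track, member in families:
        fam = [c for c in cells if member(c)]
        groups = {"|".join(c): values[c][row] for c in fam}
        if len(groups) < 2 or any(len(v) < 2 for v in groups.values()):
            continue
        if any(not all(math.isfinite(x) for x in v) for v in groups.values()):
            continue
        posthoc = pairwise_posthoc(groups, method=config.posthoc_method, alpha=config.alpha)
        means = {k: float(np.mean(v)) for k, v in groups.items()}
        letters = compact_letter_display(posthoc, means)
        for c in fam:
            out[c][track] = letters["|".join(c)]
    return {c: (v[0], v[1]) for c, v in out.items()}


def lipidome_report(
    samples: Sequence[LipidomeSample], config: RunConfig | None = None
) -> dict[str, pd.DataFrame]:
    """Compute the grouped lipidome summary tables and PCA in memory.

    Returns DataFrames keyed ``class_summary``, ``dbi_summary``,
    ``fa_summary``, ``category_summary``, ``pca_scores``, ``pca_variance``.
    Each summary holds per-cell mean, SD, two post-hoc letter tracks
    (across treatments within a genotype; across genotypes within a
    treatment) and a percent relative-change column per genotype.
    """
    config = config or RunConfig()
    cells: dict[tuple[str, str], list[LipidomeSample]] = {}
    for s in sorted(samples, key=lambda s: (s.genotype, s.treatment, s.replicate)):
        cells.setdefault((s.genotype, s.treatment), []).append(s)

    per_rep: dict[tuple[str, str], list[dict[str, dict[str, float]]]] = {
        cell: [_per_replicate_stats(s, config) for s in reps] for cell, reps in cells.items()
    }
    tables: dict[str, pd.DataFrame] = {}
    genotypes = sorted({c[0] for c in cells})
    for kind in ("class", "dbi", "fa", "category"):
        row_names: list[str] = []
        for stats_list in per_rep.values():
            for st in stats_list:
                for name in st[kind]:
                    if name not in row_names:
                        row_names.append(name)
        values = {
            cell: {name: [st[kind].get(name, math.nan) for st in per_rep[cell]]
                   for name in row_names}
            for cell in cells
        }
        records = []
        letter_cache = (
            {name: _letters_for(values, name, config) for name in row_names}
            if config.letters else None
        )
        for name in row_names:
            rec: dict[str, object] = {"row": name}
            for cell in cells:
                key = f"{cell[0]}_{cell[1]}"
                vals = [v for v in values[cell][name] if math.isfinite(v)]
                rec[f"{key}_mean"] = float(np.mean(vals)) if vals else math.nan
                rec[f"{key}_sd"] = float(np.std(vals, ddof=1)) if len(vals) > 1 else math.nan
                if config.letters:
                    lt = letter_cache[name][cell]  # type: ignore[index]
                    rec[f"{key}_letter_treatment"] = lt[0]
                    rec[f"{key}_letter_cultivar"] = lt[1]
            for g in genotypes:
                ctrl = rec.get(f"{g}_{config.control_label}_mean", math.nan)
                cold = rec.get(f"{g}_{config.treated_label}_mean", math.nan)
                if isinstance(ctrl, float) and isinstance(cold, float) \
                        and math.isfinite(ctrl) and math.isfinite(cold) and ctrl != 0:
                    rec[f"rc_{g}"] = metrics.relative_change(ctrl, cold)
                else:
                    rec[f"rc_{g}"] = math.nan
            records.append(rec)
        tables[f"{kind}_summary" if kind != "class" else "class_summary"] = pd.DataFrame(records)

    tables["pca_scores"], tables["pca_variance"] = _pca(samples)
    return tables


def _pca(samples: Sequence[LipidomeSample]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """PCA of per-sample species composition, species autoscaled.

    Zero-variance species are dropped before scaling; samples are the
    observations. Explained-variance percentages sum to 100 over all
    returned components.
    """
    ordered = sorted(samples, key=lambda s: s.sample_id)
    panel = sorted({sp for s in ordered for sp in s.concentrations})
    x = np.array([[s.concentrations.get(sp, 0.0) for sp in panel] for s in ordered])
    keep = x.std(axis=0) > 0
    x = x[:, keep]
    if x.shape[1] == 0 or len(ordered) < 2:
        scores = pd.DataFrame({"sample_id": [s.sample_id for s in ordered]})
        return scores, pd.DataFrame({"component": [], "explained_variance_pct": []})
    z = (x - x.mean(axis=0)) / x.std(axis=0, ddof=0)
    pca = PCA(n_components=None, svd_solver="full")
    comps = pca.fit_transform(z)
    scores = pd.DataFrame(
        comps, columns=[f"PC{i + 1}" for i in range(comps.shape[1])]
    )
    scores.insert(0, "sample_id", [s.sample_id for s in ordered])
    scores.insert(1, "genotype", [s.genotype for s in ordered])
    scores.insert(2, "treatment", [s.treatment for s in ordered])
    variance = pd.DataFrame(
        {
            "component": [f"PC{i + 1}" for i in range(comps.shape[1])],
            "explained_variance_pct": 100.0 * pca.explained_variance_ratio_,
        }
    )
    return scores, variance


def run_lipidome_report(
    samples: Sequence[LipidomeSample],
    outdir: str | Path,
    config: RunConfig | None = None,
) -> dict[str, pd.DataFrame]:
    """Run :func:`lipidome_report` and write rounded + full-precision TSVs."""
    tables = lipidome_report(samples, config)
    _write_tables(tables, outdir)
    return tables


# ---------------------------------------------------------------------------
# transcriptome report

def transcriptome_report(
    records_a: Sequence[DERecord],
    records_b: Sequence[DERecord],
    config: RunConfig | None = None,
    family_map: Mapping[str, str] | None = None,
    annotations: AnnotationMap | None = None,
) -> dict[str, pd.DataFrame]:
    """Venn partition, tolerance candidates, family tally and enrichment.

    Enrichment (when an annotation map is given) is run on the candidate
    set. Returns DataFrames keyed ``venn``, ``candidates``,
    ``family_tally`` and ``enrichment``.
    """
    config = config or RunConfig()
    tol = tolerance_set(
        records_a, records_b,
        fdr_max=config.fdr_max, min_abs_log2fc=config.min_abs_log2fc,
        ratio_min=config.ratio_min, basis=config.ratio_basis,
    )
    venn = pd.DataFrame(
        {
            "set": ["common", "only_a", "only_b", "ratio_passed", "discordant", "candidates"],
            "size": [len(tol.common), len(tol.specific_a), len(tol.specific_b),
                     len(tol.ratio_passed), len(tol.discordant), len(tol.candidates)],
        }
    )
    candidates = pd.DataFrame({"gene_id": sorted(tol.candidates)})
    deg_a = call_deg(records_a, config.fdr_max, config.min_abs_log2fc)
    tally_rows = []
    if family_map is not None:
        for fam, (n_up, n_down) in family_tally(
            {g: d for g, d in deg_a.items() if g in tol.candidates}, family_map
        ).items():
            tally_rows.append({"family": fam, "n_up": n_up, "n_down": n_down})
    tally = pd.DataFrame(tally_rows, columns=["family", "n_up", "n_down"])
    if annotations is not None and annotations.terms:
        enrichment = enrich(tol.candidates, annotations, fdr_max=config.enrich_fdr_max)
    else:
        enrichment = pd.DataFrame()
    return {"venn": venn, "candidates": candidates, "family_tally": tally,
            "enrichment": enrichment}


def run_transcriptome_report(
    records_a: Sequence[DERecord],
    records_b: Sequence[DERecord],
    outdir: str | Path,
    config: RunConfig | None = None,
    family_map: Mapping[str, str] | None = None,
    annotations: AnnotationMap | None = None,
) -> dict[str, pd.DataFrame]:
    """Run :func:`transcriptome_report` and write the TSVs."""
    tables = transcriptome_report(records_a, records_b, config, family_map, annotations)
    _write_tables(tables, outdir)
    return tables


def _write_tables(tables: Mapping[str, pd.DataFrame], outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for name, df in tables.items():
        rounded = df.copy()
        for col in rounded.columns:
            if pd.api.types.is_float_dtype(rounded[col]):
                rounded[col] = rounded[col].round(2)
        rounded.to_csv(outdir / f"{name}.tsv", sep="\t", index=False)
        df.to_csv(outdir / f"{name}_full.tsv", sep="\t", index=False)
        logger.info("wrote %s (%d rows)", outdir / f"{name}.tsv", len(df))
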