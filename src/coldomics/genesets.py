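"""Differential-expression set algebra and annotation enrichment.

Covers the transcriptome side of a two-cultivar stress comparison:
thresholding DE result tables into directed DEG sets, the cross-cultivar
Venn partition, construction of the stress-tolerance candidate set (common
DEGs whose fold change in the tolerant cultivar exceeds the sensitive
cultivar's by a ratio threshold, united with tolerant-exclusive DEGs),
TF-family tallies, and hypergeometric term enrichment with
Benjamini–Hochberg FDR control.

The DE fit itself (dispersion estimation, shrinkage) is out of scope:
records arrive precomputed with a log2 fold change and an adjusted p.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

__all__ = [
    "DERecord",
    "ToleranceGeneSet",
    "AnnotationMap",
    "call_deg",
    "venn_partition",
    "tolerance_set",
    "family_tally",
    "enrich",
]


@dataclass(frozen=True)
class DERecord:
    """One gene in one contrast: log2 fold change and adjusted p (FDR)."""

    gene_id: str
    log2fc: float
    fdr: float
    contrast: str = ""

    def __post_init__(self) -> None:
        if not 0.0 <= self.fdr <= 1.0:
            raise ValueError(f"gene {self.gene_id!r}: fdr {self.fdr} outside [0, 1]")


@dataclass
class ToleranceGeneSet:
    """The partitioned DEG sets of a two-cultivar contrast comparison."""

    common: frozenset[str]
    specific_a: frozenset[str]
    specific_b: frozenset[str]
    ratio_passed: frozenset[str]
    candidates: frozenset[str]
    discordant: frozenset[str] = field(default_factory=frozenset)


@dataclass
class AnnotationMap:
    """term_id → gene set over a stated gene universe."""

    terms: dict[str, frozenset[str]]
    universe: frozenset[str]
    labels: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        stray = set().union(*self.terms.values(), frozenset()) - self.universe
        if stray:
            raise ValueError(
                f"annotated genes outside the universe: {sorted(stray)[:5]}"
                + ("…" if len(stray) > 5 else "")
            )


def call_deg(
    records: Iterable[DERecord],
    fdr_max: float = 0.05,
    min_abs_log2fc: float = 1.0,
) -> dict[str, int]:
    """Threshold one contrast's records into a directed DEG set.

    A gene is called iff ``fdr < fdr_max`` and ``|log2fc| > min_abs_log2fc``
    (both strict); the value is the regulation direction, +1 or −1.
    """
    out: dict[str, int] = {}
    seen: set[str] = set()
    for r in records:
        if r.gene_id in seen:
            raise ValueError(f"duplicate gene {r.gene_id!r} in contrast")
        seen.add(r.gene_id)
        if r.fdr < fdr_max and abs(r.log2fc) > min_abs_log2fc:
            out[r.gene_id] = 1 if r.log2fc > 0 else -1
    return out


def venn_partition(
    set_a: Iterable[str], set_b: Iterable[str]
) -> tuple[frozenset[str], frozenset[str], frozenset[str]]:
    """(common, only_a, only_b) — intersection and the two set differences."""
    a, b = frozenset(set_a), frozenset(set_b)
    return a & b, a - b, b - a


def tolerance_set(
    records_a: Sequence[DERecord],
    records_b: Sequence[DERecord],
    fdr_max: float = 0.05,
    min_abs_log2fc: float = 1.0,
    ratio_min: float = 1.5,
    basis: str = "linear_fc",
) -> ToleranceGeneSet:
    """Build the tolerance candidate set from two cultivars' DE tables.

    Contrast *a* is the tolerant cultivar. Common DEGs with concordant
    direction are ranked by the ratio of their absolute fold changes:
    ``2^|log2fc_a| / 2^|log2fc_b|`` (``basis="linear_fc"``, default) or
    ``|log2fc_a| / |log2fc_b|`` (``basis="log2"``). Genes pass at
    ``ratio >= ratio_min`` (inclusive). Direction-discordant common genes
    are excluded from the ratio filter and reported separately.
    ``candidates = ratio_passed ∪ specific_a``.
    """
    if basis not in ("linear_fc", "log2"):
        raise ValueError(f"basis must be 'linear_fc' or 'log2', got {basis!r}")
    deg_a = call_deg(records_a, fdr_max, min_abs_log2fc)
    deg_b = call_deg(records_b, fdr_max, min_abs_log2fc)
    common, only_a, only_b = venn_partition(deg_a, deg_b)

    lfc_a = {r.gene_id: r.log2fc for r in records_a}
    lfc_b = {r.gene_id: r.log2fc for r in records_b}
    missing = [g for g in common if g not in lfc_a or g not in lfc_b]
    if missing:
        raise ValueError(f"common genes missing a record: {sorted(missing)[:5]}")

    passed: set[str] = set()
    discordant: set[str] = set()
    for g in common:
        if deg_a[g] != deg_b[g]:
            discordant.add(g)
            continue
        if basis == "linear_fc":
            ratio = 2.0 ** (abs(lfc_a[g]) - abs(lfc_b[g]))
        else:
            ratio = abs(lfc_a[g]) / abs(lfc_b[g])
        if ratio >= ratio_min:
            passed.add(g)
    return ToleranceGeneSet(
        common=common,
        specific_a=only_a,
        specific_b=only_b,
        ratio_passed=frozenset(passed),
        candidates=frozenset(passed) | only_a,
        discordant=frozenset(discordant),
    )


def family_tally(
    directed_genes: Mapping[str, int],
    family_map: Mapping[str, str],
) -> dict[str, tuple[int, int]]:
    """Per-family (n_up, n_down) counts of a directed gene set.

    Genes absent from ``family_map`` are tallied under ``"unassigned"``,
    so counts sum to the gene-set size.
    """
    up: Counter[str] = Counter()
    down: Counter[str] = Counter()
    for gene, direction in directed_genes.items():
        fam = family_map.get(gene, "unassigned")
        (up if direction > 0 else down)[fam] += 1
    return {fam: (up[fam], down[fam]) for fam in sorted(set(up) | set(down))}


def enrich(
    gene_set: Iterable[str],
    annotations: AnnotationMap,
    fdr_max: float = 0.05,
) -> pd.DataFrame:
    """Hypergeometric over-representation test per term, BH-corrected.

    For a term of size K in a universe of size N and a drawn set of size n
    with overlap k, p is the upper tail P(X >= k) of Hypergeom(N, K, n).
    q values are Benjamini–Hochberg across all tested terms; a term is
    significant iff ``q <= fdr_max`` (inclusive).
    """
    genes = frozenset(gene_set)
    stray = genes - annotations.universe
    if stray:
        raise ValueError(
            f"genes outside the annotation universe: {sorted(stray)[:5]}"
            + ("…" if len(stray) > 5 else "")
        )
    n_univ, n_set = len(annotations.universe), len(genes)
    rows = []
    for term_id, members in annotations.terms.items():
        k = len(genes & members)
        big_k = len(members)
        p = float(hypergeom.sf(k - 1, n_univ, big_k, n_set))
        rows.append(
            {
                "term_id": term_id,
                "label": annotations.labels.get(term_id, term_id),
                "overlap": k,
                "term_size": big_k,
                "set_size": n_set,
                "universe_size": n_univ,
                "expected": big_k * n_set / n_univ if n_univ else 0.0,
                "pvalue": min(p, 1.0),
            }
        )
    df = pd.DataFrame(
        rows,
        columns=[
            "term_id", "label", "overlap", "term_size", "set_size",
            "universe_size", "expected", "pvalue",
        ],
    )
    if len(df):
        df["qvalue"] = multipletests(df["pvalue"].to_numpy(), method="fdr_bh")[1]
        df["significant"] = df["qvalue"] <= fdr_max
        df = df.sort_values(["qvalue", "pvalue", "term_id"], ignore_index=True)
    else:
        df["qvalue"] = np.array([], dtype=float)
        df["significant"] = np.array([], dtype=bool)
    return df
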