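"""Replicate-level group statistics for table annotation.

One-way ANOVA, pairwise post-hoc tests (Tukey HSD on the studentized-range
distribution, protected Fisher LSD on pooled-variance t tests), a
compact-letter-display builder (insert-and-absorb), the comparative-CT
(ΔΔCT) qPCR relative-expression transform, and Pearson concordance
between expression estimates from two platforms.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats as sps

__all__ = [
    "AnovaResult",
    "PosthocResult",
    "QpcrRecord",
    "one_way_anova",
    "pairwise_posthoc",
    "compact_letter_display",
    "qpcr_relative_expression",
    "concordance",
]

POSTHOC_METHODS = ("tukey_hsd", "fisher_lsd")


@dataclass
class AnovaResult:
    f: float
    p: float
    df_between: int
    df_within: int
    ms_within: float
    degenerate: bool = False


@dataclass
class PosthocResult:
    """Pairwise significance at ``alpha`` for the listed groups.

    ``significant[i, j]`` is True when groups i and j differ at alpha;
    the matrix is symmetric with a False diagonal.
    """

    labels: list[str]
    significant: np.ndarray
    pvalues: np.ndarray
    method: str
    alpha: float


@dataclass
class QpcrRecord:
    """One qPCR measurement: target and reference-gene CT for one sample."""

    sample_id: str
    target_ct: float
    reference_ct: float
    condition: str
    is_calibrator: bool = False


def _as_groups(design: Mapping[str, Sequence[float]]) -> tuple[list[str], list[np.ndarray]]:
    labels = list(design)
    groups = [np.asarray(design[g], dtype=float) for g in labels]
    if len(groups) < 2:
        raise ValueError("at least two groups required")
    for lab, g in zip(labels, groups):
        if g.size < 2:
            raise ValueError(f"group {lab!r} needs n >= 2 replicates, got {g.size}")
    return labels, groups


def one_way_anova(design: Mapping[str, Sequence[float]]) -> AnovaResult:
    """Classical one-way ANOVA between/within decomposition.

    The all-zero within-variance case is flagged degenerate: p = 0 when any
    means differ (separation is certain), p = 1 when all values coincide.
    """
    _, groups = _as_groups(design)
    k = len(groups)
    n_total = sum(g.size for g in groups)
    grand = np.concatenate(groups).mean()
    ssb = sum(g.size * (g.mean() - grand) ** 2 for g in groups)
    ssw = sum(((g - g.mean()) ** 2).sum() for g in groups)
    dfb, dfw = k - 1, n_total - k
    if ssw == 0.0:
        if ssb == 0.0:
            return AnovaResult(0.0, 1.0, dfb, dfw, 0.0, degenerate=True)
        return AnovaResult(math.inf, 0.0, dfb, dfw, 0.0, degenerate=True)
    f = (ssb / dfb) / (ssw / dfw)
    p = sps.f.sf(f, dfb, dfw)
    return AnovaResult(f, p, dfb, dfw, ssw / dfw, degenerate=False)


def pairwise_posthoc(
    design: Mapping[str, Sequence[float]],
    method: str = "tukey_hsd",
    alpha: float = 0.05,
) -> PosthocResult:
    """All-pairs post-hoc comparison after one-way ANOVA.

    ``tukey_hsd`` uses the studentized-range distribution (family-wise
    control, not gated on the omnibus test). ``fisher_lsd`` runs
    pooled-variance t tests with no family correction but is *protected*:
    if the omnibus ANOVA is non-significant at alpha, no pair is flagged.
    """
    if method not in POSTHOC_METHODS:
        raise ValueError(f"method must be one of {POSTHOC_METHODS}, got {method!r}")
    labels, groups = _as_groups(design)
    k = len(labels)
    anova = one_way_anova(design)
    pvals = np.ones((k, k))

    if anova.degenerate:
        for i, j in itertools.combinations(range(k), 2):
            pvals[i, j] = pvals[j, i] = 0.0 if groups[i].mean() != groups[j].mean() else 1.0
    elif method == "tukey_hsd":
        res = sps.tukey_hsd(*groups)
        pvals = np.asarray(res.pvalue)
        np.fill_diagonal(pvals, 1.0)
    else:
        mse, dfw = anova.ms_within, anova.df_within
        for i, j in itertools.combinations(range(k), 2):
            se = math.sqrt(mse * (1 / groups[i].size + 1 / groups[j].size))
            t = (groups[i].mean() - groups[j].mean()) / se
            pvals[i, j] = pvals[j, i] = 2 * sps.t.sf(abs(t), dfw)

    significant = pvals < alpha
    np.fill_diagonal(significant, False)
    if method == "fisher_lsd" and not anova.degenerate and anova.p >= alpha:
        significant[:] = False  # protected LSD: omnibus gate
    return PosthocResult(labels, significant, pvals, method, alpha)


def compact_letter_display(
    posthoc: PosthocResult,
    means: Mapping[str, float],
) -> dict[str, str]:
    """Letter codes summarising all pairwise comparisons.

    Insert-and-absorb: start with one letter joining all groups; for each
    significantly different pair present together in a letter set, split
    the set into two (one without each member); drop sets contained in
    another. Letters are then named 'a', 'b', … in descending order of the
    best (largest-mean) group each set contains, ties broken by label, so
    the top-mean group always carries 'a'.

    Output satisfies: two groups share a letter ⟺ they are not
    significantly different.
    """
    sig = np.asarray(posthoc.significant)
    if sig.shape[0] != sig.shape[1] or not np.array_equal(sig, sig.T):
        raise ValueError("pairwise significance matrix must be square and symmetric")
    if np.any(np.diag(sig)):
        raise ValueError("pairwise matrix must be reflexively non-significant")
    labels = posthoc.labels
    idx = {lab: i for i, lab in enumerate(labels)}
    # descending mean, then label, defines both processing and letter order
    rank = sorted(labels, key=lambda g: (-means[g], g))

    sets: list[set[str]] = [set(labels)]
    for a, b in itertools.combinations(rank, 2):
        if not sig[idx[a], idx[b]]:
            continue
        new_sets: list[set[str]] = []
        for s in sets:
            if a in s and b in s:
                new_sets.extend((s - {a}, s - {b}))
            else:
                new_sets.append(s)
        # absorb: drop sets contained in another (keeps display minimal)
        sets = [
            s for i, s in enumerate(new_sets)
            if s and not any(i != j and s < t or (s == t and i > j)
                             for j, t in enumerate(new_sets))
        ]
    order = {g: i for i, g in enumerate(rank)}
    sets.sort(key=lambda s: min(order[g] for g in s))
    letters = {g: "" for g in labels}
    for li, s in enumerate(sets):
        ch = _letter(li)
        for g in rank:
            if g in s:
                letters[g] += ch
    return letters


def _letter(i: int) -> str:
    # a..z, then aa, ab, ... for pathologically many letter sets
    out = ""
    i += 1
    while i:
        i, r = divmod(i - 1, 26)
        out = chr(ord("a") + r) + out
    return out


def qpcr_relative_expression(records: Sequence[QpcrRecord]) -> dict[str, float]:
    """Comparative-CT relative expression, 2^(−ΔΔCT), per sample.

    ΔCT = CT(target) − CT(reference); ΔΔCT subtracts the arithmetic mean
    ΔCT of the calibrator samples, so calibrator expression geometric-
    averages to 1.
    """
    if not records:
        raise ValueError("no qPCR records supplied")
    for r in records:
        if not (math.isfinite(r.target_ct) and math.isfinite(r.reference_ct)):
            raise ValueError(f"missing or non-finite CT for sample {r.sample_id!r}")
    calib = [r.target_ct - r.reference_ct for r in records if r.is_calibrator]
    if not calib:
        raise ValueError("no calibrator samples flagged")
    calib_dct = float(np.mean(calib))
    return {
        r.sample_id: 2.0 ** -((r.target_ct - r.reference_ct) - calib_dct)
        for r in records
    }


def concordance(
    values_a: Mapping[str, float],
    values_b: Mapping[str, float],
) -> tuple[float, bool]:
    """Pearson r between two per-gene value maps on their shared genes.

    Returns ``(r, defined)``; zero variance on either side yields
    ``(nan, False)``.
    """
    shared = sorted(set(values_a) & set(values_b))
    if len(shared) < 3:
        raise ValueError(f"need >= 3 shared genes, got {len(shared)}")
    a = np.array([values_a[g] for g in shared])
    b = np.array([values_b[g] for g in shared])
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        return math.nan, False
    r = sps.pearsonr(a, b).statistic
    return float(r), True
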