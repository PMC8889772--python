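# Methods

## Scope and model

The package analyses a two-genotype × two-treatment membrane-lipidome
design at the lipid-species level, together with the matching
transcriptome-side set algebra. A species is identified only by head-group
class, total acyl carbons and total double bonds (sum-composition
shorthand); no sn-position, isomer or adduct resolution is attempted, and
raw MS or sequencing data are out of scope — inputs are quantified species
tables and precomputed differential-expression results.

## Lipidome statistics

Class totals are plain sums over species; category fractions divide class
sums by the grand total. Mol % supports two denominator scopes: the whole
lipidome (`total`) or each class renormalised to 100 (`within_class`).

The double-bond index weights each species' double-bond count N by its
mol % and sums, DBI = Σ N × mol %. Two scales are exposed: `per_formula`
divides by 100 and equals the mean number of double bonds per molecule;
`table_magnitude` leaves the sum undivided, the convention under which
per-class values are exactly additive to the total (and ~100× the
per-molecule mean). The default is `(scope=total, scale=table_magnitude)`
because it is the only convention under which the packaged DBI table is
internally consistent (its Total row equals the sum of its class rows to
print precision). Published per-class DBI values from the emulated
platform could not be reconciled with the caption-style formula under any
simple mol-% denominator — e.g. the free-fatty-acid class's printed DBI
is ~30 % above what its own printed species amounts give — so species-level
DBI correctness is certified against a brute-force oracle on randomized
samples, while table-level checks treat the printed class DBI values as
inputs and verify only the aggregation arithmetic (additivity and relative
change). The total DBI reported under `within_class` scope still uses
whole-lipidome mol %, since within-class percentages do not aggregate.

Relative change is RC = 100 × (treated − control)/control, computed on
cell means; undefined when the control mean is zero (raised). Statistics
with a zero denominator that is a legitimate data outcome rather than a
caller error (UFA/SFA with no saturated pool, DG/TG with no TG, Pearson r
on a constant vector) return NaN with a `defined=False` flag instead of
raising, so batch reports survive degenerate cells.

Units are nmol g⁻¹ FW throughout, the packaged tables' convention (the
source material is internally inconsistent between g⁻¹ and mg⁻¹; the
table unit was adopted).

## Group statistics and letters

One-way ANOVA uses the classical between/within decomposition; the
zero-within-variance case is flagged degenerate with p = 0 (means differ)
or 1 (identical). Tukey HSD uses the studentized-range distribution and is
not gated on the omnibus test; Fisher's LSD uses pooled-variance t tests
without family correction but is protected — when the omnibus ANOVA is
non-significant at α no pair is flagged. In tests the LSD⊇Tukey flagging
property is therefore asserted on unadjusted p-values (always) and on
flags only when the omnibus gate is open.

Compact letter displays use the insert-and-absorb construction: one
letter set containing all groups, split on each significantly different
pair, absorb subset letters, then name letters in descending order of
each set's best group mean (ties broken lexicographically), so the
largest mean always carries "a". The defining invariant — two groups
share a letter iff their pairwise test is non-significant — is re-checked
on every display in the test suite. Following the two-track annotation
convention of factorial tables, reports carry one letter track across
treatments within a genotype and a second across genotypes within a
treatment.

qPCR relative expression uses the comparative-CT method:
ΔCT = CT(target) − CT(reference), ΔΔCT subtracts the arithmetic mean
calibrator ΔCT (equivalently the geometric mean on the expression scale,
so calibrator expression geometric-averages to 1), and expression is
2^−ΔΔCT. Cross-platform concordance is the Pearson product-moment r on
shared genes (≥ 3 required).

## Gene sets

DEG calling is strict on both thresholds (FDR < 0.05, |log2FC| > 1);
enrichment significance is inclusive (q ≤ 0.05). These follow the
inequality directions conventionally printed with each threshold. The
tolerance candidate set takes common DEGs with concordant direction and a
fold-change ratio in the tolerant genotype of at least `ratio_min` (1.5,
inclusive), united with tolerant-exclusive DEGs. The ratio basis is the
linear absolute fold change 2^(|log2FC_a| − |log2FC_b|) by default; a
`log2` basis (ratio of |log2FC| values) is exposed as an option because
the field's usage is ambiguous. Direction-discordant common genes are
excluded from the ratio filter and reported separately. Enrichment is a
one-sided hypergeometric upper tail per term with Benjamini–Hochberg
correction across the terms of one annotation source per call; callers
with multiple sources (e.g. GO vs pathway) run them separately.

The DE fit itself is consumed, not reimplemented: published DEG counts of
the motivating study (which depend on its deposited raw reads) are not
reproduction targets; the set algebra is instead verified by oracle
equivalence and planted-truth recovery on synthetic tables.

## Synthetic data

The lipidome generator draws each replicate amount as mean × exp(ε) with
ε ~ Normal(−σ²/2, σ²), σ² = log(1 + cv²), so the expectation equals the
specified mean exactly. Log-normal noise was chosen because concentrations
are positive and replicate CVs in published class tables sit around
2–10 %; the default cv = 0.05 and n = 3 replicates per cell mirror that
regime. The default panel has 218 species: species named in the packaged
tables verbatim, each class completed to a plausible size with C:DB
combinations from a fixed carbon grid — the completion is synthetic, as
the emulated platform's full species list is not published. Default cell
means spread the packaged class totals across each class's species with
geometrically decaying weights, so class totals match the printed table
in expectation while species structure remains synthetic. What the
generator does *not* emulate: between-species correlation within a
replicate, censoring at the detection limit, and platform drift — passing
recovery tests therefore certify the arithmetic, not robustness to those
real-data features.

The DE generator plants per-contrast DEG sets with |log2FC| drawn from a
truncated normal (mean 2.5, sd 0.6, floored at 1.1) and FDR ~
Uniform(0, 0.04); a configurable fraction of the shared planted genes
receives a linear fold-change ratio ≥ 1.5 between contrasts and the rest
a ratio in [1, 1.5). Null genes get log2FC ~ Normal(0, 0.2) and FDR ~
Uniform(0, 1); setting the null sd to 0 gives noiseless tables on which
candidate recovery is exact. All randomness flows from one explicit seed.

## Problem sizes and numerical choices

The test suite runs randomized oracle-equivalence checks at 200 seeded
instances per operation, planted-recovery checks at 50 replicates (3×
standard-error bands via the delta method for RC), null-FDR control over
200 enrichment simulations, and Monte-Carlo envelopes at 1000 draws —
sizes at which all checks complete in seconds while sampling error is
well below the asserted tolerances. Printed-table reproduction is
asserted to 0.05 absolute on recomputed statistics (the floor set by
2-decimal rounding of the printed means being re-combined over ~15
terms); per-species relative changes are only asserted where the control
mean is ≥ 10, since rounding noise on sub-unit means exceeds the printed
RC precision. Rendered report tables round to 2 decimals; full-precision
companions are always written alongside. PCA autoscales each species
(center, unit variance; zero-variance species dropped) with samples as
observations — autoscaling is a choice, and published explained-variance
figures whose preprocessing is unspecified are deliberately not treated
as reproduction targets.

## Known limitations

* Table-derived pseudo-samples carry one representative species per class,
  so only class-level statistics are meaningful on them.
* The compact-letter-display absorb step keeps displays minimal in
  practice but global minimality is only asserted (by exhaustive search)
  at small group counts in tests.
* Protected LSD deliberately departs from textbook (unprotected) LSD;
  with it, LSD can flag fewer pairs than Tukey when the omnibus test
  fails.
* BH control is within one annotation source per call; cross-source FDR
  is the caller's responsibility.
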