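# coldomics

Quantitative analysis of plant cold-stress membrane lipidomes and
transcriptomes, built for two-genotype (tolerant vs sensitive) ×
two-treatment (control vs cold) comparisons of the kind used in rice
(*Oryza sativa*) chilling studies. The package takes species-level lipid
quantification tables (shorthand such as `MGDG 34:3`, amounts in
nmol g⁻¹ FW) and precomputed differential-expression result tables, and
produces the standard publication-shaped outputs: per-class concentration
tables with post-hoc letters and relative-change columns, double-bond
index (DBI) tables, fatty-acid saturation summaries, PCA of lipid
composition, DEG Venn partitions, cold-tolerance candidate gene sets,
transcription-factor family tallies and term-enrichment tables.

## What it computes

* **Lipid nomenclature** — parsing/formatting of sum-composition
  shorthand (`<CLASS> <carbons>:<double_bonds>`) over the 14 head-group
  classes (MGDG, DGDG, SQDG; PA, PC, PE, PG, PI, PMeOH; LPE, LPC; DG,
  TG; FA) grouped into galactolipid / phospholipid / lysophospholipid /
  neutral / free-fatty-acid categories.
* **Lipidome metrics** — class and category totals, mol-% composition,
  the double-bond index DBI = Σ N × mol % (per-formula ÷100 or
  table-magnitude scale), percent relative change
  RC = 100 × (cold − control)/control, TFA/UFA/SFA pools and the
  UFA/SFA ratio, DG/TG turnover ratio.
* **Group statistics** — one-way ANOVA, Tukey HSD and protected Fisher
  LSD post-hoc tests, compact letter displays (groups sharing a letter do
  not differ at α), comparative-CT (2^−ΔΔCT) qPCR relative expression,
  and Pearson concordance between platforms.
* **Gene-set comparison** — DEG calling (FDR < 0.05, |log2FC| > 1,
  strict), cross-genotype Venn partition, the tolerance candidate set
  (common DEGs with linear fold-change ratio ≥ 1.5 in the tolerant
  genotype, united with tolerant-exclusive DEGs), TF-family tallies, and
  hypergeometric enrichment with Benjamini–Hochberg FDR (≤ 0.05).
* **Synthetic data** — seeded generators for a 218-species lipidome with
  log-normal replicate noise and for paired DE tables with planted
  common/specific/ratio structure, returned with ground truth.

## Worked example

```python
import coldomics as co
from coldomics import fixtures as fx

# the packaged printed class-concentration table, one cell as a sample
ky_ctrl = fx.class_mean_sample("KY131", "control")
print(round(co.class_totals(ky_ctrl).grand_total, 2))       # 13061.29
print(round(co.category_fraction(ky_ctrl, "galactolipid"), 2))  # 64.78
print(round(co.relative_change(5084.35, 6796.77), 2))       # 33.68  (MGDG, cold vs control)

summ = co.fatty_acid_summary(fx.fa_mean_amounts("KY131", "cold"))
print(round(summ.ufa, 2), round(summ.ratio, 2))             # 161.53 1.63
```

The grand total (13061.29 nmol g⁻¹ FW) is the sum of the 14 class totals
in the tolerant genotype under control conditions; galactolipids (MGDG +
DGDG + SQDG) carry 64.78 % of it. MGDG rises 33.68 % under cold in the
tolerant genotype, and the cold fatty-acid pool holds 161.53 nmol g⁻¹ FW
of unsaturated species at a UFA/SFA ratio of 1.63.

A full simulated run from the shell:

```
coldomics simulate --seed 3 --outdir sim/
coldomics lipidome --table sim/lipidome.tsv --metadata sim/lipidome_metadata.tsv --outdir lip/
coldomics transcriptome --de-table sim/de_tables.tsv \
    --contrast-a cold_vs_control_a --contrast-b cold_vs_control_b --outdir tx/
```

writes class/DBI/fatty-acid summary tables (mean ± SD, letters, RC),
PCA scores, the DEG Venn partition, candidate gene list and tallies as
plain TSV.

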