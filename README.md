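# domlink

Coupled analysis of molecular dissolved-organic-matter (DOM) composition and
bacterioplankton community structure, as used in short-term marine time
series: ultrahigh-resolution FT-ICR-MS peak lists are turned into a table of
molecular formulas, 16S-derived OTU tables are cleaned and normalized, and
both are linked to each other and to environmental covariates through
distance-based multivariate statistics and a correlation network.

The package is aimed at microbial ecologists and marine geochemists who have
(a) calibrated negative-mode mass-peak lists, (b) an OTU count table with
taxonomy paths, and (c) an environmental covariate table for the same
samples — and who want the full analysis chain reproducible in one place,
with a synthetic-data generator that makes every stage testable against
known ground truth.

## What it computes

**Formula assignment** (`formula_pipeline`). Peaks with S/N ≥ 4 are aligned
across samples (single-linkage within a ppm tolerance), filtered by
occurrence (kept when detected in more than two samples, or — if present in
fewer than 20% of samples — when S/N > 20 somewhere), and assigned CHNOSP
formulas: the neutral mass of the singly charged [M−H]⁻ ion is m/z +
1.007276 Da, and candidates within tolerance must satisfy integer DBE ≥ 0,
0.3 ≤ H/C ≤ 2.5, O/C ≤ 1.2, must avoid implausible heteroatom combinations
(NSP, N₂S, N₃S, N₄S, N₂P, N₃P, N₄P, NS₂, N₂S₂, N₃S₂, N₄S₂, PS₂), and must
be unique — ambiguous masses are dropped. Known contaminants, their CH₂
homologous series and all ¹³C isotopologs are removed, and intensities are
normalized per sample to relative abundances.

**Molecular descriptors** (`dom_descriptors`). Per formula:

    DBE    = 1 + ½(2C − H + N + P)
    AI_mod = (1 + C − ½O − S − ½H) / (C − ½O − S − N − P)

plus the van Krevelen ratios H/C and O/C and a compound class (saturated
fatty acids at H/C ≥ 2.0 or O/C ≥ 0.9; polycyclic aromatics at AI_mod >
0.66; polyphenols at 0.5 < AI_mod ≤ 0.66; unsaturated aliphatics at 2.0 >
H/C ≥ 1.5, peptide-like when N is present; highly unsaturated at AI_mod ≤
0.5 and H/C < 1.5). Per sample: intensity-weighted average mass and class
abundances.

**Multivariate statistics** (`multivariate_stats`). Euclidean, Hellinger
and Bray–Curtis distances (the latter customarily on square-root-transformed
intensities); PCoA; the ANOSIM R statistic and non-hierarchical *k-R*
clustering that searches for the k-group partition maximizing R; one-way
PERMANOVA (999 permutations); a two-class LDA effect-size feature ranking
(Kruskal–Wallis screen at p < 0.05, bootstrap LDA scoring, log-LDA
threshold 2); distance-based linear models (DistLM, stepwise selection on
adjusted R², permutation p-values) with dbRDA ordination; and RELATE matrix
rank correlation.

**Association network** (`association_network`). All pairwise
OTU–formula–environment correlations (Pearson or Spearman) with two-sided
p-values, optional Holm–Bonferroni adjustment, a pivot table of significant
coefficients per |r| bin and sign, and a graph of high correlations
(|r| ≥ 0.9, p < 0.05) exported as GraphML/TSV for network GUIs.

**Synthetic data** (`synthetic_data`). Generates all three inputs with
known ground truth: a valid formula universe and per-sample peak lists with
ppm mass error, ¹³C partners, a CH₂ contaminant series and unassignable
noise peaks; Dirichlet-multinomial OTU counts with a planted two-group
effect and organelle-labelled taxa; positive environmental covariates with
planted multicollinearity; and planted OTU–molecule correlations.

## Worked example

```sh
domlink simulate --seed 3 --out sim
domlink assign  --peaks sim/peaks.tsv --contaminants sim/contaminants.txt --out dom.tsv
domlink describe --dom dom.tsv --out desc.tsv
domlink prep    --otu sim/otu_counts.tsv --taxonomy sim/otu_taxonomy.tsv \
                --env sim/env.tsv --out-prefix prep
domlink cluster --table prep.otu_rel.tsv --distance hellinger --k 2 --out groups.tsv
domlink effectsize --table prep.otu_rel.tsv --groups groups.tsv --out lefse.tsv
domlink network --otu prep.otu_rel.tsv --dom dom.tsv --env prep.env_norm.tsv \
                --out-prefix net
```

prints, stage by stage:

```
assigned 198 formulas across 17 samples
retained 78 taxa
ANOSIM R = 0.973; PERMANOVA pseudo-F = 7.658, p = 0.0010 (999 permutations, seed 0)
33 discriminative features (log-LDA >= 2.0)
40186 pairs tested (p adjustment: none); network has 10 nodes / 12 edges
```

Reading this: of the 200 planted formulas, 198 survive the full filter
cascade (the two missing ones fall to the occurrence filter); 78 of 98 OTUs
remain after organelle and 0.1%-abundance filtering; *k-R* clustering of the
Hellinger distances recovers the planted two-group structure almost
perfectly (R = 0.973) and PERMANOVA confirms it at the smallest attainable
p (1/1000); the effect-size ranking reports the planted differential OTUs
(log-LDA scores ≈ 4–5) along with compositional ripple effects; and at only
17 samples a handful of the ~40,000 tested pairs exceed |r| ≥ 0.9 by chance
— the pivot table and the optional `--adjust holm` flag are there precisely
to keep that multiplicity visible.

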