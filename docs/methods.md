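# Methods

This note documents the models and procedures implemented in `domlink`, the
defaults and why they were chosen, what the synthetic-data generator does
and does not emulate, and the numerical conventions that matter when
comparing results across tools.

## Formula assignment

Peaks are singly charged deprotonated ions: neutral mass = m/z + 1.007276 Da
(proton mass with the electron mass folded in). Candidate CHNOSP formulas
are enumerated inside configurable element ranges (defaults C 1–100,
H 1–200, N 0–4, O 0–50, S 0–2, P 0–1) within a mass tolerance of 0.5 ppm by
default; both values are instrument- and lab-dependent and are exposed as
parameters. Enumeration is exact: the hydrogen count is solved analytically
on a cached (C, N, O, S, P) grid, and tests verify equivalence with
brute-force nested enumeration.

Chemical plausibility requires an integer, non-negative DBE,
0.3 ≤ H/C ≤ 2.5 and O/C ≤ 1.2 — standard bounds for marine DOM. Twelve
heteroatom combinations (NSP meaning "all three present", and the exact
(N,S,P) signatures N₂S…N₄S, N₂P…N₄P, NS₂…N₄S₂, PS₂) are excluded as
chemically implausible; the signatures are matched exactly, with unlisted
heteroatoms at zero.

The shipped cascade order is fixed and logged: S/N ≥ 4 screen → cross-sample
alignment → occurrence filter → isotopolog screen → candidate enumeration →
chemical filters → heteroatom exclusion → double-assignment drop →
contaminant removal → sum normalization. Two conventions deserve note:

- *Alignment* is single-linkage chaining of the pooled, sorted m/z values
  within the ppm tolerance. If a chain captures two peaks of one sample,
  the higher-intensity peak is kept and the conflict logged. How masses are
  matched across samples is rarely reported by instrument pipelines; any
  bounded-diameter grouping gives the same result at sub-ppm tolerances.
- *Double assignments are dropped*, not resolved to the lowest-error
  candidate. An ambiguous mass carries no reliable molecular information at
  the stated tolerance.
- The occurrence filter keeps a mass detected in more than two samples, or
  present in fewer than 20% of samples with S/N > 20 at least once. The
  S/N ≥ 4 screen runs before occurrence counting.

Contaminant removal takes a user-supplied list of neutral masses (these
lists are lab-specific and unpublished as a rule), expands each by its CH₂
homologous series within the mass window, adds the ¹³C isotopolog of every
removed mass, and removes matching assignments within tolerance. A separate
isotopolog screen drops aligned columns sitting one ¹³C spacing
(+1.003355 Da) above a column of higher intensity before any assignment is
attempted.

`normalize_intensities` divides each sample's retained intensities by their
sum; rows of the resulting DOM table sum to 1 to within 10⁻⁹ and the values
are treated as relative abundances.

## Descriptors and compound classes

DBE = 1 + ½(2C − H + N + P); AI_mod = (1 + C − ½O − S − ½H) /
(C − ½O − S − N − P). When the AI_mod denominator is ≤ 0 or the numerator
is < 0 the aromaticity index is undefined for such aliphatic compositions
and is clamped to 0. Compound classes partition the H/C–O/C–AI_mod space by
a fixed rule order (saturated fatty acids → polycyclic aromatics →
polyphenols → aliphatic band, peptide-like when N > 0 → highly
unsaturated → unspecified). The literature's class definitions overlap at
the margins (an H/C = 1.6 formula with nitrogen is both "unsaturated
aliphatic" and "peptide-like"); fixing the precedence makes the
classification total and deterministic, and the boundaries are configurable
(`ClassBounds`).

## Community and environment preparation

Organelle and eukaryote taxa are removed by substring match on the taxonomy
path (default labels Chloroplast, Mitochondria, Eukaryota); relative
abundances are then recomputed and taxa with mean relative abundance
< 0.1% (inclusive threshold) are dropped. "Average relative abundance" is
the mean across samples of per-sample proportions, not the pooled-count
proportion, and organelle removal precedes the abundance test.
Environmental variables are natural-log transformed and z-scored with the
population standard deviation, so transformed columns have mean 0 and
variance 1 exactly; non-positive values are rejected unless an explicit
offset is configured, because the targeted covariates (temperature,
salinity, nutrient and gas concentrations) are positive.

## Multivariate statistics

Distances: Euclidean; Bray–Curtis (optionally on square-root-transformed
intensities, the customary variance-stabilizer for spectral data);
Hellinger = Euclidean on row-wise square-root proportions.

PCoA Gower-centers the squared dissimilarities and eigen-decomposes.
Negative eigenvalues of semi-metric inputs are reported unmodified — no
Lingoes or Cailliez correction — and coordinates are returned for positive
axes only.

ANOSIM R = (mean between-group rank − mean within-group rank)/(M/2), with
M = n(n−1)/2 and average ranks on ties. *k-R clustering* maximizes R by
greedy single-sample reallocation from random initial partitions (moves
that would empty a group are forbidden), keeping the best of 50 restarts;
it is deterministic given a seed, and tests verify it attains the
exhaustive-search optimum for n ≤ 10 and for n = 17 with k = 2.

PERMANOVA uses SS_total = (1/n)Σ_{i<j}d²ᵢⱼ, SS_within = Σ_g(1/n_g)
Σ_{i<j∈g}d²ᵢⱼ and pseudo-F = ((SS_T − SS_W)/(k−1))/(SS_W/(n−k)); p-values
come from raw label permutation with p = (#{F* ≥ F}+1)/(B+1), B = 999 by
default. Note that permutations reproducing the observed partition
reproduce the observed F, so the minimal p is attainable only when the
fraction of partition-preserving permutations is below 1/(B+1) — true for
the 17-sample design (≈4·10⁻⁹) but not for, say, a balanced 6-sample one.

DistLM works on the Gower-centered matrix G: for a centered predictor
matrix with hat matrix H, R² = tr(HGH)/tr(G) and pseudo-F =
(tr(HGH)/m)/(tr((I−H)G(I−H))/(n−m−1)). Marginal (single-predictor) and
sequential (per accepted step) tests permute the sample identities of G —
the closed-source original offers several permutation schemes; this one is
used for both test types and is documented here as the package's choice.
Stepwise selection alternates forward additions and backward drops accepted
when adjusted R² = 1 − (1−R²)(n−1)/(n−m−1) increases, stopping at a local
optimum. Collinear predictor columns are refused by name: dropping
collinear covariates is an analyst decision, and the
`multicollinearity_report` helper lists candidate pairs (|r| > 0.6 among
environment variables) without making it. dbRDA eigen-decomposes HGH for
the selected predictors.

The effect-size ranking is *LEfSe-style*, not byte-identical to the
published multiclass tool: two classes only; features scaled to a
per-sample sum of 10⁶; Kruskal–Wallis screen at p < 0.05 (uncorrected, as
in the original); per-feature score = log₁₀(1 + mean over 30 bootstrap
rounds of ½(|Δμ_f| + |w_f|·ES)), where each round subsamples ⅔ of each
class, fits a regularized LDA (least-squares solver with automatic
shrinkage), w is the unit-norm discriminant vector, ES the projected
between-class mean difference and Δμ_f the raw between-class mean
difference of feature f; features with score ≥ 2 are reported with the
group of higher mean. The known property of this family of scores — that
any feature passing the rank test with an absolute difference above 10⁻⁴
of total abundance clears the threshold, so per-run false-positive counts
track the Kruskal–Wallis pass count rather than vanishing — is discussed
under Limitations.

RELATE computes the Spearman rank correlation of corresponding
off-diagonal dissimilarities and permutes the sample identities of one
matrix.

## Association network

Pearson p-values use the t distribution with n−2 df; Spearman p-values use
the same approximation for n ≥ 10 and exact enumeration of the
permutation null below that (falling back to the approximation under
ties). The network keeps pairs with p < 0.05 and |r| ≥ 0.9. Raw
(uncorrected) p-values are the default, with Holm–Bonferroni available as
`--adjust holm`; the chosen mode is recorded in the output. The pivot table
counts significant coefficients in half-open |r| bins [0, 0.5), [0.5, 0.6),
…, [0.9, 1] split by sign and node-kind pair; the last bin is closed so
|r| = 1 is counted.

## Synthetic-data generator

Defaults mirror a daily coastal surface-water design: 17 samples in two
groups (9 + 8), 98 OTUs of which 5 carry organelle labels, sequencing depth
log-normal around 10⁵ reads, and 8 environmental variables with planted
correlations (temperature–TDN 0.51, temperature–nitrite 0.65, salinity–DOC
−0.60, salinity–O₂ −0.56) matching the multicollinearity structure such
series show. The formula universe defaults to 200 formulas between 150 and
800 Da — a desk-scale stand-in for the thousands of formulas a 15 T
instrument resolves, chosen so the full cascade runs in seconds while every
filter still has work to do. Mass error is Gaussian with 0.1 ppm sd;
formula presence per sample is Bernoulli(0.8); S/N is log-normal
(median 50 for analyte peaks, 6 for noise); 30% of formulas carry a ¹³C
partner at isotope-ratio intensity; the contaminant series uses palmitic
acid and dioctyl phthalate as base masses with four CH₂ steps each.

Two constructions make ground truth unambiguous, and they are generator
properties, not pipeline assumptions: noise peaks are placed at least 5 ppm
from any chemically valid candidate mass, and universe formulas are drawn
so that each is the *unique* surviving candidate at the assignment
tolerance (otherwise the double-assignment rule would correctly delete
them and recovery ceilings would reflect mass-coincidence statistics
instead of code behavior).

OTU counts are Dirichlet-multinomial (concentration 50 — strongly
overdispersed relative to multinomial sampling, to stress the compositional
methods); the planted group effect multiplies expected proportions of the
differential OTUs by exp(log-fold effect), default ln 10, an
order-of-magnitude shift typical of bloom transitions. Environmental
covariates come from a Gaussian copula exponentiated to log-normal
marginals (spread 0.25), which keeps values positive and correlation
attenuation under exponentiation below ~0.02. Planted OTU–molecule
correlations redraw the named columns jointly from a copula with a small
log spread (0.1) so realized Pearson correlations stay within ±0.05 of the
targets even for negative targets, where log-normal attenuation is
strongest.

What the generator does **not** emulate: raw transients/scans and
resolution-dependent peak shapes, chimeras, sequencing error profiles,
taxonomy misassignment, sample dropout, temporal autocorrelation of the
day-to-day series, and compositional coupling between the DOM table and
the OTU table beyond explicitly planted edges. Passing tests therefore
demonstrate correctness of the computations and recoverability of planted
structure — not robustness to every artifact of real spectra or libraries.

## Problem sizes used in tests

The test suite and `scripts/acceptance.py` use the study-scale defaults
(17 samples) wherever the property under test allows, and larger n where a
statistical tolerance demands it: n = 40 for effect-size recovery, n = 200
for network precision/recall and planted correlations, n = 1000 for
realized-collinearity checks. Permutation-test calibration uses 999
permutations and 500 replicates per test (300 in the acceptance script);
brute-force clustering oracles run at n ≤ 10 exhaustively and at n = 17
with a vectorized enumeration of all 2¹⁶ − 1 bipartitions.

## Known limitations

- Grouping samples by maximizing ANOSIM R and then "confirming" the groups
  with PERMANOVA on the same distance matrix is circular; the package
  implements the workflow as practiced but the PERMANOVA p-value should be
  read as descriptive, not inferential.
- The effect-size ranking inherits the permissive false-positive behavior
  of uncorrected per-feature screening: under a global null with ~100
  features, some feature passes the Kruskal–Wallis screen in most runs,
  and any such feature with an absolute abundance difference above 0.01%
  of the per-sample total clears the log-LDA = 2 threshold. Interpret
  reported features jointly with their scores and group means, or raise
  `alpha`/`lda_threshold`.
- Pearson/Spearman correlations on relative abundances ignore
  compositional coupling; SparCC-style compositionality-aware association
  is out of scope and the network should be read accordingly.
- PCoA/dbRDA handle semi-metric inputs by reporting negative eigenvalues
  without correction; proportion-explained figures use positive axes only.
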