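# Methods

## Model and assumptions

The unit of analysis is the isoform fraction IF(i,s): transcript *i*'s
abundance divided by its gene's total abundance in sample *s*. The
switch model assumes antagonistic differential usage — a rise in one
isoform's fraction is mirrored by a fall in one or more sibling
isoforms (fractions sum to 1, so per gene Σ dIF = 0 with complete
data). Abundances are consumed as TPM-like non-negative values;
quantification, alignment and variant calling are upstream of this
package.

Differential usage is tested by permuting group labels and recomputing
|dIF|. The test is exact under within-group exchangeability of samples
and makes no distributional assumption about usage noise. p-values use
the add-one estimator (1 + exceedances)/(n_perm + 1), counting ties
against rejection, so p is never 0 and the null rejection rate at
α = 0.05 sits just below α (≈ 0.049 at n_perm = 999). Each sample's
missing-fraction pattern travels with it through the permutation.
Permutations are drawn under a canonical (sorted) group ordering, which
makes p-values bit-identical under swapping the contrast direction.

A switch pair requires dIF of ±0.1 and min member q < 0.05 (q < 0.05
is the one threshold the underlying analysis specifies; 0.1 is a
conventional minimum-effect cut). The gene-level q takes the minimum
member p, Bonferroni-scales it by the gene's testable isoform count,
caps at 1 and BH-adjusts across genes — a deliberately conservative
composite because member isoform p-values of one gene are dependent.

## Structural consequences

Features (spliced length, 5'/3'UTR lengths, intron count, domain set,
coding flag) come from exon/CDS models in 0-based half-open genomic
coordinates; GTF input is converted at parse time. On the "−" strand
the 3'UTR is genomically leftmost; feature extraction is
strand-symmetric by construction. Non-coding transcripts carry UTR
lengths of 0 by convention — their missing ORF is expressed through the
coding flag, and UTR categories are therefore only compared between two
coding isoforms (otherwise every ORF-loss pair would fabricate a
spurious UTR-shortening call). UTR and length categories require a
minimum difference of 50 nt to ignore annotation jitter; domain gain
and loss may co-occur (disjoint differences); all other opposing labels
are mutually exclusive. "Gene length" is spliced transcript length,
not genomic span. Genome-wide asymmetry per category uses an exact
two-sided binomial test on gene-level majority directions (ties drop
from both counts but stay in the denominator).

## Mutation association

Mutation burden scales with gene length, so both association statistics
are referenced to length-matched backgrounds: candidates within a ±20%
multiplicative length window (|log L − log L_q| ≤ log 1.2), sampled
uniformly without replacement with a fixed seed, topped up with nearest
neighbours by log-length distance (ties broken lexicographically) when
the window is thin. The gene statistic matches on median isoform
length with k = 100; the isoform-level Jaccard statistic matches on
transcript length with k = 200. The significance threshold is Z > 1.6
(one-sided upper tail, the 90% confidence bound), kept verbatim rather
than rounded to 1.645. The gene background is drawn from all annotated
genes excluding the query (configurable); the Jaccard null uses the
sampled isoforms' own J values, not permuted sets. A per-sample
switch call — needed for the Jaccard intersection — is a group-B sample
whose fraction deviates from the group-A mean by ≥ τ = 0.1 in the
direction of the group-level dIF; τ is this package's reading, as no
standard definition exists.

In the pipeline (not the low-level functions), k for the Jaccard
background is reduced to pool−1 with a logged warning when fewer than
k switched isoforms exist; the low-level functions raise instead.

## Synthetic cohort generator

The generator emulates the study conditions end to end: 23 nevi and 57
melanomas; 500 genes with 1–5 isoforms (exon counts 1–8, exon lengths
80–400 nt, spliced lengths mostly 0.5–3 kb, random strand, 85% coding
with domains from a small vocabulary); 50 switch genes whose melanoma
usage moves dIF_effect = 0.3 of mass from a down- to an up-isoform;
gene totals negative binomial (log-normal means exp(N(3,1)) ≈ 20 TPM
median, dispersion φ = 0.2, var = m + φm²); per-(gene, sample) usage
Dirichlet with concentration 30 around the group proportions (within-
group IF sd ≈ 0.07–0.09, comparable to real cohort usage variability).
Mutations are Poisson per gene and sample at 0.5/kb of median isoform
length — chosen so that long genes are mutated in over half the cohort,
matching the heavily mutated melanoma setting the analysis targets —
with 20 genes 3-fold enriched in melanomas, classes drawn at fixed
frequencies (missense 0.60, synonymous 0.15, 3'UTR 0.10, 5'UTR 0.05,
nonsense 0.05, splice-site 0.05), and 20 co-occurrence isoforms whose
switched melanoma samples carry ≥1 mutation with probability 0.8.

Planting uses exact counts (seeded shuffle, deterministic assignment)
for switch genes, ORF-loss pairs and the 60/40 3'UTR
shortened/lengthened split, so ground-truth proportions equal the
configured fractions exactly and recovery tests score the analysis, not
planting noise. All generators are bit-reproducible under a fixed seed,
and emitted files round-trip through the package's parsers.

What the generator does *not* emulate: read-level noise and mapping
bias, isoform-correlated quantification uncertainty, real exon-intron
statistics, mutational signatures, batch effects, and
expression-dependent mutation detectability in RNA-seq. Passing
recovery tests therefore demonstrate correctness and calibration of the
statistics under the stated generative model, not performance on real
cohorts.

## Numerical choices

* Fractions are missing (NaN) below gene expression ε = 1 TPM; isoforms
  with < 2 usable samples in a group are untestable (p missing, passed
  through BH untouched).
* Permutation exceedance uses a 1e-12 tolerance so exact ties count as
  ≥ despite float noise.
* Degenerate zero-spread Z backgrounds yield z = +∞ (query above
  background mean) or 0, flagged as degenerate.
* Empty Jaccard unions return J = 0.
* Pair lists are sorted by min member q with lexicographic tie-breaks;
  all outputs are deterministically ordered, and pipeline reruns with
  one config are byte-identical (provenance headers carry a config
  hash, seed and version — no timestamps).

## Problem sizes used in tests

Calibration and recovery checks run at desk scale, chosen to keep the
Monte-Carlo error of each scored rate small relative to the tolerance
it is checked against:
2000 null isoforms × 999 permutations for test calibration; the default
500-gene cohort for switch recovery; 2000 genes for mutation-Z
calibration/recovery; 440 switched isoforms (220 switch genes) with
k = 200 for the Jaccard null; 200 consequence genes for the asymmetry
recovery.

## Known limitations

* The permutation test treats samples as exchangeable within groups; it
  does not model covariates or batch structure.
* Gene-level q from min-p/Bonferroni is conservative for genes with
  many correlated isoforms.
* Multi-group designs are handled as pairwise contrasts, not jointly.
* The per-sample switch call threshold τ is a convention; Jaccard
  values shift with τ, though the length-matched Z largely absorbs
  this.
* Consequence classification is annotation-bound: domains and coding
  status are inputs, never predicted.
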