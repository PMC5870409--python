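# Methods

## In-silico restriction analysis

Site scanning is single-strand, on the reference orientation of the
cluster, with each enzyme's IUPAC pattern supplied in that orientation
(DdeI CTNAG, XmnI GAANNNNTTC, HindIII AAGCTT, HincII GTYRAC, HinfI GANTC).
Double-strand scanning would double-count palindromes (HindIII) and the
five diagnostic sites are defined on one strand, so the simpler model is
also the correct one here.  All overlapping matches are reported; nothing
downstream depends on match consumption because a locus call only asks
whether at least one match *starts* inside the locus window.  Windows are
0-based half-open everywhere internally; conversion to 1-based coordinates
happens only at the VCF boundary.  A sequence `N` matches only the pattern
code `N`: an unknown base must never manufacture a site call.  Fragment
prediction places the cut at `match position + cut offset` and always
partitions the sequence.

HbS genotyping reads the codon-6 DdeI call on each chromosome: cut = HbA,
site lost = HbS, so (+,+) → HbAA, one loss → HbAS, (−,−) → HbSS; a missing
call yields "unknown" rather than a guess.

## Haplotype table

The five classical patterns and five named atypical subtypes ship as a
versioned JSON config (`table-ref16-default`) rather than constants: the
published pattern tables live in supplementary material that varies between
sources, and users genotyping against a different reference should be able
to swap the table without touching code.  The generator and the classifier
always bind to the same table, which makes cohort-level results
table-consistent by construction; classification itself is an exact match
(classical label, named atypical subtype, `atypical-other` for anything
else, `unresolved` whenever a site state is missing).

Frequencies are reported per chromosome over resolved calls, percentages
to one decimal place.  Pair combinations collapse atypical subtypes into a
single `atypical` category by default, the granularity at which such
cohorts are reported; the collapse is configurable.  Named-atypical
subtype percentages can be computed over all resolved chromosomes or over
atypical chromosomes only — both conventions occur in the literature and
both are exposed (`denominator="all" | "atypical"`); the package asserts
nothing that depends on the choice.

## Population statistics

*Hardy-Weinberg.* The default test is the exact conditional test: condition
on the observed allele counts, enumerate every heterozygote count of the
same parity, and sum the probabilities of configurations no more probable
than the observed one.  At cohort sizes near 50 the chi-square
approximation is unreliable in the tails; chi-square is available as an
option.  Probabilities use log-gamma arithmetic with a 1e-12 log-tolerance
so equal-probability configurations are always included.

*F-statistics.* The headline estimator is Wright's frequency-only variance
ratio F = Var(p)/(p̄(1−p̄)) for a pair of populations, because the
cross-population comparison is done on published allele frequencies where
no genotype tables exist.  With both populations fixed for the same allele
the ratio is 0/0 and we return 0 (no variation to apportion).  A
Weir-Cockerham theta from genotype counts is provided for users with full
genotype data; it is sample-size corrected and can be slightly negative
near zero differentiation.  The population × population matrix averages
per-SNP values; pairs with a missing frequency are flagged and excluded
from the average rather than imputed.

*Cline trend.* Spearman rank correlation between the (fixed, geographic)
population order and the MAF vector, midranks for ties.  With ≤ 8
populations the two-sided p-value enumerates all k! orderings exactly
(720 at six populations), making the smallest attainable p 2/720; beyond
that a seeded Monte-Carlo permutation sample with an add-one correction is
used.  A constant MAF vector is degenerate (statistic 0, p 1, flagged).

## LD and haplotype blocks

Two-locus haplotype frequencies come from direct counting on phased data.
On unphased genotype tables only the double heterozygote is
phase-ambiguous; EM iterates its expected cis fraction with tolerance
1e-8 and a 1000-iteration cap, and the log-likelihood is non-decreasing by
construction.  A table consisting solely of double heterozygotes carries
no phase information: EM is returned at its 0.25 initialization and
flagged unidentifiable.  (For such a table the likelihood in the cis
fraction is maximized at the boundary, but EM's interior fixed point is
the natural uninformative report.)

D, D' and r² follow the standard definitions; D' confidence bounds use the
conventional normalized-likelihood grid over |D'| in [0,1] (101 points by
default, configurable), with allele frequencies fixed at sample estimates
and the sign of D from its point estimate.  The lower bound is the
smallest grid value whose cumulative likelihood reaches 5 %, the upper the
largest with 5 % upper-tail mass.

Gabriel blocks use the Haploview default thresholds, all exposed in
`GabrielParams`: strong LD when CI lower ≥ 0.70 and upper ≥ 0.98, strong
recombination evidence when upper < 0.90, a span is a block when ≥ 95 % of
its informative pairs are strong, with pairs involving a monomorphic
marker uninformative and excluded from the denominator.  Candidate spans
are selected greedily longest-first, ties to the leftmost start, into a
non-overlapping set.  The O(m²) pair scan is fine at the panel sizes this
package targets (tens of markers in a 100 kb window).  Multi-marker
haplotype frequencies within a block require phased input; generalizing
the two-locus EM to longer haplotypes is out of scope.

## Bifurcation trees and EHH

Trees are rooted at a core allele and extend marker-by-marker in physical
order, proximal or distal; equal positions are an input error.  At each
depth, haplotypes missing the next allele leave the tree and are counted
per depth, so the invariant "node counts at depth d sum to root count
minus cumulative drops" is always checkable (drop lists cover every
depth even when no haplotypes remain).  Missing data are dropped, never
imputed — branch widths must count observed haplotypes.  EHH(d) is the
pair-matching probability Σ C(n_h,2)/C(n_core,2); computing it from the
tree's depth-d counts or directly from haplotype strings gives identical
values, which the tests exploit as a cross-check.  At the core, allele A
(HbA, cut DdeI site) is treated as ancestral and T (HbS) as derived,
overridable.  Subsampling a panel to a fixed number of haplotypes per
population (analyses conventionally use 20) is an explicit seeded
operation, never implicit.

## Synthetic data: what it emulates, and what it does not

The generator produces the structures the analysis consumes:

* **Cohorts** — per-chromosome haplotype labels drawn from a mixture
  (multinomial by default, largest-remainder exact allocation on request),
  the five-site pattern realized verbatim from the table, HbS alleles
  binomial at the cohort frequency, and marker-SNP alleles independent
  Bernoulli draws per chromosome, i.e. genotypes under exact HWE — the
  study populations this emulates conform to HWE, and no inbreeding
  parameter is modelled.  Haplotype background and HbS allele are drawn
  independently (cohorts are overwhelmingly HbAA, so background-HbS
  linkage is negligible there).
* **Sequences** — one amplicon template with a placeholder window per
  locus; cut/uncut variants differ by a single base and the AC-repeat
  spacer can never harbor a recognition site (it contains no G or T), so
  digest ∘ emit is the identity on profiles and HbS alleles.
* **Panels** — founder haplotypes copied within blocks, founder choice
  independent across recombination breakpoints.  This block-copy model is
  deliberately simpler than coalescent simulation: it creates exactly the
  within-block LD and across-breakpoint equilibrium the block detector and
  bifurcation trees need, at desk scale, with analytically known truth.
  Complementary founder pairs (used by the pipeline and the boundary-
  recovery checks) keep every marker polymorphic with within-block
  |D'| = 1.

Default study conditions: three southern cohorts (South Africa n=50 with
HbS frequency 0, Zimbabwe n=50 at 0.06, Malawi n=58 at 0.035) with
atypical-heavy haplotype mixtures, and a six-population cline
(equatorial → southern) with ABO-proxy and HBB-proxy MAFs decreasing
0.35→0.12 and 0.30→0.10 and a flat 0.25 MARVELD3-proxy — two gradients and
one non-gradient.  The cline MAF values are illustrative of the
equatorial-vs-southern contrast, not calibrated to any specific dataset.

What passing tests therefore show: the algorithms are correct against
independent oracles and recover known generator truth.  What they do not
show: robustness to coalescent LD decay, genotyping error, demographic
structure or real recombination-rate variation — real panels should be
read in via the VCF interface and judged on their own.

Every spec carries an explicit seed; a master seed derives per-stage seeds
by SHA-256 hashing of stage names (stable across runs and platforms,
always < 2³¹).  Identical spec + seed gives byte-identical outputs.

## Problem sizes used by the checks

The acceptance script and test suite run at sizes chosen to make the
statistical assertions sharp but cheap: exhaustive HWE enumeration over
all 1 770 genotype tables with n ≤ 20; 50 random tables for EM vs a 1e-4
grid; block recovery on 12-marker panels with breakpoints at markers 4
and 8, 500 individuals, 10 seeds; 100 random panels for the bifurcation
oracle; 200 replicates at 500 individuals/population for trend power
(detection: negative statistic with exact p ≤ 0.05); n = 2000 individuals
for parameter recovery (3-binomial-SE bands).

## Known limitations

* No methylation sensitivity, partial digestion or gel-mobility modelling
  in the digest; no statistical phasing of unphased five-site genotypes.
* The frequency-only Fst carries no sample-size correction by design;
  use the Weir-Cockerham option when genotype tables are available.
* Multi-allelic sites are dropped (logged) at VCF input, not decomposed.
* Block detection assumes diallelic markers and modest marker counts;
  there is no genome-scale LD pruning.
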