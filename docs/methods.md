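# Methods

This note documents the statistical models behind `strpopkit`, the
conventions the implementation commits to, and what the synthetic-data
based tests do and do not establish.

## Data model

STR alleles are repeat-number labels with an optional partial-repeat
suffix (`13`, `13.2`). Labels are structured text, never floats: `13.2`
means 13 repeats plus 2 bases, and must stay distinct from any decimal
reading. Ordering is by (repeat count, partial bases), matching how
population surveys order table rows. Genotypes are unordered pairs stored
canonically. Missing calls are excluded per locus, so every per-locus
statistic uses that locus's typed count n_l; published panels typically
have complete data (n_l = n), and the missing-data handling is this
package's generalisation.

When a frequency table is loaded from a publication rounded to 4
decimals, allele counts are reconstructed as round(freq x 2n). This is
exact whenever the published cells came from integer counts (k/2n rounds
back to k for all n in the usual survey range), and documented as
approximate otherwise. A loaded column must sum to 1 within a tolerance
of 5e-3 by default (4-decimal rounding over up to ~25 alleles).

## Forensic parameter panel

Per locus, with p_i the allele frequencies, n typed individuals and h
heterozygotes:

- HO = h / n
- HE: biased form 1 - sum p_i^2, or unbiased (2n / (2n - 1)) times that.
  Both are implemented; the library default is the unbiased estimator,
  while the bundled published panel demonstrably used the biased form
  (the biased fit to its HE column is ~1e-4, the unbiased ~1e-3), so the
  mode is a flag, never hard-coded.
- PIC (Botstein): 1 - sum p_i^2 - (sum p_i^2)^2 + sum p_i^4.
- MP: observed convention sums squared observed genotype frequencies
  (the Powerstat-spreadsheet convention, default when genotypes exist);
  the expected convention sums squared Hardy-Weinberg genotype
  frequencies, 2 (sum p^2)^2 - sum p^4, and is the fallback when only a
  frequency table is available. PD = 1 - MP.
- PE = HO^2 (1 - 2 HO (1 - HO)^2) (Brenner convention; the alternative
  exclusion formulas in the literature are deliberately not implemented).
- TPI = 1 / (2 (1 - HO)), +inf with a warning when HO = 1.

Cumulative statistics multiply across loci in log space: CPD =
1 - prod MP_l and CPE = 1 - prod (1 - PE_l). A 21-locus CPD differs from
1 by ~1e-20, far beyond fixed-point display, so reports always carry the
complement prod MP_l in scientific notation alongside.

Report rounding is 4 decimals, half away from zero (the convention of
forensic tables); internal computation is always full precision.

## Hardy-Weinberg exact test

The test conditions on the observed allele counts m_a. Under the null,
a genotype array {n_ij} has the Levene probability

    P = n! 2^h prod_a m_a! / ((2n)! prod_{i<=j} n_ij!),

computed in log space. The p-value sums P over all arrays no more
probable than the observed one; ties belong to the tail
(conditional-probability ordering, the convention of standard exact-HWE
software). Exhaustive enumeration walks genotype arrays with a capacity
prune so every visited branch is feasible; `auto` enumerates up to 1e6
arrays (the pipeline caps this lower, at 2e4, for throughput) and
otherwise samples.

Sampling exploits a fact that simplifies both correctness and error
analysis: conditional on allele counts, all ordered arrangements of the
2n allele copies into n gamete pairs are equally likely (each array has
n!/prod n_ij! labelled assignments times 2^h orderings — exactly its
Levene weight). Two samplers are built on this uniform representation:

- `mc` (default for large problems): a full shuffle per replicate gives
  independent draws from the Levene distribution; the binomial standard
  error is exact. This is the "conventional Monte Carlo" variant of Guo
  and Thompson's proposal.
- `mcmc`: a switch chain that transposes two random allele tokens per
  step. On the uniform target every proposal is accepted, so the chain
  needs no acceptance ratio; burn-in defaults to 1e4 steps and the
  standard error is estimated by batch means (50 batches) to account for
  autocorrelation honestly.

An earlier chain formulated on unordered genotypes with a 2^(delta h)
acceptance was found to violate detailed balance (proposal multiplicities
differ between forward and reverse moves when alleles repeat) and was
replaced; the test suite pins both samplers to exhaustive enumeration on
random tables.

Monte-Carlo p-values use the add-one estimator (1 + hits)/(1 + reps) and
can never be 0.

## Genotypic linkage disequilibrium

The two-locus test is genotypic: no haplotype phase is assumed (none is
observable in an unphased population survey). The statistic is
G = 2 sum o ln(o/e) over the genotype-by-genotype contingency table;
significance comes from permuting locus-B genotypes among individuals
typed at both loci, p = (1 + #{G* >= G_obs})/(1 + reps). Each locus pair
draws from an independent seed stream derived from the master seed and
the pair name, so the matrix is reproducible regardless of evaluation
order. Bonferroni is the only default multiplicity correction (0.05/210
for a 21-locus panel, displayed at two significant figures as 0.00024).
Haplotype-frequency estimation (EM, D', r^2) is out of scope: the
workflow tests for LD, it does not estimate its strength.

## Differentiation and distances

`wc_theta` implements the Weir-Cockerham (1984) variance-components
estimator over r populations: per allele, the among-population (a),
among-individual-within-population (b) and within-individual (c)
components are formed from sample sizes, allele frequencies and
heterozygote proportions; theta = sum a / sum (a + b + c) over alleles
and loci. Negative estimates are legitimate (the estimator is unbiased
around zero differentiation) and are preserved in all reports; they are
floored at zero only inside exported distance matrices, because NJ and
MDS require dissimilarities, and the flooring is logged.

The permutation p-value shuffles individuals between the two populations
(sizes preserved), one permutation per replicate applied across all loci
so between-locus correlation of the statistic survives under the null;
default 1000 permutations with the add-one estimator.

Nei's DA distance is 1 - (1/L) sum_l sum_a sqrt(x_la y_la) over the union
allele space (alleles private to one population contribute zero). For
reference populations that published only frequency tables, Nei's G_st
((H_T - H_S)/H_T) and the Reynolds coancestry estimator are provided;
both are frequency-level approximations and deliberately not presented
as the genotype-based theta.

## Trees and ordination

Neighbour joining follows Saitou-Nei: minimise
Q_ij = (r - 2) d_ij - R_i - R_j, join, and compute branch lengths with
the standard formulas; the final three taxa close with the three-point
rule. Ties in Q are broken by the lexicographically smallest input-order
label pair, making output platform-independent; Newick children follow
input label order for reproducible text. Negative branch estimates
(possible for non-additive input) are clamped to zero with the deficit
moved to the sister branch, and logged. On additive matrices the
algorithm is exact, which the suite verifies against path-distance
round-trips and scikit-bio's independent implementation.

Classical (Torgerson) MDS double-centres the squared distances,
eigendecomposes, and embeds on the top k non-negative eigenvalues. The
full eigenvalue list is always reported so negative eigenvalues
(non-Euclidean input, routine for Fst matrices) are visible rather than
silently dropped; the strain statistic summarises the discarded mass. An
optional SMACOF refinement (Guttman updates from the classical start,
cap 300 iterations, tolerance 1e-6) is deterministic. Only the relative
configuration is meaningful; axes are arbitrary up to rotation and
reflection.

## Synthetic data generator

The generator produces data whose truth is known, so estimator recovery
is checkable end to end:

- Ancestral spectra: per locus, an allele count uniform on a configured
  range (default 5-18), labels drawn without replacement from the repeat
  ladder 7-24 with microvariant probability 0.08, frequencies from a
  symmetric Dirichlet (concentration 1). These defaults mimic the shape
  of real non-CODIS forensic panels (5-20 alleles per locus spanning
  repeats 7-24 with occasional microvariants).
- Population spectra: Balding-Nichols, Dirichlet(p_a (1 - F)/F), so
  E[p] = p_anc and Var[p] = F p (1 - p); F = 0 copies the ancestor.
- Genotypes: P(A_iA_i) = p_i^2 + f p_i (1 - p_i),
  P(A_iA_j) = 2 p_i p_j (1 - f), realised by drawing two parental
  alleles and copying the first with probability f. f = 0 is
  Hardy-Weinberg truth for type-I-error checks; f > 0 is the alternative
  for power checks.
- LD pairs: with probability r an individual's locus-B genotype is a
  fixed allele-rank image of its locus-A genotype, else independent.
  Injection is at genotype level because the pipeline's LD test is
  genotypic; haplotype-level LD is a documented non-goal.

The default panel dimensions (21 loci, 307 individuals per population,
12 populations) match the scale of the bundled survey so an end-to-end
run at publication scale is one command. Everything is regenerable
bit-exactly from (config, seed); derived random streams are keyed by
crc32 of stage/population names, never by Python's salted `hash`.

What the generator does not emulate: genotyping artefacts (stutter,
allelic dropout, null alleles), mutation processes, family structure, or
realistic linkage maps. Passing calibration tests on this generator
therefore demonstrates correctness of the estimators under the stated
models, not robustness to laboratory error.

## Bundled survey data and its reconstruction

The package ships the allele-frequency table and forensic-parameter
table of a published 21-locus non-CODIS survey of 307 Kyrgyz
individuals (168 alleles; machine-readable CSVs under
`strpopkit/data/`). The frequency table's machine-readable source had
lost the column alignment of rare alleles; the shipped copy was
recovered by constraint satisfaction — each locus column must hold
integer counts summing to 2n = 614 and reproduce the published per-locus
HE and PIC within print rounding, with repeat-nomenclature anchors for
the x.2 microvariant ladder — followed by a plausibility ranking of the
admissible assignments. The frequency values themselves are exactly the
published cells; only the locus attribution of a handful of
single-observation alleles is inferred, and the chosen table reproduces
the published PIC column at 4 decimals on 20 of 21 loci. The per-locus
summary statistics and all counting checks are invariant across the
admissible assignments.

## Scope of numeric reproduction

Per-locus and cumulative forensic parameters of the bundled survey are
reproduced from its own tables. Between-population results (pairwise
DA/Fst tables, tree and embedding layouts) depended on eleven reference
populations whose raw genotypes were never deposited; those analyses are
therefore validated by exactness and recovery properties on synthetic
data at matched scale (the structural-mirror test runs 1 genotyped + 11
frequency-only populations over 21 loci), not by numeric comparison.

## Problem sizes used in the test suite

Calibration checks run at sizes chosen to give stable rates while
keeping the suite interactive: HWE type-I error over 1000 biallelic loci
at n = 100; Monte-Carlo-versus-enumeration agreement over 100 tables at
n = 25 with 1e4 replicates; theta recovery over 200 replicates per F in
{0.01, 0.05, 0.15} at 21 loci x 300 diploids; permutation type-I error
over 200 same-source pairs at 8 loci x 80 diploids with 99 permutations.
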