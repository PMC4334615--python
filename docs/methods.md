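# Methods

## Study design being modeled

The package models a two-stage association design.  In the discovery
stage, DNA from 10 individuals per pool, two pools per condition (CTR,
SUP, OMA, DIE), is hybridized to an allele-specific SNP array, and
group allele frequencies are estimated from fluorescence rather than
genotypes.  In the replication stage, shortlisted SNPs are genotyped
individually in an independent case-control cohort.  The synthetic
cohort generator exists so that every stage can be exercised and
checked end to end with known ground truth.

## Synthetic cohort generator

* **Allele-frequency spectrum.** Population minor-allele frequencies
  are uniform on [maf_low, maf_high] (default [0.05, 0.5]).  The
  array's A/B labels are assigned at random per SNP
  (`random_allele_labels`, default on): on real chips the designated
  A allele is the minor allele for about half the SNPs, and without
  this the estimated F_A never approaches 0 and the mean-ratio
  pre-selection threshold of 20 could never fire.  Planted effect SNPs
  keep B as the minor allele so the configured odds ratio acts on the
  risk allele.
* **Effect model.** A planted SNP shifts the case-group allele
  frequency so the allelic odds ratio versus controls equals the
  configured value: p_case = OR·p / (1 − p + OR·p).  Genotypes are
  then drawn under Hardy-Weinberg equilibrium within each group
  (two independent Bernoulli alleles), which is the simplest model
  consistent with reporting allele-level odds ratios.
* **Pools.** Pool frequencies are exact functions of the genotypes:
  (allele-B copies in the pool) / (2 × pool size), so they live on the
  grid k/20 for 10-individual pools.  All measurement noise enters at
  the intensity stage.  An optional log-normal per-individual DNA
  quantity jitter (`pool_weight_jitter`, default 0) emulates imperfect
  pool equalization; it is off by default because the emulated
  protocol re-checks DNA quantity after pooling.
* **Intensity model.** For an allele with pool frequency q:
  PM = S·q·L + floor and MM = β·S·q·M + floor, with S the signal scale
  (1000 fluorescence units), β the mismatch leakage (0.1), floor = 20
  units, and L, M independent unit-mean log-normal factors with CV 0.1
  per probe (5 probes per SNP per allele).  Only PM − MM is consumed
  downstream, so the additive floor cancels and the noise-free
  estimate is exact; with the default noise the estimated pool
  frequencies track the truth with MAE ≈ 0.01 and correlation ≈ 0.997.
  The model is linear in frequency with no probe-sequence effects, no
  cross-hybridization structure, and a noise-free additive floor —
  passing tests therefore validate the statistical machinery, not the
  physics of any particular chip.
* **Missingness.** Individual genotype calls are masked uniformly at
  2.5% (matching a 97.5% genotyping rate) to exercise call-rate
  accounting; pooled DNA is unaffected by call missingness.
* **Seeding.** One global seed; every sub-stream (frequencies,
  genotypes per group, missingness, intensities, nulls per chromosome)
  is derived deterministically from it, so identical config + seed
  reproduce every output byte.

## Allelotyping

f = max(PM − MM, 0) per probe (real arrays show MM > PM on dim probes;
clamping keeps frequencies in [0, 1]), summed across probes per allele
(ratio of sums — robust to a single dim probe), then
F_A = f_A/(f_A + f_B).  A SNP × pool with zero total signal is marked
non-callable rather than raising; chip-level QC is treated as a
property of the input data.  Before any ratio, frequencies are clamped
to [ε, 1 − ε] with ε = 1e-4 so ratios stay finite and positive.

## Ratio statistic and pre-selection

The mean of the four case/control cross ratios and their coefficient
of variation (sample SD with n − 1 by default; the n convention is a
config switch) summarize each SNP × subtype.  Pre-selection keeps
mean ≥ 20 **or** mean ≤ 1/20: the depleted mirror is required because
an allele enriched in controls shows up as a tiny mean when the ratio
is formed with the array's fixed A allele.  Note that swapping cases
and controls maps a selected SNP into the opposite regime exactly only
for replicate-consistent (low-CV) ratio sets — the mean of reciprocals
is ≥ the reciprocal of the mean — but those are precisely the sets the
statistic is designed to reward.

## Monte-Carlo null and empirical p

For each chromosome, n_chip × n_reps artificial SNPs are simulated,
each with four random pool frequencies passed through the identical
clamp/ratio/mean/CV machinery.  Extremity is joint: a null pair is at
least as extreme as an observation when its mean is at least as far
from 1 in the same direction and its CV is no larger, which rewards
large, replicate-consistent shifts and penalizes noisy ones.

The raw dominance probability (1 + #extreme)/(1 + N) of a random null
pair is **not** uniform — it is a joint tail probability evaluated at
a random point — so it cannot serve directly as a p-value.  The
package therefore uses it as an ordering score and reports its rank
within the null's own scores, (1 + #{null score ≤ obs score})/(1 + N),
which is uniform under the null by construction, keeps the add-one
floor 1/(N + 1) for an observation more extreme than every null pair,
and preserves the intended ordering exactly.  The raw probability
remains available as `mode="dominance"`.  Self-scores for large nulls
are computed with an O(N log N) Fenwick-tree sweep (numba-accelerated
when available).

Two null-generation modes exist:

* `uniform` (default): four independent Uniform(0, 1) frequencies,
  clamped.  This is the historical choice, but it under-represents
  zero-count pools relative to any real MAF spectrum, so on pooled
  binomial data it is anticonservative for the clamp-floor-driven
  extremes (most pre-selected SNPs pass the 5% cut).
* `empirical`: resample observed per-SNP frequency quadruples and
  randomly permute each across the case/control slots.  Because the
  four pool frequencies of a null SNP are exchangeable, this
  permutation null is calibrated for the cohort at hand; it is what
  the calibration measurements use, and the recommended mode in
  practice.

The FDR stage keeps p < α (default 0.05) in `paper` mode — the
original design equated this cut with a 5% FDR — or applies
Benjamini-Hochberg in `bh` mode.  Shortlist rule A keeps SNPs whose
gene region carries ≥ 2 selected SNPs or that are selected in ≥ 2
subtypes; rule B keeps SNPs with p ≤ 0.001 whose control-pool
frequency is within 0.1 (absolute) of an external reference table
when one is supplied.

## Replication statistics

* Genotypic association: Pearson chi-square on the 3×2 table,
  all-zero genotype rows dropped, no continuity correction; a single
  informative row is flagged degenerate rather than tested.
* Allelic odds ratio: cross-product ratio on the derived 2×2 allele
  table, always oriented to the case-enriched allele (OR ≥ 1) — the
  convention that reproduces every published value — with the 95%
  Woolf interval; a zero cell triggers the Haldane-Anscombe +0.5
  correction and a flag.
* HWE in controls: 1-df chi-square goodness of fit by default, the
  conditional exact test as an option; monomorphic SNPs report p = 1
  with a flag.
* Breslow-Day heterogeneity across strata against the Mantel-Haenszel
  common OR, Tarone-corrected by default.  Discovery-stage strata are
  reconstructed from pool-frequency point estimates × pooled
  chromosome count, rounded — approximate by construction, since a
  pooled design never observes discovery allele counts — and the
  resulting Phet is reported but never treated as exact.
* Missing genotypes are excluded listwise per SNP and reported as a
  call rate.

## Problem sizes used in the shipped measurements

The test suite and acceptance script run the discovery machinery at
2,000 array SNPs × 200 Monte-Carlo replicates (and 1,000 × 100 inside
the 20-seed type-I loop), sizes chosen so the full statistical
behavior — pre-selection tail, calibration, power ordering — is
visible while a complete run stays interactive on one CPU.  Chip-scale
profiles (e.g. 19,865 SNPs on chromosome 1, ~262,000 total) are
configuration values, not code, and run the same path.

Power against planted effects is measured as the median empirical p of
10 planted risk alleles per replicate cohort, 20 replicate cohorts per
odds-ratio level (1.5, 2.5, 4), all planted at MAF 0.3: a single
planted SNP per cohort leaves the three-level ordering at the mercy of
pool-sampling noise (two pools of 20 chromosomes quantize frequencies
coarsely), while pooling planted SNPs estimates the same stochastic
ordering with usable precision.

## Known limitations

* No linkage disequilibrium, population stratification, or batch
  structure in the generator; every SNP is independent.
* The intensity model is linear with multiplicative noise only; no
  probe-sequence or GC effects, no saturation.
* The discovery stage's published 280-SNP list cannot be reproduced:
  it requires the original raw array data, which were never deposited.
  The package instead verifies the statistical properties the design
  claims (calibration, type-I control, power ordering, recovery).
* With 10-individual pools the mean-ratio ≥ 20 pre-selection can only
  fire through zero-count pools hitting the ε clamp, so pre-selected
  SNPs are dominated by rare-allele sampling extremes; this mirrors
  the magnitudes visible in the published top-ranked lists but makes
  the uniform null mode anticonservative (see above).
* The exact construction of the published cross-stage heterogeneity
  values is not recoverable; Phet is oracle-tested against a reference
  implementation but not asserted against published numbers.
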