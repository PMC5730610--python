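# Methods

## Data model

A `GenotypeMatrix` holds diploid calls for N individuals × L loci as
unordered pairs of per-locus integer allele codes, with a single explicit
missing sentinel; half-calls are rejected at construction (a VCF half-call
is demoted to missing on read). Population membership comes from an
explicit popmap, never from sample-name parsing. Loci carry optional
RAD-tag labels so one-SNP-per-tag selection can run; there is no global
allele registry because RAD tags are anonymous.

## Filtering

Three filters, applied in a fixed order:

1. **single SNP per tag** — the first locus in input order within each tag;
2. **MAF** — pooled over all typed individuals across populations, strict
   inequality (`maf > threshold`); for multiallelic loci MAF is defined as
   1 − (frequency of the most common allele), which equals min(p, 1−p)
   for biallelic loci. Monomorphic and fully missing loci always drop.
3. **completeness family** — for each cutoff k, keep loci typed in ≥ k
   individuals. Individuals are never removed. The summary reports
   100·k/N rounded half-up to one decimal (half-up, not banker's:
   100·30/96 = 31.25 must read 31.3).

MAF is evaluated once on the full matrix, not re-evaluated per family
member: the family members are meant to be nested subsets of one
upstream-filtered locus set.

## Estimators

Default: Nei (1987) / Nei–Chesser sample-size-corrected gene diversities
with ratio-of-averages multilocus aggregation (formulas in the README).
Decisions that matter under heavy missingness:

* A population with fewer than two typed individuals at a locus is
  excluded from that locus — the unbiased Hs needs n ≥ 2. A locus retained
  by a weak completeness cutoff may therefore rest on very few
  populations.
* A locus typed in < 2 populations has no F_ST; ht = 0 (monomorphic) makes
  F_ST undefined, hs = 0 makes F_IS undefined. Undefined values are NaN
  with explicit flags and are excluded from multilocus means — silently
  substituting 0 or 1 would manufacture or hide the extreme-locus tail
  that heavy filtering debates revolve around.
* Multilocus components (ho, hs, ht) are averaged over the loci typed in
  ≥ 2 populations, and F_ST/F_IS recomputed from those averages, so both
  ratios refer to one locus set.
* Multiallelic (microsatellite) loci go through the same formulas over all
  alleles.

**Weir–Cockerham θ** is the alternative estimator: variance components
a, b, c per allele per locus, per-locus θ = Σa/Σ(a+b+c), multilocus θ by
pooling components across loci. The two estimators differ in a way that is
itself informative: Nei's ht uses the unweighted mean of the sampled deme
frequencies, so with K demes its expectation is deflated by roughly
(K−1)/K relative to the island-model parameter F (≈ 0.092 for F = 0.1,
K = 12); θ corrects for deme sampling and centres on F. Both recover
F = 0.10 within ±0.015 on clean panels (L = 5,000), but a bootstrap CI
intended to cover a *generating* F must be built on θ — the Nei estimate's
CI covers its own population quantity, not F. The loci-bootstrap coverage
check in the tests uses θ for exactly this reason.

One-vs-rest pairwise F_ST relabels all non-focal individuals into a single
pooled population and reruns the multilocus estimator on the two-group
matrix. Per-location Ho/F_IS use each population's own loci
(Ho over loci with ≥ 1 typed member; F_IS from mean Ho and mean Hs over
the loci where Hs is defined, so F_IS = (He − Ho)/He holds exactly on that
shared locus set).

## Resampling

Because every multilocus statistic here is a ratio of per-locus component
averages, a replicate over a locus subset only needs the per-locus
components re-averaged; the implementation computes components once and
resamples them, which is exact, and keeps 100-replicate experiments cheap.

* Bootstrap CIs: loci resampled with replacement, percentile method
  (chosen over BCa for transparency), B = 1,000 by default, closed
  endpoints. Replicates on which the statistic is undefined are redrawn
  (cap 10·B) so the replicate count is exact.
* Subsampling: draws without replacement at each requested size,
  100 repetitions by default; each size's distribution is compared against
  the full matrix's estimate/CI and optionally an external reference CI.
* Seeding: replicate i of an experiment seeded s uses
  `default_rng(SeedSequence((s, i)))` (subsampling adds the size index),
  so any single replicate can be regenerated in isolation and results are
  platform-stable.

## PCA

Allele-dosage encoding (biallelic loci: count of allele 1; multiallelic
loci: one-hot per-allele dosages), centred by 2p̂, optionally scaled by
sqrt(p̂(1−p̂)) (the default, standard for SNP PCA; `none` is exposed
because normalisation conventions differ between tools). Missing dosages
are imputed to the locus mean before centring, so an individual with no
data sits at the origin rather than at an artefactual extreme.
Monomorphic columns are dropped with a warning; an all-monomorphic matrix
is an error. Components come from the SVD of the standardised matrix;
explained variances are the eigenvalues of the individual-covariance
matrix (column count as divisor), so they sum to its trace.

## Synthetic panels

The generator's default shape mirrors the sampling design the pipeline
targets: **12 populations × 8 diploids (N = 96)**, biallelic SNPs, one SNP
per (singleton) tag, ancestral minor-allele frequency uniform on
[0.05, 0.5] so panels pass a MAF > 0.05 filter by construction. Deme
frequencies follow Balding–Nichols with dispersion F (the expected F_ST);
Balding–Nichols was chosen over coalescent simulation because the
closed-form F target is the quantity every recovery test needs.
Microsatellite panels use symmetric-Dirichlet ancestral frequencies and
Dirichlet(ancestral·(1−F)/F) deme frequencies, the multi-allele analogue.
Genotypes are Hardy–Weinberg within demes. Everything is deterministic
from (config, seed).

Missingness mechanisms, layered on a clean panel:

* **MCAR** — one rate for every cell; the neutral baseline. Under MCAR the
  completeness-filtered estimates stay unbiased, which is what licenses
  attributing any filtering-dependent shift to the mechanism rather than
  the filter.
* **Per-individual** — each individual its own rate (sample-quality
  differences between collection sites).
* **Restriction-site allelic dropout** — the biased mechanism. Each locus
  gets a null allele *linked to one SNP haplotype background* (the
  background is drawn with probability equal to its ancestral frequency,
  so the null usually rides the major allele). The locus's ancestral null
  fraction within that lineage is drawn from `q_law` (default uniform on
  [0, 1]) and propagated to demes by Balding–Nichols with the panel's F.
  A copy carrying the linked allele is null with its deme's fraction: two
  nulls → missing call; one null → the surviving haplotype is called
  homozygous (a heterozygote is miscalled); zero → unchanged.

The linkage is essential, not decorative. If nulls strike gene copies
independently of allele identity, observed allele frequencies stay
unbiased and the sample-size corrections of the Nei–Chesser estimator
absorb the thinning exactly — no F_ST inflation appears (we verified this
both analytically and by simulation). With linkage, the deme-to-deme
variation of dropout severity distorts observed frequencies differently in
each deme and deflates heterozygosity preferentially for the common
allele, producing the three signatures together: missing data
concentrated in a subset of loci, a heterozygote deficit, and inflated
F_ST that grows as completeness filtering is relaxed (with a tail of
apparent fixed differences, F_ST > 0.975, at the most liberal cutoffs).

`q_law`'s default span [0, 1] makes per-locus missingness range from zero
to near-complete, matching the qualitative spectrum of real RAD matrices
where the weakest completeness cutoff retains loci present in only a
handful of individuals. A narrow law (say uniform on [0, 0.5]) caps
per-locus missingness near 25% and cannot populate that spectrum — no
locus is then removed even by moderate cutoffs and no extreme-F_ST tail
can form. The real per-locus dropout spectrum is unpublished; the default
is a documented assumption, not a fit.

What the generator does *not* emulate: read-level noise and depth-driven
genotyping error, linkage between loci, SSR stepwise mutation, migration
structure beyond the symmetric island model, and the very high overall
missingness fraction (≫ 50%) of raw RAD 'populations' output, which in
real data also reflects depth variation across libraries. Passing tests
therefore demonstrate the statistical machinery and the dropout mechanism,
not a calibrated reconstruction of any particular empirical matrix.

## Problem sizes in the tests

The test suite and acceptance script size their simulations to what the
claims need: L = 5,000 loci for estimator recovery (Monte-Carlo error
≈ 0.002), 20 seeded replicates at L = 1,500 for the dropout-bias
direction, 100 seeded runs at L = 1,000 (B = 200) for bootstrap coverage,
and 2,000 loci for PCA separation — the smallest sizes at which the
expected effects dwarf their Monte-Carlo noise.

## Known limitations

* The Nei-estimator deme-sampling deflation (above) is reported, not
  corrected; use θ when an absolute island-model F is the target.
* Percentile bootstrap CIs undercover slightly at small locus counts
  (8-locus microsatellite panels have very wide, unstable CIs — which is
  itself the scientifically expected behaviour).
* The dropout corner case q = 1 silences every copy of the linked lineage;
  calls not carrying that lineage survive. A model in which q = 1 wipes
  the whole matrix would require allele-independent nulls, which (see
  above) cannot express the biases this package exists to study.
* genepop support covers the standard 2-/3-digit diploid dialect only.
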