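# Methods

## Problem and model

Given a curated set of risk alleles for a trait and multi-population
genotype (or frequency) data, the package answers three questions: is a
given risk allele over- or under-represented in a population relative
to a pooled reference; which populations share enrichment profiles; and
how does a population's aggregate risk-allele burden relate to disease
prevalence.

### Effect-allele harmonization

A catalog row reports a "strongest SNP-risk allele" (`rsID-X`) plus an
odds ratio or beta. The effect allele used for counting is the reported
allele when OR > 1 or β > 0, and the *other* member of the biallelic
pair when OR < 1 or β < 0 (orientation `flipped`). Evidence exactly at
the null (OR = 1, β = 0) or absent leaves the direction undefined:
those records are kept with orientation `ambiguous` and the reported
allele (or the ALT allele when the risk allele is printed as `?`) is
used for counting. Dropping them instead would systematically remove
variants whose minor allele is poorly annotated and bias subgroup
comparisons; the flag propagates to all outputs so users can exclude
them. Deduplication keys on (rsid, trait), keeps the first occurrence,
and prefers a direction-resolved copy over an ambiguous one — the
criterion is deterministic and auditable, which matters more here than
any particular choice among duplicates. A reported allele matching
neither REF nor ALT is a harmonization error; the record is quarantined
with a reason rather than silently dropped.

### Allele frequencies

Effect-allele dosage of a diploid sample is the number of copies of the
effect allele (0/1/2); when the effect allele is the VCF REF, dosage is
2 minus the ALT count. Only biallelic SNPs are used; multiallelic sites
and allele-pair mismatches are skipped and reported. Per SNP and group,
`EAF = Σ dosage / (2 × n_called)` with the denominator counting
non-missing calls only (reference panels of this kind are essentially
complete, so this choice is almost always invisible, but it keeps the
estimator unbiased under sporadic missingness). All coordinates are
1-based; no half-open intervals anywhere. Palindromic (A/T, C/G) sites
are processed but flagged, since their strand cannot be verified from
the allele pair alone. Frequency-only cohorts get counts reconstructed
as `round(EAF × 2N)`; such cells carry a `reconstructed` flag because a
frequency printed to 2–4 digits bounds the statistic's precision.

### The signed enrichment statistic

For population counts (k_pop, n_pop) and reference counts
(k_ref, n_ref) the two-sided Fisher exact P sums hypergeometric
probabilities of all tables (at the fixed margins) no more likely than
the observed one, with the conventional 1e-7 relative tolerance for the
"no more likely" comparison. The summation runs in log space: log-pmf
terms from log-gamma, combined with logsumexp. This is not cosmetic —
with a 3,444-chromosome cohort against a 5,008-chromosome reference,
P values below 1e-300 occur in real data, and the log-space sum yields
the exact log10 P where a linear-scale computation returns 0. The
linear P is reported too, floored at the smallest positive double with
a saturation flag. The signed statistic is `-log10(P)` when
eaf_pop > eaf_ref, `+log10(P)` when below, 0 at equality; a cell is
`enriched` when the value strictly exceeds 1.301, `depleted` below
−1.301, else `similar` (1.301 = −log10 0.05). No multiple-testing
adjustment is applied in the default path — the threshold is a raw
P < 0.05 rule — and one-sided alternatives are available behind a flag.

The default reference pool *includes* the focal population (a
population is compared against the global average it is part of). An
`exclude_focal` mode subtracts the focal counts from the pool first;
the tests' null-calibration check uses that mode, since only there is
the comparison statistically independent and the nominal type-I rate
meaningful.

### Clustering and the frequency comparison

Population columns of the signed matrix are clustered
agglomeratively. The default distance is correlation distance
(1 − Pearson r between profiles) with average linkage: the magnitude of
a signed log10 P scales with cohort size, so under Euclidean distance a
large cohort (the n = 1722 Korean column, |values| up to ~245 against
~100-sample 1000 Genomes populations) separates from everything as a
singleton regardless of its pattern, which is a statement about sample
size, not ancestry. Correlation distance compares the *shape* of the
enrichment profile and is invariant to that scale; on the bundled
reference panel it yields the same two continental blocks for average,
complete and Ward linkage. Euclidean distance remains available.
Missing cells are imputed as 0 (absence of evidence of deviation) and
counted; columns are sorted lexicographically before linkage so ties
break deterministically, and the tree is emitted as a merge list and a
Newick string whose branch lengths are merge-height differences.

The Kruskal–Wallis rank-sum test compares the per-population EAF
distributions over the SNP set (scipy implementation, tie-corrected,
chi-squared approximation with groups − 1 df). The all-ties degenerate
case is reported as H = 0, P = 1.

### Composite genetic risk score

`score = Σ Xᵢ / (2 I)` over the SNP set, unweighted. Missing dosages
are dropped from numerator and denominator and `n_snps_used` is
reported; a sample with no usable SNP is rejected. The score is linear
in the dosages, so a population's mean score equals its mean EAF over
the SNP set when nothing is missing — an identity the tests assert to
1e-12. Equal weights are deliberate: per-allele effect sizes estimated
in one ancestry transfer poorly to others, so a weighted score would
import exactly the bias this analysis is trying to measure; a
log-OR-weighted variant exists as an extension but is not part of any
validated result. The release-concordance filter retains a SNP iff the
frequency difference between two releases of the same cohort is ≤ 0.10
(strictly greater differences are excluded; the boundary is kept).
High-pressure prevalence is decomposed as
`(1 − NTG proportion) × OAG prevalence`, and population mean scores are
correlated with prevalence by Pearson R over the inner join on group
labels (≥ 3 groups required; constant vectors are an error, dropped
groups are reported).

## Synthetic data

The generator emulates the structure of a 1000-Genomes-style resource —
populations nested in super-groups, per-SNP global frequencies,
population drift, HWE diploid genotypes — via the Balding–Nichols
model: p_pop ~ Beta(p(1−F)/F, (1−p)(1−F)/F), mean p, variance p(1−p)F,
with fixed frequencies (0/1) passing through. Defaults: global
frequency prior Uniform(0.05, 0.95) to avoid boundary degeneracies;
dosages Binomial(2, p_pop); rsIDs from rs900000 up to avoid colliding
with real identifiers; everything deterministic under the spec seed.

`scenario_two_clusters` is the standard fixture: 60 SNPs, six
populations of 200 in two super-groups, ±0.25 shifts on the first 20
SNPs (opposite sign per super-group, so the pooled reference stays at
the global frequency and the designed cells are genuinely enriched or
depleted against it), within-super-group drift F = 5e-4. That drift
value comes from a power calculation, not tuning: at 500 samples per
population against the pooled reference, frequency deviations of about
0.034 become significant at the 1.301 threshold, while F = 5e-4 drift
perturbs null frequencies by sd ≈ 0.011 — comfortably below it — so
null cells stay `similar` and the recorded per-cell truth is
recoverable. What the generator does *not* model: linkage
disequilibrium between SNPs, non-equilibrium demography, genotyping
error and strand flips, and correlated drift between populations.
Passing the recovery tests therefore shows the pipeline is correct
under idealized sampling, not that real panels are this clean.

## Bundled reference tables

The two 52-SNP tables (global and East Asian scope) carry published
per-population EAFs and signed log10 P values for the IOP-associated
SNPs, with cohort sizes recorded in `refdata.COHORT_SIZES`.
Reconstructing counts from the printed frequencies and re-running the
package's Fisher statistic reproduces the printed statistics almost
exactly (correlation > 0.999 on the Korean column), which both
validates the implementation and confirms the published values are
plain two-sided Fisher tests of the reconstructed tables. The printed
Korean column of the global table classifies as 24 enriched / 26
depleted / 2 similar at the 1.301 threshold. The companion 135-SNP
panel exists only as supplementary spreadsheets and is not
redistributed; `refdata.load_oag_panel()` raises a descriptive error,
and the analyses that need it (its classification counts, the
Kruskal–Wallis value computed on it) are expressed in the test suite
but cannot pass without that data.

## Numerical and design notes

- Fisher exactness is tested against a pure-integer enumeration oracle
  (exhaustive for small margins, seeded random up to margins of 30) at
  1e-12, and against an independent library implementation on large
  counts.
- P values are never clamped before the log — the signed statistic is
  derived from the log-space sum directly, so it is exact even when
  the linear P saturates.
- Classification uses strict inequalities at ±1.301; a value exactly at
  the threshold is `similar`.
- Monte-Carlo test tolerances are 3 standard errors from closed-form
  moments (Beta moments for drift, binomial for HWE, empirical SE for
  score means); problem sizes (10,000 individuals × 135 SNPs for the
  score expectation, 200 SNPs × 6 × 300 samples for null calibration,
  500/population for ground-truth recovery) keep the whole suite under
  a minute on one CPU.
- Pipeline runs are reproducible: sorted-key JSON, fixed float formats
  (frequencies at 6 decimals), and a manifest recording config, seed
  and version; reruns are byte-identical.

## Known limitations

Strand is never flipped beyond REF/ALT orientation, so a palindromic
SNP reported on the opposite strand would be mis-counted (it is flagged
but not corrected). Reconstructed counts inherit the printing precision
of published frequencies; statistics computed from them are faithful to
roughly the same precision, which is why published log10 P magnitudes
are reproduced to pattern rather than digit. The prevalence correlation
is an interface, not an inference: with a handful of populations and
literature prevalence estimates, R carries no uncertainty
quantification here.
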