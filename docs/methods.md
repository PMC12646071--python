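# Methods

## Model and assumptions

A doubleton is a site where one base (the major allele, taken throughout as
the ancestral state — no outgroup polarization) is carried by all but two of
the m sampled haploid genomes and a single other base by exactly two. Two
generative scenarios are considered: (i) a single mutation inherited by two
genomes that are, at that site, each other's closest genealogical relatives
("reciprocal closest relatives", RCR); (ii) two independent mutations on two
external branches — a recurrent doubleton, whose carriers are unrelated
beyond the population average. Doubletons whose minor allele is ancestral,
and back-mutation histories, are assumed negligible (the simulator flags
them; they are well under 1% in all shipped configurations).

### Recurrence estimation from triallelic singletons

Conditional on a site with ancestral base X having received two external-
branch mutations, the chance both hit the same base Y is P[X→Y]², while the
chance of hitting two different bases Y, Z is 2·P[X→Y]·P[X→Z]. Eliminating
the unknown per-class probabilities gives the identity implemented in
`mutation_spectrum.estimate_recurrent_count`:

    Nest[X→Y,Y] = N[X→Y,Z1] · N[X→Y,Z2] / (2 · N[X→Z1,Z2])

with N the observed triallelic singleton counts. The per-class recurrent
proportion is Nest/D; the overall proportion is a ratio of sums ΣNest/ΣD,
never an average of ratios. The estimator assumes class-specific mutation
probabilities constant along the genome (no sequence-context effects) and
that triallelic singletons arise from exactly two external-branch mutations.
Classes whose denominator count is zero are undefined (a hard error for the
single-class function; excluded with a warning from the overall sums).

Confidence intervals: for each major base the three triallelic pair counts
are resampled as one multinomial with trials equal to the number of genome
sites with that major base and event probabilities N/trials; the estimator
is recomputed per replicate and the 2.5th/97.5th percentiles taken
(percentile intervals, no bias correction; 10,000 replicates by default —
percentile intervals from only a few hundred replicates are measurably
anti-conservative). Doubleton counts are held fixed. When the input is a
variant-only table (e.g. simulator output), invariant genome positions are
added to the trial counts assuming a uniform base composition.

### Segment scan on unphased genotypes

Two individuals identical by descent around a focal site cannot be
homozygous for different alleles inside the shared tract. The scan walks
outward from the focal site over the biallelic-restricted site table to the
nearest such "inconsistent homozygote" site on each side; heterozygous
sites never terminate a scan. Bounds are the inconsistent positions
themselves and length = right − left, overcounting the shared tract by the
two boundary sites — kept for comparability with the difference-of-positions
statistic. Scans reaching a contig end are discarded and counted; doubletons
carried as one homozygous individual are excluded; segments are
deduplicated on (pair, bounds), a segment possibly carrying several
doubletons. Matched "random" segments rerun the scan from the same focal
position for a seeded uniform pair of non-carriers.

### Bayes update from linked rare variants

P[RCR|¬d] for two random diploid individuals has the closed form 8/(3(m−1))
(4 cross-individual sequence pairs × the haploid form 2/(3(m−1)), itself
the exact sum over coalescent histories; the test suite verifies the
identity in exact rational arithmetic). A linked rare variant (LRV) is a
minor allele of sample-wide haploid count n ∈ [2, n_max] carried (≥1 copy,
unphased) by both segment individuals strictly inside the bounds, the focal
doubleton site(s) excluded; allele counts are taken on the full table, not
the biallelic restriction. P[LRV|d] and P[LRV|¬d] are the fractions of
doubleton and random segments whose smallest shared-variant count is ≤ n
(cumulative) or exactly n (incremental). The Bayes factor (an approximation
that assumes the two segment classes exhaust the possibilities) is

    BF ≈ 1 + (P[LRV|d] − P[LRV|¬d]) / (P[RCR|d]·P[LRV|¬d] − P[LRV|d]·P[RCR|¬d])

and posterior odds = prior odds × BF. The calling threshold n* is the
largest n whose incremental posterior, and that of every smaller count,
is ≥ 0.95; calling uses the overall prior only (per-class priors are
computed and exported but not used). Cumulative proportions drive calling;
incremental ones drive threshold selection.

## Simulation design and truth extraction

Four demographic scenarios are simulated with msprime (Hudson coalescent,
discrete genome, Jukes–Cantor finite-site mutations, so triallelic and
recurrent configurations arise naturally): panmictic/5-deme island ×
constant-size/100-fold instantaneous expansion. Truth: each carrier
genome's allele is traced to the nearest recorded mutation event on its
root path; a doubleton's origin count is the number of distinct events
across its two carriers (0, with a flag, when the minor allele is the
untouched ancestral state; such sites count as non-recurrent and non-RCR).

Two desk-scale preset families ship, both 1/1000 diffusion rescalings of
the reference parameters (sizes and times ÷1000, μ ×1000), which preserve
θ = 4Nμ per bp and hence all site-count distributions:

- `DESK_SCENARIOS` (segment pipeline, calibration): 50 diploids, 300 kb,
  1–4 pooled replicates. The recombination rate is set below the strict
  rescaling (ρ = 0.06/bp instead of 0.72/bp): per-site counts are
  recombination-independent, genealogies still turn over every few tens of
  bp, and the saving buys several-fold more sequence per CPU-second;
  shared segments are correspondingly longer than a strict rescaling would
  give.
- `ESTIMATOR_SCENARIOS` (estimator CI validation): 150 diploids (300 for
  the higher-diversity island scenarios), 3 pooled replicates of
  0.5–1.5 Mb, ρ further reduced. The ratio estimator has two
  finite-size biases that the reference-scale conditions render negligible
  and these presets keep small relative to the CI width: a plug-in bias
  ∝ 1 / per-cell triallelic count, and contamination of the triallelic
  counts by sites where one "singleton" is the ancestral base stranded on
  a single genome — measured at ~4.5% of triallelic sites at m = 100,
  halving with each doubling of m (~1.5% at m = 300).

A structural caveat applies to CI-versus-truth coverage in these
validations: the bootstrap interval carries only the estimator's
(triallelic-count) sampling noise, while the "true" recurrent proportion
it is compared against is itself a realized fraction over the run's
finite set of doubletons. At matched θ the two noise sources are
comparable (σ_truth ≈ 0.8·σ_estimate for the constant-size scenarios) and
their ratio is scale-invariant — both shrink as 1/√L — so the effective
per-run coverage of a nominal-95% interval tops out near 85–90% even for
an unbiased estimator, at desk scale or any other. The percentile
interval's short left tail (the ratio statistic is right-skewed, so the
interval sits slightly above the point estimate) costs a few further
points when the estimate runs high. Point estimates themselves agree with
truth to within a few percent in all four scenarios.

The island migration rate cannot be rescaled (0.01 × 1000 > 1 per
generation); presets use 0.05/generation, keeping the strong-migration
regime (4Nm ≫ 1) of the reference configuration. Reference-scale configs
(`FULL_SCENARIOS`: N up to 10⁸, 1,000 diploids, 70 × 1 Mb) are included
but are cluster-scale.

What the synthetic data does not emulate: sequencing and genotyping error,
missing-data patterns and accessibility masks, sequence-context mutation-
rate variation (the kernel is uniform), gene conversion, selection, and
chromosome-scale recombination-rate heterogeneity. Passing validation
therefore shows the estimators are correct for clean genotypes under the
stated genealogical model, not that real-data artifacts cannot bias them;
on real data the quality filters (accessibility mask, missingness removal)
stand in for the clean-genotype assumption.

## Numerical choices

- Nest is carried at full precision; rounding (half-up) only for display.
- The overall prior is clamped just inside (0, 1) for degenerate inputs
  with no triallelic evidence, keeping the odds update defined.
- In bootstrap replicates, a class with zero resampled numerator counts
  and a zero denominator contributes 0 (no evidence of recurrence); a zero
  denominator with non-zero numerators is undefined and excluded from that
  replicate, mirroring the point estimator's rule.
- Eq.-5 Bayes factors with a non-positive denominator, or non-positive BF
  values at noisy thresholds, are masked (NaN) in posterior curves rather
  than raised; threshold selection stops at the first masked or failing
  count.
- Coordinates are 1-based inclusive everywhere except BED output
  (0-based half-open). VCFs with non-increasing positions are rejected;
  duplicate-position records are skipped with a log count.
- Ties for the major allele are classed `other_polymorphic` and excluded
  from all estimators.
- Median standard errors in grouped reports use the binomial
  order-statistic method by default (a seeded bootstrap is available),
  since the choice is not standardized in the field.

## Known limitations

- The Bayes factor is an approximation; its error is bounded empirically
  by the calibration check (inferred posterior within ±0.05 of the true
  RCR fraction at every populated threshold in the shipped scenarios)
  rather than derived.
- Per-class calling thresholds, multiple-LRV evidence combination, and
  k-ton (k > 2) extensions are out of scope.
- The estimator degrades when per-cell triallelic counts are small
  (plug-in bias) or samples are small (ancestral-singleton contamination);
  both regimes are quantified above and avoided in the shipped presets.
- Statistical phasing, genotype calling and annotation pipelines are out
  of scope; site-class comparisons accept any labelled BED as input.
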