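# Methods

## The assay being modeled

A test strain (plasmid-carrying and/or chromosomally mutated,
GFP-negative) is mixed 1:1 with a GFP-tagged wild-type reference,
diluted 1:400 into fresh medium, and grown for one batch cycle.
Competitor proportions before and after growth are measured by flow
cytometry (10,000 events per measurement). Each strain is competed in
six replicates; the plasmid-free wild type, which anchors the
normalization, in 36.

## Relative fitness

For one replicate, with cell numbers N of each competitor before and
after the cycle,

    W = ln(N_final,gfp− / N_initial,gfp−) / ln(N_final,gfp+ / N_initial,gfp+).

W is the ratio of realized Malthusian parameters; W = 1 is neutrality.
The log base is irrelevant to W (natural log is used for intermediates).

**Counts scale.** Cytometry measures proportions, not absolute numbers,
and W is *not* invariant to rescaling the two timepoints independently:
adding the same constant ln(b/a) to both the numerator and denominator
of a ratio of logs changes the ratio unless the two fold-changes are
equal. W therefore requires counts on a common scale per competitor —
proportions multiplied by the culture size at each timepoint, or any
per-competitor consistent scale. The two invariances that do hold, and
are property-tested, are (i) joint rescaling of all four counts and
(ii) rescaling both counts of one competitor by one constant.

**Normalization cascade** (order fixed):

1. `vs_gfp_reference`: the raw W above, per replicate.
2. `vs_plasmid_free_wildtype`: median over the strain's replicates
   divided by the median over the plasmid-free wild type's replicates
   (this removes the cost of the GFP tag). Per-replicate values divide
   each replicate by the control *median* — replicates are not paired
   with control replicates, since only medians are anchored.
3. `vs_plasmid_carrying_wildtype`: optional further division by the
   plasmid-carrying wild type's fitness, for cross-background displays.

Medians of an even number of replicates are the mean of the two central
order statistics. Zero counts raise an error by default; an explicit
`pseudocount=True` substitutes one event instead (silent pseudocounts
distort small competitions, so this is opt-in). A pseudocounted record
can legitimately yield W ≤ 0 (the competitor declined), so fitness
estimates are only required to be finite; positivity is enforced where
the cascade divides.

Cost is reported as (1 − W) × 100 percent; negative costs are benefits.

## Epistasis

The multiplicative null for a plasmid p and mutation m is
W_expected = W(p;−) · W(−;m), both marginals being medians at the
`vs_plasmid_free_wildtype` level. Epistasis is

    ε = W(p;m) − W(p;−) · W(−;m).

Replicate-level ε subtracts the product of marginal *medians* from each
replicate W (again not replicate-paired). For the wild type both
marginals are 1, so its ε replicates are W − 1 and its median ε is zero
by construction: the reported aggregate is evaluated median-first
(median(W)/median(W) − 1), which is exactly 0.0 in floating point; the
median of the per-replicate group agrees to machine precision.

**Classification.** The comparison family consists of the ε-groups of
all plasmid–mutation combinations plus the wild type; single-determinant
strains are excluded because their ε is identically zero by construction
(observed equals marginal), exactly like the wild type's. An omnibus
one-way ANOVA over the family is computed and reported; each combination
is contrasted against the wild-type group with a Tukey-adjusted p value
(studentized-range adjustment over the full family of pairwise
comparisons; the contrasts against the control are computed directly via
the Tukey–Kramer statistic, which is numerically identical to the
full-family computation and much cheaper for ~20 groups). A combination
is called positive/negative by the sign of its median ε when its
contrast is significant at α (default 0.05), otherwise "none"; the Tukey
adjustment already controls the family-wise error, so no additional
omnibus gate is applied. A significant contrast with median ε exactly 0
(a measure-zero tie) is classified "none" with a warning. The family is
one panel of genotypes per analysis; analyses of separate mutant panels
form separate families.

**Sign epistasis** is called when the double-determinant strain's median
fitness exceeds both single-determinant strains' and both Tukey
contrasts (within the three-group family) are significant at α.

An error-propagation alternative (`bootstrap_epistasis_test`) estimates
the standard error of median(combo) − median(p)·median(m) by bootstrap
and returns a normal-approximation p; it is a cross-check mode, not the
default.

## Generic statistics

Classical (non-Welch) one-way ANOVA (`scipy.stats.f_oneway`; F = 0,
p = 1 when all values are equal), Tukey HSD (`scipy.stats.tukey_hsd`),
and Spearman rank correlation with average ranks for ties. For n < 10 —
the size of the feature-vs-cost screens — the Spearman p value is an
exact permutation probability (all n! pairings enumerated); for larger
n the usual t approximation is used. Tests are two-sided throughout.

## Plasmid features

- **CAI**: relative adaptiveness w(c) = freq(c)/max synonymous freq per
  family under the bacterial genetic code (NCBI table 11);
  zero-frequency sense codons floored at w = 0.01; single-codon families
  (ATG, TGG) included with w = 1. CAI of an ORF is exp(mean ln w) over
  its codons; stop codons excluded (an internal stop warns but the value
  is computed); codons containing ambiguous bases skipped and counted.
  Alternative start codons are scored as the literal codon.
- **GC%**: 100 × (G+C)/(A+C+G+T); ambiguity codes excluded from both
  numerator and denominator.
- **Copy number**: mean plasmid depth / mean chromosome depth from a
  3-column per-position depth TSV (1-based positions).
- **ORF extraction**: CDS annotations, 1-based inclusive coordinates on
  input converted to Biopython's 0-based half-open internally; minus
  strand reverse-complemented; circular wrap-around joins supported.
  No ORF length filter is applied.
- The bundled reference table (`data/ecoli_k12.cut`) carries E. coli
  K-12 codon frequencies typed from standard published usage values; any
  EMBOSS-style `.cut` file or 2-column TSV (codon, count) can be
  supplied instead (dialect auto-detected; only within-family ratios
  matter).

## The synthetic-data generator

The generator emulates the assay's statistical structure, with defaults
fixed at the protocol's design constants: expansion factor G = 400
(the dilution, so one cycle returns the culture to carrying capacity),
10,000 events per measurement, 6 replicates per strain and 36 for the
wild type.

- **Growth**: over one cycle the reference expands by G and the test
  strain by G^w. This is the unique model under which the log-ratio
  estimator is exact in the noise-free limit (W being a ratio of
  Malthusian parameters), making the round-trip property testable in
  closed form.
- **Cytometry**: a two-class multinomial draw at fixed total events, at
  each timepoint; sampled counts are rescaled to the latent culture
  total so records carry counts on the common scale the estimator
  needs. No doublet/debris classes — gating is out of scope.
- **Growth noise**: optional lognormal perturbation of each
  fold-expansion, independent per competitor per replicate
  (median-preserving: F·exp(ε), ε ~ N(0, sd²)); default sd = 0.
- **Landscape**: marginal fitness values for single-determinant
  genotypes; combinations get the product of marginals plus an optional
  additive epistasis shift. The wild type has w = 1 by construction.
- **Seeding**: replicate r of genotype g uses a SHA-256-derived seed
  from (master seed, g, r), so streams are independent of execution
  order and runs are byte-identical under a fixed seed.
- **Toy plasmids**: circular records with non-overlapping ORFs
  (ATG ... stop, length divisible by 3, random strand); internal codons
  drawn per amino acid, choosing the family-optimal codon with
  probability `codon_bias_strength`; intergenic bases adjusted to hit
  the target GC (an error is raised when ORFs leave too little
  intergenic space to reach it).
- **Depth tables**: gamma-distributed per-position depths with the
  requested coefficient of variation (constant when 0); plasmid mean =
  copy number × chromosome mean. Default sizes 5,000 chromosome and
  1,000 plasmid positions.

What the generator does *not* emulate: plasmid loss or conjugative
transfer during competitions, arabinose-induction kinetics, cytometry
gating artefacts, day/block effects, or non-exponential growth phases.
Passing tests therefore show the estimator and classifier are correct
for the assay's sampling structure, not that real competitions are free
of those effects.

## Simulation study sizes and calibration

The null-calibration and power studies use a 6-plasmid × 3-mutation
factorial (costs 10–30% and 20–40%, matching the magnitudes typical of
such panels), 200 simulated experiments per study. Under the null the
pooled fraction of combination calls that are not "none" runs near
0.01 at α = 0.05: Tukey's adjustment controls the family-wise rate
across the whole panel, so per-combination false calls are much rarer
than α, partly offset by the shared-marginal-median noise that the
replicate-level ε construction introduces between groups. Because the
rate is this small, a 200-experiment estimate of it still carries a
standard error of roughly 0.002 (calls cluster within experiments), so
individual 200-experiment estimates scatter noticeably around the
structural value. An injected ε of +0.10 is recovered as "positive"
essentially always at this design (per-replicate W noise at 10,000
events is ~0.01).

The sampling-consistency study (500 experiments × 6 replicates at
true w = 0.8) bounds the median estimator's bias well inside ±0.02.

## Known limitations

- The ANOVA/Tukey machinery assumes roughly equal within-group
  variances; strongly heteroscedastic panels would need a Welch-type
  alternative, which is deliberately not implemented.
- ε-groups share the control median and marginal medians, so they are
  not independent; the classifier is calibrated by simulation (above)
  rather than by exact theory.
- The copy-number proxy assumes unbiased, uniform read mapping to both
  replicons; real GC- or repeat-driven mapping bias is not modeled.
- CAI uses the reference-usage weight convention with a 0.01 floor;
  expression-weighted variants are out of scope.
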