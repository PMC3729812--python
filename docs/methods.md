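# Methods

## The statistical problem

A GWAS-derived set of risk loci is treated as one candidate network, and the
question is whether that network departs from genome-wide patterns of
population differentiation and haplotype structure — the signature expected
if selection has acted on an appreciable fraction of its members. All three
tests in this package are *empirical*: the null distribution is always the
rest of the genome (or a simulation standing in for it), never a fitted
demographic model. This is deliberate; human demographic history is complex
and poorly identified, and demography moves the whole genome together, so a
candidate set that stands out against random genomic regions cannot be
explained by demography alone.

## Weighted F_ST

Per SNP, for `r` population samples with `n_i` sampled chromosomes (twice
the non-missing diploid count), alternate-allele counts `a_i`,
`p_i = a_i/n_i` and `p̄ = Σn_i p_i / Σn_i`:

```
MSP = Σ n_i (p_i − p̄)² / (r − 1)
MSG = Σ n_i p_i (1 − p_i) / Σ (n_i − 1)
n_c = (Σ n_i − Σ n_i²/Σ n_i) / (r − 1)
F_ST = (MSP − MSG) / (MSP + (n_c − 1) MSG)
```

Pooled comparisons (e.g. a continental group) merge their samples into one
sample, so scans are always `r = 2`. The estimate is ≤ 1, equals 1 exactly
when there is no within-sample variation, and is negative when between-sample
variation falls below its sampling expectation (identical frequencies give
`−1/(n_c − 1)`). Sites monomorphic across both samples have no defined
estimate and are flagged rather than scored 0. A site is **qualifying** when
its estimate is defined and strictly positive; all downstream fractions use
qualifying sites only. Chromosome counts (not individual counts) are used
because allele counts are the sufficient statistic at this level. Sites
where a pooled sample has fewer than two chromosomes are skipped and logged.

Two cautions that the test suite makes explicit: the *mean of per-site
ratios* is not an unbiased estimate of genome-wide differentiation (the mean
over qualifying sites is biased up by the positivity constraint, the mean
over all segregating sites is biased down by ratio nonlinearity). Where a
single differentiation parameter is wanted, `multilocus_fst` combines the
per-site mean squares as `Σ(MSP − MSG)/Σ(MSP + (n_c − 1)MSG)`, which is
consistent for the Balding–Nichols drift parameter and is what the
parameter-recovery tests assert on.

## Region scoring and the empirical null

Candidate loci become fixed 50-kb analysis windows: a locus ≤ 50 kb is
replaced by one window centred on its midpoint (±25 kb); a longer locus is
tiled with ⌊L/50 kb⌋ consecutive windows from its start, dropping the
trailing remainder. Anchoring at the locus start is an arbitrary but
deterministic choice; the remainder is dropped rather than emitted as a
short window so every scored window has identical size. Windows that would
extend below position 0 are rejected outright.

A window's score is the fraction of its qualifying SNPs whose F_ST exceeds
the genome-wide 99% boundary for the comparison. The boundary is the
inverse-ECDF (type-1) quantile of a large qualifying-SNP sample — 2,200,000
SNPs at full scale, configurable down — and outliers are values *strictly*
above it, so at most 1% of the estimation sample is an outlier by
construction. A window is flagged when its fraction exceeds 1%.

Significance is assigned by scoring `n_random` same-size windows (11,000 at
full scale) drawn uniformly over the chromosome lengths, with replacement;
windows with zero qualifying SNPs are redrawn. The empirical P is the
fraction of random windows with a fraction ≥ the candidate's — one-tailed
(excess only), ties counted, no pseudo-count, so P may be exactly 0 and is
granular at 1/`n_random`. The same random-window set is reused for every
region of one comparison, which makes P monotone in the observed fraction;
a fresh set (with a recorded seed) is drawn per comparison.

At the network level, the count `k` of regions with P < α among `m`
evaluable regions is referred to the Binomial(m, α) upper tail,
`P(X ≥ k)`. Windows tiled from loci in the same proximity cluster are
collapsed to one before counting (a cluster is significant if any member
is), since overlapping flanks are not independent trials. The binomial tail
treats regions as exchangeable Bernoulli trials; residual linkage between
nearby clusters makes it mildly anti-conservative, which the
cluster-collapse mitigates.

## Locus clustering

Same-chromosome loci closer than 2 Mb (inter-interval gap, single linkage)
share a cluster; the 2-Mb scale is a physical-distance proxy for genetic
independence, chosen over a recombination-map distance for simplicity.
Cluster labels are derived from the smallest start in the cluster, so the
assignment is invariant to input order.

## iHS network randomization

Normalized iHS is consumed as a precomputed position-scored track; computing
iHS from haplotypes is out of scope. A region's statistic is the maximum
|score| among its sites — normalized iHS is signed, and extreme values of
either sign mark sweeps, so the absolute value is the standard reading; a
`signed=True` switch preserves the literal "highest score" alternative.
Regions overlapping no scored site are unevaluable and shrink the network
symmetrically (random networks match the evaluable count).

The observed statistic is the mean of per-region maxima. Random networks of
the same size are drawn uniformly over the track's chromosomes with two
constraints: every window must contain a scored site, and same-chromosome
window starts must be ≥ 2 Mb apart. Sampling is by per-draw rejection;
because an early accepted window can make later placements infeasible on
small genomes, a network whose pending draw stalls is restarted from
scratch rather than looping forever (an explicit capacity bound rejects
outright impossible requests first). `p = #(random mean ≥ observed)/n_random`
with ties counted and no pseudo-count.

With `collapse_clusters`, one region is drawn uniformly per cluster, the
network mean computed, and the observed statistic averaged over ten such
draws before the randomization — non-independent nearby loci then contribute
once each.

## Ancient heterozygosity under low coverage

The observed statistic is the fraction of non-missing calls that are
heterozygous across the site set (49 sites in the motivating application;
an individual heterozygous at 9 of 49 sites scores 9/49 ≈ 0.184). Modern
panel distributions hold one such value per individual.

Without sequencing error, `c` reads from a heterozygote show both alleles
with probability `1 − 2^(1−c)`, so shallow coverage biases the observed
statistic down. Two simulated distributions bracket the effect:

* **expected**: per replicate, each site's genotype is drawn under
  Hardy–Weinberg at the modern derived-allele frequency `q_s` (het
  probability `2q_s(1−q_s)`); 500 replicates by default. HWE is assumed
  because only the marginal heterozygote probability enters.
* **coverage-resampled**: for each genotype replicate, reads are drawn at
  the ancient individual's observed per-site depths (each read copies one
  of the two alleles with probability 1/2, sampling allele identities with
  replacement, since the physical read stack is not reconstructible), and a
  site scores heterozygous only if both alleles appear; 2,500 read
  replicates per genotype replicate, 1,250,000 values total. Per-site, the
  expected call rate is `2q(1−q)(1 − 2^(1−c))`, which the tests verify
  against the simulation.

The resampled distribution is stochastically below the expected one —
coverage can only hide heterozygotes. No sequencing-error, contamination,
post-mortem-damage or reference-bias term is modelled (a documented
limitation): the scheme isolates the pure depth effect. Depth-0 sites are
excluded from denominators, not imputed. The ancient value's placement in a
modern distribution is its fractional rank, ties averaged.

## The synthetic-data generator

The generator defines the conditions under which the pipeline is validated.

* **Panels** follow Balding–Nichols: ancestral frequencies
  Uniform(0.05, 0.95) (mostly segregating sites, configurable), each
  population's frequency Beta(p(1−F)/F, (1−p)(1−F)/F) (mean `p`, variance
  `F·p(1−p)`; `F = 0` degenerates to `p` exactly), genotypes Binomial(2,
  frequency). This model was chosen because the estimator's expectation
  under it is known, giving a closed parameter-recovery surface. Defaults:
  SNP positions uniform without ties at ~10 SNPs/kb (full variant-call
  density for a sequenced human panel); missingness 0, injectable.
* **Sweeps** are half-open intervals that either raise the drift parameter
  (`fst_shift`, must exceed every background F) or add a positive offset to
  track scores (`ihs_shift`); overlapping sweep regions are rejected.
* **Tracks** are standard-normal scores at uniform deduplicated positions,
  at a configurable density (500 sites/Mb in the tests — the sparse,
  SNP-array-like density of public iHS tracks).
* **Pileups** draw Poisson depths (a fixed-depth override exists for exact
  closed-form checks) and have no error model, matching the resampling
  scheme they feed.

What the generator does *not* emulate: linkage disequilibrium between SNPs
(sites are independent given the frequencies), realistic site-frequency
spectra, haplotype structure (so iHS tracks are score-level stand-ins, not
haplotype-derived), sequencing error, or demographic events (growth,
migration, bottlenecks). Passing tests therefore demonstrate that the
*statistical machinery* is correct and calibrated under a clean null — not
that real human data satisfy that null; on real data, LD makes nearby SNPs
and nearby windows correlated, which is exactly why the region-level
empirical null and cluster collapsing exist.

## Numerical and reproducibility choices

* Coordinates are 0-based half-open everywhere internally (BED native; VCF
  positions converted on read). The X chromosome and other non-autosomes
  are excluded on VCF read by default. Multi-allelic and non-SNP records
  are dropped with a count.
* Quantiles are type-1 (inverse ECDF), so thresholds are always attained
  sample values and the ≤ 1% outlier guarantee is exact.
* Empirical P-values and randomization p-values use ≥ with no pseudo-count;
  users combining them downstream should note P = 0 is possible.
* Range-maximum queries over track scores use a cached sparse table, making
  the 100,000-network default practical in seconds.
* Every stage seed derives from the master seed by a fixed integer offset
  (`selnet.pipeline.STAGE_SEED_OFFSETS`), modulo 2³¹; stages are re-runnable
  independently and bit-identically, and output files carry the config hash
  and seed.

## Scale of the shipped experiments

The test suite and `scripts/acceptance.py` run everything at reduced scale,
chosen as the smallest sizes at which the asserted properties are sharp:
panels of 2 × 50 diploids with 20,000–200,000 SNPs on 10–20 Mb genomes,
1,000 random windows per comparison (down from 11,000), 2,000 random
networks (down from 100,000), and 100–500 × 250–2,500 resampling replicates.
Null-calibration checks use 100 seeds; power checks use 200 replicates
(region test, ≥ 95% power required against a planted F = 0.4 sweep) and 100
seeds (iHS test, median p < 0.05 against +2 offsets). Full-scale defaults
(11,000 / 100,000 / 500 × 2,500 / 2,200,000-SNP threshold samples) remain
the library and CLI defaults.

## Known limitations

* The binomial network test assumes evaluable regions are independent
  trials after cluster collapse; long-range LD violates this mildly.
* Empirical P granularity is 1/`n_random`; at reduced counts, extreme
  quantiles are coarse.
* The iHS stage never recomputes scores from haplotypes, so any bias in the
  upstream track propagates.
* The ancient-heterozygosity correction addresses depth only; contamination
  and damage would both *raise* apparent heterozygosity and are not
  modelled.
* Random windows are sampled uniformly over chromosome lengths without
  masking unassembled or low-complexity regions; on real genomes a
  callability mask should be applied upstream.
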