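# Methods

## The forward model

`genoerode.simdata` implements a discrete-generation Wright–Fisher model
of a diploid, randomly mating, monoecious population (selfing permitted).
The genome is `n_genes` genes of `gene_length` bp laid contiguously on
`n_chromosomes` chromosomes (genes assigned proportionally). Meiosis
draws one inheritance bit per gene per gamete: free recombination between
genes, complete linkage within a gene. This preserves within-gene linkage
disequilibrium — the ingredient that makes runs of homozygosity and
background selection behave realistically — at negligible cost, while
keeping genes exchangeable.

New mutations arrive as a Poisson process with expectation `2Nμ·L` per
generation, each at a uniform position (an infinite-sites approximation:
each mutation is its own biallelic site; positional collisions, which are
rare, are resolved at emission by keeping the older mutation). With
probability `p_neutral` a mutation is neutral; otherwise its homozygous
selection coefficient is drawn as `s = −Gamma(shape, scale)` with mean
`mean_s`. Fitness is multiplicative across sites, `1 + h·s` per
heterozygous and `1 + s` per homozygous genotype, floored at zero
(implemented by clipping `s` at −1; a homozygote for `s ≤ −1` is lethal).
Parents are drawn per gamete with probability proportional to fitness.

### Parameters and defaults

| parameter | default | units | why |
|---|---|---|---|
| demography | 500,000 gens at N=16,000; exponential crash to 375 over 5 gens; recovery to 8,000 over 10 | diploids, generations | the whaling-era history of the Southern Ocean study population |
| μ | 1.12×10⁻⁸ | mutations/bp/gen | pedigree-based humpback whale rate |
| genome | 25,314 genes × 1,000 bp | bp | gene count of the blue whale reference annotation; the product (25.3 Mbp) is the represented genome size |
| `p_neutral` | 0.3 | – | roughly the synonymous/non-coding fraction of coding-region mutations |
| DFE | Gamma, shape 0.186, mean s −0.01 | – | a widely used point estimate of the human deleterious DFE, the standard stand-in for mammals without a species-specific fit |
| h | 0.5 | – | additive by default; no consensus dominance model exists for cetaceans. An `h(s)` recessive parameterization can be emulated by changing `h` |
| transition fraction | 2/3 | – | a genome-wide Ti/Tv ratio of ~2 |

The DFE and dominance values are package defaults, clearly configurable;
they are not measurements for this species.

### Rescaling

`rescale_model(…, lam)` shrinks the burn-in epoch only: size and duration
divided by λ, mutation rate and selection coefficients multiplied by λ
*within that epoch*. This preserves the population mutation rate `4Nμ`
and the scaled selection intensity `2Ns`, so the equilibrium diversity
and the selected site-frequency spectrum match the unscaled model (up to
the usual rescaling distortions for very strong `s·λ`, which are clipped
at −1). The crash and recovery epochs run in natural generations at
natural size, so drift per calendar generation — the quantity that
determines the bottleneck's genomic footprint — is untouched, and the
expected outcome is independent of λ. The test suite uses λ = 40 and the
acceptance script λ = 20; both satisfy the preserved-compound-parameter
conditions.

The optional `scale_bottleneck=True` divides the crash/recovery sizes by
λ too while keeping their natural generation counts. That amplifies
per-generation drift roughly λ-fold and is *not* a faithful reduction of
the model; it exists to emulate whole-model-rescaled simulation designs.

### Expected heterozygosity loss

For the default demography the neutral expectation is

    loss = 1 − Π_t (1 − 1/(2·N_t^parent)) ≈ 0.60%,

where the product runs over the 15 crash/recovery generations and `N` is
indexed by the *parent* generation (two lineages sampled in generation t
coalesce among the parents). Replicated runs of the simulator agree with
this within sampling error (the DFE adds a small increment through
selection against exposed variants). Substantially larger losses over 15
generations require amplified drift, i.e. the `scale_bottleneck` mode.
At desk scale (large μ, small N) the new-mutation input during the crash
is not negligible; the exact expectation adds `+2μ` per generation to the
recursion, and the oracle tests use bottlenecks deep enough that the
drift term dominates.

### What the generator emulates, and what it does not

Synthetic cohorts carry realistic allele-frequency spectra, per-genotype
depths (`DP ~ Poisson(6)` by default, allelic depths binomial for
heterozygotes, GQ increasing with depth), and injected low-count C→T/G→A
transition sites mimicking post-mortem deamination (ground-truth flagged
for filter validation). Not modelled: mapping bias and reference bias,
index hopping/contamination, fragment-length-dependent damage gradients
along reads, structured missingness, linked-read artifacts, and
population structure or migration. Passing tests therefore demonstrate
the correctness of the statistics and filters under the stated model,
not robustness to every artifact of real historical DNA.

## Temporal harmonization

Rules apply in a fixed order: (i) genotypes asserting the variant allele
with fewer than 3 supporting reads become missing; (ii) heterozygotes
with an alternate-read fraction outside the closed interval [0.35, 0.75]
are recoded homozygous for the allele with more reads, ties toward the
reference; (iii) transition sites with fewer than 3 variant copies across
all retained genotypes are removed (counted after (i)–(ii) in the
combined cohort). The stack is idempotent, order-stable, and never
creates alleles. Because injected deamination artifacts are low-count
transitions by construction, rule (iii) removes them essentially
completely while never touching a transversion.

## ROH model

Two states (autozygous/non-autozygous) over the ordered non-missing
genotypes of one sample on one chromosome. Emissions:
`P(het | AZ) = error_rate` (default 10⁻⁴),
`P(het | HW) = 2p(1−p)` at the site's alternate-allele frequency
(estimated from the dataset unless supplied; clipped away from 0 and 1).
Transitions between adjacent sites at distance d bp:
`P(switch) = 1 − exp(−rate·d)` with default entry 6.7×10⁻⁸/bp and exit
5×10⁻⁹/bp — the published defaults of the standard HMM caller for
unphased genotypes, adopted here as overridable package defaults.
Decoding is exact Viterbi with uniform initial probabilities; ties prefer
the non-autozygous state, so autozygosity is never over-called. A
contiguous autozygous stretch becomes a segment only if it contains at
least 50 homozygous genotypes, with boundaries at the outermost
homozygous sites (1-based inclusive; BED export converts to 0-based
half-open). `F_ROH` divides the summed length of segments strictly longer
than the threshold (1 Mbp) by the autosomal genome length. With
variant-only input the callable length must be supplied; whether
monomorphic positions enter the heterozygosity denominator is exposed via
that same length parameter.

## Polarization and load

An allele is ancestral iff its pooled-sample frequency exceeds 0.95 *and*
it matches at least one outgroup genome; the other allele is derived;
sites where no allele qualifies are dropped and counted. The frequency is
computed on the pooled historical+contemporary samples, so only
low-frequency derived variants are analyzable — the by-design behaviour
of the rule. With more than 10 diploids the threshold is attainable by
polymorphic sites; smaller cohorts retain nothing.

Potential load counts sites where a sample carries ≥ 1 derived allele
(variant-wise; allele-wise counting would weight homozygotes twice and is
available by summing dosages). Realized load is the homozygous-derived
fraction of those sites (undefined, reported missing, at zero potential).
R_x/y uses cohort frequencies over called gene copies only; a site enters
when its category matches, both cohorts have calls, and the cohort union
carries a derived allele. Uncertainty: delete-one jackknife over
autosomes, `SE² = (B−1)/B · Σ(R_b − R̄)²`, CI = jackknife mean ± 1.96·SE.
A chromosome contributing no usable category sites leaves its jackknife
replicate equal to the full estimate.

Cohort comparisons use the Mann–Whitney U test: for ≤ 20 pooled values
the two-sided p-value is exact by complete enumeration of group
assignments (ties handled by midranks, deviations measured from
`E[U] = n_x·n_y/2`); larger samples use the tie-corrected normal
approximation.

## Trajectory utilities

Per-generation summaries across estimator runs use the mean, median and
percentile (2.5/97.5) intervals. Census conversion multiplies by a fixed
Ne:Nc ratio (default 4). Generation-time calibration divides the elapsed
calendar years by the anchored generation offset; dating maps generation
g to `sampling_year − g·gen_time`. `G = n·ϑ/N_E` accepts ϑ per generation
bin or one total; estimates with `G ≤ 100` are flagged (values near 50
are conventionally unreliable). Catch correlation accumulates catches
forward in time, assigns each dated generation the cumulative total at
its year, and computes Pearson r (p from the t transformation with n−2
degrees of freedom); a zero-variance side is an error, not a silent NaN.

## Numerical and implementation choices

* All randomness flows from one integer seed through independent spawned
  streams (kernel chunks, cohort sampling, emission); identical seeds
  give bit-identical replicates.
* The simulator stores haplotypes as ragged arrays of mutation ids
  (neutral and selected classes kept separately so fitness only touches
  selected sites), compiled with numba; fixed and lost mutations are
  pruned and the table compacted every 100 generations. Pruning fixed
  mutations is exact for relative fitness since a fixed factor cancels.
* Degenerate inputs fail loudly: empty timepoints, sample sizes above the
  population, zero callable length, non-positive Ne, constant series in
  the correlation, missing allelic depths (the error names the sample).
* Test problem sizes — 500 genes and 20 replicates for the replicated
  bottleneck study, 8–10 kb genomes for the neutral-theory oracles —
  were chosen so each oracle has a sharp closed form and the whole suite
  runs comfortably on one CPU.

## Known limitations

* No tree-sequence recording; summary statistics only.
* One biallelic SNP per position; no recurrent or back mutation.
* No recombination-map input; within-gene recombination is exactly zero.
* The LD-based Ne estimation algorithm itself is out of scope — only its
  output dialect is consumed; `G` therefore requires the user to supply
  ϑ when the estimator does not report it.
* Annotation impact categories are inputs (or simulated via |s|
  thresholds, defaults LOW ≤ 10⁻⁴ < MODERATE ≤ 10⁻² < HIGH); no
  annotation engine is re-implemented.
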