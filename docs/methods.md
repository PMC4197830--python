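# Methods

This note documents the models and numerical conventions behind
`popdiffscan`: what each statistic computes, what the synthetic-data
generator does and does not emulate, and the choices made where the
design was genuinely open.

## Polarization and frequencies

All statistics operate on haplotypes coded 0 = ancestral, 1 = derived.
Sites whose ancestral-allele annotation is missing, or matches neither
allele, are dropped and counted; symbolic structural-variant records
without an annotation may optionally assume the reference allele is
ancestral (deletions are then derived relative to the reference state) —
an assumption, and logged as such. Frequencies are computed over
observed alleles only: a site with missing genotypes uses a reduced
denominator, and a group with no observed alleles has a missing DAF at
that site. The pooled DAF is total derived / total observed alleles
over all panel samples.

Coordinates are 1-based inclusive throughout; BED input is converted on
read. Sites are kept sorted by (chrom, pos, alt), and ranking ties are
broken in genomic order so that every run is deterministic.

## Differentiation scans

ΔDAF for a pair of groups is the signed difference of their DAFs;
ranking uses |ΔDAF| with the sign retained as the direction (the group
with the higher frequency), which makes the two orientations of a pair
equivalent. The per-site F_ST estimator is the Weir & Cockerham (1984)
two-group variance-components form applied to allele counts (phased
haplotypes are the sampling unit), F = (MSP − MSG)/(MSP + (n_c−1)MSG);
0/0 sites are reported missing and slightly negative estimates are kept
as computed.

The HighD scan marks the top percentile of |ΔDAF| genome-wide *before*
peak-picking, then partitions **all** scanned variants (not only the
marked ones) into non-overlapping blocks of 5,000 consecutive variants
per chromosome, takes the most differentiated marked variant per block,
and retains it above the level-specific threshold (0.7 between
continents, 0.25 within; strict inequalities). This keeps windows
genomically local, which is the point of windowing: hitchhikers cluster
around the driving variant. Windows never cross chromosome boundaries,
and a short final block is scanned like any other. A windowless
threshold-only mode exists for small variant sets (e.g. exomic INDELs).
The LowD scan applies the pooled-DAF band [0.40, 0.60] with the open
exclusion interval (0.45, 0.55) exactly as stated — 0.40, 0.45, 0.55
and 0.60 are admitted — computes cvDAF with the sample (n−1) standard
deviation over population DAFs, and keeps the minimum-cvDAF site of
each 100-survivor window when cvDAF < 0.01.

Matched controls are drawn without replacement (never reused across
targets) from the scanned universe, matching the assigned population's
DAF within ±0.02 (relaxed stepwise to ±0.05, then reported unmatched)
and the distance-to-nearest-gene-start bin (genic, (0,1 kb], (1,10 kb],
(10,100 kb], >100 kb). The tolerances and bins are module defaults
exposed in configuration.

## Haplotype statistics

EHH around a core allele is the probability that two random carriers
are identical at all sites between the focal position and the query
offset, Σ_h C(n_h,2)/C(n,2) over extended-haplotype classes. iHH is the
trapezoidal integral of EHH over genetic distance on both sides,
stopping after the first segment that drops below the 0.05 cutoff; a
side that never reaches the cutoff within the window (1 Mb or the map
edge) integrates to the edge and is flagged truncated rather than
dropped (a strict mode can drop). iHS = ln(iHH_ancestral/iHH_derived);
XP-EHH = ln(iHH_A/iHH_B) with all haplotypes per population. Raw scores
are z-standardized within derived-frequency bins of width 0.05; bins
with fewer than 20 scores merge into their neighbours. A reproducible
subsample of 30 individuals per group makes population- and
continent-level runs comparable. The cutoff and bin width are the
conventional values of the source methods, exposed as configuration.

## Hard-versus-soft classification

For a focal site, the carrier haplotypes are the strings (one symbol
per polymorphic callset site, the focal site excluded) of all
derived-allele carriers in the assigned group within focal ± 1 kb.
D is the frequency-weighted mean Levenshtein distance between each
distinct carrier haplotype and the major haplotype, the major
haplotype contributing zero — equivalently, the expected number of
edit operations separating a random carrier from the modal haplotype.
Two points were genuinely open and were settled quantitatively:

- *Weighting.* Weights are relative frequencies among **all** carriers.
  Renormalizing over the non-major haplotypes would force D ≥ 1
  whenever any alternative exists, which is incompatible with observed
  hard-sweep values of order 10⁻³.
- *Normalization.* D is **not** divided by the haplotype length.
  Dividing by the number of window sites shrinks simulated sweep values
  by more than an order of magnitude below the reference scale
  (hard-sweep exemplars 0.001–0.026, standing variation ≈ 0.18), while
  the unnormalized statistic reproduces both the scale and the
  complete/partial sweep ratio. Both alternatives remain available as
  flags (`per_site`, `renormalize_alternatives`) and the choice is
  visible in the output.

Edit distances are computed with edlib; with one symbol per site the
strings are equal length, and the true edit distance (≤ Hamming) is
kept for generality with indel alleles. Major-haplotype ties break
lexicographically. A site is hard-like iff D ≤ 0.026 **and** the local
recombination rate (map rate averaged over the 2-kb window) lies in
[0, 0.025] cM/Mb, boundaries inclusive; without a rate it is
unclassifiable. The chance-corrected hard fraction is the hard-like
rate among targets minus that among matched controls, with a Fisher
exact test on the 2×2 table.

## The synthetic-data generator

The generator emulates the study system — phased diploid genomes from
three continental groups with polarized alleles — under a configurable
out-of-Africa skeleton: a constant-size African population (N = 12,500
diploids), a Eurasian founder episode (N = 600 for 100 generations from
3,500 generations ago) recovering to N = 7,700, a Europe/East-Asia
split 2,000 generations ago through founder episodes of N = 800 into
constant sizes of 8,000, symmetric migration (1.5×10⁻⁴ per generation
between Africa and the Eurasian ancestor, 2.5×10⁻⁵ between the three
later continents), mutation 1.5×10⁻⁸ /bp/gen, crossover 1×10⁻⁸
/bp/gen, and gene conversion initiating at 4.5×10⁻⁹ /bp/gen with
500-bp mean tracts. These values follow the published calibrated
three-population models, with one desk simplification: constant
post-split sizes instead of recent exponential growth. The parameters
were fixed after verifying that mean per-site F_ST between sampled
continents falls in the range characteristic of the AFR/EUR/ASN system
(≈0.1; the suite asserts this realism check on every run). Optionally each continent subdivides 200 generations ago
into its ~10 constituent populations with within-continent migration
5×10⁻³, for population-level analyses such as cvDAF.

*Engine.* Everything from the out-of-Africa split onward runs as a
discrete-generation Wright–Fisher simulation over an explicit
haplotype × site 0/1 matrix: per generation, each offspring haplotype
chooses a source deme (migration), copies a uniformly drawn parent
haplotype, recombines with a second parent with probability 1−e^(−ρ)
(one crossover per meiosis; ρ ≪ 1 makes double crossovers negligible),
receives gene-conversion tracts likewise, and acquires new mutations
at unoccupied integer positions (infinite sites; collisions redrawn).
Lost and globally fixed columns are purged periodically. The
equilibrium ancestral population that seeds the forward phase is drawn
from an msprime coalescent simulation with matching θ and ρ — the
standard-coalescent burn-in replaces ~10N generations of forward
equilibration; the forward engine owns all demography, migration and
selection. Samples are drawn without replacement at present; every
sampled dataset contains exactly the segregating sites of the sample,
polarized by construction.

*Rescaling.* Desk scale uses population-size rescaling by λ = 10:
sizes and times ÷ λ, per-generation rates × λ, preserving θ = 4Nμ,
ρ = 4Nr and times in 2N units. Regions default to 100 kb (the study's
600-kb regions shrunk for desk runs), with the selected variant at the
region centre. A KS check confirms λ = 5 and λ = 10 give
indistinguishable differentiation distributions.

*Sweeps.* Selection is additive (1, 1+s, 1+2s) on a new mutation in
one population; a sweep lasts 200–1,200 generations and always ends
401 generations before sampling, with s tuned to drive the allele to a
target frequency in {0.2, 0.4, 0.6, 0.8, 1.0}. Implementation: a cheap
per-deme allele-frequency trajectory (binomial Wright–Fisher with
selection and migration) is rejection-sampled until the end-of-sweep
frequency is within ±0.05 of the target, with bisection-style
adjustment of s around the deterministic logistic solution; the full
simulation is then conditioned on the accepted trajectory by enforcing
the per-deme carrier counts each generation (carrier offspring draw
carrier parents, with the focal-site segment always inherited from the
primary parent, and conversion tracts never overwriting the focal
site). This is the standard conditioned-sweep construction and makes
every emitted replicate honour its target class. After the sweep ends
the allele drifts freely for the remaining 401 generations, so the
sampled frequency lies below the end-of-sweep value on average;
replicate class membership is defined by the controlled end-of-sweep
frequency, and both values are recorded.

*What passing tests do and do not show.* The generator produces
SNP-only, single-chromosome, neutrally recombining regions with exact
polarization and no genotyping error, missingness, or imputation noise
(INDEL/SV classes and quality fields enter through hand-built
fixtures). Results under it demonstrate the statistical machinery and
the relative behaviour of the statistics under controlled selection;
they do not certify performance on real callsets with ancestral
misassignment, variable accessibility, or admixture.

## Power analysis

Detection thresholds are the 95th empirical percentile (linear
interpolation) of neutral ΔDAF/F_ST scores. The neutral score
distribution is, by default, the **pooled per-site** score distribution
across neutral replicates; the per-replicate regional maximum is
available as `threshold_mode="replicate_max"`. The pooled reading was
adopted because regional neutral maxima between continents sit near
0.5–0.7, a threshold no partial sweep (final AF 0.2–0.4, ΔDAF ≈ 0.2)
could ever exceed — under that reading the statistic's reported high
power for partial sweeps would be unattainable, so it cannot be the
intended construction. Per-site scores are the max over the three
continental pairs, identically for neutral and sweep replicates.
Sensitivity is the fraction of sweep replicates whose selected variant
scores above the threshold, per final-AF class and overall (balanced
across classes), with exact Clopper–Pearson intervals; calibration is
checked by treating one random segregating site per neutral replicate
as a pseudo-selected variant, whose detection rate must match the 5%
FDR. Default desk sizes are 500 neutral replicates and 50–55 per sweep
class (the study-scale counts divided by ~6), always recorded in the
output.

The neutral expectation for genome-wide HighD counts runs the full
between-continent scan on neutral replicates and scales the yield to
the 2,526,390,487-bp accessible genome, with a bootstrap CI over
replicates; a sensitivity helper sweeps the post-split migration rate,
which is the parameter this expectation is most sensitive to.

## Enrichment statistics

Gene-set overlap enrichment compares the fraction of candidate-hosting
genes found in a reference (positive-selection) list against 100
control draws matched in count only, with a one-sided one-sample t-test
(controls < observed); a degenerate control distribution (sd = 0) is
reported as such. The control-gene universe is the genes bearing at
least one scanned variant. Genic enrichment is a Fisher exact test on
genic status versus matched controls, with a Haldane-corrected odds
ratio reported alongside when a cell is zero. Genotype concordance
compares unordered genotypes (derived dose; 0|1 ≡ 1|0) at shared sites
over shared samples, summarized by variant class; allele-frequency
concordance is a per-group Spearman correlation; LD proxies are sites
with r² > 0.8 (strict) within a window of a target.

## Numerical conventions and limitations

- Empirical quantiles use linear interpolation; rank P-values are
  rank/N with genomic-order tie-breaks.
- All randomness flows from a single seed through spawned
  `SeedSequence` children; identical seeds give bit-identical
  replicates, scans and control draws.
- The engine's diploidy is random union of gametes (no explicit
  individuals); selection acts through the carrier-frequency update,
  which at these s values is indistinguishable from individual-based
  additive selection.
- Strong rescaled selection coefficients (sλ up to ≈ 0.6 for the
  shortest complete sweeps) stretch the diffusion equivalence of
  rescaling; the trajectory conditioning keeps realized classes exact,
  but very short sweeps are the least faithfully rescaled regime.
- Mean simulated haplotype-homogeneity values are sensitive to local
  θ and to recent-growth rare variation that the constant-size desk
  model underrepresents; the complete-versus-partial ordering is
  robust, the absolute class means less so.
- The neutral-expectation analysis is extremely sensitive to the
  migration rate and accessible-genome size, which is precisely why it
  is exposed as a sensitivity analysis rather than a point estimate.
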