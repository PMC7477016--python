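# Methods

`sweepscan` implements a selection-scan and population-differentiation
pipeline for phased, bi-allelic SNP panels from two (or more) populations,
together with a forward Wright–Fisher simulator that generates such panels
with known ground truth. This note records the statistical definitions, the
numerical conventions, the simulator's design and its limits, and the design
choices that were genuinely open.

## Statistics

**Exact Hardy–Weinberg test.** For genotype counts (hom-ref, het, hom-alt)
the test enumerates every heterozygote count compatible with the observed
allele counts, computes each configuration's conditional probability
(multinomial ways × 2^het), and sums the probabilities of configurations no
more likely than the observed one — the standard exact two-sided convention.
Mid-p is not used. Probabilities are computed in log space; p ∈ (0, 1].
Note the attainable floor: with n diploids the most extreme configuration has
p ≈ 1.4e-3 at n = 10, so a p < 0.001 threshold can only ever remove sites in
cohorts of ≥ 11 diploids.

**QC cascade.** Site filters run in a fixed order — missingness > 10%, minor
allele count < 3, MAF < 1%, HWE p < 0.001 — then individuals with > 10%
missing data are removed, then one stage-specific step: LD thinning to
pairwise r² < 0.1 (population-structure stage; greedy, 50-SNP windows with
step 5, missing dosages mean-imputed only inside the correlation) or a MAF ≥
5% floor (selection-scan stage). Each step reports its removals, so
removed + surviving = input at every step. "Fewer than 3 calls" is read as a
minor-allele-count rule, consistent with a removal table whose largest class
is "MAF < 1% or minor allele count ≤ 2".

**Inbreeding F.** Per individual, F = (O_hom − E_hom)/(L − E_hom) over called
polymorphic sites, with per-site expected heterozygosity 2p(1−p)·2n/(2n−1)
(small-sample correction). Sites with p ∈ {0, 1} carry no information and are
excluded; individuals with no usable sites get NaN.

**Tajima's D.** Computed in non-overlapping 3 kb windows (default) from
phased haplotypes: S = polymorphic columns, π = mean pairwise differences
(per site 2c(n−c)/(n(n−1)) summed over the window), and D from the standard
constants a₁, a₂, b₁, b₂, c₁, c₂, e₁, e₂ of the estimator. D is undefined
(NaN, never 0) when S = 0. Windows tile each chromosome, so chromosome
partitioning at window boundaries leaves every statistic unchanged.

**Weir–Cockerham F_ST.** Two-population variance components from per-site
haploid allele counts (the estimator's haploid-data form: a = between-
population component, b = within; the within-individual term c is identically
0 on this data type, and fst = a/(a+b+c) so the usual identity holds).
Sites monomorphic across both populations, or with fewer than two called
chromosomes in either, are NaN. Region means are ratio-of-sums
(Σa / Σ(a+b+c)), the low-bias convention; a mean-of-ratios alternative is
available behind a flag because printed tables rarely say which was used.
The "Wright's F_ST" of the field's tooling is in practice this
Weir–Cockerham estimator; that convention is followed here.

**EHH, iHH, iHS.** EHH at distance x from a core site is Σ_h C(m_h, 2) /
C(n, 2) over distinct extended haplotypes spanning core→x among the n
carriers of the chosen core allele; it starts at 1.0 and is monotonically
non-increasing. The core allele itself never partitions the carriers — for
allele-specific profiles carriers share it by construction, and for the
allele-agnostic (site) profile this is the site-EHH normalization that makes
the profile insensitive to core-site heterozygosity. iHH is the trapezoidal
integral of EHH against physical position, each arm truncated at its first
crossing below the 0.05 cutoff with linear interpolation of the crossing;
arms also stop at chromosome ends and at inter-SNP gaps above 200 kb
(configurable). Unstandardized iHS = ln(iHH_ancestral / iHH_derived);
standardization to mean 0, sd 1 within derived-allele-frequency bins of width
0.05, with pooled-moment fallback (flagged) for bins of fewer than two sites.
Where ancestral polarity is a ref-based fallback, downstream rules use |iHS|.
Distances are physical; no genetic map support.

*Border handling.* By default (`discard_border=True`) a site whose EHH is
still at or above the cutoff when an arm hits the chromosome end or a gap is
excluded from the scan, the convention of the field's reference
implementation: truncated integrals otherwise inflate score variance near
chromosome ends. On the simulator's deliberately small 1 Mb test genome this
convention backfires — the longest-haplotype sites near a sweep are exactly
the ones whose EHH reaches the border, so the scan would discard its own
strongest evidence — and the packaged experiments therefore pass
`discard_border=False`. On chromosome-scale real data the default is
appropriate and the choice only matters at telomeres.

**xpEHH.** Per site, the allele-agnostic EHH profile is integrated within
each population; the unstandardized score is ln(iHH_pop1 / iHH_pop2),
standardized genome-wide. Positive extremes mean longer haplotypes (candidate
selection) in population 1; swapping populations negates the raw score. Two
integration conventions are implemented: each population truncated at its own
cutoff crossing (default), or both integrated to the boundary where the EHH
of the pooled two-population sample crosses the cutoff (`shared_boundary=True`,
the original cross-population formulation). The packaged experiments use the
shared boundary: it measures both populations over a common physical span,
which sharpens the contrast at a sweep and tightens the neutral background.

**Sweep windows and gene ranking.** The genome is tiled in 100 kb bins; each
bin's statistic is the fraction of its scan SNPs with |iHS| > 2; bins with
fewer than 20 SNPs are excluded; the significant set is the top 1% of
included bins by fraction, with ties at the quantile boundary all retained
(an inclusive reading of "the 1% of bins with the highest fraction"). On a
1 Mb test genome this means essentially the single best window. Differential
candidates require a window to pass (extreme count strictly > 20) in
population A and not in B, with an optional fixation filter (selected-allele
frequency ≥ threshold in A, < threshold in B). Per-gene evidence aggregates
means over SNPs inside the gene interval for |iHS|, Tajima's D (via
bin-overlap means of 3 kb windows) and F_ST (ratio-of-sums), and the max for
xpEHH — matching the aggregation implied by a "mean/max" gene table. Genes
passing the gates (F_ST mean at or above the 0.95 gene quantile, xpEHH max >
2.5) are ranked best-first on each of Tajima's D mean, F_ST mean and xpEHH
max (average ranks on ties) and ordered by the summed rank. Larger metric =
better rank throughout, the only direction consistent with "high F_ST, high
Tajima's D, high xpEHH" as selection evidence.

**f3 admixture test.** Per SNP, (c − a)(c − b) − h_c/n_c with h_c =
c(1−c)·n_c/(n_c−1), the finite-sample correction applied to the target only.
The estimate is the mean over SNPs; the standard error is a weighted
delete-one-block jackknife over contiguous 5 Mb blocks (weights = SNP
counts); Z = f3/SE. Significantly negative Z is evidence that the target
derives from a mixture of populations related to the two sources; drift alone
cannot produce it. SNPs with an undefined frequency in any population are
dropped listwise. No outgroup normalization: sign and Z are the inferential
surface. Block span is physical because no genetic map is used; it is
configurable and recorded in the result.

## The simulator

Discrete-generation forward Wright–Fisher on binary haplotypes: N_e diploids
per population; per-gamete parent sampling weighted by fitness (1, 1+s/2,
1+s additive at the sweep site, in the selected population only); Poisson
mutation onto fresh uniform positions (infinite sites, collisions re-drawn,
no back mutation); single-crossover recombination with probability r·L per
meiosis at a uniform breakpoint; populations split by copying; an admixture
pulse founds a target population by drawing each haplotype from source A with
probability α; diploids are formed by random haplotype pairing at output
time, and output is a phased VCF 4.2 with the AA tag (ancestral = allele 0,
the simulator's known truth). Byte-identical output under a fixed seed.

**Defaults are the study conditions.** Two populations of N_e = 500, 1 Mb of
sequence, 50 sampled diploids per population (the per-population scale of the
cohort the pipeline targets), split depth 22 generations (t/2N_e ≈ 0.022,
inside the 0.008–0.025 F_ST band reported between East African populations).
μ = 5.5e-7/bp/generation is calibrated so the MAF ≥ 5% scan-site density
matches the cohort's ≈ 3,100 scan SNPs per Mb; r = 2.5e-7/bp/generation is a
compromise discussed below.

**Fast equilibration.** Instead of a many-N_e-generation burn-in, the
founding population is drawn from the stationary neutral site-frequency
spectrum (E[#sites at derived count i] = θ/i, carriers assigned uniformly at
random — correct SFS, zero initial LD) and then evolved N_e further
generations so linkage builds up. The SFS is exact at stationarity;
background LD is only partially equilibrated (it approaches equilibrium on
the coalescent timescale), so background haplotype lengths are somewhat
shorter than at full equilibrium. Sweep-recovery contrasts are conservative
under this shortfall; absolute background EHH decay lengths are not to be
read as calibrated to any real population.

**Hard-sweep seeding and timing.** The sweep allele is injected at the
population split on a single donor haplotype; when the configured start
frequency exceeds 1/2N, the extra copies are clones of the donor — emulating
an allele that drifted to its start frequency on one background (a hard
sweep). Selection runs until the end-condition frequency is reached,
restarting from the split state if the allele is lost; the neutral sister
population evolves the same realized number of generations, so the realized
split depth (recorded in the truth record) exceeds the nominal one when the
sweep is slow.

**Rescaling caveat (important).** Shrinking N_e to 500 while scaling μ and r
up keeps θ and ρ realistic, but a sweep's duration in generations shrinks
only logarithmically — so relative to the inflated r, rescaled sweeps are
eroded by recombination and post-MAF-filter mutation far more than the
real-population sweeps the method was designed for (r·d·2T at the footprint
scale is several times its real-data value for s ≤ 0.07 at N_e = 500, where
N_e·s ≤ 35 is barely a hard sweep at all). The packaged recovery experiments
therefore draw s from U(0.08, 0.1) — the top of the plausible range, where
N_e·s ≥ 40 — and sample the sweep at 75% frequency, the regime where iHS has
its documented power; near fixation the swept markers leave the MAF window
and power collapses onto xpEHH. Even so, per-replicate recovery under these
desk-scale conditions plateaus well below 1 (see Limitations).

**Frequency-only drift companion.** f3 needs only per-site allele
frequencies, so sign-recovery experiments at 50k SNPs use a frequency-level
Wright–Fisher (ancestral frequencies from the neutral spectrum, binomial
drift per generation, pulse admixture as the α-mixture of source
frequencies, binomial sampling noise). Sites are unlinked; positions are
spread over a 2 Gb pseudo-genome so the 5 Mb block jackknife has ~400
non-trivial blocks.

**Synthetic gene annotation.** Uniform tiles (20 kb genes, contiguous in the
packaged experiments) written as BED. They are coordinate scaffolding for the
aggregation and ranking machinery, not models of gene structure.

## What the tests do and do not show

The simulator emulates neutral SFS structure, drift differentiation, pulse
admixture and single-origin sweeps on a 1 Mb, 10-window genome. It does not
emulate: genome-scale standardization backgrounds (the paper standardizes
over ~9M SNPs, where sweeps are negligible mass; on 1 Mb the sweep's own
sites contaminate the bin moments and cap attainable |z|), realistic
demography, variable recombination/mutation maps, soft sweeps, background
selection, genotyping error or phasing error (panels are born phased and
complete). Passing recovery tests therefore demonstrates that the pipeline's
machinery finds planted signals under honest conditions — not that its power
on this toy genome equals the genome-scale power of the original study.

Quantified limits under the packaged study conditions (measured across
development replicates, then frozen): the sweep-containing window is the
top-1% window in roughly 60–90% of replicates depending on the 20-replicate
batch, and a window within 100 kb of the sweep in 75–95% (extreme |iHS|
concentrates partly at the footprint edges — the classic "donut" — so the
adjacent window wins a minority of the time); the top rank-sum gene overlaps
the sweep window in roughly 45–75%, bounded mainly by the xpEHH > 2.5 gate
sitting near the z-ceiling a 1 Mb standardization panel can produce. The
batch-to-batch spread is what a per-replicate success probability of ~0.6–0.8
implies at n = 20. The acceptance suite asserts the strict joint figure, and
the acceptance script reports strict and within-100 kb rates side by side.

## Numerical conventions and degenerate inputs

VCF positions are 1-based inclusive internally; all window and interval
arithmetic is 0-based half-open; BED is written 0-based half-open. Undefined
statistics are explicit NaN, never silently dropped. Multi-allelic and
non-SNP records are dropped with a count, never decomposed. Ancestral
polarity comes from the AA INFO tag when it matches ref or alt; otherwise
ref = ancestral with a per-site fallback flag, and analyses that need
polarity should use |iHS|. Empty windows, empty candidate sets and
monomorphic sites all produce valid empty/NaN output rather than errors.
Oracle agreement for the closed-form statistics is asserted at 1e-12, for
haplotype statistics at 1e-9.
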