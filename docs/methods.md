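# Methods

This note documents the models, parameter choices and numerical decisions
behind `sexscan`, and what the synthetic data can and cannot establish.

## Cross simulator

### Genome and markers

Markers are placed uniformly at random along each chromosome (counts
multinomial in physical length) with genetic positions obtained by linear
bp→cM scaling per chromosome. Defaults emulate a RAD-seq intercross
dataset: 22 chromosomes of 40 Mb / 60 cM, 10,000 SNPs, two F0, two F1×F1
families, ~180 F2, negative-binomial read depth with mean 25 and size 8
(inside the 12–50× range typical for such data), 5% missingness, 1%
genotype error. Three marker classes exist:

* **species-diagnostic** sites (default rate 0.2 of markers, matching the
  ~10–24% of SNPs retained as homozygous-alternative between founders in
  comparable datasets): grandmother homozygous reference, grandfather
  homozygous alternative;
* **gametolog** sites: a variant private to the Y (or W) haplotype,
  placed within ±15 cM of the determiner at rate 0.05 per marker, which at
  default marker density yields on the order of ten Y/W-linked sites —
  the order of magnitude seen in real young-sex-chromosome crosses;
* remaining sites are monomorphic within founders (half reference, half
  alternative homozygotes), emulating invariant RAD sites; they are
  eliminated by the MAF filter, as in real data. `founder_het_rate`
  (default 0) can re-introduce within-founder polymorphism; the default
  keeps founders fully inbred apart from the species difference, which is
  what the diagnostic-site ascertainment assumes and makes the sex
  chromosome's heterozygosity attributable to gametologs alone.

### Recombination

Adjacent-interval exchanges are independent Bernoulli draws with
probability r(d) of the configured map function. For Haldane
(r = (1−e^(−2d))/2) this Markov chain is exactly the no-interference
Poisson crossover process. For Kosambi (r = tanh(2d)/2) it is the standard
adjacent-interval approximation — the same one intercross genotype HMMs
use — which reproduces r(d) exactly between adjacent loci and approximates
it between distant ones. Pairwise map-function fidelity is tested at
d ∈ {1, 10, 50} cM over 10,000 meioses.

A configurable zero-recombination window (default ±2 cM) around the
determiner applies to meioses of heterogametic parents only: X–Y (Z–W)
recombination is suppressed where the determiner resides, while the
homogametic parent's chromosomes recombine freely. This is the minimal
representation of a young, largely recombining sex chromosome.

### Sex determination arithmetic

Phenotypic sex is assigned per F2 in this order:

1. *determiner*: carriers of the Y (W) allele are male (female); with
   probability 1 − penetrance the implied sex is replaced by a fair coin;
   `sd_system = none` makes sex a fair coin outright.
2. *modifier* (optional second locus, carried on one haplotype of a chosen
   founder): carriers of ≥1 modifier allele have their sex forced to the
   modifier's direction (feminizing → F) with the modifier's own
   penetrance. The modifier therefore overrides the determiner, which is
   the simplest truth table consistent with dominant sex modifiers.

F1 sexes are assigned strictly by the determiner (a fully penetrant F1 is
required anyway to found a family with one dam and one sire; pairs are
resampled until both sexes appear). Composition-specific viability is a map
(composition, sex) → survival probability applied by rejection sampling,
with an explicit error after a bounded number of rejected batches.

### Noise model

Depth ~ NB(mean, size), shared across sexes (real comparable data show
female/male depth ratios of ~0.9–1.1 everywhere, i.e. no degeneration). An
optional deletion span halves the depth of Y/W carriers over a region, for
testing the depth-ratio diagnostic. Genotype errors replace a call with one
of the two other genotypes uniformly; missingness is independent per
genotype. Errors are applied before missingness.

### What the simulator does not model

Read-level artifacts (allelic dropout correlated with alleles, paralogous
mapping, indel proximity), linkage-map estimation error (maps are emitted
with the true marker order and positions), B chromosomes (only their
phenotypic effect is representable through a modifier locus), and
within-species polymorphism by default. Passing tests therefore demonstrate
correctness of the statistical machinery under idealized RAD-like noise,
not robustness to alignment pathology.

## Filter cascade

Order: genotype depth mask (< 10 reads → missing) → site missingness
(> 50% removed) → individual filters (mean depth < 12 or > 50% missing
removed) → site missingness again → MAF (≥ 0.05 kept) → depth-IQR site
filter. Boundary semantics follow the printed thresholds exactly (strict
">"/"<", inclusive "at least").

The depth-IQR rule is read as an upper bound: site mean depth ≤ (mean of
site means) + 1.5 × IQR(site means). Two numerical choices: the bound is
inclusive (with uniform depths IQR = 0 and a strict bound would delete
everything), and the rule is iterated to a fixed point so the surviving set
itself satisfies the bound — this makes the whole cascade idempotent, a
property the test suite asserts. Fewer than 4 sites leave the IQR undefined
and the filter passes through with a warning.

The Hardy–Weinberg filter (applied only upstream of single-marker
regressions, as in the source workflow) uses the standard exact SNP-HWE
test (probabilities of heterozygote counts conditional on allele counts;
two-sided by summing outcomes no more probable than the observed),
implemented in-package and verified against direct factorial enumeration.
Sites with F2 heterozygote proportion > 0.75 are treated as collapsed
paralogs and removed from the F1-het ascertainment.

An allelic-balance correction of founder genotypes is provided as an
approximation (heterozygous F0 calls with minor-read fraction < 0.2 recoded
to the majority homozygote) but is a no-op unless per-allele read counts
are supplied — the VCFs this package writes carry only total depth.

## Sex-contrasted statistics

The F1-heterozygous site proxy averages the F2 alternative-allele frequency
of males and of females and keeps sites with the average in [0.45, 0.55].
At the mapping-cohort sizes this package targets (n ≈ 150–220) the binomial
sampling SE of that average is ~0.026–0.030, so the band captures ~90–95%
of true F1-het sites; at n = 100 the capture rate is analytically only
~84%, a property of the band, not of the implementation (the test suite
checks the observed sensitivity against an exact binomial-convolution
oracle at the realized sex counts).

The permutation test shuffles one sex-label vector per replicate shared
across all sites (10,000 replicates by default, seeded). Shared labels make
the genome-wide pattern of one replicate internally consistent and cost one
matrix multiplication per block; per-site independent draws would only
inflate runtime. The tail is one-sided in the direction of the observed
difference; ties count as extreme; `p_emp` carries the (1+k)/(1+B)
correction for ranking while the significance flag applies the raw
"at most 1 of 10,000 as extreme" rule. Heterozygote-difference statistics
run genome-wide (not only on F1-het sites): fully Y/W-linked sites have a
mean-of-sexes allele frequency of 0.25 and would be excluded by the AF
band, yet they carry the entire heterogamety signal.

A chromosome is called XY (ZW) when ≥ 3 significant sites exist and ≥ 80%
of them share the positive (negative) sign; both knobs are configurable.

## Association scans

Single-marker ANOVA treats sex (0/1) as the response and genotype (up to 3
classes) as the factor; F is converted by LOD = (n/2)·log10(F·df/(n−df−1)+1)
with df = classes − 1, so the formula reduces correctly when a class is
absent; PVE = (1 − 10^(−2·LOD/n))·100. Perfect separation (zero
within-group variance) caps the LOD at 50 with a flag. A family covariate
is available on this path as an extra-sum-of-squares F test after an
additive family term.

Interval mapping computes conditional genotype probabilities by
forward–backward over the intercross chain (states hom/het/hom; stationary
prior 1/4,1/2,1/4; transitions from the map function between consecutive
positions; symmetric emission error, default 0.05) on the marker set
augmented with a 1 cM pseudomarker grid. The binary single-QTL model — each
genotype class k has its own probability π_k of being male — is fitted at
every position by EM on the genotype-probability mixture; this is the exact
maximum-likelihood formulation of binary interval mapping (an IRLS scheme
on expected dosages would be an approximation, so EM was preferred). π is
clipped to [1e-6, 1−1e-6]; hitting the clip marks separation; LOD is capped
at 50. Genome-wide thresholds are the 1−α quantiles of the max-LOD null
distribution over seeded sex-label permutations (1,000 by default).

The 95% Bayesian credible interval normalises 10^LOD over a chromosome's
positions and returns the *exact* smallest contiguous span containing the
peak with ≥ 95% mass (two-pointer search; verified against full interval
enumeration), then widens the endpoints to the nearest flanking true
markers. The interval scan runs on the species-diagnostic marker set (the
linkage-map markers): monomorphic and Y/W-linked sites do not follow the
intercross genotype model and would distort the HMM.

cM→bp interpolation fits one cubic smoothing spline per chromosome with
the penalty chosen by generalized cross-validation (a fixed smoothing
parameter in another ecosystem's parameterization is not portable);
predictions are clipped to the mapped bp range and made monotone
non-decreasing. Chromosomes with < 5 mapped markers fall back to linear
interpolation.

## Allele tracing

Y/W-linked sites: heterozygous in every F0/F1 individual of the
heterogametic sex and homozygous in the homogametic line (surrogate mode:
conspecific males/females of the relevant species stand in for the missing
pedigree). The two-site composition decode combines (a) the most strongly
sex-linked Y/W site — ranked by permutation p, then |het_diff|, then
position — with (b) the most strongly sex-linked species-diagnostic site.
Diagnostic sites show no heterozygote contrast, so (b) is ranked by the
grandpaternal-genotype frequency contrast |freq_gp_m − freq_gp_f|; because
that contrast is flat within sampling error across the linked region, all
candidates within one SE of the maximum are treated as tied and the one
physically closest to the chosen Y/W site is used. Decodes inconsistent
with the cross structure (a Y carrier with zero grandpaternal alleles; two
grandpaternal X copies without a Y) are flagged recombinant; a missing
genotype at either site yields "unresolved"; discordant flags mark
phenotype vs genotype-predicted sex conflicts. Note the decode is exact
only for sites fully linked to the determiner — a site at recombination
fraction r mis-assigns ~r of the F2 through genuine recombination.

Run smoothing for visualization/denoising replaces maximal runs of ≤ 3
equal genotypes whose five immediate neighbours on each side are equal to
one another (both sides the same value) and different from the run, in a
single left-to-right pass over the input vector (no cascading); missing
genotypes break both runs and flanks. This is the only genotype-error
heuristic applied — no phasing is performed; explicit missing-data handling
replaces it throughout.

Composition summaries reweight each sex to 0.5 before pooling (undoing
sex-ratio distortion) and test each composition's count against its
Mendelian expectation (¼ per F1 gamete combination, collapsed over
identical labels) with an exact binomial test.

## Windowed divergence

Site filters, in order: > 25% missing removed; genotypes < 10 reads set
missing; variant sites whose minor allele has ≤ 2 copies removed
(monomorphic sites pass — they carry no allele-count evidence of error).
Heterozygosity is the individual's heterozygous proportion per half-open
1 Mb window; the denominator is the individual's genotyped SNPs unless a
per-window callable-site count is supplied (a SNP-only call set cannot
yield a per-sequenced-position denominator by itself). dxy uses the
frequency form p_A(1−p_B) + p_B(1−p_A) per site, averaged over sites where
both groups have data; it is symmetric and verified against explicit
allele-pair enumeration. Windows are anchored at position 0.

## Pipeline and reproducibility

A single global seed fans out to stage seeds (simulate, sexstats, scan)
via `numpy.random.SeedSequence.spawn`, so stages are independently
reproducible and identical configs produce byte-identical tabular outputs.
The heterogamety call drives tracing and windows by default; the system can
be asserted (`heterogamety: XY|ZW`) to trace from the scan-peak chromosome
when modifiers dilute the permutation signal below the calling rule — the
diluted call is expected behaviour, not a defect.

## Problem sizes in the test suite

The suite scales simulations to what the checks require: map-function
fidelity at 10,000 meioses; Punnett recovery at 10,000 F2; permutation
calibration at 5,000 segregating sites × 120 individuals × 10,000
permutations; end-to-end recovery over 100 seeded crosses of 1,000 markers
on 4 chromosomes × 150 F2 (4 chromosomes preserve the per-cM marker
density of a 10,000-marker, 22-chromosome dataset, which is what the
gametolog-site yield depends on). All stochastic assertions use 3–4 SE
tolerances around values derived from closed forms, exact enumeration or
independent brute-force implementations.

## Known limitations

* Kosambi long-range recombination fractions are approximate (see above).
* The permutation flag's strict ≤1/10,000 rule has low power for diluted
  signals (incomplete penetrance, modifiers) at moderate sample sizes; the
  marker-regression path is the robust fallback there.
* Surrogate mode assumes surrogates share the founders' haplotypes; real
  conspecific panels segregate additional variation.
* The allelic-balance correction requires per-allele read counts that VCFs
  produced by this package do not carry.
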