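# Methods

This note documents the statistical procedures implemented in `sweepsignal`,
the defaults they ship with, what the synthetic-data generator does and does
not emulate, and the numerical choices made where a convention had to be
fixed.

## Data model and coordinates

Genotypes are alt-allele dosages (0/1/2, missing = −1) for samples ×
variants; haplotypes are binary 2N × variants matrices with no missing
values (phasing is upstream — the haplotype statistics assume their input
VCF is fully phased and error loudly otherwise). Positions are 1-based and
strictly increasing within a chromosome; BED output converts to 0-based
half-open. Variants are sorted by (chromosome, position) on input, with
chromosome names ordered numerically where possible.

A `GenotypeMatrix` cannot represent which haplotype of a heterozygote
carries the alt allele, so its VCF writer emits `0|1` for every het;
haplotype-faithful output goes through `write_phased_vcf` on the
`HaplotypeMatrix`. Routing phased data through the genotype writer silently
randomizes phase and measurably degrades EHH-based scans — the distinction
is deliberate and documented on both writers.

## Quality control and diversity

`qc_filter` applies one fixed-order pass: (1) drop samples with missing
fraction > `mind` (default 0.05), (2) drop variants with missing fraction >
`geno` (0.05) among remaining samples, (3) drop variants with MAF < `maf`
(0.05). The order mind → geno → maf is fixed for reproducibility; PLINK's
internal ordering is version-dependent. A single pass is not mathematically
idempotent: removing variants can push a borderline sample's missing
fraction over `mind` on a second application. At array-realistic
missingness (~1–2%) this does not occur; the semantics are the standard
single-invocation PLINK behavior.

Per-breed diversity: per SNP with n genotyped diploids and alt frequency p,
Ho = heterozygote fraction, He = 2p(1−p)·2n/(2n−1) (small-sample
corrected), MAF = min(p, 1−p); breed values are means over SNPs (SNPs with
<2 genotyped samples in the breed are excluded from its means) and
F = 1 − H̄o/H̄e. F from breed-mean heterozygosities was chosen over averaged
per-individual inbreeding because it is well defined at small n and
represents heterozygote excess (F < 0) naturally.

LD pruning is greedy and windowed (50 SNPs, step 5, r² > 0.2): within each
window the member of an offending pair with the lower overall MAF is removed
(tie: the later position), repeating until no pair exceeds the threshold.
Removal by lower MAF is a deterministic, documented stand-in for PLINK's
internal ordering.

## Runs of homozygosity

The sliding-window scorer follows detectRUNS semantics: a 15-SNP window is
homozygous when it holds ≤1 heterozygous and ≤1 missing call; each SNP's
score is the fraction of its covering windows that are homozygous, with edge
SNPs using their smaller denominator (padding was rejected because it
distorts edge scores); a SNP is in-run when its score strictly exceeds 0.05.
Strict inequality is covered by a boundary test. One consequence worth
knowing: a lone heterozygote immediately flanking a long homozygous stretch
joins the run, because its trailing window contains exactly one het — the
constructed-fixture tests freeze this behavior explicitly.

Maximal in-run stretches become ROH when they hold ≥3 SNPs, span ≥1 Mb
(first SNP to last SNP, inclusive; no window extension) and carry ≥1 SNP
per 100 kb. No additional max-gap rule is applied inside runs — the density
filter already bounds sparsity. Length classes are left-closed right-open in
Mb ([1,6), [6,12), [12,24), [24,48), [48,∞)); percentages are per-breed and
rounded to two decimals. F<sub>ROH</sub> divides a sample's summed ROH
length by the summed autosome lengths from the chromosome-length table.
ROH islands are maximal runs of consecutive map SNPs (consecutive on the
marker map, not in base pairs) whose ROH incidence across a breed's
individuals strictly exceeds 0.60.

## Haplotype statistics

EHH at SNP x for a core allele is the probability that two random carrier
haplotypes are identical at every SNP from the core to x inclusive, computed
per side as Σ C(n_g,2)/C(n_c,2) over identity groups. iHH integrates EHH
over physical distance by trapezoids, per side, truncating at the linearly
interpolated point where the curve crosses 0.05 (the conventional cutoff);
a side that reaches the chromosome end while still above the cutoff is
flagged truncated but retained — no gap penalty is applied between adjacent
SNPs, as array maps are relatively even and any penalty constant would be
arbitrary here.

iHS is ln(iHH₁/iHH₀), unpolarized: SNP arrays carry no ancestral-allele
call, so allele 1 is simply the alt allele and every downstream threshold
uses |z|. Standardization is within 20 equal-width bins on the allele-1
frequency; bins holding <10 SNPs are merged with their smaller adjacent
neighbour (ties to the left); z uses the sample standard deviation (n−1).
SNPs with within-panel MAF < 0.05 or fewer than two carriers of either
allele are skipped and logged. Windows of 500 kb tile each chromosome from
coordinate 0 advancing 250 kb; windows with ≥5 scored SNPs are retained,
the statistic is mean |z|, and candidates are windows at or above the
empirical 99th percentile. Quantiles are taken right-closed at an actual
data value (numpy's `higher` method) and ties at the threshold are all
included, so the candidate fraction is approximately — never exactly — the
nominal top fraction.

XP-EHH compares whole-population (pooled, unconditional) iHH between two
panels on identical marker maps: raw = ln(iHH_A/iHH_B), standardized by the
genome-wide mean and sample sd. Swapping the populations negates every raw
score exactly. Outlier SNPs (|z| at or above the top-1% threshold) are
merged into intervals when ≤250 kb apart; each interval is labelled with
the favored population by the sign of its mean z (positive → first
population). SNP-level outlier merging (rather than re-using the 500-kb
window scheme) is the documented choice for this statistic.

## FST

Per SNP the two-population Weir–Cockerham (1984) variance components a
(among populations), b (among individuals within populations) and c (within
individuals) are computed from diploid sample sizes, alt frequencies and
observed heterozygote fractions; θ = a/(a+b+c), which may legitimately be
negative near zero differentiation. Windows aggregate as a ratio of sums
Σa/Σ(a+b+c) — never a mean of per-SNP ratios, which explodes at
low-information SNPs; a test pits the two against each other on a
heterogeneous window. SNPs monomorphic across the pooled pair, or with <2
genotyped diploids in either breed, are excluded. Window scheme: 500 kb /
250 kb step, ≥3 SNPs, top 1% per breed pair (the outlier fraction is
configuration, mirroring the other scans, since no universal FST cutoff
exists).

## Consensus regions

Candidate intervals from all four methods are merged per chromosome,
method- and breed-agnostic, whenever the gap between successive spans
(next start − current end − 1) is ≤250 kb, transitively; breed resolution
happens only at classification. Evidence attribution: ROH and iHS intervals
support their own breed; XP-EHH supports its favored breed; an FST interval
is pair-level and supports a member breed only when that breed already has
within-population or XP-EHH evidence in the region — FST alone can never
assign a breed, which is what rejects two-breed hotspots supported only by
shared ROH plus their pairwise FST.

A breed qualifies *primary* with ≥3 distinct methods including at least one
within-population (ROH/iHS) and one between-population (FST/XP-EHH) method,
and *secondary* with exactly one of each. When several breeds qualify, the
region is assigned only to a unique best breed with strictly more methods
than every rival; otherwise it is unassigned. A breed reaching three methods
without the within/between mix is not tiered (logged); with only two
within-population methods defined this cannot arise from single-breed
evidence, but the guard keeps the invariant explicit.

## Synthetic panels

The generator is a deliberately simple caricature — adequate to create the
LD, haplotype-sharing and differentiation structure the statistics consume,
and not a demographic model:

* **Map and founders.** Per chromosome, SNP positions are uniform
  (deduplicated, sorted) and site frequencies p_j ~ Uniform(0.1, 0.5);
  founder frequencies are bounded away from 0 so MAF filtering does not
  empty the panel. K = 20 founder haplotypes carry allele 1 at site j with
  probability p_j.
* **Mosaics.** Each sample haplotype copies founders Li–Stephens style,
  switching to a uniformly chosen founder between adjacent SNPs with
  probability 1 − exp(−ρd), ρ = 10⁻⁶/bp — at the default 50-kb marker
  spacing this gives ~5% switch probability per step and LD decaying over a
  few hundred kb. The marginal law of a haplotype is the realized founder
  pool, not the latent Uniform draw; the convergence test compares against
  the pool.
* **Population splits.** Per population and site, p′ ~ Beta(p(1−F)/F,
  (1−p)(1−F)/F) (Balding–Nichols; Var = p(1−p)F). The population's founder
  pool is then built with allele counts matched to p′ by randomized rounding
  rather than i.i.d. Bernoulli draws: Bernoulli founders would add a second
  drift term of order (1−F)/K to the realized between-population variance
  (~0.04 at K = 20), visibly inflating Weir–Cockerham estimates above the
  target. With matched founders the genome-wide ratio-of-sums estimate
  calibrates to the target within ±0.02 at 5,000 SNPs and 25 diploids per
  population.
* **Sweeps.** A hard copy-paste event: one carrier haplotype is the core,
  its focal allele is set to 1, and ⌈f_s·2N⌉ haplotypes are overwritten
  with the core's alleles over [focal − L_left, focal + L_right] with
  L ~ Exponential(mean λ) independently per haplotype, emulating
  recombination-eroded sweep edges. Detectability is tuned by (f_s, λ).
  Note that a *diploid* homozygous run around the focal SNP has length
  ~min of two exponentials per side, so ROH islands require generous flanks
  (λ of several Mb at the default map) even at high f_s, whereas iHS and
  XP-EHH respond at λ = 500 kb.
* **Defaults.** Two 40-Mb chromosomes at 800 SNPs each (50-kb spacing, i.e.
  medium-density array scale) and 25 diploids per population — a desk-scale
  emulation of a multi-breed array panel that keeps a ten-seed end-to-end
  recovery experiment within a few minutes on one CPU. Diploids are formed
  by pairing consecutive haplotypes; output is phased VCF plus population
  map, chromosome-length table and truth BED.

What passing tests on these panels show: the scans detect the haplotype
and frequency structure they claim to detect, at the planted effect sizes,
under clean phased data with no genotyping error. What they do not show:
robustness to phasing error, array ascertainment bias, real demographic
history (bottlenecks, admixture), or mutation/recombination heterogeneity —
none of which the generator models.

## Degenerate inputs and numerical conventions

* Chromosomes shorter than the ROH window are scored over the single
  truncated window (warning logged).
* EHH group refinement stops once the curve reaches exactly 0 (it cannot
  recover); curves that reach the chromosome end above the iHH cutoff are
  flagged.
* iHS bins with zero raw-score variance produce NaN z (excluded from
  windows, logged); an all-identical XP-EHH raw vector standardizes to 0.
* Empirical top-quantile thresholds use numpy's right-closed `higher`
  method; all ties at the threshold are included.
* Pair-level r² for LD pruning uses pairwise-complete observations and
  treats zero-variance or <2-observation pairs as uncorrelated.
* All simulation randomness flows from a single integer seed through
  `numpy.random.default_rng`; reruns are bitwise identical.

## Known limitations

* iHS/XP-EHH are unpolarized; with ancestral-allele calls available the
  standard polarized scores would be preferable.
* The ROH scorer intentionally reproduces sliding-window semantics,
  including the single-flanking-heterozygote inclusion noted above; the
  consecutive-runs ROH method is out of scope.
* GO/KEGG enrichment is out of scope (external, database-version-dependent);
  the per-region gene list TSV is the hand-off artifact.
* The consensus tie-break (unique strictly-larger method count) is a
  documented choice; alternative resolutions of equal-evidence regions are
  defensible.
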