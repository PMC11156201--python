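# Methods

`purgescan` couples a forward-time Wright–Fisher simulator to a
population-genomic analysis pipeline in order to test, end to end, whether
the signature of *genetic purging* — reduced deleterious burden in small,
bottlenecked, partially selfing populations, despite their smaller effective
size — is recovered by the same statistics a resequencing study would
compute: a per-individual genetic-load proxy, class-stratified unfolded site
frequency spectra (SFS), windowed diversity and differentiation scans, and
runs of homozygosity (ROH).

## The forward simulator

**Model.** Diploid Wright–Fisher with non-overlapping generations. The
per-generation cycle is mutation → viability selection → mating. Fitness is
multiplicative across sites with per-site genotype fitnesses 1, 1−hs, 1−s;
parents are sampled proportionally to viability; each offspring is produced
by self-fertilisation with the population's selfing probability F, otherwise
by random union of gametes from two (possibly identical, at rate 1/N)
parents. Demography is a tree of populations: daughters are founded at their
split generation by sampling founders with replacement from the parent, and
per-population epochs set diploid sizes through time.

**Sites and mutation.** The simulator first builds a deterministic toy
reference genome: single-exon protein-coding genes on alternating strands
separated by random intergenic sequence. From the codon structure it derives
three mutable site pools, each position carrying one bound alternate allele:

* *neutral-4fold* — fourfold-degenerate third codon positions (s = 0);
* *deleterious-missense* — positions whose bound substitution is
  nonsynonymous (selection coefficient `sel_coeff`, dominance `dominance`);
* *stopgain* — positions whose bound substitution creates a stop codon
  (`s_lof`, `h_lof`).

Because alleles are bound at genome-build time, the emitted VCF, the
functional truth labels, and the codon-aware annotator agree by
construction (and this agreement is asserted in the tests rather than
assumed). Mutation is per reference copy: events are drawn uniformly over
(site × individual × haplotype) slots at rate μ per copy per generation;
hits on copies already carrying the alternate allele are no-ops, which is an
exact Poisson thinning to the reference copies. Sites remain strictly
biallelic; a site fixed in every population is retired as a substitution
(its position cannot become polymorphic again, a deliberate simplification
that costs ~μ·t of the pool over a run and is kept negligible by the run
lengths used). A final mutation round precedes observation so sampled
genomes include the current generation's mutations, matching coalescent
terminal-branch expectations for the singleton class.

**Linkage.** Default `independent`: each site segregates independently at
gamete formation (free recombination), which makes single-locus closed forms
exact — neutral diversity π = 4Nμ, the neutral SFS E[ξ_i] ∝ 1/i, selfing
heterozygosity (1 − F_IS)·2pq with F_IS = F/(2−F), and additive/recessive
mutation–selection balance. The alternative `block` mode transmits whole
parental haplotypes (a single non-recombining segment). None of the
statistics in scope require LD realism, so independence is the default.

**Outgroups.** Two single-genome outgroup columns are generated from the
true ancestral allele (the reference base): each lineage substitutes
independently with probability 1 − exp(−d) per site, uniformly over the
other three bases. Outgroups are never polymorphic, matching single-genome
outgroup assemblies.

**Determinism.** All randomness is drawn from per-(population, generation)
streams keyed from the master seed; identical configs reproduce
byte-identical bundles.

**Calibration caveats.** At the mutation rates desk-scale runs need
(10⁻⁵–10⁻⁴ per site per generation, orders of magnitude above the plant
nuclear point estimate of ~7×10⁻⁹ which would require genome- and
population-scale runs), three small systematic effects exist and are kept
below test tolerances by construction: substitution retirement (∝ μt),
finite burn-in (∝ e^(−t/2N)), and drift bias of recessive mutation–selection
balance. For the last, the diffusion mean lies below the deterministic
√(u/s) unless 2N√(us) is large; the calibration check therefore uses
N = 20,000 and u = 4×10⁻⁵ (2N√(us) = 80), where an independent single-locus
Wright–Fisher oracle puts the stationary mean within ~6% of √(u/s).

## The highland/lowland scenario

The preset emulates a fragmented alpine system at desk scale: one large,
outcrossing lowland population at stationarity, and four highland isolates
that split from it, pass through a glacial bottleneck with high selfing
(F = 0.8), and then partially recover. With fully recessive deleterious
mutations (h = 0), selfing exposes new mutations as homozygotes almost
immediately (the per-copy purging rate is ≈ s·F_IS, selection-dominated even
at bottleneck sizes), so deleterious variants are purged while neutral
variants only drift; the post-bottleneck recovery regenerates an excess of
rare, still-selected deleterious variants. `scale="small"` uses a 400 kb
genome, lowland N = 100 (burn-in 800 generations = 8N), bottleneck N of
15–30 for 30 generations, recovery to N of 60–95 for 50 generations, with
μ_neutral = 2×10⁻⁵, μ_del = 8×10⁻⁶, s = 0.3, and 15 sampled
diploids per clade; `scale="default"` scales everything up ~4×. Highland
π_s ends reduced but of the same order as the lowland's, not erased — the
regime the analysis assumes. Fifteen samples per clade keep the projected
SFS at n = 30 haplotypes, where the homozygous-rare class characteristic of
selfers (a new mutation typically rides in one homozygous individual, a
doubleton at DAF 2/30) still falls below the rare-variant threshold of 0.1.

The highland selfing rate is a free parameter of the scenario, not an
empirical estimate for any species; 0.8 was chosen as "highly selfing but
not obligate" and is configurable.

## The analysis pipeline

* **Filter** — per-call depth < minDP set missing first (skipped with a
  warning when no depth field exists, as for simulated bundles); then sites
  with called fraction < 0.8 or minor allele frequency < 0.05 are dropped,
  MAF computed over called alleles only. The purging experiment applies the
  MAF filter only ahead of ROH detection (`maf_filter_for_roh_only`): ROH
  scanning conventionally runs on common SNPs, while the load/SFS stages
  need the rare variants the MAF filter would destroy.
* **Annotation** — codon-aware classification from reference FASTA + GFF3
  CDS models (1-based positions; minus-strand codons on the reverse
  complement; CDS phase honoured; CDS length not divisible by three after
  phase excludes the transcript from codon classes with a warning).
  Region classes: CDS / intron / upstream / downstream / intergenic, with a
  1 kb flank for upstream/downstream (conventional default; configurable in
  `annotate.FLANK_BP`). Variant effects: synonymous, nonsynonymous,
  stopgain, stoploss; multi-transcript conflicts resolve to the most severe
  effect, while fourfold-degenerate status requires unanimity across
  transcripts covering the site as CDS (conservative for π_s). Standard
  nuclear code only.
* **Polarization** — two-outgroup parsimony. Outgroups agreeing on a focal
  allele make it ancestral (`resolved`); agreeing on a third allele makes
  both focal alleles derived (`resolved-external`; these count toward
  derived-allele dosages but are excluded from the unfolded SFS, whose
  frequency axis needs one derived allele, and from the load proxy by
  default since they add a constant offset); disagreement or a missing
  outgroup leaves the site `unresolved` and excluded everywhere, with counts
  reported.
* **Diversity** — per-site π = 2c(n−c)/(n(n−1)); windows are half-open
  [start, end) with the 50 kb/10 kb sliding convention for π and F_ST and
  non-overlapping 10 kb windows for fourfold diversity π_s (dividing by the
  number of fourfold reference positions per window). Window π divides by
  window length (monomorphic positions count as zero), keeping magnitudes
  per-bp. Missing genotypes adjust the per-site n.
* **F_ST** — Weir–Cockerham (1984) two-population variance components with
  the random-mating (Hardy–Weinberg) expectation for heterozygote
  frequencies, since only allele counts enter; windows report the
  ratio-of-sums estimator Σa / Σ(a+b+c), negative values retained, missing
  below 10 SNPs per window (configurable).
* **ROH** — sliding SNP-window scan: windows of 40 SNPs, homozygous when
  holding ≤ 2 heterozygous and ≤ 10 missing calls; a SNP qualifies when
  ≥ 5% of its spanning windows are homozygous (the threshold is the minimum
  fraction); maximal runs of qualifying SNPs, split at gaps > 1000 kb,
  trimmed to homozygous non-missing ends, and reported when ≥ 40 SNPs,
  ≥ 30 kb, and ≥ 1 SNP per 50 kb. Windows truncated at chromosome ends
  count toward hit rates. These exact rules (truncation, trimming, ties)
  are frozen by a brute-force window-enumeration oracle in the test suite.
* **Load** — per sample, the ratio of derived deleterious-missense (dnSNP)
  allele dosage to derived fourfold-degenerate allele dosage, over called
  genotypes at resolved sites only; dosage counting by default (heterozygote
  = 1, homozygote = 2), carrier counting behind a flag. Undefined when the
  denominator is zero (flagged, excluded from clade medians). Clade
  comparisons use Wilcoxon rank-sum tests with Benjamini–Hochberg adjustment
  across pairs; the π_s–load relation reports Pearson and Spearman
  coefficients with no causal claim.
* **SFS** — unfolded spectra on a fixed number of haplotypes via
  hypergeometric projection of each site's (derived, called) counts; fixed
  classes excluded; the projection fails loudly when more than half the
  sites have fewer called haplotypes than requested. Rare fraction =
  Σ_{i/n<t} ξ_i / Σ ξ_i with t = 0.1 by default (configurable).
* **Sweeps** — top-q outlier windows by empirical order statistics
  (cutoff = the (1−q) quantile, `method="higher"`, ties included); window-level
  intersection of two tracks; candidate genes overlap ≥ 1 bp of an
  intersected window (gene-level intersection available behind a flag);
  parallel candidates are the set intersection across comparisons. The
  second track is either an external score table (e.g. a cross-population
  composite-likelihood scan) or any internally computed window track.

## The purging experiment

Each replicate simulates the scenario twice — recessive (h = 0) and additive
(h = 0.5) arms — runs the full pipeline on each bundle, and tabulates:
pooled-highland vs lowland sample-median load, median 10 kb π_s, mean
per-sample ROH total length, mean per-clade rare-dnSNP fraction (projection
n = 30, DAF < 0.1), and the Spearman correlation of clade median π_s with
clade median load across the five clades. The recessive arm is expected to
show highland load < lowland load (sign test across replicates), lower
highland π_s, larger highland ROH totals, a highland excess of rare dnSNPs,
and a positive π_s–load correlation; the additive arm is tabulated with no
ordering enforced — deleterious variants are then so efficiently removed in
both settings that the load proxy collapses and the highland/lowland gap
largely disappears, which is the recessivity dependence the purging
interpretation requires.

## Problem sizes and degenerate inputs

Replicated checks run at deliberately small problem sizes chosen as desk
scale (e.g. 30 experiment replicates of the small scenario; neutral
calibrations with N = 40 over 480 generations and 50 replicates; the
mutation–selection balance check at N = 20,000 over a ~30-site pool);
the methods above do not depend on these sizes. Degenerate inputs are
defined rather than left to chance: an empty segregating-site set yields a
header-only VCF; a window with no SNPs has π = 0 (not missing) but F_ST
missing; monomorphic sites contribute nothing to load or SFS; a population
whose every individual has zero viability aborts the run naming the
generation; constant input to the correlation stage returns flagged NaNs;
and a constant outlier track returns every window with a warning.

## Known limitations

* No recombination map, gene conversion, or LD structure; ROH in
  `independent` mode arise statistically from elevated homozygosity rather
  than from IBD segments, so ROH *lengths* are not demographically
  interpretable — only between-group contrasts are used.
* The toy genome has single-exon genes only (the annotator itself handles
  multi-exon, phased, multi-transcript models, which are covered by
  hand-built fixtures in the tests).
* One-way mutation without back-mutation; substitution retirement slowly
  shrinks the mutable pool on very long runs.
* The load proxy is a relative burden measure; it is not fitness-scaled
  load, and masked vs realised load are not decomposed.
* Outgroup generation ignores among-lineage rate variation and ancestral
  polymorphism, so polarization accuracy on simulated data is an upper
  bound for real outgroup alignments.
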