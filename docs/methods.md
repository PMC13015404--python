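# Methods

`sexscan` infers sex-determining (SD) regions from whole-genome
resequencing of phenotypically sexed individuals, and characterizes a
divergent sex-linked paralog with diagnostic k-mers. This note documents
the statistical models, the synthetic-data generator, the numerical
choices, and the limits of what the bundled tests demonstrate.

## Statistical models

### Per-SNP differentiation

Males and females are treated as the two populations of the Weir &
Cockerham (1984) variance-component F_ST estimator. For each biallelic
site with per-sex called sample sizes n_m, n_f, alt-allele frequencies
p_m, p_f and observed heterozygote fractions h_m, h_f, the components

    a  (among sexes), b  (among individuals within sex), c  (within individuals)

are computed from the 1984 closed forms with r = 2, and θ = a/(a+b+c).
Sites monomorphic across both sexes have an undefined θ and are excluded
from the weighted genome-wide value Σa / Σ(a+b+c) (setting them to zero
would dilute it). A fully sex-linked SNP — heterogametic sex entirely
heterozygous, homogametic sex entirely homozygous — gives θ = 1/2 exactly
for every equal sample size n ≥ 2; this algebraic identity is the working
signature of sex linkage and is verified to 1e-12 against an independent
implementation that derives the same components from the nested
allele-level ANOVA mean squares.

### SNP classification

A SNP is called XY when p_m ∈ [0.45, 0.55] and p_f ∈ [0, 0.05] ∪
[0.95, 1]; ZW with the sexes exchanged; bounds inclusive. The tolerance
absorbs genotyping error without demanding the exact 0.5 / 0 pattern. At
the default bounds the two calls are mutually exclusive.

### Windowed model selection

Per non-overlapping 10-kb window, three genotype-likelihood models are
compared:

* **NULL** — each SNP follows Hardy–Weinberg at its pooled allele
  frequency; log-likelihood summed over non-missing genotypes; one free
  frequency per SNP (k = m).
* **XY** — each SNP is, with window-shared probability ρ, fully
  sex-linked: males heterozygous and females homozygous, each observed
  genotype matching that expectation with probability 1−ε and each of the
  two other states ε/2. The homozygote class of the homogametic sex (ref
  vs alt) is chosen per SNP to maximize the component likelihood, ties
  toward the reference class. Otherwise (probability 1−ρ) the SNP follows
  the NULL term. k = m + 1.
* **ZW** — the same with sexes exchanged.

ρ is maximized on [0, 1] by golden-section search (tolerance 1e-6; the
per-SNP mixture makes the window log-likelihood concave in ρ, and the
boundary values are always evaluated since ρ̂ is frequently exactly 0
or 1). BIC uses N_obs = the number of non-missing genotype observations
in the window — an explicit choice; per-SNP sample sizes are an
alternative that would change the penalty by at most a few nats and none
of the qualitative calls. ΔBIC = BIC_NULL − BIC_model, so the NULL nested
at ρ = 0 guarantees ΔBIC ≥ −ln N_obs, and ΔBIC > 2000 marks strong
support. For a window of 50 fully linked SNPs with 20 individuals per sex
the per-SNP log-likelihood gap is ≈ 30.7 nats, hence ΔBIC ≈ 3070 — which
is why the 2000 threshold separates cleanly. ε defaults to 0.01; an
optional profile-likelihood pass over {0.001, 0.005, 0.01, 0.02, 0.05}
can select it from the data. This mixture is this package's own
formulation of an SDpop-style test; equivalence with SDpop's richer
parameterization (additional segregation types, paralogy classes) is not
claimed, and output headers label it accordingly.

### Region calling

Classified SNPs of the chosen system with θ ≥ 0.2 are single-linkage
clustered with a 100-kb gap tolerance; clusters of ≥ 10 SNPs become
candidate regions delimited by their first and last SNP (1-based
inclusive; size = end − start). Each region reports its mean θ and the
number of overlapping windows with ΔBIC above threshold; regions without
window support are retained by default — support is corroborating
evidence, not a gate, since real polygenic architectures include regions
with clear SNP clusters but no window signal. The three clustering
parameters are package defaults chosen so that regions spanning the
plausible range (a few kb to ~800 kb, tens to hundreds of SNPs) are
representable; all are configurable.

### Coverage and k-mers

Coverage analysis bins per-individual depth (5-kb bins), averages per
sex, and works on log2((m̄+pc)/(f̄+pc)) with pseudocount pc = 0.1; the
detector calls maximal runs of smoothed ratio ≥ 0.58 (≈1.5×) at least
20 kb long, bridging single-bin dropouts. Because it is a ratio detector,
repeat-driven coverage spikes shared by both sexes are not called.

K-mer analysis counts canonical 31-mers (lexicographic minimum of word
and reverse complement, packed 2-bit into uint64), merges counts per sex,
filters at a minimum merged count (20 or 40), and takes set differences:
male-specific, female-specific, common. The default compares the filtered
sets (mirroring a merge→filter→compare order); a strict mode additionally
requires absence from the other sex's unfiltered table. Localization is
exact canonical matching against the reference — for 31-mers, exact
matching is the well-defined core of read-mapping the sets back; no
mismatch tolerance is attempted.

### Paralog diagnostics

The two copies are aligned globally with affine gaps (match +1, mismatch
−2, gap of length L costs −6 − L) via Biopython's PairwiseAligner; the
aligned columns are collapsed into a SNV/insertion/deletion variant
table. Premature stops in the derived copy are reported in a
canonical-anchored frame; codons downstream of a frameshifting indel are
flagged frame-ambiguous rather than silently translated.

Diagnostic k-mers (24 bp) are windows of the target transcript that span
at least one indel junction or at least two linked SNVs, differ from the
best-matching window of every alternative locus by ≥ 2 edits (edlib infix
alignment, both strands), occur exactly once in the target, and — when a
reference is supplied — nowhere else in the genome. Selection greedily
covers distinct events (largest indel first) and fills remaining slots by
difference count, which on the default paralog pair yields three k-mers
at the 18-bp deletion junction and one at the 2-bp deletion, matching the
intended panel structure. Screening counts exact canonical occurrences in
RNA-seq reads (positive at ≥ 1 by default: the use case is detection, not
quantification); matching read pairs are extracted, merged when mates
overlap by ≥ 10 bp exactly, located on the target by infix alignment, and
validated when the fragment covers ≥ 2 distinct diagnostic events
("multiple linked variants").

## Synthetic data

The generator produces: HWE genotypes at sampled alt frequencies
(uniform 0.05–0.95 by default) at SNP density 0.01/bp; inside declared SD
regions every SNP is fully sex-linked before noise. Genotyping error
(default 0.005) replaces a genotype by one of the other two states with
equal probability; missingness (default 0.02) is i.i.d., with optional
per-sample excess to exercise the 70% exclusion rule. Depths are Poisson
around per-individual means drawn from N(10, 2). Depth tracks are
negative binomial per bin (dispersion 20). Read sets are uniform random
fragments of each individual's diploid genome with uniform substitution
errors; the male-limited insertion is present in the (male-derived)
reference, absent from females and hemizygous in males. The paralog
generator builds a stop-free CDS across exons and derives the second copy
by an in-frame 18-bp exon-1 deletion, a frameshifting 2-bp exon-2
deletion, a planted in-frame stop inside the designated domain interval,
a tiled simple-repeat insertion in intron 1, and background SNVs (1%)
that are re-drawn if they would create a spurious in-frame stop. RNA-seq
libraries allocate read pairs to transcripts by largest-remainder
rounding with a guaranteed minimum of one fragment for any nonzero
abundance — the phenomenon being emulated is presence at extremely low
abundance, and a generator that sometimes emits zero copies of a
"present" transcript would conflate scaling with biology.

What the generator does **not** emulate: linkage disequilibrium and
recombination, demography/coalescent structure, indels in the population
VCF, quality-score profiles, GC or mappability bias, partial sex linkage,
or expression noise beyond multinomial sampling. Passing tests therefore
demonstrate correctness of the inference machinery under the stated
generative assumptions, not robustness to every artifact of real data.

## Problem sizes

Reference scenarios are Mb-scale stand-ins for Gb-scale genomes, with
window/bin sizes and thresholds kept at full-scale values so they
transfer: the localized-XY scenario is a 3-Mb chromosome with an 80-kb SD
region, 19 males / 19 females; the polygenic-ZW scenario has three
regions on two of three chromosomes (20/20); the NULL calibration genome
is 5 Mb (500 windows); the read-based k-mer scenario is a 250-kb
chromosome with a 20-kb male-limited insertion at ~10× per individual;
the screening panel has 23 libraries of 15k–100k read pairs, except the
two spiked libraries at 2M pairs so that relative abundance 1e-5 still
yields ~20 target fragments (scaling the spiked libraries as aggressively
as the nulls would leave a single fragment and make detection depend on
fragment placement rather than on the method).

## Numerical notes and edge cases

* Genotype dosage −1 encodes missing; depth masking precedes all site
  filters and never resurrects a site; all filter boundaries inclusive.
* HWE probabilities are clipped at 1e-12 before log to handle fixed
  sites inside windows.
* θ may be negative (sampling noise around zero differentiation);
  weighted F_ST may be slightly negative genome-wide.
* π uses the full window span as denominator, including monomorphic and
  uncalled positions.
* k-mers containing non-ACGT characters are skipped, not substituted;
  counting is invariant under reverse-complementing any subset of reads.
* Coordinates: 0-based half-open internally and in BED/bedGraph; 1-based
  in VCF and in the region-summary table.
* All randomness flows through explicit integer seeds
  (`numpy.random.default_rng`); identical seeds give byte-identical
  outputs.

## Known limitations

* The window mixture models only full sex linkage within the
  heterogametic sex; partially sex-linked or recombining strata are
  summarized by ρ̂ < 1 rather than modeled explicitly.
* Exact k-mer matching will under-localize in repetitive or highly
  divergent references where alignment-based mapping would still place
  k-mers.
* The k-mer pipeline holds per-individual count tables in memory; it is
  designed for the Mb-scale synthetic genomes, not Gb-scale real data.
* Read-pair merging uses exact overlap only; sequencing errors inside
  the overlap defeat merging (the pair is then analyzed unmerged, which
  only weakens, never inflates, linked-variant validation).
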