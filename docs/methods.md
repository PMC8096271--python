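# Methods

`vntrkit` is a desk-scale pipeline for copy-number-variable minisatellite
tandem repeats (VNTRs) with repeat units of 7–126 bp. This note documents
the models and procedures it implements, the choices made where the design
was genuinely open, and what its synthetic data do and do not show about
real sequencing data.

## Repeat model and genotype encoding

A reference tandem-repeat (TR) locus is an interval on a reference genome
carrying a repeat pattern of length 7–126 bp repeated `ref_copies` times
(fractional copies allowed; the stored value is exactly the array length
divided by the pattern length, so detectability arithmetic and realized
arrays never disagree). An allele is an integer change in copy number,
encoded as **CGL** (copies gained or lost): `CGL = observed − round(ref)`.
A per-sample genotype at a locus is the set of detected alleles, each with
a read-support count (**SP**). A genotype of `0` means only the reference
allele was seen; `0,+2` is heterozygous reference / two-copy gain. Note
that a homozygous call is indistinguishable from a hemizygous one in this
encoding — the genotype is a set of observed alleles, not a dosage.

Loci come in two flavours: *singletons* (unique by pattern plus flanking
sequence) and *indistinguishable* families (dispersed loci with shared
pattern and near-identical flanks). Reads matching an indistinguishable
family cannot be attributed to one locus and are discarded; all cohort
statistics run on singletons.

## Wraparound alignment and copy counting

Copy numbers are measured with a local dynamic-programming alignment of a
sequence against the infinite cyclic extension of the pattern. DP columns
are indexed modulo the pattern length, so the alignment may start at any
pattern phase and wrap any number of times. Scores are match +2, mismatch
−5 and −7 per gapped base (linear gaps; the scheme gives a single gap
number, so affine gaps are out of scope). `N` scores as a mismatch.

The within-row horizontal recurrence wraps around the cyclic row and is
resolved by at most two relaxation sweeps; this is exact because each
gapped base costs −7 < 0, so no optimal run of gaps spans a full pattern
cycle. Ties prefer match/mismatch over gaps and then earlier query starts,
making paths deterministic. Optimality is verified in the test suite
against exhaustive Smith–Waterman enumeration over tiled patterns at every
phase.

The copy number of an alignment is the number of **pattern positions
consumed** (diagonal plus pattern-gap moves) divided by the pattern length,
reported at 0.01 resolution. Whether copy counting should use consumed
pattern positions or aligned query length is a convention choice; consumed
positions make a one-base deletion inside one unit still count as a whole
unit, which matches how a geneticist counts copies.

## Detectability rules

Two constraints decide which alleles *could* be observed:

* the repeat array plus a minimum 10 bp flank on each side must fit inside
  a read: `array + 20 ≤ read_length`;
* the repeat finder needs a floor of `min_copies` pattern copies to call an
  array. The floor is 1.8–1.9 depending on pattern length; the genotyping
  side uses the conservative 1.9 by default, while the loss-observability
  summary (`detectable_fractions`) uses 1.8, so a one-copy loss needs at
  least 2.8 reference copies. Both constants are parameters.

`detectable_cgl_range` combines the two into an integer CGL interval per
locus and read length; it drives platform comparisons (alleles only seen by
longer reads are excluded before computing agreement) and the scoring of
end-to-end recovery.

## Genotyping from reads

For each read (both orientations), each singleton locus' array-adjacent
10 bp flank seeds are located; the sequence between them is aligned to the
pattern with wraparound DP. The read is assigned by pattern identity (up to
cyclic rotation and reverse complement) plus flank identity over 10–50
array-adjacent bases at a 90% threshold; ties between two loci, or any hit
on an indistinguishable family, discard the read. Per-read copy numbers are
rounded to the nearest integer, and every integer value supported by at
least two reads becomes an allele call.

Per-sample loci with more alleles than expected chromosome copies
(autosomes 2; X 2/1 and Y 0/1 for females/males) are removed as *multis*.
After filtering, a locus is a **VNTR** if any sample carries a
non-reference allele.

Cohorts are written as two VCF 4.2 files (all genotyped loci, and the
VNTR subset) with FORMAT fields `SP` and `CGL`; sample sex travels in
structured `##SAMPLE` header lines so a cohort roundtrips exactly. Reading
goes through pysam, so emitted files are library-validated.

## Cohort statistics

* **Common / private**: a VNTR locus is common when at least
  `ceil(0.05 n)` samples carry a non-reference allele and private when
  between 1 and `floor(0.01 n)` do. The ceil/floor pair is the only
  convention that gives 126 and 25 at n = 2504.
* **Heterozygosity**: per sample, the share of its VNTR loci (loci where it
  carries a non-reference allele) with two distinct called alleles. The
  denominator is configurable to all genotyped loci; the VNTR-restricted
  default reflects that allele discovery, not true homozygosity, limits the
  measurable quantity.
* **Gain/loss spectrum**: every non-reference allele occurrence (per sample
  per locus) binned by CGL, with the loss/gain fold ratio at one decimal.
* **Tumor/normal**: heterozygosity in each tissue, somatic alleles (in the
  tumor, absent in the normal at loci genotyped in both), loss of
  heterozygosity (het in normal, single-allele in tumor) and loci dropped
  entirely in the tumor.
* **Annotation overlap**: interval-tree flags for any ≥1 bp overlap on
  0-based half-open coordinates. Enrichment statistics over those flags are
  out of scope.

## Validation procedures

* **Mendelian**: an autosomal locus is consistent when the child's allele
  pair splits as one allele present in the mother and one in the father; a
  son's X allele must appear in the mother, his Y allele in the father.
  Loci without genotypes in all required members are unevaluated. Four
  tiers restrict evaluation (all; both parents het; trio het; trio het with
  three distinct genotypes). A child single-allele call is scored leniently
  (explainable by either parent) — exactly the ambiguity the stricter tiers
  exist to remove.
* **Cross-platform**: over loci genotyped by both platforms and VNTR in at
  least one, the Jaccard ratio of non-reference alleles, after removing
  alleles undetectable at the shorter read length.
* **Long reads**: a predicted allele is confirmed when at least one long
  read measures a copy number within ±0.25 of `ref_copies + CGL`. Reads
  arrive pre-assigned per locus; `longread_copy_estimates` localizes the
  array between the locus flanks before counting, because alignment over
  the raw read can over-count wherever flanking bases happen to continue
  the pattern.

## Population-specific alleles and ancestry

Samples become binary vectors over (locus, CGL) alleles of the common loci
("presence" = carrier, not dosage); columns in under 5% of samples are
dropped. PCA mean-centres but does not scale (the data are binary).
Ancestry is predicted by a decision tree on the top 10 PCs with a
stratified 70/30 split and 10-fold CV selecting `max_depth` from
{None, 8, 5, 3}; candidates are ordered deepest-first because on tied CV
scores the unbounded tree refits more stably on the full training
partition than a truncated one.

Markers are found per (allele, super-population) with a one-sided Fisher
exact test (over-representation; the hypergeometric upper tail), BH FDR
across all tests, and a log2 odds-ratio floor of 1. Zero cells get the
Haldane–Anscombe 0.5 correction for the reported log2 OR only; the p-value
stays exact. The virtual-gel table renders each observed allele as its
fragment length, `pattern × (ref_copies + CGL)` bp.

## Expression association

Genes pair with VNTR loci when their interval hulls lie within 10 kb
(TSS-anchored distance is available as an alternative; hull distance is
the default since pairing is stated over genes, not promoters). Genotype
classes are the sorted CGL multiset per sample (`0/+1`); samples without a
call form one pooled `other` class. A locus is kept only with ≥2 classes
(≥3 when `other` is present), each of ≥20 individuals; genes with median
TPM of 0 are dropped. Expression is log2(TPM+1) — the pseudocount is a
package choice.

Hidden structure is estimated by iterative surrogate extraction: repeatedly
residualize on the known design plus accepted factors, take the leading
principal component of the residual, and accept it unless its absolute
correlation with an existing covariate or factor exceeds 0.85, stopping at
the first rejection or at 15 factors. This is a deliberately simple
surrogate-variable scheme, not a reimplementation of published iterative
SVA; it recovers planted batch factors (individually when one is planted,
as a subspace when several are). Two caveats are documented by tests: on
pure noise the correlation rule essentially never fires (successive
residual PCs are orthogonal to the design by construction), so the
estimator runs to its cap and returns uninformative factors each
explaining ≈1/min(genes, samples) of variance — harmless for
residualization; and on very small gene panels a single strong genotype
effect can dominate a residual PC and be absorbed, so the scan should be
run on realistic panel sizes (hundreds of genes or more).

Each retained pair gets a one-way fixed-effects ANOVA of residuals across
genotype classes, BH adjustment across all tested pairs, and (for
reporting) the maximum pairwise difference of class residual means.

## Synthetic data: what it emulates and what it does not

The generator produces every input the pipeline consumes, deterministically
from (config, seed):

* **Reference**: non-overlapping loci with primitive random patterns,
  50 bp recorded flanks, placed on an autosome plus X (5%) and Y (2%)
  contigs; 16% of loci are laid down as indistinguishable pairs (shared
  pattern, one mismatch per flank), mirroring the composition of a curated
  human minisatellite reference set.
* **Allele model**: per haplotype, the reference allele has weight 0.8 and
  non-reference CGLs follow a truncated geometric in |CGL| with losses
  favoured 1.8:1 over gains — the loss/gain ratio observed in large human
  cohorts. The real allele-frequency distribution of human VNTRs is
  unknown; this stand-in is fully configurable. Haplotypes are sampled
  independently per locus (no linkage). Marker alleles override the
  frequency of one allele per population (`f_in` / `f_out`).
* **Trios**: one allele from each parent per autosomal locus; a per-locus
  mutation probability perturbs one inherited allele by ±1 copy. Sexes
  alternate within populations for deterministic covariate balance.
* **Reads**: uniform positions and strands over the sample's chromosome
  copies, substitution errors only (no indels, no quality model, no PCR or
  GC bias). Coverage is **per haplotype**: read count =
  coverage × total haplotype length / read length, which is the
  Lander–Waterman expectation under that definition.
* **Expression**: per-gene log2 baseline N(5,1) plus sparse sex and
  population effects, hidden-factor loadings, planted per-genotype-class
  shifts and N(0, 0.5) noise; TPM is the exponentiated value. Effect genes
  are placed adjacent to their driving locus; filler genes live on a
  separate contig.

Consequently, passing tests demonstrate the correctness of the algorithms
and the statistical machinery under a clean generative model — they do not
demonstrate robustness to indel sequencing errors, mapping ambiguity beyond
the planted indistinguishable families, linkage, population admixture, or
real expression normalization artefacts.

## Problem sizes and numerical choices

The bundled analyses run at desk scale by design: tens to a few hundred
loci, cohorts of up to a thousand samples for the ancestry replication, and
a ~1000-pair expression scan; these sizes give stable statistics while
keeping any single test in seconds. Degenerate inputs are defined rather
than rejected wherever a convention exists: empty alignments return score
0 with zero copies; a constant allele matrix embeds to all-zero scores with
zero explained variance; a zero-gain spectrum reports an undefined ratio;
an empty allele union makes platform consistency undefined rather than 1.
Floating-point boundaries in the detectability rules carry a 1e-9 epsilon
so printed one-decimal copy numbers compare as intended.
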