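# Methods

## Study design the package models

A recessive Mendelian disorder segregating in a closed, inbred population:
affected individuals inherit both copies of the causal allele from a common
ancestor, so they are homozygous not only at the causal site but across a
surrounding chromosomal segment (autozygosity). Mapping proceeds by finding
runs of homozygosity (ROH) shared by affected relatives, then filtering the
sequenced cohort's variants down to case-specific, exonic, in-region,
protein-changing candidates, and finally validating the survivor by pedigree
segregation, population carrier screening and allelic association.

## ROH detection

Per sample and chromosome, every contiguous window of `window_snps` markers
is scored homozygous when it contains at most `max_het_per_window`
heterozygous and `max_missing_per_window` missing calls. A marker is
*eligible* when at least `window_hit_threshold` of the windows covering it
are homozygous; maximal runs of eligible markers are split at inter-marker
gaps above `max_gap_kb` and reported when they satisfy `min_segment_snps`,
`min_segment_kb` and one SNP per `min_density_kb_per_snp`. Segment bounds
are the outermost eligible marker positions — marker-anchored and
reproducible, at the cost of marker-scale slop relative to the true IBD
breakpoints (at default marker density roughly 3–20 kb per edge).

Defaults (window 50 SNPs, ≤1 het, ≤5 missing, threshold 0.05, ≥100 SNPs,
≥1000 kb, 50 kb/SNP density, 1000 kb gap) follow the widely used v1.07
defaults of the standard ROH search tool; all are overridable.

QC order matters and is logged: samples failing the call-rate bound are
dropped first, then markers are filtered on call rate and on MAF computed
from the retained samples. All three thresholds are strict lower bounds.

Shared regions intersect the per-case ROH interval sets and additionally
require *allele sharing*: at every marker where no case is missing, all
cases must be homozygous for the same allele. Mismatching markers split a
region (configurable `max_allele_mismatches`, default 0). With one case the
segments pass through verbatim.

## Filtering funnel

Four stages in fixed order, each recorded as a (label, count) pair:
case-specific recessive (every case homozygous-alternate; panel
homozygotes ≤ `max_panel_hom_alt` = 0 and panel heterozygotes ≤
`max_panel_het` = 0 by default — the strict reading of "case-specific"; a
relaxed carrier-tolerant mode is available because a recessive model does
not forbid panel carriers), exonic overlap (any annotated exon, 1-based
inclusive), shared-region membership, and protein-changing effect class
(missense, nonsense, frameshift — the classes a mapping study treats as
candidate-worthy). Variants with a missing case genotype are excluded by
default (conservative for degraded, e.g. FFPE, samples); a
`case_missing_as_hom_alt` flag relaxes this. Stages 2–4 commute; the
ledger's counts are non-increasing by construction.

## Consequence annotation

Genomic positions are projected onto the spliced CDS strand-aware (minus
strand: offsets count from the genomic CDS end and alleles are
complemented). SNVs are classified by translating the reference and mutated
codon (standard nuclear code); indels by frame effect, with indels that
extend outside the spliced CDS classified `non_coding` and excluded from
the protein-changing set — splice-effect scoring is out of scope. Notation
uses the simplified single-letter dialect of mapping-study tables
(`p.R11*`, `p.A78fs`, synonymous `p.X11=`) rather than full HGVS
(`p.(Arg11Ter)`); multi-allelic records are assumed decomposed and indels
left-normalised before annotation. One consequence per (variant,
transcript); across transcripts the most severe class wins
(nonsense > frameshift > missense > inframe > synonymous > non-coding).
Truncation statistics for a nonsense at codon *k* of an *n*-residue product
report *k* − 1 retained residues and (*k* − 1)/*n*.

## Segregation, carrier screen, association

Expected genotype sets under the recessive model: affected → {hom-alt};
obligate carrier (parent/grandparent of an affected) → {het}; other
unaffected → {het, hom-ref}. Sheet samples missing from the genotypes are
listed as inconsistencies, never dropped. Carrier frequency is the
heterozygote fraction of the screened population, rounded half-up to one
decimal percent; homozygous-alternate individuals are reported separately
as genetically affected. The association test is the Pearson chi-square on
the 2×2 allele-count table (hom-alt contributes 2 alternate alleles, het
1/1), df = 1, no continuity correction — chosen because it is the standard
allelic test for this design; Fisher's exact is available as an
alternative. Unaffected relatives are pooled with population controls by
default (flag to exclude). The tail probability is computed as
erfc(√(χ²/2)), exact to ~1e-308, with an asymptotic log-erfc expansion
supplying log₁₀(p) beyond double underflow; p-values are never formed by
1 − CDF subtraction.

## Synthetic cohort generator

The generator's defaults are the package's study conditions. Cohort counts
are at study scale — 7 cases, parent + grandparent (obligate carriers) + 3
healthy siblings, 176 population controls of whom exactly 3 carriers, 136
panel genomes — while the genome is shrunk to 3 contigs × 10 Mb with 3,000
array SNPs per contig (~3.3 kb spacing), since cohort statistics must match
the modeled design but genome size need not. Array allele frequencies are
Uniform(0.05, 0.5) with Hardy–Weinberg genotypes, matching the MAF > 0.05
QC regime; background variant density is 2 × 10⁻⁴ per bp (a deliberate
reduction of whole-genome SNV density to keep desk-scale runs fast);
genotyping error 10⁻³ and missingness 10⁻², typical array performance.

The planted 2 Mb interval is homozygous for one shared haplotype in all
cases *and* in the parent and grandparent; only the cases are homozygous
for the causal allele, the carriers are heterozygous — the configuration
that makes the causal site, not the haplotype, the discriminating signal.
One of the three healthy siblings is a carrier. Genes hosting the causal
variant and the in-region decoys are placed a quarter of the way into the
interval, interior to the marker-scale edge slop of window-based detection.
The designated transcript is plus-strand, two-exon (30 bp + remainder,
mirroring a variant in its second exon), 1121 codons with codon 11 fixed to
CGA so that C>T at spliced CDS position 31 creates a TGA stop; at least one
other gene is minus-strand so strand-aware code paths are exercised.

Five decoys are planted, one per funnel failure mode: case-specific but
non-exonic; exonic but outside the interval; exonic in-interval but
heterozygous in one case; exonic in-interval but synonymous; exonic
in-interval but homozygous in two panel genomes. Decoy genotype
proportions beyond these constructions are free parameters of the design
(nothing pins them), and the classes are deliberately minimal — one each —
on top of Poisson background variants whose in-interval genotypes are
forced homozygous-reference in the haplotype carriers (the shared
haplotype carries reference alleles). Decoys count as background content:
a zero background rate yields a cohort containing only the causal variant.

All randomness derives from one master seed through fixed per-component
stream offsets (reference 11, array 13, cohort 17), so identical
configurations give byte-identical outputs and the array can be re-noised
without changing the reference.

What the generator does **not** emulate: linkage disequilibrium and
recombination structure beyond the planted IBD block, mutation-rate and
site-spectrum realism, read-level artifacts (no FASTQ/BAM), relatedness
among controls, and genotype-calling error correlation. Passing tests
therefore demonstrate correctness of the algorithms under the stated
generative model, not robustness to every failure mode of real array or
sequencing data.

## Numerical and interface choices

- Genotypes are int8 codes (0 hom-ref, 1 het, 2 hom-alt, −1 missing)
  shared across all modules.
- Coordinates: GFF3/VCF/PED-MAP and all in-memory intervals are 1-based
  inclusive; BED output is 0-based half-open.
- PLINK text PED/MAP does not record allele polarity; the reader assigns
  major/minor by frequency (alphabetical tie-break) unless explicit allele
  hints are passed.
- Degenerate inputs raise typed errors rather than returning empty
  results: QC removing everything, chi-square with a zero margin,
  truncation statistics on a non-nonsense consequence, unknown sample ids.
- Problem sizes in the test suite: property checks run on reduced
  fixtures (2 × 600 kb genome, 3 cases) with detector parameters scaled to
  the 200 kb planted interval; recovery and recall checks run 20 full-scale
  fixtures, the classifier/oracle comparison 1,000 random transcript–variant
  pairs, chosen as the sizes at which the checked distributions stabilise.

## Known limitations

- The ROH detector reports marker-anchored boundaries; true IBD breakpoints
  between markers are not interpolated.
- Allele sharing with the default zero-mismatch allowance fragments shared
  regions at genotyping errors; raise `max_allele_mismatches` for noisy
  arrays.
- The annotator handles SNVs, simple insertions and deletions; complex
  substitutions, duplication notation and splice-site effects are out of
  scope.
- Consensus ROH across discordant phenotype groups, LD pruning and
  ROH-based inbreeding coefficients are not implemented.
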