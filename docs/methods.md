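# Methods

This note documents the models and procedures implemented in `svfw`, the
parameters that matter, what the synthetic-data generator does and does not
emulate, and the numerical choices made where the design was genuinely open.

## Study design emulated

The package models an integrated DNA + RNA SV study of matched tumor/blood
pairs: six patients, whole-genome paired-end sequencing of both tissues,
tumor RNA sequencing, and an expression microarray with eight unrelated
normal controls. All inputs are simulated; every stage is scored against the
generator's planted truth rather than against external data.

## Synthetic data generator

**Reference.** Two chromosomes (760 kb and 740 kb) of uniform random sequence
plus a 60 kb excluded-name chromosome (a toy chrY) that exercises the
exclusion filter. Each main chromosome carries telomeric tracts (2 kb per
end, recorded in the centromere/telomere mask) with an N-filled assembly gap
inside each, and interior low-complexity tracts: fixed 500-bp repetitive
dinucleotide runs, with tract count ~ Poisson(density · length / 500) at
density 0.02. Because calls within 100 kb of a gap or centromere/telomere
tract are filtered, the generator plants everything in the interior
[102 kb, length − 102 kb); the masked structure near the ends is there for
the filter to act on, and the repetitive tracts produce genuinely ambiguous
(MAPQ 0) alignments for the mapper.

**Annotation.** 80 non-overlapping single-transcript genes (80 % coding,
20 % on the minus strand). Coding genes have 4–6 exons (terminal exons
320–480 bp, internal 170–360 bp, introns 650–1200 bp), a 5'UTR of 140–240 nt,
a 3'UTR of ~140–260 nt, and a CDS whose length is forced to a multiple of 3.
Six gene-desert intervals (22 kb each, three per chromosome) are kept
gene-free with 5 kb clearance. The toy CDS is random sequence — it has no
start/stop codons — so "reading frame" means codon-grid preservation, which
is what the frame tests check via translation.

**Planted SVs.** A roster of 55 SVs covers all seven structural classes and
every taxonomy subclass: promoter, alternative 5'/3' UTR, coding fusions
(in- and out-of-frame), 5'-truncated (onto a noncoding gene and onto
unannotated sequence), uncharacterized-orientation fusions (a deletion onto a
minus-strand partner, so both genes read into the junction), intronic and
all exonic intragenic subclasses, gene-desert SVs of every class, and two
blood-only SVs. Donor chromosomes are represented as lists of reference
segments, so edits compose cleanly and truth breakpoints are exact by
construction; reciprocal translocations are kept coordinate-monotone so
successive tail swaps remain well defined. Placement rejects:

* junctions with micro-homology (either flank able to extend across the
  junction), so validated breakpoints can be compared to truth base-exactly —
  left-alignment inside homology tracts is still implemented and tested with
  hand-built fixtures;
* breakpoints whose gene association would be ambiguous under the
  classifier's rules (gene bodies outrank promoter windows);
* breakpoints within 200 bp of any mask or closer than ~1 kb to another SV
  (clusters of distinct SVs must not merge).

Event sizes are chosen so each class sits above the insert-size detection
limit at the study's depth: deletions ≥ 150 bp (fusion deletions span
3–28 kb between partner genes), inversions ≥ 600 bp, tandem duplications
500–700 bp (large enough that all spanning pairs are everted), inverted
duplications 700–850 bp (larger than the maximal insert, so the two
same-strand clusters are unambiguous), insertions 106–125 bp and transposed
segments 110–140 bp (see *Detectability arithmetic*). Germline SVs are
carried by 1–6 patients (45 % single-carrier, ~55 % multi-sample); somatic
SVs by one tumor (6 % by two). Germline insertions get at least two carriers:
insertion support per sample sits near the call threshold, and a germline
variant segregating in several individuals is identifiable from any of its
carriers.

**Reads.** Fragments are uniform per chromosome; insert length is normal
(μ = 350, σ = 35) truncated at 2L; mate 1 is the forward fragment start,
mate 2 the reverse complement of its end; 75 bp reads at 30× per tissue,
error-free by default (a uniform substitution rate is available). RNA reads
come from the spliced transcriptome (background depth 6×) plus, for each
planted SV marked transcribed in a carrier tumor, its spliced fusion
transcript at ~45× junction depth (insert 200 ± 20). Fusion placements keep
at least 120 transcribed nt on each side of the junction so spanning pairs
(a whole read per partner) can exist. The expression matrix gives every gene
a shared lognormal baseline, scales affected genes by the planted
fold-change in carrier tumors only, and applies multiplicative lognormal
noise (σ = 0 by default, which reproduces planted ratios exactly).

**What the generator does not emulate.** Sequencing errors and quality
scores (beyond optional uniform substitution), diploid phasing, overlapping
or nested SVs, repeat-mediated SV formation (junctions are deliberately
homology-free), alternative splicing, isoform-level expression, and fusion
transcripts whose 3' side is unannotated sequence (the transcriptome-based
RNA detector cannot assign such a partner, so those SVs are planted
untranscribed). Passing tests therefore demonstrate correctness of the
pipeline's logic under clean, well-separated events — not robustness to
noisy alignments, complex rearrangements, or repeat-rich junctions.

## Calling

The mapper is exact and seed-based (31-mer seeds): MAPQ 60 for a unique
exact placement, 0 for ties. A fallback placement with mismatches is
penalized 30 per mismatch, which keeps any inexact placement below the
MAPQ 35 evidence cutoff: junction-crossing reads whose few overhanging bases
happen to match the reference must not nudge cluster boundaries. Reads with
no placement go to the unmapped store that feeds targeted assembly.

Discordant pairs (both mates MAPQ ≥ 35) are clustered per signature with a
μ + 3σ window. Two robustness steps protect clusters from the far insert
tail of perfectly normal pairs (≈1 % of pairs at k = 2.5): members whose
observed insert is > 4.5σ from the cluster median are split off, and the
retained members must be jointly consistent with a single junction pair
(each mate bounds its junction coordinate to an interval; on one chromosome
the left junction cannot lie right of the right one). Junction regions are
reported with a μ + 5σ bound so they always contain the true breakpoint.

Cluster geometry is then refined into call types:

* reciprocal interchromosomal cluster pairs merge into one translocation;
* (+,+)/(−,−) same-strand cluster pairs with matching regions merge into one
  inversion; a self-co-located same-strand cluster paired with an
  opposite-orientation spanning cluster marks an inserted reverse-complement
  copy (inverted duplication) — under a forward–reverse library an inverted
  copy produces exactly this geometry and no everted pairs;
* an excision (deletion-signature) cluster joined by distant-mate "link"
  clusters to a common re-insertion point is a transposition; a co-located
  insertion-signature cluster at that point is absorbed. Links are consumed
  so they cannot surface as spurious deletions;
* everted clusters are tandem duplications (< 100 bp implies the
  small-duplication artifact class; overlapping duplications sharing exactly
  one margin are co-amplicons); a short-insert cluster co-located with an
  everted cluster is absorbed into the duplication;
* co-located contradictory insert-size clusters of comparable support
  (within 1:3) are emitted as `undefined`;
* remaining large/short-insert clusters are deletions/insertions.

Support threshold: max(3, round(physical coverage ∕ 8)) = 9 at the default
30×, configurable per sample.

### Detectability arithmetic

A novel insertion of size s is visible only through pairs whose insert lies
in [s + 2L, s + μ − kσ] (both mates must clear the novel sequence, and the
observed insert must fall below the short-insert cutoff). The expected
support is (coverage∕2L) · ∫ over that window of P(insert > x) dx. At 30×,
L = 75, μ = 350, σ = 35 this peaks at ≈8.6 — *below* the support threshold
of 9 — for every insertion size when k = 3. The discordance window is an
undocumented parameter of the original tooling, so this package defaults to
k = 2.5, which keeps the window conservative while giving insertions an
expected support of ~11; insertion sizes of 106–125 bp sit at that optimum.
The same arithmetic fixes transposed-segment sizes.

## Filtering

Rules fire in a fixed order, each call counted once against the first rule
that removes it: artifact classes (small_duplication, co_amplicon,
undefined); > 50 % of the call footprint (both regions plus the spanned
interval for intra-chromosomal calls) in low-complexity sequence; either
region within 100 kb of a centromere/telomere tract or assembly gap; either
region on an excluded-name chromosome. Removal counts plus the retained set
always equal the input, and filtering is idempotent.

## Assembly validation

Per filtered call, the read pool is every pair with ≥1 mate mapped within
500 bp of either region — which drags in the unmapped junction-crossing
mates — capped at the 800 pairs nearest the regions; the global unmapped
pool can be added by flag (off by default: in a paired library every
junction read has a locally mapped mate). The de Bruijn sweep runs k from
⌈L∕2⌉ to L in 2-bp steps; k-mers below coverage 2 are pruned; unbranched
paths ≥ L become contigs, augmented by a second read-off pass (greedy
coverage-ranked extension with a reversed base-order tie-break); contigs
that are substrings (or reverse-complement substrings) of longer ones are
redundant and removed, merging their k-value provenance.

Split-mapping chains maximal exact matches (≥ 20 bp, 20-mer seeds, either
strand) greedily over the contig. Adjacent fragment pairs imply junction
hypotheses: same-strand forward jumps are deletions, backward jumps tandem
duplications, ≥20 bp of unexplained contig between co-located flanks is an
insertion (in either contig orientation), opposite strands are
inversion-type junctions, different chromosomes translocations; a
transposition call accepts its excision-junction (deletion-pattern) contig.
A call is confirmed when a hypothesis of the matching type falls inside the
call regions (± μ + 3σ slack) and the same junction is reproduced with the
opposite seed-scan order; micro-homology (fragment overlap on the contig,
≤ 10 bp) left-aligns the breakpoint and is reported.

## Classification

Identity for deduplication is SV type + chromosome pair + both breakpoints
within 10 bp (transitive closure; canonical coordinates are the smallest in
the group). Junction orientation is deliberately not part of the identity:
an inversion's two junction contigs imply the same breakpoint pair with
different orientations, and carrier samples may surface either one first.
Origin: germline when seen in ≥1 tumor and ≥1 blood anywhere in the cohort,
somatic when tumor-only, blood_only otherwise (excluded from the cancer set
but retained in output).

Fusion-partner assignment works per junction configuration (one or two per
SV type; a reciprocal translocation has two): the 5' partner's transcription
must read into the junction on the donor-upstream side and the 3' partner's
away from it downstream. The intergenic subclass follows the 5' partner
breakpoint's genic region (promoter window = 5 kb upstream of the TSS;
intronic breakpoints are evaluated at the retained exon boundary) with
precedence promoter > alt 5'UTR > coding fusion > alt 3'UTR; a coding 5'
partner joined to a noncoding gene or unannotated sequence is 5'-truncated;
an SV whose configurations all fail the canonical layout is an
uncharacterized RNA. Frame: c5 = coding bases retained upstream of the
junction in the 5' partner, c3 = coding bases discarded upstream in the 3'
partner; in frame iff c5 ≡ c3 (mod 3). Junctions upstream of the 3' CDS
retain the whole ORF (c3 = 0); junctions past its stop are out of frame.
Region arithmetic uses the canonical transcript per gene (longest CDS, then
longest transcript, then lexicographic id). Intragenic SVs are intronic when
both breakpoints are non-exonic — "within the same intron" is relaxed to
"within introns", since the two ends of one SV can occupy different introns —
else exonic with precedence CDS > 5'UTR > 3'UTR > noncoding.

## RNA and expression integration

The fusion detector matches reads against the spliced transcriptome: a read
whose prefix (≥ 10 nt) lies in one gene and suffix (≥ 10 nt) in another is a
split read (the switch point is mapped back to a genomic boundary); pairs
whose mates lie wholly in the two partners with opposite senses are spanning
pairs. A call requires ≥1 of each, and single-locus junctions are discarded.
DNA breakpoints are exon-adjusted before matching (introns are spliced out),
and junction agreement is evaluated in transcript coordinates with a 10-nt
tolerance: chance homology across a splice can shift the genomic coordinate
by a whole intron while the transcript offset moves by a base or two.
Promoter-subclass SVs are excluded from RNA matching (a promoter swap does
not create a chimeric transcript body) and analyzed by expression instead.

A promoter or alternative-5'UTR SV affects its 3' partner (which gains the
new regulatory region); an alternative-3'UTR SV affects its 5' partner. Fold
change is the carrier tumor's value over the mean of the eight controls,
two-sided: > 2 or < 0.5 flags the SV differential if any carrier passes.

## Reporting

Four tables summarize a cohort (class × origin with percentages,
multiplicity histogram, intergenic subclass × {DNA, RNA-detected,
differential}, class × expression). A packaged fixture of published counts
(`svfw/data/paper_counts.tsv`, each entry with a source tag) drives
`percentage_of`, which rounds half away from zero using exact integer
arithmetic; the test suite reproduces thirty published percentage ratios
from their printed numerator/denominator pairs.

## Problem sizes and determinism

The default cohort is the package's study condition: 2 × ~750 kb
chromosomes, 80 genes, 55 planted SVs, six tumor/blood pairs at 30× DNA
coverage, tumor RNA, and an 8-control expression matrix. All randomness
flows from a single master seed through per-stage derived seeds; identical
configurations produce byte-identical outputs. Constraint placement can, for
rare placement seeds, fail to fit the full roster; the pipeline then advances
the placement seed deterministically until it fits.

## Known limitations

* The mapper, assembler, split-mapper and fusion detector are exact-match
  algorithms suited to the clean simulated reads; they are not replacements
  for production aligners/assemblers on real, error-containing data.
* Insertions larger than the insert size are invisible to the paired-end
  signatures by construction (their junction reads still reach the unmapped
  store, but no candidate call is generated to validate).
* Complex/nested events, somatic subclonality, and copy-number context are
  out of scope; every planted SV is heterozygosity-free (haploid donor
  model) and isolated.
* Gene-desert SVs are classified but carry no functional annotation, and no
  statistical enrichment test is run on class frequencies — only the raw
  counts are reported.
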