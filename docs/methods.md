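# Methods

## Coordinate model and edit algebra

All internal coordinates are 0-based, half-open, on the forward strand;
GenBank/GFF3 I/O converts from the 1-based inclusive file convention. A
design is an `EditPlan`: an ordered list of non-overlapping substitutions,
deletions and insertions in wild-type coordinates. Plans are applied in one
left-to-right pass, so wild-type coordinates never shift mid-application,
and each application builds a `Liftover` — a piecewise monotone map between
wild-type and designed frames in which deleted wild-type positions and
inserted designed positions map to nothing. Features are re-coordinated
through the liftover; a feature whose every base is deleted is dropped and
logged rather than truncated. Plan inversion (substitutions restore the
stored original, deletions become insertions and vice versa, with adjacent
deletion-inversions merged into one insertion) recovers the wild-type
sequence bit-exactly; this is enforced as a property test and as an
acceptance check over 100 random fixtures.

## The refactoring rules

**loxPsym allocation.** One insertion of the 34-bp symmetric loxPsym motif
(`ATAACTTCGTATAATGTACATTATACGAAGTTAT`; the policy validates that any
configured motif equals its own reverse complement) is placed
`loxpsym_offset_bp` = 3 bp downstream of the stop codon, in the gene's own
orientation, of every non-essential ORF. Both policy versions additionally
refuse an insertion whose point falls inside another real (verified or
uncharacterized) gene's CDS: sites belong between genes, and an insertion
inside a host CDS would contradict the protein-conservation invariant the
design itself enforces. Under v2, all dubious ORFs lose their sites (the
configuration that caused mapped growth defects is a dubious ORF whose site
lands in the 5′ UTR of an overlapping real gene), and no insertion point may
fall within `utr_exclusion_bp` = 250 bp upstream of a verified start codon
on either strand, measured to the motif edge nearest the start codon.
Because the motif has zero width in wild-type coordinates, that edge
distance equals the distance from the insertion point to the start-codon
boundary. Two eligible insertions colliding at the same point are merged
into a single motif. Convergent gene pairs may legitimately carry two sites
in one intergene; merging happens only on exact coordinate collision.

**Stop-codon swaps.** Every ORF whose (spliced) CDS ends in TAG receives a
single strand-aware substitution at the third stop position (G→A on the
coding strand). Under v2, dubious ORFs whose stop codon lies inside a
verified gene's CDS are skipped, because the swap would be an uncontrolled
edit of the host's coding sequence. On fixtures carrying such nested
dubious ORFs, the v1 design can therefore show protein-integrity violations
in its own audit — deliberately so: the audit is the instrument that makes
that class of defect visible.

**Tandem-repeat smashing.** Exact tandem repeats inside CDS are detected by
a primitive-period scan: a run qualifies when its smallest period is at
least `min_tandem_repeat` = (3, 3) unit length and copies. Requiring the
*primitive* period excludes homopolymers and dinucleotide wobble, which are
not what repeat-driven synthesis failures are about. Recoding is confined
to codons whose synonymous replacement changes only bases inside the
detected span, applied in every second repeat unit with the
maximal-difference codon choice (below). The historical failure mode this
regresses against is a repeat-smasher that recoded an entire CDS instead of
the repeat; the tests assert zero edited positions outside the detected
span and an unchanged protein.

**Restriction-site removal.** Every occurrence of a policy enzyme motif
(either strand; the defaults GGTACC and GAATTC are palindromic) overlapping
a verified/uncharacterized CDS is destroyed by the fewest synonymous
substitutions: candidate (codon, alternative) pairs are ranked by number of
changed bases, then codon usage, then alphabetically, and the first
candidate whose application leaves the local window free of every policy
motif wins. Sites spanning a CDS boundary fall back to one intergenic
transition when the codon route fails (the stop codon is never touched).
Purely intergenic occurrences are left alone by default — the segmenter may
exploit them — unless `remove_intergenic_enzyme_sites` is set.

**Synonymous codon choice.** Where a maximal change is wanted (PCR tags,
repeat smashing) the replacement is the synonymous codon maximizing Hamming
distance to the original, ties broken by higher *S. cerevisiae* usage, then
alphabetically; where a minimal change is wanted (site removal) the ranking
is fewest changed bases first, then usage, then alphabetical. Both are
deterministic, so a design is a pure function of (annotation, policy).

**Element deletion.** tRNA gene bodies, introns (the spliced frame is
checked first; removal cannot change the protein because the designed CDS
*is* the spliced CDS), and LTR/Ty/subtelomeric repeats are deleted. The
removed tRNAs are also emitted as a flanked FASTA mirroring the
tRNA-array complementation construct used to restore fitness in strains
that miss low-redundancy tRNAs.

## PCR tags

A tag is a codon-aligned window of 33 bp (11 codons, inside the configured
28–33 bp band) recoded with the maximal-difference rule. Candidates are
tiled left to right along each verified/uncharacterized CDS and accepted
when they (a) avoid every previously planned edit and every other gene's
exons, (b) lie inside one exon and one chunk, (c) reach
`min_tag_mismatches` = 8 (discriminative allele-specific qPCR; configurable),
(d) admit primers in the Tm band, and (e) have synthetic primers with zero
exact matches in the wild-type chromosome (cross-amplification screen, both
strands). Windows of one gene never overlap — the regression for the
overlapping-tag pair that once changed a serine to arginine. Primers are
the shortest window prefix/suffix (16–33 nt) whose nearest-neighbor Tm
falls in `tag_tm_band` = 58–62 °C under qPCR-like conditions (500 nM
primer, 50 mM Na⁺, 3 mM Mg²⁺, 0.8 mM dNTPs; Biopython `Tm_NN`).
`minimize_tags` then applies the per-(gene, chunk) quota — v2 keeps the
single highest-mismatch tag, leftmost on ties; v1 keeps everything. Tag
recoding is length-preserving, so chunk coordinates computed before tag
application remain valid; the pipeline re-extracts chunk terminus k-mers
from the final sequence.

## Segmentation

Cut points are chosen greedily left to right, aiming at the middle of the
6–10 kb chunk band, and locally shifted (first acceptable position scanning
outward, within ±`boundary_shift_bp` = 1500 bp) so that the 40-mers at the
prospective termini (at offsets 0, 40 and 450 bp behind the cut, covering
both overlap geometries) are unique in the designed sequence and outside
essential or blacklist-tagged CDS. Where no acceptable position exists the
nominal cut stands and `check_termini` reports the violation instead —
violations are data, not errors. Chunks within a megachunk share exactly
40 bp; the first chunk of each megachunk extends 450 bp into its
predecessor as the SwAP-In homology arm. Chunk counts are grouped into
megachunks of five (then four) per group; a leftover group outside 4–5 is
flagged. Naming is A1…A5, B1…, through Z then AA, BB; markers alternate
URA3/LEU2 from the first megachunk, and `marker_plan` reports the CDS (if
any) each terminal-chunk marker would disrupt. Terminus screening counts
exact k-mer occurrences (k = 40) on both strands; the shared 40-bp junction
of two adjacent chunks is one physical terminus and is checked once. An
extra occurrence inside a telomere feature is classed as telomere homology,
the failure mode of telomeric chunks with cross-chromosome subtelomeric
similarity. Uniqueness is exact matching, not alignment: deterministic and
sufficient for the misintegration hazard it screens; genuinely diverged
homology would need an aligner and is out of scope.

## The audit

Counts are derived twice: from the edit plan, and independently from
sequences — a non-overlapping motif scan for loxPsym (valid because the
wild type carries zero motifs, which is checked), and a per-ORF wild-vs-
designed stop-codon comparison for swaps. Disagreement between derivations
is itself a violation. The protein sweep translates every
verified/uncharacterized ORF in both frames (stop-class changes TAG/TAA are
not protein changes). Under v2 the audit also verifies that no loxPsym
motif intersects the designed-frame exclusion window upstream of any
verified start codon. `diff_designs` refuses two audits of different wild
types and raises if any refinement count (loxPsym sites, stop swaps, tag
windows) grows from v1 to v2.

## Segregant-frequency defect mapping

The simulator draws each haploid progeny chromosome from a fair random
parental phase with a homogeneous Poisson crossover process (no
interference) at `crossover_rate_per_bp` = 3.5 × 10⁻⁶ — about 3 crossovers
over a 900-kb chromosome, i.e. ~0.35 cM/kb, a realistic yeast value. A
strain is unfit with probability `penetrance` if any defect locus carries
the synthetic allele, else with `baseline_unfit_rate` = 0.05 (background
rho⁻-like failures). Markers are conceptually one PCR tag per megachunk.
`locus_frequency` computes exact count ratios per fitness class;
`call_defect_intervals` returns maximal marker runs with
f_syn_fit ≤ `low_thresh` and f_syn_unfit ≥ `high_thresh`. CRISPR-assisted
arm replacement is modeled as one forced crossover at the Cas9-cut marker,
not as a molecular simulation.

With **two** defect loci, the unfit class is diluted by strains carrying
only the other defect, which caps the expected f_syn_unfit at a defect
locus near 0.65 even at 0.9 penetrance. The default thresholds were
therefore chosen from a pilot run at the study conditions (30 strains, 16
markers, two fully linked defect loci, 200 replicate panels) and frozen at
`low_thresh` = 0.45 / `high_thresh` = 0.55: depletion/enrichment relative
to the Mendelian expectation of 0.5. A defect locus counts as recovered
when a called interval comes within one marker of it.

## The fixture generator

`make_mini_chromosome` lays out features left to right with ≥300 bp spacers
(so the 250-bp exclusion window can never reach a neighbouring gene by
accident), flanking telomeres, and an optional centromere. It engineers,
with valid gene structure on both strands: ORFs of all three curation
classes with chosen stop codons; essential and conditionally tagged genes;
intron-bearing ORFs; one CDS with an exact 9-bp × 5 tandem repeat; CDSs
with planted restriction sites; tRNAs and LTR repeats; and the two overlap
geometries that drove the v2 policy — a dubious ORF whose 3′ end extends
7 bp past an antisense verified start (its loxPsym point lands 10 bp into
the exclusion window) and a dubious ORF nested antisense inside a verified
CDS with its TAG stop in the host's coding sequence. Overlap-pair sequences
are solved by constrained resampling so both reading frames are stop-free.
After assembly the sequence is scrubbed: chance enzyme-motif occurrences
and chance coding tandem repeats outside the planted ones are mutated away
(inside CDS by swapping in a different non-stop codon — the fixture is
wild type, there is no protein to preserve). Ground truth is recorded as
exact expected rule firings for both policy versions, recounted from the
layout by straight-line logic independent of the rule engine. The generator
emulates gene *geometry*, not yeast sequence statistics: base composition
is i.i.d. at GC 0.38, there are no transcript isoforms, no real codon-usage
structure, and no homology beyond what is planted. Passing fixtures
therefore validates the rule logic and bookkeeping, not performance on real
chromosome annotation quirks.

## Problem sizes

The test suite and the acceptance script run fixtures of 17–90 kb with
10–30 genes: large enough that every rule, both overlap geometries, and
multi-megachunk segmentation are exercised, while a full v1 + v2 pipeline
pair completes in about a second. Segregant mapping uses 200 replicate
panels of 30 strains over 16 markers.

## Known limitations

* Dual-derivation of the loxPsym count requires a motif-free wild type;
  for a wild type already carrying motifs only the plan-derived count is
  meaningful.
* Restriction-site enumeration treats IUPAC-ambiguous recognition sequences
  as literal strings; degenerate motifs would need expansion.
* The 5′ UTR is operationalized as a fixed upstream window, since no
  transcript models are consumed.
* Marker cassette geometry is a single insertion coordinate; cassette
  length and promoter orientation are not modeled.
* Tag windows avoid other genes' exons entirely, which is more conservative
  than historical designs; genes fully covered by overlaps get no tags.
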