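# synchrom

A synthetic chromosome design toolkit for Sc2.0-style genome refactoring in
*Saccharomyces cerevisiae*, written for synthetic-genomics groups planning
(or re-planning) chromosome-scale builds.

Starting from an annotated wild-type chromosome (GenBank, or GFF3 + FASTA,
plus an ORF classification table), the toolkit plans and applies the full
refactoring rule set, partitions the result for assembly, audits the design,
and simulates the genetic mapping used to localize design defects:

* **loxPsym allocation** — the 34-bp symmetric Cre site
  `ATAACTTCGTATAATGTACATTATACGAAGTTAT` inserted 3 bp downstream of the stop
  codon of every eligible non-essential ORF (the substrate for SCRaMbLE);
* **stop-codon recoding** — every TAG stop swapped to TAA by a single
  third-position substitution;
* **PCR-tag design** — codon-aligned windows (28–33 bp) synonymously recoded
  to maximize mismatches, with allele-specific primers (nearest-neighbor
  Tm), cross-amplification screening, a no-overlap rule per gene, and a
  per-gene-per-chunk quota;
* **synonymous clean-up** — exact tandem repeats inside CDS broken by
  recoding confined to the repeat span; restriction sites inside CDS
  destroyed by minimal synonymous substitutions;
* **element deletion** — tRNA genes (with a tRNA-array FASTA for
  complementation constructs), introns, and LTR/Ty/subtelomeric repeats;
* **segmentation** — 6–10 kb chunks with 40 bp overlaps, grouped into
  megachunks of 4–5 chunks with 450 bp homology arms and alternating
  URA3/LEU2 markers (SwAP-In planning), with terminus screening for
  non-unique 40-mers and for conditionally essential genes;
* **audit** — every headline count derived twice (edit plan vs. sequence
  scan), a global protein-integrity sweep, and a v1-vs-v2 comparison;
* **segregant mapping** (`synchrom.segmap`) — simulation of synthetic ×
  wild-type backcross panels (Poisson crossovers, penetrant defect loci) and
  per-locus synthetic-allele frequencies by fitness class,
  f<sub>SYN</sub><sup>fit</sup> vs f<sub>SYN</sub><sup>unfit</sup>, with
  interval calling for defect localization.

Two policy versions are built in. **v1** reproduces the original design
conventions; **v2** encodes the debugging lessons from real builds: loxPsym
sites are withheld from dubious ORFs and from a 250-bp exclusion window
upstream of verified start codons (dubious ORFs overlapping the 5′ region of
real genes were a systematic cause of growth defects), TAG→TAA swaps are
reverted for dubious ORFs whose stop lies inside another gene's CDS, and PCR
tags are minimized to one per gene per chunk. Every numeric rule constant
lives in one place, `DesignPolicy`.

Because every stage is testable without external data, the package includes
a deterministic fixture generator (`synchrom.fixtures`) that builds
mini-chromosomes with known ground truth — including dubious ORFs
antisense-overlapping verified genes, nested dubious ORFs with TAG stops
inside a host CDS, tandem-repeat-bearing CDSs, and planted restriction
sites — and records exactly how many times each rule must fire.

## Worked example

```python
from synchrom import DesignPolicy, design_chromosome, diff_designs
from synchrom.fixtures import FixtureSpec, make_mini_chromosome

ann, gt = make_mini_chromosome(FixtureSpec(seed=1))   # 60 kb, 25 ORFs
r1 = design_chromosome(ann, DesignPolicy.v1())
r2 = design_chromosome(ann, DesignPolicy.v2())
print(r2.report.summary())
print(diff_designs(r1.report, r2.report).to_string(index=False))
```

prints

```
Audit of miniXVI (wild type 60000 bp)
  loxpsym_sites          17
  stop_swaps             4
  tag_windows            21
  tag_recoded_bp         693
  rs_sites_recoded       2
  rs_recoded_bp          12
  repeat_smash_orfs      1
  trna_genes_removed     3
  trna_bp_removed        225
  introns_removed        2
  repeat_bp_deleted      640
  insertions_bp          578
  deletions_bp           1033
  final_length           59545
  no violations

             count    v1    v2  delta
     loxpsym_sites    22    17     -5
        stop_swaps     5     4     -1
       tag_windows   341    21   -320
```

The v2 design drops five loxPsym sites (the three free-standing dubious
ORFs plus the two dubious ORFs engineered to overlap verified genes), keeps
the TAG stop of the one dubious ORF nested inside a verified CDS, and trims
341 candidate PCR tags to the one-per-gene-per-chunk quota. `final_length`
always equals wild-type length + insertions − deletions, and the audit
re-derives every count from the designed sequence itself; any disagreement
with the plan would be reported as a violation. A `synchrom` command-line
interface wraps the same pipeline (`synchrom design`, `synchrom audit`,
`synchrom fixture`, `synchrom simulate-cross`).

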