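# Methods

## The problem and the assay model

SVA elements (SINE-R/VNTR/Alu composites) are the youngest human
retrotransposon family; many copies are polymorphic between individuals.
`svascan` implements the computational side of a targeted-amplification
assay for discovering and genotyping polymorphic SVA insertions: two nested
element-specific primers amplify the 5' end of each SVA copy together with
its 5' genomic flank, and 100-bp paired-end sequencing yields, per fragment,

* **read 1** ("SVA Read") — the element side, containing (part of) the
  5' (CCCTCT)n hexamer run and the 40-bp Alu-like region, and
* **read 2** ("Flanking Read") — the genomic flank, which localises the
  insertion.

Only elements that retain both primer-binding sites — consensus positions
78–137, 1-based, inside the Alu-like region — are amplifiable.  5'
truncation past this window makes a copy invisible to the assay, which is
why amplifiability is a first-class predicate (`is_amplifiable`) rather
than a filtering afterthought.

The expected biological fragment length is
`flank + 6·(hexamer copies) + 40`, plus 132 bp of sequencing adapters; the
library is size-selected near 500 bp (~370 bp of biological sequence).

## Read scoring

Whether a read 1 derives from an SVA is decided by a local alignment of the
read against the consensus *scoring target* — the consensus subsequence
covering the 40-nt Alu-like query and the primer window (65 nt in the
bundled model).  Scoring is Smith–Waterman with +1 match, −2 mismatch and a
linear 2.5-per-gapped-position cost; the raw score S (floored to an
integer) is converted to a bit score with the Karlin–Altschul formula

    bits = (λ·S − ln K) / ln 2,   λ = 1.28, K = 0.46,

the standard gapped constants for the +1/−2 scoring pair.  A perfect 40-nt
match scores 75.0 bits.  Reads are retained at 48 bits (**relaxed** — keeps
the older, more diverged SVA_D/E copies) or 65 bits (**stringent** — in
practice ≤1 mismatch in the query, enriching near-consensus young SVA_F
copies).  Under +1/−2, each substitution costs 3 raw points, so the relaxed
cutoff tolerates ~4 substitutions in a full-width 40-nt alignment.

Numerical choices: exact DP is used instead of a seeded heuristic (at
≤120-nt reads this is fast and never scores below a heuristic, a
deliberately conservative deviation); both read strands are scored and the
maximum taken; `N` always scores as a mismatch; scores are reported to
0.1 bit.  The DP is vectorised across reads (linear gap costs reduce the
within-row dependency to a running maximum), so a full cohort scores in
seconds.  Tests pin the implementation to an independent Biopython
`PairwiseAligner` oracle with exact agreement.

The bundled consensus is a **synthetic stand-in** (the published consensus
is distributed externally): hexamer unit ×12 at positions 1–72, a random
Alu-like/VNTR/SINE-R body, and a poly-A tail, 1,316 nt total.  The 40-nt
query sits at consensus 73–112, immediately 3' of the hexamer region.  Any
real consensus can be supplied as FASTA with configurable primer-window and
query coordinates; all scoring constants are config-exposed.  Because the
consensus is synthetic, genome-specific amplifiability fractions of real
annotation sets are out of scope.

## Locus building

Flanking-read alignments (SAM/BAM; from any mapper, or the simulator's
truth emitter) are filtered: unmapped/secondary/supplementary records are
dropped, and MAPQ < 29 removes multi-mappers (the cutoff is inclusive:
MAPQ 29 passes).  Insertion-proximal coordinates — the alignment endpoint
nearest the element junction: the end on the plus strand, the start on the
minus strand, because the flank is 5' of the element — are sorted and
chained: consecutive same-contig, same-strand coordinates join one cluster
when they differ by ≤ 500 bp (single-linkage; equivalent to the transitive
closure of the pairwise within-window relation, which the tests verify by
brute force).  The representative position is the junction-proximal member
coordinate (max on +, min on −).  Opposite-strand clusters are kept
separate; catalogs are matched within the same 500-bp window.

Per-locus, per-individual support:

* **depth** — member read count;
* **UR** ("unique reads") — distinct (contig, 5'-most aligned coordinate,
  strand) keys, a PCR-duplicate surrogate (the underlying assay cannot
  distinguish duplicates otherwise; this definition is a design choice and
  is stated prominently here because "unique reads" is often left
  undefined);
* **TPM** (tags per million) — depth ÷ the individual's total mapped reads
  × 10⁶, rounded to 2 decimals.  The denominator is the pre-MAPQ-filter
  mapped total (a config flag switches to post-filter totals).

## Calibration

Presumed fixed loci — clusters on amplifiable reference elements absent
from the known-polymorphic catalog — act as an internal truth set present
in every genome.  For each individual, sensitivity(t, u) is the fraction of
fixed loci with TPM ≥ t and UR ≥ u; the grid defaults to t, u ∈ {0..20}
(step 1).  A pooled grid sums depth and UR per locus over individuals and
recomputes TPM over the summed totals; pooled sensitivity is never below
any individual's (more evidence never hurts), and both grids are checked
for monotonicity on every run.  `select_cutoffs` returns the most stringent
pair still meeting the 90% target, ordering UR-major then TPM (ties toward
larger TPM); the ordering is config-switchable and recorded in output
metadata, since any such search needs an explicit, reproducible tie-break.
If no cell meets the target, the minimal cutoffs are returned with a
warning rather than an error.

## Locus typing, genotypes and trio filtering

Types partition the loci: a cluster matching the known-polymorphic catalog
(within the window) is *known polymorphic* — catalog matches win over
reference matches; otherwise a cluster on an amplifiable reference element
is *reference fixed*; everything else is *novel polymorphic*.  Presence
genotypes are binary (the single-sided assay cannot separate het from hom):
an individual carries a locus iff TPM and UR both meet that individual's
calibrated cutoffs.  Raising support can never flip present → absent.

De novo candidates in a trio offspring are loci called present in the
offspring and *shown by nobody else*: any other individual removes the
candidate either through a presence call or through raw support of
depth ≥ 1 (`min_evidence_depth`).  Discarding a candidate deliberately
needs far less evidence than asserting one — with germline SVA
retrotransposition at roughly one event per 916 births, six offspring give
`1 − (1 − 1/916)⁶ ≈ 0.0065` expected chance of one true event, so surviving
candidates are much more likely to be artifacts; candidates inside
annotated repeats are flagged as the characteristic false-positive mode.
A `concordance_report` helper compares two presence matrices (e.g. pipeline
calls vs. an external genotyping experiment) per locus and overall.

## Annotation

Loci are 1-bp points at their representative positions (the assay localises
a junction, not an interval).  Genic categories follow the precedence
CDS > UTR > undefined-exonic > intron > intergenic across all overlapping
transcripts, so categories partition the loci; the precedence rule is
needed because disjoint reporting is not derivable from a GTF alone.
Chromatin-state abundance assigns each locus to its containing segment and
normalises insertion counts by the number of segments per state —
"locations" is read as segment count, with a base-pair denominator
available via `basis="bp"`; loci outside every segment are tallied as
`unsegmented`.

## The synthetic-data generator

`svascan.simulate` emulates the full assay so that every stage is testable
without external data.  Defaults (the generator's study conditions):

| parameter | default | rationale |
|---|---|---|
| cohort | 2 trios (6 individuals) | smallest pedigree-bearing cohort |
| contigs | 2 × 400 kb | hosts 200 elements at ≥3 kb spacing |
| fixed elements | 200 | ~170 amplifiable after truncation |
| known / novel polymorphic | 20 / 20 | desk-scale catalog and discovery sets |
| subfamily mix | D 0.6, E 0.2, F 0.2 | old-to-young abundance ordering |
| divergence | D 5%, E 2%, F 0.5% | age-graded distance from consensus |
| hexamer copies | uniform 5–30 | no published length distribution; assumption |
| truncation | P=0.2, 1–400 bp removed | 5'-truncation is the known loss mode; assumption |
| read length / error | 100 bp, 0.5%/base | short-read defaults |
| mean on-target depth | 30× per diploid locus | calibration-scale coverage |
| fragment | ~N(370, 30) bp biological | ~500 bp library minus adapters |
| off-target noise | 5% of pairs | exercises bit-score specificity |

Founder genotypes are Hardy–Weinberg draws at per-locus allele frequencies
(uniform 0.05–0.5 by default); offspring receive one allele from each
parent; planted de novo loci get one copy in a named offspring only.
Minus-strand insertions take their flank from the sequence 3' of the
insertion point in reference orientation, reverse-complemented — the "5'
flank" is element-relative.  Elements truncated past the primer window
emit no on-target pairs.  Noise pairs have uniformly random read-1 sequence
and uniformly random flank placement with uniform MAPQ 0–60.  The truth
bundle holds the planted-insertion table, the genotype matrix, per-read
provenance, and an error-free flanking alignment SAM at MAPQ 60 that can
replace an external mapper.

What the generator does **not** model: PCR duplicates, non-uniform quality
profiles, chimeric fragments, reference gaps/repeat-induced mismapping
(truth alignments are exact), VNTR internal structure, and realistic
hexamer/truncation distributions (none are published).  Passing tests
therefore demonstrate the correctness of the pipeline's logic and
statistics under the stated generative model, not calling performance on
real libraries — in particular, mapping ambiguity in repeats, the dominant
false-positive mode for single-sided junction assays, enters only through
the MAPQ filter, not through simulated mismapping.

### The error-free control regime

Exact-recovery tests use a degenerate configuration: sequencing error 0,
noise 0, subfamily divergence 0, and 60× coverage.  Divergence must be 0
because a fixed element whose 40-nt query carries ≥5 substitutions is
invisible to the relaxed filter *by design* (every read from it fails), so
"every amplifiable insertion is recovered" is only guaranteed when elements
match the consensus; coverage is doubled so heterozygous carriers saturate
support and the regime tests logic rather than coverage statistics.

## Problem sizes and numerics

Test and acceptance runs use the defaults above (6 individuals, ~33 k read
pairs, ~170 amplifiable fixed loci), which a laptop processes in seconds.
All randomness flows from a single integer seed; identical configs produce
byte-identical FASTQ/SAM/summary outputs.  TPM is reported to 2 decimals
and bit scores to 1 decimal; raw alignment scores are floored before bit
conversion; degenerate inputs (empty reads, zero totals, empty fixed-locus
sets, missing read groups) raise or warn as described in module docs.

## Known limitations

* Bit-score constants are the documented defaults for the +1/−2 scheme; a
  library generated with other parameters needs the scheme overridden.
* UR is a start-coordinate surrogate for duplicate collapse; libraries with
  UMIs would support a sharper definition.
* Breakpoints are single-sided: no target-site duplications, no 3'
  transductions, and representative positions sit up to a few hundred bp
  from the true junction (always within the 500-bp matching window in the
  generative model).
* The desk-scale genome makes TPM values far larger than in a real
  multi-million-read library; the TPM axis of the default grid saturates
  and UR does most of the calibration work at this scale.
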