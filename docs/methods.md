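# Methods

## Problem setting

A structurally variable region of a graph-like human assembly has one
placement on a primary-assembly chromosome (the reference haplotype) and
one or more alternate-locus scaffolds (alternate haplotypes). The two
representations are largely but not entirely identical; their divergent
positions, when embedded in otherwise well-aligned sequence, are
*alignable scaffold-discrepant positions* (ASDPs). In a sample that
carries the alternate haplotype, short reads from it map onto the
primary assembly and the variant caller emits a call at essentially
every ASDP. The package turns that fingerprint into a per-region
diplotype call and flags the implicated variants.

## Alignment refinement

The distributed region↔scaffold alignments are encoded as `Gap=` block
descriptors: `M` (aligned, mismatches allowed, no gaps), `I` (extra
sequence in the scaffold), `D` (extra sequence in the reference). These
alignments are often fragmented, so they are used only as anchors:

* **Chunking.** `I`/`D` blocks of at least 1,000 nt (configurable) mark
  inversion-scale events; the descriptor is split there and each chunk
  is aligned independently. The boundary blocks themselves contribute no
  seeds. Second alignment lines of a GFF3 target (inversions) are kept
  as separate records and processed as independent chunks; scaffolds
  placed in reverse orientation are reverse-complemented at load time so
  all downstream code sees forward/forward alignments.
* **Seeding.** Each `M` block of length L is trimmed by
  `min(floor(0.05 L), 50)` nt per end (M-block ends are frequently
  noisy) and retained as a gapless seed iff the core is strictly longer
  than 50 nt. Runs of `N` longer than 10 nt in the scaffold segment
  split a seed, because the source alignments treat `N` stretches as
  matches and they carry no anchoring signal; sub-seeds failing the
  50-nt rule are dropped.
* **Banded chain alignment.** A global affine-gap alignment of each
  chunk is computed over a restricted cell set: a Chebyshev band of
  half-width 10 around every seed diagonal, plus the full rectangles
  connecting consecutive seed endpoints (and the chunk boundaries), each
  grown by the band half-width. Scoring is match +5, mismatch −2,
  gap open −20, gap extend 0 — so a gap of any length costs exactly 20.
  Within the allowed cells the score is maximal; whenever the
  unrestricted optimum stays inside the allowed set the result equals
  the full O(nm) DP (property-tested against an independent oracle).

  Using full inter-seed rectangles rather than a thin band along the
  straight line between seeds is deliberate: a straight-line band of
  half-width 10 cannot contain the optimal path across an inter-seed
  indel longer than about twice the band, which would corrupt every
  planted indel in that size range. The rectangles stay small because
  seeds cover most of the sequence.
* **Tie-breaking.** The traceback prefers diagonal steps over gaps on
  the reference row over gaps on the scaffold row, making output
  byte-deterministic. With no seeds at all, a full unbanded DP is run up
  to a 20,000-nt limit (beyond it the aligner refuses rather than
  silently spending quadratic time).
* **Trimming.** The region/scaffold alignments begin and end with
  identical anchor sequence, so each alignment is cut down to the
  columns between its first and last difference before any analysis.

## ASDP discovery

Candidate events are maximal runs of consecutive discrepant columns
(mismatch or gap). Event alleles are the gap-stripped strings over the
run; a pure indel is anchored on the preceding reference base (VCF
convention; the following base at the alignment start). Classification
follows allele lengths: both length 1 → SNV; equal lengths ≥2 → block
substitution; reference longer → deletion; scaffold longer → insertion.
Mixed runs (mismatch and gap columns adjacent) are emitted as one event
and classified by the same length rules, so the four categories
partition all events. Event size is the allele length for substitutions
and the longer-allele length minus one for indels; events of 50 nt and
more are structural class, matching the upper size limit of common
small-variant callers.

The high-confidence filter slides a 50-column window one column at a
time across the alignment; an event is excluded iff some fully contained
window overlapping it has more than ten discrepant columns (alignments
shorter than the window are one window). *Discrepant* counts columns,
not events — the literal reading of the published filter. A consequence
worth knowing: an isolated indel longer than 10 nt excludes itself,
because the windows inside its own gap run exceed the budget. Events are
nevertheless retained in the output VCF with their confidence flag, and
the structural class is additionally excluded from the inference set
unless explicitly included.

## Diplotype inference

For a region, R is the set of sample calls (one per ALT allele of each
VCF row, genotype from the first sample's GT) restricted to the interval
between the region's first and last alignment difference — reconstructed
as the left-normalized span of its ASDP records — and A is the
high-confidence, small-class ASDP set of one alternate locus. Matching
is one-to-one on (chrom, pos, ref, alt) after normalization: shared
suffix trimmed, indels shifted left through repeat tracts when the
reference sequence is available, shared prefix trimmed. A
`position_only` mode relaxes matching to the normalized position.

The residual variants are `RV = (R \ A) ∪ (A \ R)`; an unmatched ASDP is
interpreted as a variant that *would* have to be real under the
alternate-locus hypothesis (possibly a dropout, but the model has no
coverage information). Per region:

1. compute |RV| for every associated locus; the minimum wins (ties:
   larger overlap, then lexicographically smallest accession —
   determinism, nothing more);
2. the locus is present iff |RV| < |R|, strictly — otherwise the region
   is homozygous primary assembly;
3. if present, the homozygous fraction is computed over matched calls
   with a defined genotype (missing genotypes excluded; if none remain
   the fraction is undefined and the call falls back to heterozygous);
   strictly above 0.90 calls the homozygous alternate state.

Regions with |R| = 0 satisfy |RV| ≥ |R| vacuously and are reported as
homozygous primary assembly flagged `low_evidence`.

Annotation adds FILTER `ASDP_REGION` plus INFO `ASDPALT` to matched
calls in regions inferred to carry an alternate locus, INFO `REGIONGT`
to every call inside an analysed region, and leaves everything else
untouched apart from header additions.

## Synthetic data

The generator emulates the divergence structure of real
region/scaffold pairs at desk scale. Background sequence is i.i.d.
uniform ACGT with rejection of homopolymers ≥8 nt and repeated 13-mers,
so the alignment optimum is unique and truth comparisons cannot be
confounded by equivalent gap placements. Defaults per region: 5,000 nt,
9 SNVs, one insertion and one deletion of 1–8 nt, one block substitution
of 2–5 nt — about 2.4 events/kb with three quarters SNVs, mirroring the
observed density (~2.2 ASDPs/kb) and the SNV-dominated category mix of
real assembly comparisons. Event starts are at least 60 nt apart so no
50-column window spans two events; 200-nt identical flanks at the region
ends provide the anchors the refinement assumes. Small indels default to
at most 8 nt so every planted small event is recoverable under the
column-counting window filter (see above); structural events of
60–120 nt can be added and are expected to be excluded by it. Insertions
are sampled so their planted representation is already left-aligned.
Truth records are emitted in normalized VCF representation.

Sample simulation: under a homozygous-alternate diplotype every small
truth event becomes a homozygous call with probability `1 − fn_rate`
(heterozygous calls under the heterozygous diplotype; none under
homozygous reference), plus exactly `fp_count` spurious heterozygous
SNVs placed at least 30 nt from any truth event. One RNG stream per
spec seed; every output is reproducible from `rng_seed`.

What the generator does **not** model: read-level effects (coverage,
mapping ambiguity, quality-dependent dropout), recombination between the
reference and alternate haplotypes, clustered or repeat-mediated events,
and real scaffold placement geometry. Passing tests therefore
demonstrate the correctness of the algorithms under the stated event
model, not calling performance on real WGS data.

## Problem sizes used in the test suite

The suite exercises the pipeline on regions of 0.3–20 kb and cohorts of
up to 210 regions (70 per diplotype, 5% call dropout, 2 spurious calls
per region), with oracle cross-checks (full DP, exhaustive window scan,
naive set difference) on inputs small enough to brute-force. These sizes
are the package's own choice of desk-scale study conditions; published
genome-scale figures (hundreds of thousands of ASDPs over 178 regions,
population counts over cohorts of genomes) require the full assembly and
private cohorts and are deliberately out of scope.

## Known limitations

* The window filter's column counting self-excludes isolated indels
  longer than 10 nt; counting merged events instead would retain them.
  The choice is configurable only through the window parameters.
* Genotype handling reads the first sample of a VCF; multi-sample VCFs
  are not genotyped per sample.
* A trimmed alignment consisting of a single unanchored indel (sequences
  differing only by one terminal indel) has no flanking base for a VCF
  representation and is rejected rather than guessed.
* The aligner is pure Python; it is comfortable at the tens-of-kilobase
  scale of the banded search space, not at chromosome scale.
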