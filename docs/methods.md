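# Methods

## Scope and data model

The pipeline starts at transcript structures: read mapping, assembly and
homology search are upstream of it.  Coordinates are 0-based half-open
internally; GTF/GFF3 are 1-based inclusive on disk and converted at the I/O
boundary, BED is 0-based half-open.  A transcript is a sorted chain of
non-overlapping, non-adjacent exons on one chromosome and strand; its
introns are the gaps between consecutive exons and its internal exons are
all but the first and last.  Introns of 1–3 bp are accepted but logged as
suspicious (observed minima in real annotations are ~5 bp; the floor is
left to the caller).

## Event identification

**Deduplication.**  "Identical" means an exactly identical exon chain.
Transcripts sharing an intron chain but differing in terminal exon extents
stay distinct; they can pair without producing events (see below), which
avoids inventing fuzzy-end merge semantics.

**Chimera filter.**  A transcript is dropped when *any* intron exceeds
100 kb (strictly greater; an intron of exactly 100,000 bp survives).
Extremely long introns in mapped data are typically fusions of adjacent
genes rather than real splicing.

**Locus clustering.**  Single-linkage over pairwise exonic overlap
(≥ 1 bp) on compatible strands.  Under the default `strict` policy only
equal strands connect, except that unknown-strand transcripts may join
either strand's cluster; `lenient` ignores strand.  Overlap confined to an
intron of the partner does not connect.  Implementation: a span-sweep
bounds candidate pairs, then union-find over exact exon-overlap tests;
equivalence with brute-force BFS over all pairs is asserted in tests.

**Variant regions.**  Comparison of two splice chains is restricted to the
intersection of their extents.  Shared (position, kind) sites are anchors;
the intersection boundaries also anchor *provided both transcripts are
exonic there*.  Maximal runs of non-shared sites between consecutive
anchors become variant regions; runs not bounded by anchors on both sides
are discarded as unresolvable within the shared window.  Consequences that
are deliberate design choices:

- Variation confined to terminal-exon extents produces **no** event — the
  four basic types are all internal-splice-site events, and alternative
  transcription start/end is out of scope.
- A single-exon transcript can reveal intron retention against a spliced
  partner only when the spliced intron lies fully inside its exon.
- One isoform pair can contribute several events (one per region); a
  single region combining two or more basic variations is one Complex
  event, never split.

**Classification** is a closed template match on the region (side-swapped
as needed, sites read in transcript orientation): complete intron vs empty
→ IntronR (the *empty* side's transcript retains the intron, recorded once
per pair with a flag naming the retaining isoform); included exon vs empty
→ ExonS; one site per side, both donors (shared acceptor anchor) → AltD;
both acceptors (shared donor anchor) → AltA; everything else → Complex.
Fragment sizes: retained-intron length, skipped-exon length, or the
distance between the two alternative sites; Complex regions carry none and
are excluded from fragment statistics.

**Counting.**  Events are counted at pair level (each compared pair
contributes each of its regions).  Because the same structural variation
recurs across pairs of a many-isoform locus, a deduplicated count of unique
(locus, anchor, canonical code) triples is also reported.  The canonical
code lists both sides' sites relative to the left anchor with the
lexicographically smaller side first, so duplicate detection is independent
of pair orientation.

## Feature statistics

Length summaries use the sample mean and sd (ddof = 1; a singleton has
sd 0) and right-inclusive histograms (bin *w* holds lengths in
(w − width, w]; default width 100 bp).  Splice-site dinucleotides are read
in transcript orientation (minus-strand introns reverse-complemented);
introns shorter than 4 bp are skipped with a warning and N-containing
boundaries count as "Others".  Introns are deduplicated by
(chrom, strand, start, end) before counting, and an intron belongs to the
AS group iff its locus has at least one event (locus-level membership —
gene-level is the natural reading of "genes undergoing AS", and intron-level
membership is not well defined for shared introns).

The AS vs non-AS usage comparison uses the uncorrected Pearson chi-square
test of homogeneity (no Yates correction); categories with an expected
count below 5 in either group are pooled into "Others" before testing, and
all-zero categories are dropped.  When fewer than two categories survive
pooling (tiny samples) the pipeline reports no test rather than failing.
Significance threshold: 0.05.  Type-I calibration (~5 % rejection on
same-multinomial samples over 1,000 replicates) is asserted in the
acceptance suite.

Junction matrices count base occurrences at 10 exonic + 10 intronic
positions across the 5' junction and 10 intronic + 10 exonic positions
across the 3' junction, in transcript orientation; columns are normalized
to probabilities, N bases are excluded from that column's denominator, and
introns whose flanks run past a chromosome end are skipped with a warning.
Rendering of sequence logos is out of scope; the matrices are emitted as
TSV for any logo tool.

## Functional impact

**ORFs.**  Transcripts are orientation-resolved, so only the three forward
frames of the spliced sequence are scanned.  Stop codons delimit segments;
an ORF runs from the first ATG of a segment to its stop (complete) or the
sequence end (start only), and the leading segment without an ATG is
itself reported (stop only, or neither flag).  Records under `min_aa`
(default 30 residues — a common lower bound for domain-bearing peptides;
the underlying data offers no value) are dropped and the longest survivor
is flagged (ties: smallest start).  Equivalence with brute-force
enumeration over all ATG positions is asserted on random sequences.

**Domain impact.**  Domain annotations are consumed as a precomputed
transcript → domain-id-set table; running the homology search itself is
out of scope, which keeps the pipeline desk-scale while fully implementing
the categorization logic.  Per event pair: both unannotated → `both_none`;
equal non-empty sets → `same`; exactly one annotated → `one_lost`; both
annotated but unequal sets → `different` ("different" means set
inequality, not count or order).  `loss_or_change` = `one_lost` +
`different`.  The four counts partition the events exactly.

**Gene-model assignment.**  A transcript matches a model iff its spliced
sequence shares an exact, ungapped common substring of ≥ 80 nt with the
model cDNA — a deterministic restatement of a 100 %-identity ungapped
local alignment with an 80 bp floor.  Span-overlapping models are tried
first and the full set is scanned only when none matches; among multiple
matches the locus-overlapping model wins, then the longest shared
substring (binary search on the shared k-mer length), then model id.  A
sequence-free `overlap` mode exists for runs without cDNAs.  The AS rate
is the count of models matched by ≥ 1 event-participating transcript,
divided by expressed (matched) models or by all models; percentages use
the uniform rounding rule.

**TE overlap.**  An intron "contains a TE" iff any TE interval overlaps it
by ≥ 1 bp, strand-agnostic (an interval-overlap stand-in for a BLASTN
search against a repeat library; the TE track is an input).  Fractions are
over unique introns strictly longer than 50 bp, separately for retained
introns (from IntronR events) and for all gene-model introns.

## The simulator

The generator emulates a plant-like multi-exon transcriptome and defines
the conditions under which the pipeline is validated:

| parameter | default | rationale |
|---|---|---|
| internal/terminal exon length | lognormal, mean 282 bp, sd 547 bp, min 2 | observed internal-exon moments of a deeply sampled plant transcriptome |
| intron length | lognormal, mean 1,352 bp, sd 7,609 bp, min 5 | observed intron moments (heavy right tail; occasional > 100 kb draws exercise the chimera filter) |
| exon count | 2 + Poisson(3) | multi-exon genes, mean 5 exons; no empirical law is imposed by the data |
| splice-site type frequencies | GT..AG .9057, GC..AG .0268, GC..AT .0108, AT..AC .0097, CT..AC .0073, GT..AT .0072, Others .0324 | observed genome-wide usage; "Others" draws a random non-listed dinucleotide pair |
| event-type mix | IntronR .4197, AltA .2860, AltD .1616, ExonS .1328 | observed basic-type proportions, renormalized over the basic types; Complex plantable via config |
| p_expressed / p_AS | 0.965 / 0.65 | observed expressed-model fraction and AS rate |
| domain-impact mix | .310/.445/.173/.072 | observed four-way category proportions |
| TE density | 0.023 per intron > 50 bp, 150 bp intervals | observed all-intron TE fraction |
| alternative-site offset | 3 + Geometric(mean 100), capped by intron feasibility | AS fragments are short relative to introns; no empirical law available |
| candidate choice | inverse-length weighting (configurable to uniform) | reproduces the "small introns retained, small exons skipped" bias |

Each gene gets a reference isoform whose spliced cDNA carries an embedded
full-length ORF (ATG at 0, single terminal stop, no internal in-frame
stops).  Alternative isoforms each carry exactly one planted event:
IntronR merges two exons; ExonS deletes an internal exon and fuses its
flanking introns; AltD/AltA move one site *into* the intron by the offset
(so the new dinucleotide patch lands in intronic background and can never
overwrite coding sequence — offsets ≥ 3 also keep patches clear of the
parent boundary dinucleotides); Complex applies a donor and an acceptor
shift to the same intron.  New introns inherit the parent's site type.
Planted domain sets are drawn consistently per gene so every
(reference, alternative) pair realizes its drawn category.  Every planted
feature is written to a truth ledger (events, per-intron site types and TE
presence, per-pair domain categories), and a full bundle is reproducible
byte for byte from (config, seed).

What the simulator does **not** emulate: read-level noise and expression
(no FASTQ, no abundances), alternative transcription start/end, overlapping
or nested genes, antisense transcription, repeat structure beyond the
planted TE intervals, GC/codon bias (uniform background), and splice-site
motif context beyond the boundary dinucleotides.  Passing recovery tests
therefore demonstrate correctness of the structural algebra and the
statistical layers under clean structures — not robustness to mapping
error, fragmentary isoforms or mis-stranded transcripts in real data.

## Numerical and reporting conventions

- Every printed percentage is `100·n/d` rounded half away from zero to one
  decimal (implemented in exact decimal arithmetic), so any table row is
  re-derivable from its numerator and denominator.
- Determinism: identical inputs yield byte-identical event lists, codes
  and `report.json`; the only randomness in the package lives in the
  simulator behind a single seed.
- Degenerate inputs: empty length lists return an explicit empty summary;
  an empty intron group makes the chi-square unavailable (reported as
  null) rather than a synthetic value; a zero denominator in a percentage
  is an error, except the documented 0-of-0 → 0.0 convention for rates on
  empty expressed sets.
- Event-level impact and fragment statistics include alternative–alternative
  pairs of multi-isoform loci, not only (reference, alternative) pairs, so
  simulated event-type and impact proportions deviate from the planted
  per-pair mixes by construction; recovery is always scored on the planted
  pairs against the truth ledger.

## Problem sizes

The test suite validates recovery on a 3,200-gene all-AS simulation
(≥ 1,000 planted events per basic type, > 13,000 reference introns), the
oracle equivalences on 500 random chain pairs and 200 random sequences,
and the chi-square calibration on 1,000 replicates of 2 × 2,000 introns.
`scripts/acceptance.py` uses a 1,500-gene simulation under the default
conditions.  These sizes give every statistical check a comfortably
powered sample while keeping a full run on a single CPU in the
tens-of-seconds range.

## Known limitations

- Locus clustering approximates whatever merging the upstream assembler
  would do; fuzzy-end transcript merging and class codes are out of scope.
- The ≥ 80 nt exact-substring rule is stricter than a BLASTN HSP under
  sequencing error; on error-free simulations they coincide.
- The chi-square test is asymptotic; with very small intron sets the
  pipeline declines to test rather than switching to an exact test.
- Complex events are reported as a single class; no decomposition of a
  complex region into nominal basic constituents is attempted.
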