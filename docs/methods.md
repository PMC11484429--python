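# Methods

This note documents the models and algorithmic choices behind `hapasm`:
what each stage assumes, which parameters matter and why their defaults
are what they are, what the simulator does and does not emulate, and the
design decisions taken where more than one reasonable construction exists.

## Guide-haplotype model

A *guide set* is a family of reference haplotypes for one hyperpolymorphic
region that share a common backbone and differ by (i) a large
class-defining insertion block — the analogue of the extra sequence content
that distinguishes HLA class II structural haplotypes — and (ii) optional
per-class point divergence of the backbone. `ClassSpec.divergence` defaults
to 0 so that explicitly constructed guide pairs have verbatim-identical
flanks; the canonical study condition (`default_class_pair`) sets 1 % for
the LONG class. One percent substitution divergence between class
haplotypes is the realistic regime for this kind of region — divergent
haplotype classes differ by roughly one SNP per hundred bases on top of
their structural differences — and it is also what makes the classes
*operationally* distinguishable: at 1 %, about 95 % of read pairs
(2 × 150 bp from a 426 bp fragment) cover at least one discriminating site.

The backbone carries the repeat features that make real assemblies hard:
homopolymer runs (15–30 bp), short tandem repeats (period 2–6), dispersed
~300 bp repeat copies at ~98 % identity, and one 2 kb segmental-duplication
pair at 99.95 % identity, the C4A/C4B analogue. The duplication pair is
deliberately *unresolvable* by a k = 51 short-read graph; the expected and
tested behaviour is that it collapses or breaks rather than being threaded,
with the second copy's span filled from the guide in the consensus.

## Truth haplotypes and the variant ledger

A truth haplotype is a guide plus novel variants: SNV count ~
Binomial(L, rate), small INDELs, and explicit structural-variant specs.
Every variant is recorded in an ordered ledger whose replay onto the guide
must reproduce the truth sequence exactly (a tested invariant). Variant
footprints never overlap, and the first/last 150 bp are excluded so every
variant is coverable by reads — otherwise edge variants would be
unrecoverable for trivial reasons and contaminate recovery scores.

For diploid individuals, `make_diploid_truths` places a fraction
`shared_frac` (default 0.5) of variants at homologous backbone positions on
*both* haplotypes with the same allele. Both chromosomes of a real
individual share most of their differences from an unrelated reference
haplotype (identical-by-state common variation); 0.5 approximates the
genome-wide homozygous fraction of variant sites.

## Read simulation

Pairs are drawn at `depth_fold` × coverage
(`ceil(total_length · depth / (2 · read_length))` pairs) with Gaussian
fragment lengths truncated to [read length, 2 × mean]; defaults 150 bp,
30×, 426 ± 109 match the HiSeq-X-like profile of the target application.
Substitution errors are uniform at 0.2 % per base (a stand-in for a full
platform error profile; configurable), and qualities are truncated-normal
around Q35 — enough structure for the QC stage to act on, no more.
Fragments may straddle the region boundaries and are clipped to it
(`edge_mode="clip"`), emulating reads extracted from genome-scale
sequencing; this gives uniform coverage up to the region edges, which is
what region-extraction inputs actually look like. The simulator does not
model PCR/optical duplicates, GC bias, capture probe dropout, or
platform-specific quality decay — so passing tests demonstrate correctness
of the assembly machinery under idealized-but-calibrated noise, not
robustness to every artifact of production data.

## QC semantics

Poly-G artifacts are dropped at ≥ 20 consecutive G — and, by default, C,
since the artifact appears as a C-run on the opposite-sense mate; the whole
pair is dropped to avoid orphan inflation in the pair-aware binner.
Trimming strips leading/trailing bases with Q < 3 or N, truncates at the
first 4 bp window whose mean quality falls below 15, then re-strips the
tail (which makes the operation idempotent, a tested property); mates
shorter than 40 bp are dropped and single survivors routed to an orphan
stream. The window semantics are pinned by a brute-force oracle in the test
suite. Adapter removal is assumed done upstream.

## Binning

The internal aligner seeds with exact 21-mers, votes on (strand, diagonal)
candidates, and extends with edlib inside a ±30 bp band; scores are derived
from the alignment path with mismatch −6, gap open −5, gap extend −3, so
the linear mapping threshold of −0.6 per read base has its conventional
end-to-end meaning (a 150 bp read maps down to score −90, i.e. up to 15
mismatches). A pair is mapped when either mate reaches threshold.

With two guides, binning is a three-way partition — mapped(A), mapped(B),
unmapped — with each pair assigned to the guide where its summed raw score
is better, ties broken by a stable hash of the read id. Competitive
assignment is the load-bearing choice for diploid accuracy: it keeps each
per-guide read set haplotype-pure wherever the guides are distinguishable,
so heterozygous novel variants are assembled at effectively haploid
coverage instead of being averaged into 50/50 bubbles. An `independent`
interpretation (each guide gets every read that maps to it) would mix
haplotypes everywhere the guides are similar and halve heterozygous
recovery. The band limit means reads spanning INDELs larger than ~30 bp go
to the unmapped bin by design; their content re-enters through unmapped-bin
assembly and junction merging.

Superblocks cap local assemblies at 50 kb with a 300 bp flank shared
between neighbours; the flank guarantees that adjacent superblock contigs
overlap exactly and can be merged back without a guide-based decision.

## Assembly and cleaning

k = 51 balances repeat resolution against the error-induced spectrum at
150 bp read length; `min_kmer_cov` = 3 removes nearly all error k-mers at
30× while keeping the real path solid. Tips shorter than 2k are clipped
iteratively; simple bubbles with arms ≥ 95 % identical are popped keeping
the higher-coverage arm — at 95 %, heterozygous SNVs and micro-INDELs
(≤ ~5 bp) in a *mixed* read set collapse to the majority allele, while
larger alternative alleles survive as separate contigs. Contigs shorter
than 2k are dropped.

Graph traversal instantiates both orientations of every canonical k-mer,
walks maximal unbranched paths, and deduplicates by canonical sequence;
contig order is deterministic (length desc, then sequence), so runs are
byte-reproducible.

### Overlap merging and the repeat-chimera rule

Supercontigs are built by greedy longest-first suffix-prefix merging
(≥ 40 bp at ≥ 99 % identity) plus containment collapse. Two guards prevent
the classic repeat chimeras that a purely sequence-driven merge creates:

* contigs from the *same* source bin never end-join — within one graph, a
  break is a branch point the assembler chose to keep, and adjacent unitigs
  trivially share a (k−1)-mer overlap that would re-join them through a
  collapsed duplication;
* mapped-bin contigs only join when their superblock guide windows
  overlap — an honest overlap cannot exist between disjoint windows, so any
  qualifying alignment between them is a repeat artifact.

Unmapped- and gap-bin contigs merge freely (junction contigs must be able
to splice into flanking supercontigs). Without these rules the
segmental-duplication pair produced multi-kilobase false deletions; with
them, the duplication collapses into a local gap instead.

### Polishing

Reads are realigned to the supercontigs and a column is rewritten to the
pileup majority when depth ≥ 5 and the majority fraction ≥ 0.7
(substitutions and small INDELs alike). The 0.7 floor means genuinely
heterozygous columns (≈ 0.5) are never rewritten; the rule only repairs
columns where the read evidence is near-unanimous, and a column already
matching its majority is untouched (tested invariant).

## Scaffolding

Placements are built from guide-*unique* 21-mer anchors only — anchors with
two or more guide hits would inflate a contig's interval toward the other
copy of a repeat and corrupt overlap trimming. The location score is the
fraction of a contig's anchored k-mers supporting its best position
cluster; the orientation score is the majority-strand fraction within that
cluster. The filter — drop iff location < 0.1, or location < 0.3 with
orientation < 0.75 — removes ambiguous and chimeric placements and is the
mechanism by which no false structural variant > 1 kb survives into the
consensus (a tested property).

Three robustness mechanisms operate at ordering time, each added against an
observed repeat-artifact class: placed segments are clipped to their
anchored span plus 60 bp slack (long unanchored tails are other-copy
content); intervals are extrapolated from the anchor diagonal to the true
contig extents, and overlap trimming cuts along that diagonal with anchors
kept consistent through every cut; and adjacent junctions within 300 bp are
reconciled by direct sequence overlap (≥ 25 bp at ≥ 97 %) to remove
duplicated repeat flanks.

Gap closing collects pairs with a mate anchored within 400 bp of a gap,
mini-assembles them at k = 31 (min coverage 2), and splices a bridge only
when it overlaps both flanks by ≥ 40 bp at ≥ 99 % identity. Remaining gaps
are filled from the guide in lowercase (default) or with N runs; guide fill
is the natural reading of a consensus "with respect to the reference", and
the N policy is provided for reference-bias-sensitive uses. The gap mask
records exactly which consensus bases were assembled versus filled.

## Validation metrics

Assembly-to-truth alignment chains unique 51-mer anchors (longest
increasing subsequence), thins them to non-overlapping anchors, and aligns
inter-anchor pieces globally with edlib after stripping common
prefixes/suffixes — the stripping makes a clean size difference report as a
single INDEL instead of an arbitrary split of equal-cost gap placements.
Error accounting counts substitution bases and INDEL lengths (≥ `min_sv`,
default 1 bp to match the headline error-table convention; a flag raises it
to 2) as percentages of assembled length; consensus bases filled from the
guide are excluded from numerator and denominator by default, since filled
bases are reference content, not assembly output. Repeat attribution uses a
supplied annotation or, absent one, an internal low-complexity annotator
(homopolymers ≥ 10 bp; tandems of period ≤ 6 with ≥ 3 copies). When both
truth haplotypes are supplied, substitution errors whose allele-in-context
matches the other haplotype are additionally flagged as other-haplotype
inclusions rather than unexplained error.

Novel-variant recovery asks, for each ledger variant, whether the consensus
carries the alt allele between its ±25 bp truth flanks — exactly first,
then tolerating ≤ 2 edits per flank while requiring the variant ±7 bp core
to match exactly. For an insertion this requires the *entire* inserted
sequence to be present, so partially assembled large insertions count as
misses; recovery numbers are therefore conservative for long insertions.

## Problem sizes and determinism

The packaged validation experiments (`scripts/acceptance.py`) use a 150 kb
region with a 20 kb class insertion, 30×/60× coverage and three replicate
seeds — large enough to contain every repeat feature and ~170 planted
variants per haplotype, small enough that the whole battery runs in a few
minutes on one CPU. All randomness flows through explicitly seeded
generators; string hashing is avoided in favour of CRC32 so results are
identical across processes.

## Known limitations

* Near-identical duplications (the C4-like pair) are collapsed, not
  resolved; their second copy appears as guide fill. Copy-number inference
  is explicitly out of scope.
* Reads spanning very large insertions are recovered only as far as the
  unmapped-bin assembly reaches; insertions much longer than the fragment
  length would need the (absent) secondary assembly round.
* The per-guide consensi of a heterozygote are not formally phased against
  each other.
* Mapping uses a banded edit-distance kernel with a linear score derived
  from the path; for reads near the score threshold with clustered gaps the
  score is a close approximation of, not identical to, an affine-gap
  optimum.
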