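# hapasm

Haplotype-guided, reference-informed de novo assembly of short reads for
hyperpolymorphic genomic regions — the MHC being the motivating case — with
a built-in simulator and validation framework so every stage can be
exercised and scored without any external data.

## The problem

Hyperpolymorphic regions such as the ~5 Mb MHC defeat plain
reference-mapping pipelines: novel heterozygosity, copy-number variation and
large structural differences between haplotype classes (e.g. the DR-region
insertion blocks of HLA class II) mean that an individual's sequence can
differ from any single reference by far more than a mapper tolerates, while
pure de novo assembly of 150 bp reads fragments in the region's repeats.
`hapasm` takes the middle road: reads are binned against one or two
*guide haplotypes* chosen from the individual's first-field class II
genotype, assembled de novo in local windows, and the resulting supercontigs
are ordered and oriented back on the guide — so novel variation comes from
the reads, and only the large-scale ordering comes from the reference.

## Pipeline

For an individual with genotype-assigned guide haplotype(s):

1. **QC** (`readqc`) — poly-G artifact removal (≥ 20 consecutive G/C),
   optional seeded subsampling, leading/trailing Q < 3 stripping, 4 bp
   sliding-window mean-Q15 truncation, 40 bp length floor.
2. **Binning** (`haplobin`) — each pair is aligned to every assigned guide
   with an internal seed-and-extend aligner (match 0, mismatch −6, gap
   −5 − 3/bp; a read maps if its score ≥ −0.6 × length). With two guides the
   bins are competitive: a pair goes to the better-scoring guide. Mapped
   placements are grouped into overlapping blocks and merged into
   ≤ 50 kb *superblocks* with 300 bp flank overlap.
3. **Assembly** (`dbgasm`) — each superblock (and the unmapped bin) is
   assembled in a k = 51 de Bruijn graph: weak k-mers (< 3×) dropped, short
   dead-end tips clipped, near-identical bubbles popped toward coverage.
   Unmapped-bin contigs that belong to the alternative haplotype or decoy
   are filtered (≥ 50 % of length at ≥ 90 % identity); contigs merge into
   supercontigs over ≥ 40 bp suffix-prefix overlaps at ≥ 99 % identity;
   pileup majority voting (depth ≥ 5, fraction ≥ 0.7) polishes residual
   errors.
4. **Scaffolding** (`scaffolder`) — supercontigs are anchored on the guide;
   each placement gets a location score (anchored bases in its best
   position cluster / all anchored bases) and an orientation score
   (majority-strand fraction). Placements with location < 0.1, or
   location < 0.3 and orientation < 0.75, are discarded — this filter is
   what keeps false structural variants > 1 kb out of the consensus. Gaps
   are closed by paired-read mini-assembly (k = 31) where spanning inserts
   exist; the result is one continuous consensus FASTA record (gaps filled
   from the guide in lowercase, or with N), with unplaced contigs appended
   as separate records.
5. **Validation** (`evalmetrics`) — N50/length statistics, assembly-to-truth
   alignment, an error taxonomy (base-call %, non-repeat SV %, repeat SV %
   of assembled length), novel-variant recovery against a variant ledger,
   unique k-mer diversity, and PAF export for dot plots.

The simulator (`simforge`) generates the study conditions: guide classes
sharing a backbone but differing by a large class insertion (plus point
divergence), diploid truth haplotypes with ledgered novel SNVs/INDELs, and
150 bp paired reads at configurable depth with fragment length 426 ± 109.

## Worked example

```bash
hapasm run-all --control control.txt --out-dir out/
```

with `control.txt`:

```
seed      = 7
length    = 60000
classes   = SHORT:0,LONG:10000:0.01
snv_rate  = 0.001
sv_spec   = DEL:500:1,INS:120:2,DEL:35:2
depth     = 30
diploid   = true
```

simulates a SHORT/LONG heterozygote over a 60 kb backbone with a 10 kb
class insertion, assembles both haplotypes per matched guide, and prints:

```json
{
  "guide_SHORT": {
    "assembled_length": 55879,
    "total_error_pct": 0.0,
    "base_call_error_pct": 0.0,
    "snv_recovery": 0.8809523809523809,
    "sv_recovery": 1.0,
    "large_false_sv_count": 0
  },
  "guide_LONG": {
    "assembled_length": 67668,
    "total_error_pct": 0.008866820358219542,
    "base_call_error_pct": 0.007389016965182952,
    "snv_recovery": 0.9322033898305084,
    "sv_recovery": 1.0,
    "large_false_sv_count": 0
  }
}
```

Reading: each consensus covers nearly the whole haplotype (assembled_length
is the portion built from reads, not filled from the guide), total error —
mismatched plus INDEL bases as a percentage of assembled sequence — is at
the hundredth-of-a-percent level, ~90 % of the planted novel SNVs and all
planted structural variants are present in the consensus, and no spurious
structural variant over 1 kb was introduced. (SNV recovery rises with
region size; at this 60 kb scale each unassembled repeat flank hides a
larger share of the ~50 planted SNVs than it would at 150 kb.) Individual
stages are exposed as
`hapasm simulate | qc | bin | assemble | scaffold | evaluate | stats`.

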