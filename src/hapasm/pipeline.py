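"""End-to-end per-individual assembly: QC -> binning -> per-superblock de
Bruijn assembly -> cross-contig filtering -> merging -> polishing ->
scaffolding, once per assigned guide haplotype."""

from __future__ import annotations

from dataclasses import dataclass, field

from .dbgasm import (
    AssemblyParams,
    Contig,
    assemble_reads,
    filter_cross_contigs,
    merge_contigs,
    polish,
)
from .evalmetrics import (
    AlignmentSegment,
    ErrorReport,
    VariantRecovery,
    align_to_truth,
    call_errors,
    recover_novel_variants,
)
from .haplobin import BinnedReads, Superblock, bin_pairs, build_superblocks
from .readqc import QCParams, QCSummary, run_qc
from .scaffolder import ConsensusAssembly, ScaffoldParams, scaffold
from .simforge import GuideHaplotype, ReadPair, TruthHaplotype


@dataclass(frozen=True)
class PipelineParams:
    qc: QCParams = field(default_factory=QCParams)
    asm: AssemblyParams = field(default_factory=AssemblyParams)
    scaffold: ScaffoldParams = field(default_factory=ScaffoldParams)
    k_seed: int = 21
    max_block: int = 50_000
    block_flank: int = 300


@dataclass
class HaplotypeAssembly:
    """Per-guide result of one pipeline run."""

    guide_id: str
    supercontigs: list[Contig]
    consensus: ConsensusAssembly
    n_mapped_pairs: int
    n_unmapped_pairs: int
    n_corrections: int
    qc_summary: QCSummary


def assemble_individual(
    pairs: list[ReadPair],
    guides: list[GuideHaplotype],
    params: PipelineParams | None = None,
    decoys: list[tuple[str, str]] | None = None,
) -> dict[str, HaplotypeAssembly]:
    """Run the full pipeline for one individual against its assigned guide
    haplotype(s); returns one consensus assembly per guide."""
    params = params or PipelineParams()
    qc_pairs, _orphans, qc_summary = run_qc(pairs, params.qc)
    binned = bin_pairs(qc_pairs, guides, k_seed=params.k_seed)

    unmapped_seqs = [s for p in binned.unmapped for s in (p.seq1, p.seq2)]
    unmapped_contigs = (
        assemble_reads(unmapped_seqs, params.asm, "UNMAPPED") if unmapped_seqs else []
    )

    results: dict[str, HaplotypeAssembly] = {}
    for guide in guides:
        alt = [g for g in guides if g.id != guide.id]
        superblocks = build_superblocks(
            binned.placements[guide.id], guide, params.max_block, params.block_flank
        )
        by_id = {p.id: p for p in binned.mapped[guide.id]}
        mapped_contigs: list[Contig] = []
        for i, sb in enumerate(superblocks):
            seqs: list[str] = []
            for rid in sb.member_read_ids:
                pr = by_id[rid]
                seqs.append(pr.seq1)
                seqs.append(pr.seq2)
            mapped_contigs.extend(
                assemble_reads(seqs, params.asm, f"MAPPED:{sb.interval[0]}-{sb.interval[1]}")
            )

        filtered = filter_cross_contigs(
            unmapped_contigs, alt_guide=alt[0] if alt else None, decoys=decoys
        )
        merged = merge_contigs(mapped_contigs + filtered)
        run_pairs = binned.mapped[guide.id] + binned.unmapped
        polished, corrections = polish(merged, run_pairs)
        consensus = scaffold(
            polished,
            guide,
            pairs_by_id={p.id: p for p in run_pairs},
            guide_placements=binned.placements[guide.id],
            params=params.scaffold,
        )
        results[guide.id] = HaplotypeAssembly(
            guide_id=guide.id,
            supercontigs=polished,
            consensus=consensus,
            n_mapped_pairs=len(binned.mapped[guide.id]),
            n_unmapped_pairs=len(binned.unmapped),
            n_corrections=len(corrections),
            qc_summary=qc_summary,
        )
    return results


@dataclass
class HaplotypeEvaluation:
    segments: list[AlignmentSegment]
    errors: ErrorReport
    recovery: VariantRecovery


def evaluate_against_truth(
    result: HaplotypeAssembly,
    truth: TruthHaplotype,
    guide: GuideHaplotype,
    min_sv: int = 1,
    repeat_intervals: list[tuple[int, int]] | None = None,
    other_truth: TruthHaplotype | None = None,
) -> HaplotypeEvaluation:
    """Align a consensus to its ground truth and score errors and novel
    variant recovery; guide-filled bases are excluded from the error
    denominator."""
    cons = result.consensus
    segments = align_to_truth(
        cons.consensus.upper(), truth.sequence, qname=result.guide_id, tname=truth.id
    )
    errors = call_errors(
        segments,
        truth.sequence,
        repeat_intervals=repeat_intervals,
        min_sv=min_sv,
        assembled_mask=cons.gap_mask,
        other_hap=other_truth.sequence if other_truth else None,
    )
    recovery = recover_novel_variants(cons.consensus, truth, guide)
    return HaplotypeEvaluation(segments, errors, recovery)
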