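"""Ordering, orienting and consensus emission against a guide haplotype.

Supercontigs are anchored to the guide with exact k-mer matches clustered by
guide position; each placement carries a *location score* (fraction of the
contig's anchored bases supporting its best cluster) and an *orientation
score* (majority-strand fraction within that cluster).  Low-confidence
placements are dropped by the score filter — drop iff
``location < 0.1`` or (``location < 0.3`` and ``orientation < 0.75``) —
which is what keeps spurious large structural variants out of the consensus.
Surviving contigs are ordered on the guide, inter-contig gaps are optionally
closed by mini-assembly of locally anchored read pairs, and a single
continuous consensus record is emitted; the remaining gaps are filled with
guide sequence (lowercase) or N runs, and contigs that could not be placed
are reported as separate records.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from ._align import SeqIndex, colinear_chain
from ._seq import revcomp
from .dbgasm import AssemblyParams, Contig, _find_overlap, assemble_reads
from .haplobin import ReadPlacement
from .simforge import GuideHaplotype, ReadPair


@dataclass(frozen=True)
class ScaffoldParams:
    anchor_k: int = 21
    anchor_step: int = 7
    cluster_gap: int = 5000
    loc_hard: float = 0.1
    loc_soft: float = 0.3
    orient_min: float = 0.75
    gap_policy: str = "guide"  # guide | N
    close_gaps: bool = True
    gapclose_k: int = 31
    gapclose_flank: int = 400


@dataclass(frozen=True)
class Placement:
    contig_id: str
    guide_interval: tuple[int, int]
    strand: str
    location_score: float
    orientation_score: float
    #: (position in oriented contig, guide position) anchor pairs of the
    #: winning cluster's majority strand, sorted by guide position
    anchors: tuple[tuple[int, int], ...] = ()

    def __post_init__(self):
        if not (0 <= self.location_score <= 1 and 0 <= self.orientation_score <= 1):
            raise ValueError("scores must lie in [0, 1]")


@dataclass
class ConsensusAssembly:
    """One continuous guide-ordered consensus plus unplaced contigs.

    Assembled bases are uppercase; guide-filled gap bases are lowercase (or
    ``N`` under the N policy).  ``gap_mask`` partitions the consensus into
    (start, end, kind) intervals with kind ``assembled`` or ``filled``.
    """

    guide_id: str
    consensus: str
    gap_mask: list[tuple[int, int, str]]
    unplaced: list[Contig]

    @property
    def assembled_length(self) -> int:
        return sum(e - s for s, e, kind in self.gap_mask if kind == "assembled")


def anchor_contigs(
    contigs: list[Contig],
    guide: GuideHaplotype,
    params: ScaffoldParams | None = None,
) -> list[Placement]:
    """Anchor each contig on the guide and score its best location cluster.

    Contigs with no exact anchors receive no placement (novel sequence).
    """
    params = params or ScaffoldParams()
    k, step = params.anchor_k, params.anchor_step
    idx = SeqIndex(guide.id, guide.sequence, k=k, max_hits=2)
    placements: list[Placement] = []
    for c in contigs:
        # anchors: (qpos_in_oriented_frame, guide_pos, strand); only k-mers
        # unique in the guide anchor — repeat-copy hits would inflate the
        # placement interval and corrupt overlap trimming
        anchors: list[tuple[int, int, str]] = []
        anchored_q: set[int] = set()  # original-frame anchored kmer starts
        for strand in "+-":
            s = c.sequence if strand == "+" else revcomp(c.sequence)
            for q in range(0, len(s) - k + 1, step):
                hits = idx.index.get(s[q : q + k])
                if not hits or len(hits) > 1:
                    continue
                qo = q if strand == "+" else len(s) - k - q
                anchored_q.add(qo)
                for t in hits:
                    anchors.append((q, t, strand))
        if not anchors:
            continue
        anchors.sort(key=lambda a: a[1])
        # cluster by guide-position gaps
        clusters: list[list[tuple[int, int, str]]] = [[anchors[0]]]
        for a in anchors[1:]:
            if a[1] - clusters[-1][-1][1] > params.cluster_gap:
                clusters.append([a])
            else:
                clusters[-1].append(a)

        def cluster_weight(cl):
            return len({(q if st == "+" else len(c.sequence) - k - q) for q, t, st in cl})

        best = max(clusters, key=cluster_weight)
        n_plus = len({q for q, t, st in best if st == "+"})
        n_minus = len({q for q, t, st in best if st == "-"})
        strand = "+" if n_plus >= n_minus else "-"
        orientation = max(n_plus, n_minus) / max(1, n_plus + n_minus)
        location = cluster_weight(best) / max(1, len(anchored_q))
        # within the winning cluster, keep only a colinear (q and t both
        # increasing) anchor chain: a locally rearranged contig would
        # otherwise yield a nonsense interval
        major = colinear_chain([(q, t) for q, t, st in best if st == strand])
        if not major:
            continue
        # extrapolate the anchored span to the full contig extent along the
        # diagonal, so abutting contigs register as abutting on the guide
        q0, t0 = major[0]
        qn, tn = major[-1]
        interval = (max(0, t0 - q0), tn + (len(c.sequence) - qn))
        placements.append(
            Placement(
                c.id,
                interval,
                strand,
                location,
                orientation,
                tuple(sorted(major, key=lambda a: a[1])),
            )
        )
    return placements


def filter_placements(
    placements: list[Placement], params: ScaffoldParams | None = None
) -> list[Placement]:
    """Apply the placement-confidence filter: drop iff location < 0.1, or
    location < 0.3 with orientation < 0.75."""
    p = params or ScaffoldParams()
    return [
        pl
        for pl in placements
        if not (
            pl.location_score < p.loc_hard
            or (pl.location_score < p.loc_soft and pl.orientation_score < p.orient_min)
        )
    ]


@dataclass
class _Segment:
    seq: str
    t_start: int
    t_end: int


def _oriented(contig: Contig, placement: Placement) -> str:
    return contig.sequence if placement.strand == "+" else revcomp(contig.sequence)


def _trim_left(seg_seq: str, anchors, new_t: int):
    """Cut the oriented sequence so its placement starts at ``new_t``,
    extrapolating along the local anchor diagonal.

    Returns (sequence, new_start, shifted_anchors) or None when nothing of
    the segment survives."""
    for q, t in sorted(anchors, key=lambda a: a[1]):
        if t >= new_t:
            cut = max(0, new_t - (t - q))
            if cut >= len(seg_seq):
                return None
            kept = [(aq - cut, at) for aq, at in anchors if aq - cut >= 0]
            return seg_seq[cut:], (t - q) + cut, kept
    return None


def _trim_right(seg_seq: str, anchors, k: int, new_t: int):
    for q, t in sorted(anchors, key=lambda a: a[1], reverse=True):
        if t + k <= new_t:
            est_end = t + (len(seg_seq) - q)
            cut = max(0, est_end - new_t)
            if cut >= len(seg_seq):
                return None
            new_len = len(seg_seq) - cut
            kept = [(aq, at) for aq, at in anchors if aq + k <= new_len]
            return seg_seq[:new_len], est_end - cut, kept
    return None


def _clip_to_anchored_span(
    seg: "_Segment", pl: Placement, anchor_k: int, slack: int = 60
) -> Placement:
    """Cut a placed segment down to its guide-anchored span (plus slack).

    Long unanchored heads/tails are almost always the *other* copy of a
    near-identical duplication picked up by overlap merging; the copy's true
    locus is covered by its own contig, so clipping here prevents duplicated
    or chimeric sequence from entering the consensus.  Honest contig ends
    extend only a few bases past their outermost unique anchor and are left
    alone by the slack."""
    if not pl.anchors:
        return pl
    qs = min(q for q, _ in pl.anchors)
    qe = max(q for q, _ in pl.anchors) + anchor_k
    head = max(0, qs - slack)
    tail = min(len(seg.seq), qe + slack)
    if head == 0 and tail == len(seg.seq):
        return pl
    seg.t_start += head
    seg.t_end -= len(seg.seq) - tail
    seg.seq = seg.seq[head:tail]
    from dataclasses import replace as _replace

    return _replace(
        pl, anchors=tuple((q - head, t) for q, t in pl.anchors)
    )


def order_and_trim(
    placements: list[Placement],
    contigs: dict[str, Contig],
    anchor_k: int = 21,
) -> list[_Segment]:
    """Order placements on the guide and resolve overlaps.

    Overlap losers (lower location score, then shorter contig, then id) are
    trimmed back to the winner's boundary; contigs wholly shadowed are
    dropped.
    """
    ranked = sorted(
        placements, key=lambda p: (p.guide_interval[0], p.guide_interval[1])
    )
    # each entry: [segment, placement, live anchor list (oriented frame)]
    segments: list[list] = []
    for pl in ranked:
        c = contigs[pl.contig_id]
        seg = _Segment(_oriented(c, pl), *pl.guide_interval)
        pl = _clip_to_anchored_span(seg, pl, anchor_k)
        anchors = list(pl.anchors)
        if segments:
            prev_seg, prev_pl, prev_anchors = segments[-1]
            if seg.t_start < prev_seg.t_end:  # overlap on the guide
                prev_wins = (
                    prev_pl.location_score,
                    len(contigs[prev_pl.contig_id].sequence),
                    prev_pl.contig_id,
                ) >= (pl.location_score, len(c.sequence), pl.contig_id)
                if prev_wins:
                    trimmed = _trim_left(seg.seq, anchors, prev_seg.t_end)
                    if trimmed is None:
                        continue
                    seg.seq, seg.t_start, anchors = trimmed
                    if seg.t_start >= seg.t_end:
                        continue
                else:
                    trimmed = _trim_right(
                        prev_seg.seq, prev_anchors, anchor_k, seg.t_start
                    )
                    if trimmed is None:
                        segments.pop()
                    else:
                        prev_seg.seq, prev_seg.t_end, segments[-1][2] = trimmed
        segments.append([seg, pl, anchors])
    return _reconcile_junctions([s for s, _, _ in segments])


def _reconcile_junctions(
    segments: list["_Segment"],
    max_gap: int = 300,
    min_overlap: int = 25,
    min_identity: float = 0.97,
) -> list["_Segment"]:
    """Splice out sequence duplicated across adjacent contig junctions.

    Anchor-based intervals underestimate contig extents inside repeats (only
    guide-unique k-mers anchor), so two neighbours can both carry a copy of
    the same repeat flank; when their placements sit within ``max_gap`` on
    the guide and a qualifying suffix-prefix overlap exists, the neighbours
    are merged over it."""
    if not segments:
        return segments
    out = [segments[0]]
    for nxt in segments[1:]:
        cur = out[-1]
        if nxt.t_start - cur.t_end <= max_gap:
            ov = _find_overlap(cur.seq[-800:], nxt.seq[:800], min_overlap, min_identity)
            if ov:
                cur.seq = cur.seq + nxt.seq[ov:]
                cur.t_end = max(cur.t_end, nxt.t_end)
                continue
        out.append(nxt)
    return out


def close_gaps(
    segments: list[_Segment],
    pairs_by_id: dict[str, ReadPair],
    guide_placements: list[ReadPlacement],
    params: ScaffoldParams | None = None,
) -> list[_Segment]:
    """Close inter-contig gaps by local mini-assembly.

    For every gap, pairs with a mate anchored in either flank contribute both
    mates to a small de Bruijn assembly; a local contig bridging both flanks
    with >= 40 bp overlaps at >= 99 % identity replaces the gap.
    """
    params = params or ScaffoldParams()
    if len(segments) < 2:
        return segments
    flank = params.gapclose_flank
    out = [segments[0]]
    mini = AssemblyParams(k=params.gapclose_k, min_kmer_cov=2)
    for nxt in segments[1:]:
        cur = out[-1]
        gap_lo, gap_hi = cur.t_end, nxt.t_start
        if gap_hi <= gap_lo:
            out.append(nxt)
            continue
        reads: list[str] = []
        for rp in guide_placements:
            if rp.pos < gap_hi + flank and rp.end > gap_lo - flank:
                pair = pairs_by_id.get(rp.read_id)
                if pair is not None:
                    reads.append(pair.seq1)
                    reads.append(pair.seq2)
        if not reads:
            out.append(nxt)
            continue
        bridged = False
        for m in assemble_reads(reads, mini, source_bin="GAP"):
            for seq in (m.sequence, revcomp(m.sequence)):
                ov1 = _find_overlap(cur.seq[-2000:], seq, 40, 0.99)
                if not ov1:
                    continue
                ov2 = _find_overlap(seq, nxt.seq[:2000], 40, 0.99)
                if not ov2:
                    continue
                cur.seq = cur.seq + seq[ov1:] + nxt.seq[ov2:]
                cur.t_end = nxt.t_end
                bridged = True
                break
            if bridged:
                break
        if not bridged:
            out.append(nxt)
    return out


def emit_consensus(
    segments: list[_Segment],
    guide: GuideHaplotype,
    unplaced: list[Contig],
    gap_policy: str = "guide",
) -> ConsensusAssembly:
    """Concatenate ordered segments into one consensus record, filling
    remaining gaps from the guide (lowercase) or with N runs sized to the
    guide gap; unplaced contigs ride along as separate records."""
    pieces: list[str] = []
    mask: list[tuple[int, int, str]] = []
    cursor = 0  # guide coordinate
    offset = 0  # consensus coordinate

    def fill(lo: int, hi: int):
        nonlocal offset
        if hi <= lo:
            return
        src = guide.sequence[lo:hi].lower() if gap_policy == "guide" else "N" * (hi - lo)
        pieces.append(src)
        mask.append((offset, offset + len(src), "filled"))
        offset += len(src)

    for seg in segments:
        fill(cursor, seg.t_start)
        pieces.append(seg.seq.upper())
        mask.append((offset, offset + len(seg.seq), "assembled"))
        offset += len(seg.seq)
        cursor = max(cursor, seg.t_end)
    fill(cursor, len(guide.sequence))

    return ConsensusAssembly(guide.id, "".join(pieces), mask, list(unplaced))


def scaffold(
    contigs: list[Contig],
    guide: GuideHaplotype,
    pairs_by_id: dict[str, ReadPair] | None = None,
    guide_placements: list[ReadPlacement] | None = None,
    params: ScaffoldParams | None = None,
) -> ConsensusAssembly:
    """Full scaffolding stage: anchor, filter, order/trim, close gaps, emit."""
    params = params or ScaffoldParams()
    placements = anchor_contigs(contigs, guide, params)
    placements = filter_placements(placements, params)
    placed_ids = {p.contig_id for p in placements}
    unplaced = [c for c in contigs if c.id not in placed_ids]
    by_id = {c.id: c for c in contigs}
    segments = order_and_trim(placements, by_id, anchor_k=params.anchor_k)
    if params.close_gaps and pairs_by_id and guide_placements:
        segments = close_gaps(segments, pairs_by_id, guide_placements, params)
    return emit_consensus(segments, guide, unplaced, params.gap_policy)
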