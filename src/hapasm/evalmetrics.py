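"""Assembly statistics, truth-based error taxonomy, novel-variant recovery,
k-mer diversity, and dot-plot (PAF) export.

Error accounting follows the assembly-to-truth convention: the consensus is
aligned to the ground-truth haplotype, substitution mismatches are counted
as base-call error bases, INDELs of at least ``min_sv`` bases as structural
error bases (split into repeat-associated and non-repeat by overlap with a
repeat annotation), and every category is expressed as a percentage of the
assembled sequence length.  Bases filled from the guide rather than
assembled are excluded from both the numerator and the denominator by
default.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import edlib
import numpy as np

from ._align import cigar_stats, colinear_chain
from ._seq import canonical, revcomp
from .simforge import GuideHaplotype, TruthHaplotype, Variant

import re

_CIG = re.compile(r"(\d+)([=XID])")


# --------------------------------------------------------------------------
# assembly statistics


@dataclass(frozen=True)
class AssemblyStats:
    n_contigs: int
    n50: int
    total_length: int


def n50(lengths: list[int]) -> int:
    """Smallest length L such that contigs of length >= L sum to at least
    half the total assembly length."""
    if not lengths:
        raise ValueError("n50 of an empty length set is undefined")
    total = sum(lengths)
    acc = 0
    for L in sorted(lengths, reverse=True):
        acc += L
        if 2 * acc >= total:
            return L
    return min(lengths)  # unreachable; guards float weirdness


def assembly_stats(lengths: list[int]) -> AssemblyStats:
    return AssemblyStats(len(lengths), n50(lengths), sum(lengths))


# --------------------------------------------------------------------------
# assembly-to-truth alignment


@dataclass(frozen=True)
class VariantEvent:
    kind: str  # SUB | INS | DEL  (relative to the truth/target)
    qpos: int  # position on the query (assembly)
    tpos: int  # position on the target (truth)
    length: int
    q_allele: str = ""
    t_allele: str = ""


@dataclass
class AlignmentSegment:
    """A colinear alignment segment in PAF-like coordinates (query forward)."""

    qname: str
    qlen: int
    qstart: int
    qend: int
    strand: str
    tname: str
    tlen: int
    tstart: int
    tend: int
    matches: int
    block_len: int
    events: list[VariantEvent] = field(default_factory=list)


def _anchors(query: str, target_index: dict[str, list[int]], k: int, step: int):
    out = []
    for q in range(0, len(query) - k + 1, step):
        hits = target_index.get(query[q : q + k])
        if hits and len(hits) == 1:
            out.append((q, hits[0]))
    return out




def _align_piece(q: str, t: str, qoff: int, toff: int, events: list[VariantEvent]):
    """Globally align two inter-anchor pieces, appending variant events;
    returns the number of matching bases.

    Common prefixes/suffixes are stripped first so a clean size difference
    becomes one INDEL event instead of an arbitrary split of equal-cost
    gap placements."""
    if not q and not t:
        return 0
    if not q:
        events.append(VariantEvent("DEL", qoff, toff, len(t), "", t))
        return 0
    if not t:
        events.append(VariantEvent("INS", qoff, toff, len(q), q, ""))
        return 0
    if q == t:
        return len(q)
    p = 0
    while p < len(q) and p < len(t) and q[p] == t[p]:
        p += 1
    s = 0
    while s < len(q) - p and s < len(t) - p and q[len(q) - 1 - s] == t[len(t) - 1 - s]:
        s += 1
    if p or s:
        inner = _align_piece(q[p : len(q) - s], t[p : len(t) - s], qoff + p, toff + p, events)
        return p + s + inner
    res = edlib.align(q, t, mode="NW", task="path")
    qp, tp = 0, 0
    matches = 0
    for n, op in _CIG.findall(res["cigar"]):
        n = int(n)
        if op == "=":
            matches += n
            qp += n
            tp += n
        elif op == "X":
            for m in range(n):
                events.append(
                    VariantEvent(
                        "SUB", qoff + qp + m, toff + tp + m, 1, q[qp + m], t[tp + m]
                    )
                )
            qp += n
            tp += n
        elif op == "I":  # query has extra bases
            events.append(VariantEvent("INS", qoff + qp, toff + tp, n, q[qp : qp + n], ""))
            qp += n
        else:  # D: target has extra bases
            events.append(VariantEvent("DEL", qoff + qp, toff + tp, n, "", t[tp : tp + n]))
            tp += n
    return matches


def align_to_truth(
    query: str,
    truth: str,
    qname: str = "assembly",
    tname: str = "truth",
    k: int = 51,
    step: int = 13,
) -> list[AlignmentSegment]:
    """Align an assembly to its ground truth by unique-anchor chaining with
    banded global alignment of the inter-anchor pieces.

    Both orientations of the query are tried; the one with the longer anchor
    chain wins.  Returns colinear segments carrying per-base variant events.
    """
    if not query or not truth:
        raise ValueError("align_to_truth needs non-empty sequences")
    tindex: dict[str, list[int]] = {}
    for i in range(len(truth) - k + 1):
        kmer = truth[i : i + k]
        hits = tindex.get(kmer)
        if hits is None:
            tindex[kmer] = [i]
        elif len(hits) < 3:
            hits.append(i)

    best_chain: list[tuple[int, int]] = []
    best_strand = "+"
    for strand in "+-":
        oriented = query if strand == "+" else revcomp(query)
        chain = colinear_chain(_anchors(oriented, tindex, k, step))
        if len(chain) > len(best_chain):
            best_chain, best_strand = chain, strand
    oriented = query if best_strand == "+" else revcomp(query)
    if not best_chain:
        return []
    # keep only non-overlapping anchors so every inter-anchor piece is a
    # well-defined pair of substrings (anchors are sampled more densely
    # than k, and a diagonal shift between overlapping anchors would
    # otherwise be lost)
    filtered = [best_chain[0]]
    for q, t in best_chain[1:]:
        pq, pt = filtered[-1]
        if q >= pq + k and t >= pt + k:
            filtered.append((q, t))
    best_chain = filtered

    events: list[VariantEvent] = []
    matches = 0
    # leading flank
    q0, t0 = best_chain[0]
    lead_q = oriented[:q0]
    lead_t = truth[max(0, t0 - len(lead_q) - 200) : t0]
    qstart, tstart = q0, t0
    if lead_q and lead_t:
        res = edlib.align(lead_q[::-1], lead_t[::-1], mode="SHW", task="path")
        if res["editDistance"] >= 0 and res["locations"]:
            span = res["locations"][0][1] + 1
            matches += _align_piece(
                lead_q, lead_t[len(lead_t) - span :], 0, t0 - span, events
            )
            qstart, tstart = 0, t0 - span

    prev_q, prev_t = best_chain[0]
    matches += k
    for q, t in best_chain[1:]:
        matches += _align_piece(
            oriented[prev_q + k : q], truth[prev_t + k : t], prev_q + k, prev_t + k, events
        )
        matches += k
        prev_q, prev_t = q, t

    # trailing flank
    tail_q = oriented[prev_q + k :]
    tail_t = truth[prev_t + k : prev_t + k + len(tail_q) + 200]
    qend, tend = prev_q + k, prev_t + k
    if tail_q and tail_t:
        res = edlib.align(tail_q, tail_t, mode="SHW", task="path")
        if res["editDistance"] >= 0 and res["locations"]:
            span = res["locations"][0][1] + 1
            matches += _align_piece(tail_q, tail_t[:span], qend, tend, events)
            qend += len(tail_q)
            tend += span
    elif tail_q:
        qend += 0

    # report query coordinates on the original (forward) query frame
    if best_strand == "-":
        L = len(query)
        for i, ev in enumerate(events):
            q_fwd = L - ev.qpos - (ev.length if ev.kind != "DEL" else 0)
            events[i] = VariantEvent(
                ev.kind, q_fwd, ev.tpos, ev.length, revcomp(ev.q_allele), ev.t_allele
            )
        qstart, qend = L - qend, L - qstart

    seg = AlignmentSegment(
        qname,
        len(query),
        qstart,
        qend,
        best_strand,
        tname,
        len(truth),
        tstart,
        tend,
        matches,
        max(qend - qstart, tend - tstart),
        sorted(events, key=lambda e: e.tpos),
    )
    return [seg]


# --------------------------------------------------------------------------
# error taxonomy


@dataclass
class ErrorReport:
    assembled_length: int
    base_call_error_pct: float
    sv_nonrepeat_pct: float
    sv_repeat_pct: float
    total_error_pct: float
    large_false_sv_count: int
    other_hap_bp: int = 0
    sv_records: list[tuple[int, str, int, bool]] = field(default_factory=list)


def find_low_complexity(seq: str, min_homopolymer: int = 10, max_period: int = 6) -> list[tuple[int, int]]:
    """Simple internal low-complexity annotator: homopolymer runs of at
    least ``min_homopolymer`` bases and tandem repeats of period <= 6
    spanning at least three unit copies."""
    intervals: list[tuple[int, int]] = []
    n = len(seq)
    for period in range(1, max_period + 1):
        i = period
        while i < n:
            if seq[i] != seq[i - period]:
                i += 1
                continue
            j = i
            while j < n and seq[j] == seq[j - period]:
                j += 1
            span = j - (i - period)  # seed unit + matching run
            floor = min_homopolymer if period == 1 else 3 * period
            if span >= floor:
                intervals.append((i - period, j))
            i = j + 1
    if not intervals:
        return []
    intervals.sort()
    merged = [list(intervals[0])]
    for s, e in intervals[1:]:
        if s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [tuple(x) for x in merged]


def _in_intervals(pos: int, intervals: list[tuple[int, int]]) -> bool:
    import bisect

    if not intervals:
        return False
    i = bisect.bisect_right(intervals, (pos, math.inf)) - 1
    return i >= 0 and intervals[i][0] <= pos < intervals[i][1]


def call_errors(
    segments: list[AlignmentSegment],
    truth: str,
    repeat_intervals: list[tuple[int, int]] | None = None,
    min_sv: int = 1,
    assembled_mask: list[tuple[int, int, str]] | None = None,
    assembled_length: int | None = None,
    other_hap: str | None = None,
) -> ErrorReport:
    """Tally error bases from assembly-to-truth alignment segments.

    Substitutions count one base each; INDELs of at least ``min_sv`` bases
    count their full length, classified repeat vs non-repeat by the repeat
    annotation (the internal low-complexity annotator of the truth when none
    is given).  When an ``assembled_mask`` (consensus-coordinate intervals)
    is supplied, events inside guide-filled intervals are excluded and the
    assembled length excludes filled bases.  With ``other_hap`` given,
    substitution errors whose allele-in-context matches the other haplotype
    are flagged rather than blamed on assembly (tallied in ``other_hap_bp``
    but still counted in the error percentages, which measure distance to
    this haplotype's truth).
    """
    if repeat_intervals is None:
        repeat_intervals = find_low_complexity(truth)
    repeat_intervals = sorted(repeat_intervals)
    filled = (
        sorted((s, e) for s, e, kind in assembled_mask if kind == "filled")
        if assembled_mask
        else []
    )
    if assembled_length is None:
        if assembled_mask:
            assembled_length = sum(
                e - s for s, e, kind in assembled_mask if kind == "assembled"
            )
        else:
            assembled_length = sum(seg.qend - seg.qstart for seg in segments)
    base_bp = 0
    sv_rep = 0
    sv_nonrep = 0
    large = 0
    other_bp = 0
    sv_records: list[tuple[int, str, int, bool]] = []
    for seg in segments:
        for ev in seg.events:
            if _in_intervals(ev.qpos, filled):
                continue
            if ev.kind == "SUB":
                base_bp += 1
                if other_hap and ev.q_allele:
                    # does the consensus allele sit in the other haplotype?
                    ctx_q = 10
                    lo = max(0, ev.tpos - ctx_q)
                    ctx = truth[lo : ev.tpos] + ev.q_allele + truth[ev.tpos + 1 : ev.tpos + 1 + ctx_q]
                    if ctx in other_hap or revcomp(ctx) in other_hap:
                        other_bp += 1
            else:
                if ev.length < min_sv:
                    continue
                in_rep = _in_intervals(ev.tpos, repeat_intervals) or _in_intervals(
                    max(0, ev.tpos - 1), repeat_intervals
                )
                if in_rep:
                    sv_rep += ev.length
                else:
                    sv_nonrep += ev.length
                if ev.length > 1000:
                    large += 1
                sv_records.append((ev.tpos, ev.kind, ev.length, in_rep))
    denom = max(1, assembled_length)
    return ErrorReport(
        assembled_length=assembled_length,
        base_call_error_pct=100.0 * base_bp / denom,
        sv_nonrepeat_pct=100.0 * sv_nonrep / denom,
        sv_repeat_pct=100.0 * sv_rep / denom,
        total_error_pct=100.0 * (base_bp + sv_rep + sv_nonrep) / denom,
        large_false_sv_count=large,
        other_hap_bp=other_bp,
        sv_records=sv_records,
    )


# --------------------------------------------------------------------------
# novel-variant recovery


@dataclass(frozen=True)
class VariantRecovery:
    n_novel_snv: int
    n_recovered_snv: int
    n_novel_sv: int
    n_recovered_sv: int

    @property
    def snv_frac(self) -> float:
        return self.n_recovered_snv / self.n_novel_snv if self.n_novel_snv else math.nan

    @property
    def sv_frac(self) -> float:
        return self.n_recovered_sv / self.n_novel_sv if self.n_novel_sv else math.nan


def _truth_positions(truth: TruthHaplotype) -> list[int]:
    """Truth-coordinate position of every ledger variant."""
    out = []
    delta = 0
    for v in truth.ledger:
        out.append(v.pos0 + delta)
        delta += len(v.alt) - len(v.ref)
    return out


def _context_found(context: str, core: str, flank_l: str, flank_r: str, haystack: str) -> bool:
    if context in haystack or revcomp(context) in haystack:
        return True
    # tolerate nearby mismatches in the flanks but never in the core
    for hay in (haystack,):
        for probe, fl, fr in ((core, flank_l, flank_r), (revcomp(core), revcomp(flank_r), revcomp(flank_l))):
            start = 0
            while True:
                i = hay.find(probe, start)
                if i < 0:
                    break
                start = i + 1
                left = hay[max(0, i - len(fl)) : i]
                right = hay[i + len(probe) : i + len(probe) + len(fr)]
                if len(left) < len(fl) or len(right) < len(fr):
                    continue
                dl = edlib.align(fl, left, mode="NW", task="distance")["editDistance"]
                dr = edlib.align(fr, right, mode="NW", task="distance")["editDistance"]
                if dl <= 2 and dr <= 2:
                    return True
    return False


def recover_novel_variants(
    consensus: str,
    truth: TruthHaplotype,
    guide: GuideHaplotype,
    flank: int = 25,
    core_flank: int = 7,
) -> VariantRecovery:
    """Score which ledger variants the consensus actually carries.

    For every variant the expected alt-allele context (variant plus
    ``flank``-bp truth flanks) is searched in the consensus, exactly first,
    then allowing up to two edits per flank while requiring the core
    (variant +/- ``core_flank``) to match exactly.  Fractions are reported
    separately for SNVs and INDEL/SV records.
    """
    hay = consensus.upper()
    tseq = truth.sequence
    n_snv = n_rec_snv = n_sv = n_rec_sv = 0
    for v, tpos in zip(truth.ledger, _truth_positions(truth)):
        alt_len = len(v.alt) if v.type != "SNV" else 1
        ctx = tseq[max(0, tpos - flank) : tpos + alt_len + flank]
        core = tseq[max(0, tpos - core_flank) : tpos + alt_len + core_flank]
        fl = tseq[max(0, tpos - flank) : max(0, tpos - core_flank)]
        fr = tseq[tpos + alt_len + core_flank : tpos + alt_len + flank]
        found = _context_found(ctx, core, fl, fr, hay)
        if v.type == "SNV":
            n_snv += 1
            n_rec_snv += found
        else:
            n_sv += 1
            n_rec_sv += found
    return VariantRecovery(n_snv, n_rec_snv, n_sv, n_rec_sv)


# --------------------------------------------------------------------------
# k-mer diversity and PAF export


def unique_kmer_count(reads: list[str], k: int = 150) -> int:
    """Number of distinct canonical k-mers across a read set."""
    seen: set[str] = set()
    for r in reads:
        for i in range(len(r) - k + 1):
            seen.add(canonical(r[i : i + k]))
    return len(seen)


def paf_line(seg: AlignmentSegment, mapq: int = 60) -> str:
    return "\t".join(
        str(x)
        for x in (
            seg.qname,
            seg.qlen,
            seg.qstart,
            seg.qend,
            seg.strand,
            seg.tname,
            seg.tlen,
            seg.tstart,
            seg.tend,
            seg.matches,
            seg.block_len,
            mapq,
        )
    )


def dotplot_export(segments: list[AlignmentSegment], path) -> None:
    """Write alignment segments as minimal 12-column PAF suitable for
    dot-plot rendering."""
    with open(path, "w") as fh:
        for seg in segments:
            fh.write(paf_line(seg) + "\n")


def read_paf(path) -> list[AlignmentSegment]:
    out = []
    with open(path) as fh:
        for line in fh:
            f = line.rstrip("\n").split("\t")
            out.append(
                AlignmentSegment(
                    f[0], int(f[1]), int(f[2]), int(f[3]), f[4], f[5],
                    int(f[6]), int(f[7]), int(f[8]), int(f[9]), int(f[10]),
                )
            )
    return out
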