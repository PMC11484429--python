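"""Seed-and-extend alignment kernel.

A light-weight internal aligner used for read binning, polishing, contig
filtering and truth evaluation: exact k-mer seeding on an indexed target,
diagonal voting, then banded extension with edlib.  Alignment scores follow
end-to-end short-read-mapper conventions: match 0, mismatch -6, gap open -5,
gap extend -3, so the familiar ``L,0,-0.6`` linear threshold (-0.6 per read
base) is directly meaningful.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import edlib

from ._seq import revcomp

MISMATCH = 6
GAP_OPEN = 5
GAP_EXTEND = 3

_CIG = re.compile(r"(\d+)([=XIDM])")


class SeqIndex:
    """Exact k-mer position index over one target sequence (forward strand)."""

    def __init__(self, name: str, sequence: str, k: int = 21, max_hits: int = 8):
        if len(sequence) < k:
            raise ValueError(f"target {name} shorter than seed length {k}")
        self.name = name
        self.sequence = sequence
        self.k = k
        self.max_hits = max_hits
        idx: dict[str, list[int]] = {}
        for i in range(len(sequence) - k + 1):
            kmer = sequence[i : i + k]
            hits = idx.get(kmer)
            if hits is None:
                idx[kmer] = [i]
            elif len(hits) < max_hits:
                hits.append(i)
        self.index = idx


@dataclass(frozen=True)
class Hit:
    """One alignment of a query against an indexed target."""

    target: str
    pos: int  # 0-based target start
    end: int  # half-open target end
    strand: str
    score: int  # 0 for perfect; negative otherwise
    matches: int
    cigar: str  # edlib extended cigar of query (oriented) vs target window


def cigar_stats(cigar: str) -> tuple[int, int, int, int]:
    """(matches, mismatches, gap_opens, gap_bases) from an extended cigar."""
    m = x = opens = gapb = 0
    for n, op in _CIG.findall(cigar):
        n = int(n)
        if op == "=" or op == "M":
            m += n
        elif op == "X":
            x += n
        else:
            opens += 1
            gapb += n
    return m, x, opens, gapb


def score_cigar(cigar: str) -> int:
    _, x, opens, gapb = cigar_stats(cigar)
    return -(MISMATCH * x + GAP_OPEN * opens + GAP_EXTEND * gapb)


def _candidate_diagonals(seq: str, index: SeqIndex, n_seeds: int = 5, top: int = 3):
    """Vote for (strand, diagonal) candidates from sampled exact seeds."""
    k = index.k
    L = len(seq)
    if L < k:
        return []
    offsets = sorted({int(i * (L - k) / max(1, n_seeds - 1)) for i in range(n_seeds)})
    votes: dict[tuple[str, int], int] = {}
    for strand, s in (("+", seq), ("-", revcomp(seq))):
        for off in offsets:
            for pos in index.index.get(s[off : off + k], ()):
                votes[(strand, pos - off)] = votes.get((strand, pos - off), 0) + 1
    if not votes:
        return []
    # merge nearby diagonals (small indels shift them slightly)
    merged: dict[tuple[str, int], int] = {}
    for (strand, diag), v in sorted(votes.items()):
        for d in merged:
            if d[0] == strand and abs(d[1] - diag) <= 30:
                merged[d] += v
                break
        else:
            merged[(strand, diag)] = v
    ranked = sorted(merged.items(), key=lambda kv: -kv[1])
    return [d for d, _ in ranked[:top]]


def best_hit(seq: str, index: SeqIndex, pad: int = 30, min_identity: float = 0.0) -> Hit | None:
    """Best placement of ``seq`` on the indexed target, or None if no seed
    matches.  The returned score is the raw best, not thresholded."""
    target = index.sequence
    L = len(seq)
    best: Hit | None = None
    for strand, diag in _candidate_diagonals(seq, index):
        s = seq if strand == "+" else revcomp(seq)
        lo = max(0, diag - pad)
        hi = min(len(target), diag + L + pad)
        if diag >= 0 and diag + L <= len(target) and target[diag : diag + L] == s:
            hit = Hit(index.name, diag, diag + L, strand, 0, L, f"{L}=")
        else:
            res = edlib.align(s, target[lo:hi], mode="HW", task="path")
            if res["editDistance"] < 0 or not res["locations"]:
                continue
            t0, t1 = res["locations"][0]
            cig = res["cigar"]
            m, *_ = cigar_stats(cig)
            hit = Hit(index.name, lo + t0, lo + t1 + 1, strand, score_cigar(cig), m, cig)
        if best is None or hit.score > best.score:
            best = hit
        if best.score == 0:
            break
    if best is not None and min_identity > 0 and best.matches < min_identity * L:
        return None
    return best


def colinear_chain(anchors: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Longest chain of (q, t) anchors increasing in both coordinates
    (patience LIS on t after sorting by q)."""
    import bisect

    anchors = sorted(anchors)
    if not anchors:
        return []
    tails: list[int] = []
    tails_idx: list[int] = []
    back: list[int] = [-1] * len(anchors)
    for i, (q, t) in enumerate(anchors):
        j = bisect.bisect_left(tails, t)
        if j == len(tails):
            tails.append(t)
            tails_idx.append(i)
        else:
            tails[j] = t
            tails_idx[j] = i
        back[i] = tails_idx[j - 1] if j > 0 else -1
    chain = []
    i = tails_idx[len(tails) - 1]
    while i >= 0:
        chain.append(anchors[i])
        i = back[i]
    return chain[::-1]


def infix_identity(query: str, target: str) -> float:
    """Identity of the best infix alignment of query into target (strandless:
    the better of forward and reverse complement)."""
    best = 0.0
    for s in (query, revcomp(query)):
        res = edlib.align(s, target, mode="HW", task="distance")
        if res["editDistance"] >= 0:
            best = max(best, 1.0 - res["editDistance"] / len(query))
    return best


def global_identity(a: str, b: str) -> float:
    """Identity of a global (NW) alignment of two strings."""
    if not a and not b:
        return 1.0
    res = edlib.align(a, b, mode="NW", task="distance")
    return 1.0 - res["editDistance"] / max(len(a), len(b))
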