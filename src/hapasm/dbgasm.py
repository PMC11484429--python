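"""De Bruijn graph assembly of binned read sets.

Reads from each superblock (and from the unmapped bin) are assembled
independently: k-mers are counted strand-collapsed, weak k-mers are dropped,
the graph is cleaned (tip clipping, simple-bubble popping), and maximal
unbranched paths become contigs.  Unmapped-bin contigs that belong to the
alternative haplotype or to off-target sequence are filtered out, the
remaining contigs are merged into non-redundant supercontigs by
suffix-prefix overlap, and a final pileup-majority polishing pass corrects
residual consensus errors using the individual's own reads.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from ._align import SeqIndex, cigar_stats, global_identity
from ._seq import BASES, revcomp
from .simforge import GuideHaplotype, ReadPair

import edlib
import re

_CIG = re.compile(r"(\d+)([=XID])")


class EmptyGraphError(RuntimeError):
    """Raised when no solid k-mers survive cleaning; callers may retry with a
    lower ``min_kmer_cov``."""


@dataclass(frozen=True)
class AssemblyParams:
    """De Bruijn assembly parameters.

    ``k`` is the graph order (odd, 51 by default — the value that assembles
    both haplotype-mapping and non-mapping 150 bp read sets well);
    ``min_kmer_cov`` drops sequencing-error k-mers; ``tip_len_max`` and
    ``bubble_identity`` control graph cleaning; contigs shorter than
    ``min_contig_len`` are discarded.  The ``2k`` defaults follow common
    short-read assembler practice.
    """

    k: int = 51
    min_kmer_cov: int = 3
    tip_len_max: int | None = None  # default 2k
    bubble_identity: float = 0.95
    min_contig_len: int | None = None  # default 2k

    def __post_init__(self):
        if self.k % 2 == 0 or not (15 <= self.k <= 127):
            raise ValueError("k must be odd and within [15, 127]")
        if self.min_kmer_cov < 1:
            raise ValueError("min_kmer_cov must be >= 1")

    @property
    def tip_len(self) -> int:
        return self.tip_len_max if self.tip_len_max is not None else 2 * self.k

    @property
    def min_len(self) -> int:
        return self.min_contig_len if self.min_contig_len is not None else 2 * self.k


@dataclass(frozen=True)
class Contig:
    id: str
    sequence: str
    mean_cov: float
    source_bin: str  # e.g. "MAPPED:sb3" or "UNMAPPED"

    def __len__(self) -> int:
        return len(self.sequence)


# --------------------------------------------------------------------------
# k-mer counting


def count_kmers(reads: list[str], k: int) -> dict[str, int]:
    """Canonical (strand-collapsed) k-mer counts over a read set.

    Total instance count equals sum over reads of ``max(0, len - k + 1)``.
    Returns an empty multiset when k exceeds every read length.
    """
    counts: dict[str, int] = {}
    get = counts.get
    for read in reads:
        n = len(read) - k + 1
        if n <= 0:
            continue
        rc = revcomp(read)
        L = len(read)
        for i in range(n):
            kmer = read[i : i + k]
            r = rc[L - k - i : L - i]
            if r < kmer:
                kmer = r
            counts[kmer] = get(kmer, 0) + 1
    return counts


def solid_kmers(counts: dict[str, int], min_cov: int) -> dict[str, int]:
    return {km: c for km, c in counts.items() if c >= min_cov}


def estimate_best_k(
    reads: list[str], k_candidates: list[int], min_kmer_cov: int = 3
) -> int:
    """Pick the candidate k maximizing the number of distinct solid k-mers
    (abundance >= ``min_kmer_cov``); ties go to the larger k."""
    if not reads:
        raise ValueError("no reads")
    if not k_candidates:
        raise ValueError("at least one candidate k required")
    best_k, best_n = None, -1
    for k in sorted(k_candidates):
        if k % 2 == 0:
            raise ValueError("candidate k values must be odd")
        n = len(solid_kmers(count_kmers(reads, k), min_kmer_cov))
        if n >= best_n and n > 0:
            best_k, best_n = k, n
    if best_k is None:
        raise ValueError("no candidate k yields any solid kmer")
    return best_k


# --------------------------------------------------------------------------
# graph


@dataclass
class KmerGraph:
    """Directed de Bruijn graph over (k-1)-mer nodes.

    ``edges`` stores *both* orientations of every canonical k-mer with its
    canonical multiplicity, so membership tests and traversal need no
    re-canonicalization."""

    k: int
    edges: dict[str, int]

    @classmethod
    def from_solid(cls, solid: dict[str, int], k: int) -> "KmerGraph":
        edges: dict[str, int] = {}
        for km, c in solid.items():
            edges[km] = c
            edges[revcomp(km)] = c
        return cls(k=k, edges=edges)

    def out_edges(self, node: str) -> list[str]:
        e = self.edges
        return [node + b for b in BASES if (node + b) in e]

    def in_edges(self, node: str) -> list[str]:
        e = self.edges
        return [b + node for b in BASES if (b + node) in e]

    def drop(self, kmers) -> None:
        for km in kmers:
            self.edges.pop(km, None)
            self.edges.pop(revcomp(km), None)


@dataclass
class _Unitig:
    path: list[str]  # oriented edge kmers
    seq: str
    start_node: str
    end_node: str
    mean_cov: float


def _make_unitig(g: KmerGraph, path: list[str]) -> _Unitig:
    seq = path[0] + "".join(e[-1] for e in path[1:])
    cov = float(np.mean([g.edges[e] for e in path]))
    return _Unitig(path, seq, path[0][:-1], path[-1][1:], cov)


def _unitigs(g: KmerGraph) -> list[_Unitig]:
    """Maximal unbranched paths; each unitig appears once per orientation."""
    seen: set[str] = set()
    out: list[_Unitig] = []

    def walk(e0: str) -> list[str]:
        path = [e0]
        seen.add(e0)
        node = e0[1:]
        while len(g.in_edges(node)) == 1:
            nxt = g.out_edges(node)
            if len(nxt) != 1 or nxt[0] in seen:
                break
            path.append(nxt[0])
            seen.add(nxt[0])
            node = nxt[0][1:]
        return path

    for e0 in list(g.edges):
        if e0 in seen:
            continue
        src = e0[:-1]
        if len(g.in_edges(src)) == 1 and len(g.out_edges(src)) == 1:
            continue  # internal edge; reached from a proper start
        out.append(_make_unitig(g, walk(e0)))
    # anything left sits on isolated cycles
    for e0 in list(g.edges):
        if e0 not in seen:
            out.append(_make_unitig(g, walk(e0)))
    return out


def _clip_tips(g: KmerGraph, tip_len: int) -> int:
    clipped = 0
    for u in _unitigs(g):
        if len(u.seq) >= tip_len:
            continue
        if any(e not in g.edges for e in u.path):
            continue  # already removed via its reverse complement
        dead_front = len(g.in_edges(u.start_node)) == 0
        dead_back = len(g.out_edges(u.end_node)) == 0
        if dead_front != dead_back:  # attached at exactly one end
            g.drop(u.path)
            clipped += 1
    return clipped


def _pop_bubbles(g: KmerGraph, identity: float) -> int:
    popped = 0
    groups: dict[tuple[str, str], list[_Unitig]] = {}
    for u in _unitigs(g):
        groups.setdefault((u.start_node, u.end_node), []).append(u)
    for arms in groups.values():
        if len(arms) < 2:
            continue
        arms.sort(key=lambda u: (-u.mean_cov, u.seq))
        keeper = arms[0]
        for arm in arms[1:]:
            if any(e not in g.edges for e in arm.path):
                continue
            if global_identity(arm.seq, keeper.seq) >= identity:
                g.drop(arm.path)
                popped += 1
    return popped


def build_and_clean(solid: dict[str, int], params: AssemblyParams) -> KmerGraph:
    """Build the graph from a solid spectrum and clean it: clip short
    dead-end tips iteratively, then pop near-identical simple bubbles,
    keeping the higher-coverage arm."""
    if not solid:
        raise EmptyGraphError("empty solid k-mer spectrum")
    g = KmerGraph.from_solid(solid, params.k)
    for _ in range(3):
        if _clip_tips(g, params.tip_len) == 0:
            break
    _pop_bubbles(g, params.bubble_identity)
    if _pop_bubbles(g, params.bubble_identity):
        pass  # a popped arm can reveal one more layer; one extra round is enough
    for _ in range(2):
        if _clip_tips(g, params.tip_len) == 0:
            break
    if not g.edges:
        raise EmptyGraphError("graph empty after cleaning")
    return g


def extract_contigs(
    g: KmerGraph, params: AssemblyParams, source_bin: str = "UNKNOWN"
) -> list[Contig]:
    """One contig per maximal unbranched path, reverse-complement
    deduplicated, in deterministic order (length desc, then sequence)."""
    uniq: dict[str, _Unitig] = {}
    for u in _unitigs(g):
        rc = revcomp(u.seq)
        key = u.seq if u.seq <= rc else rc
        uniq.setdefault(key, u)
    contigs = []
    for key, u in uniq.items():
        if len(key) < params.min_len:
            continue
        contigs.append((key, u.mean_cov))
    contigs.sort(key=lambda t: (-len(t[0]), t[0]))
    return [
        Contig(f"{source_bin.lower()}_c{i}", seq, cov, source_bin)
        for i, (seq, cov) in enumerate(contigs)
    ]


def assemble_reads(
    reads: list[str],
    params: AssemblyParams,
    source_bin: str = "UNKNOWN",
    retry_min_cov: int = 1,
) -> list[Contig]:
    """Count, clean, and extract contigs for one read bin.

    If the spectrum is empty at ``min_kmer_cov`` (shallow bins), the bin is
    retried once at ``retry_min_cov`` before giving up with an empty list.
    """
    counts = count_kmers(reads, params.k)
    for mc in dict.fromkeys([params.min_kmer_cov, retry_min_cov]):
        solid = solid_kmers(counts, mc)
        if not solid:
            continue
        try:
            g = build_and_clean(solid, params)
        except EmptyGraphError:
            continue
        return extract_contigs(g, params, source_bin)
    return []


# --------------------------------------------------------------------------
# cross-haplotype / off-target contig filtering


def _best_span(seq: str, index: SeqIndex, step: int = 25):
    """Largest query span supported by diagonal-consistent exact anchors.

    Returns (qstart, qend, tstart, tend) or None."""
    k = index.k
    hits: list[tuple[int, int]] = []  # (qpos, tpos) forward sense
    for s, flip in ((seq, False), (revcomp(seq), True)):
        cur = []
        for q in range(0, len(s) - k + 1, step):
            for t in index.index.get(s[q : q + k], ()):
                cur.append((q, t))
        if len(cur) > len(hits):
            hits = cur
    if not hits:
        return None
    # cluster by diagonal
    hits.sort(key=lambda h: (h[1] - h[0], h[0]))
    best = None
    i = 0
    while i < len(hits):
        j = i
        while (
            j + 1 < len(hits)
            and abs((hits[j + 1][1] - hits[j + 1][0]) - (hits[i][1] - hits[i][0])) <= 200
        ):
            j += 1
        cluster = hits[i : j + 1]
        qs, qe = min(h[0] for h in cluster), max(h[0] for h in cluster) + k
        ts, te = min(h[1] for h in cluster), max(h[1] for h in cluster) + k
        if best is None or (qe - qs) > (best[1] - best[0]):
            best = (qs, qe, ts, te)
        i = j + 1
    return best


def filter_cross_contigs(
    contigs: list[Contig],
    alt_guide: GuideHaplotype | None = None,
    decoys: list[tuple[str, str]] | None = None,
    min_len_frac: float = 0.5,
    min_identity: float = 0.9,
) -> list[Contig]:
    """Remove unmapped-bin contigs belonging to the alternative haplotype or
    to off-target (decoy) sequence.

    A contig is removed iff at least ``min_len_frac`` of its length aligns to
    a filter target at >= ``min_identity`` identity.
    """
    targets: list[SeqIndex] = []
    if alt_guide is not None:
        targets.append(SeqIndex(alt_guide.id, alt_guide.sequence, k=21))
    for name, seq in decoys or []:
        targets.append(SeqIndex(name, seq, k=21))
    if not targets:
        return list(contigs)

    kept = []
    for c in contigs:
        removed = False
        for idx in targets:
            span = _best_span(c.sequence, idx)
            if span is None:
                continue
            qs, qe, ts, te = span
            if (qe - qs) < min_len_frac * len(c.sequence):
                continue
            pad = 100
            window = idx.sequence[max(0, ts - pad) : te + pad]
            frag = c.sequence[qs:qe]
            ident = max(
                _hw_identity(frag, window), _hw_identity(revcomp(frag), window)
            )
            if ident >= min_identity and (qe - qs) >= min_len_frac * len(c.sequence):
                removed = True
                break
        if not removed:
            kept.append(c)
    return kept


def _hw_identity(query: str, target: str) -> float:
    res = edlib.align(query, target, mode="HW", task="distance")
    if res["editDistance"] < 0:
        return 0.0
    return 1.0 - res["editDistance"] / len(query)


# --------------------------------------------------------------------------
# overlap merging


def _find_overlap(a: str, b: str, min_overlap: int, min_identity: float) -> int:
    """Length of a qualifying suffix(a)/prefix(b) overlap, or 0."""
    probe = b[: min(21, len(b))]
    start = 0
    best = 0
    while True:
        s = a.find(probe, start)
        if s < 0:
            break
        ov = len(a) - s
        if min_overlap <= ov <= len(b):
            if global_identity(a[s:], b[:ov]) >= min_identity:
                best = max(best, ov)
        start = s + 1
    return best


def _bin_interval(bin_label: str) -> tuple[int, int] | None:
    if bin_label.startswith("MAPPED:"):
        body = bin_label.split(":", 1)[1]
        if "-" in body:
            try:
                s, e = body.split("-")
                return int(s), int(e)
            except ValueError:
                return None
    return None


def _bins_compatible(bins_a: frozenset[str], bins_b: frozenset[str]) -> bool:
    if bins_a & bins_b:
        return False
    ivs_a = [iv for iv in map(_bin_interval, bins_a) if iv is not None]
    ivs_b = [iv for iv in map(_bin_interval, bins_b) if iv is not None]
    if not ivs_a or not ivs_b:
        return True  # unmapped/gap bins join freely
    return any(
        a[0] < b[1] and b[0] < a[1] for a in ivs_a for b in ivs_b
    )


def merge_contigs(
    contigs: list[Contig],
    min_overlap: int = 40,
    min_identity: float = 0.99,
    respect_bins: bool = True,
) -> list[Contig]:
    """Greedy overlap-layout merge into non-redundant supercontigs.

    Near-identical containments collapse onto the container; remaining
    suffix-prefix overlaps of at least ``min_overlap`` bases at
    >= ``min_identity`` identity are joined longest-first until none
    qualify.

    With ``respect_bins`` (default) two contigs from the *same* source bin
    are never end-joined: they come from one de Bruijn graph that already
    decided to keep them apart (a branch point), and re-joining them across
    their shared (k-1)-mer would undo that — the classic path through a
    collapsed near-identical duplication.  Mapped-bin contigs additionally
    only join when their superblock guide intervals overlap (labels of the
    form ``MAPPED:<start>-<end>``): an honest sequence overlap cannot exist
    between disjoint guide windows, so any such candidate is a repeat
    artifact.  Unmapped/gap-bin contigs merge freely.
    """
    seqs: list[tuple[str, float, frozenset[str]]] = [
        (c.sequence, c.mean_cov, frozenset([c.source_bin])) for c in contigs
    ]
    seqs.sort(key=lambda t: (-len(t[0]), t[0]))

    # containment collapse
    survivors: list[tuple[str, float, frozenset[str]]] = []
    for seq, cov, bins in seqs:
        contained = False
        for big, _, _ in survivors:
            if len(seq) > len(big):
                continue
            maxdist = int((1 - min_identity) * len(seq))
            for s in (seq, revcomp(seq)):
                res = edlib.align(s, big, mode="HW", task="distance", k=maxdist)
                if 0 <= res["editDistance"] <= maxdist:
                    contained = True
                    break
            if contained:
                break
        if not contained:
            survivors.append((seq, cov, bins))

    # iterative greedy overlap joining
    while True:
        best = None  # (ov, i, j, oriented_b)
        n = len(survivors)
        for i in range(n):
            a = survivors[i][0]
            for j in range(n):
                if i == j:
                    continue
                if respect_bins and not _bins_compatible(
                    survivors[i][2], survivors[j][2]
                ):
                    continue
                for b in (survivors[j][0], revcomp(survivors[j][0])):
                    ov = _find_overlap(a, b, min_overlap, min_identity)
                    if ov and (best is None or ov > best[0]):
                        best = (ov, i, j, b)
        if best is None:
            break
        ov, i, j, b = best
        a, cov_a, bins_a = survivors[i]
        _, cov_b, bins_b = survivors[j]
        merged = a + b[ov:]
        cov = (cov_a * len(a) + cov_b * len(b)) / (len(a) + len(b))
        survivors = [s for idx, s in enumerate(survivors) if idx not in (i, j)]
        survivors.append((merged, cov, bins_a | bins_b))

    survivors.sort(key=lambda t: (-len(t[0]), t[0]))
    return [
        Contig(f"super_{i}", seq, cov, "MERGED")
        for i, (seq, cov, _) in enumerate(survivors)
    ]


# --------------------------------------------------------------------------
# pileup polishing


@dataclass(frozen=True)
class Correction:
    contig_id: str
    pos: int
    kind: str  # SUB | INS | DEL
    old: str
    new: str
    depth: int
    support: int


class _MultiIndex:
    """Joint 21-mer index over a contig set."""

    def __init__(self, contigs: list[Contig], k: int = 21, max_hits: int = 8):
        self.k = k
        self.contigs = contigs
        idx: dict[str, list[tuple[int, int]]] = {}
        for ci, c in enumerate(contigs):
            seq = c.sequence
            for i in range(len(seq) - k + 1):
                kmer = seq[i : i + k]
                hits = idx.get(kmer)
                if hits is None:
                    idx[kmer] = [(ci, i)]
                elif len(hits) < max_hits:
                    hits.append((ci, i))
        self.index = idx


def _locate(seq: str, midx: _MultiIndex, pad: int = 30):
    """Best placement of a read across the contig set.

    Returns (contig_idx, tstart, cigar, oriented_seq) or None."""
    k = midx.k
    L = len(seq)
    if L < k:
        return None
    offsets = sorted({0, L // 2, L - k})
    votes: dict[tuple[int, str, int], int] = {}
    for strand, s in (("+", seq), ("-", revcomp(seq))):
        for off in offsets:
            for ci, t in midx.index.get(s[off : off + k], ()):
                key = (ci, strand, t - off)
                votes[key] = votes.get(key, 0) + 1
    if not votes:
        return None
    best_out = None
    best_score = None
    for (ci, strand, diag), v in sorted(votes.items(), key=lambda kv: -kv[1])[:3]:
        target = midx.contigs[ci].sequence
        s = seq if strand == "+" else revcomp(seq)
        if 0 <= diag and diag + L <= len(target) and target[diag : diag + L] == s:
            return (ci, diag, f"{L}=", s)
        lo = max(0, diag - pad)
        hi = min(len(target), diag + L + pad)
        res = edlib.align(s, target[lo:hi], mode="HW", task="path")
        if res["editDistance"] < 0 or not res["locations"]:
            continue
        if best_score is None or res["editDistance"] < best_score:
            best_score = res["editDistance"]
            t0 = res["locations"][0][0]
            best_out = (ci, lo + t0, res["cigar"], s)
    return best_out


def polish(
    contigs: list[Contig],
    pairs: list[ReadPair],
    min_depth: int = 5,
    min_frac: float = 0.7,
) -> tuple[list[Contig], list[Correction]]:
    """Majority-vote pileup polishing.

    Reads are realigned to the contigs; a column is rewritten to the majority
    allele (substitution or small INDEL) when depth >= ``min_depth`` and the
    majority fraction reaches ``min_frac``.  Columns already matching the
    pileup majority are never touched.
    """
    if not contigs:
        return [], []
    midx = _MultiIndex(contigs)
    cov = [np.zeros(len(c.sequence) + 1, dtype=np.int32) for c in contigs]
    subs: dict[tuple[int, int], dict[str, int]] = {}
    inss: dict[tuple[int, int], dict[str, int]] = {}
    dels: dict[tuple[int, int], dict[int, int]] = {}

    for pair in pairs:
        for seq in (pair.seq1, pair.seq2):
            loc = _locate(seq, midx)
            if loc is None:
                continue
            ci, tstart, cigar, s = loc
            cov_arr = cov[ci]
            t = tstart
            q = 0
            for n, op in _CIG.findall(cigar):
                n = int(n)
                if op == "=":
                    cov_arr[t] += 1
                    cov_arr[t + n] -= 1
                    t += n
                    q += n
                elif op == "X":
                    cov_arr[t] += 1
                    cov_arr[t + n] -= 1
                    for m in range(n):
                        d = subs.setdefault((ci, t + m), {})
                        b = s[q + m]
                        d[b] = d.get(b, 0) + 1
                    t += n
                    q += n
                elif op == "I":  # extra bases in the read
                    d = inss.setdefault((ci, t), {})
                    ins = s[q : q + n]
                    d[ins] = d.get(ins, 0) + 1
                    q += n
                elif op == "D":  # bases missing from the read
                    cov_arr[t] += 1
                    cov_arr[t + n] -= 1
                    d = dels.setdefault((ci, t), {})
                    d[n] = d.get(n, 0) + 1
                    t += n

    depth = [np.cumsum(c[:-1]) for c in cov]
    corrections: list[Correction] = []
    edits: dict[int, list[tuple[int, str, str, str, int, int]]] = {}

    def consider(ci, pos, kind, old, new, support):
        d = int(depth[ci][pos]) if pos < len(depth[ci]) else 0
        if d >= min_depth and support >= min_frac * d:
            edits.setdefault(ci, []).append((pos, kind, old, new, d, support))

    for (ci, pos), alleles in subs.items():
        base, support = max(alleles.items(), key=lambda kv: (kv[1], kv[0]))
        if base != contigs[ci].sequence[pos]:
            consider(ci, pos, "SUB", contigs[ci].sequence[pos], base, support)
    for (ci, pos), alleles in inss.items():
        ins, support = max(alleles.items(), key=lambda kv: (kv[1], kv[0]))
        consider(ci, pos, "INS", "", ins, support)
    for (ci, pos), lens in dels.items():
        ln, support = max(lens.items(), key=lambda kv: (kv[1], kv[0]))
        consider(ci, pos, "DEL", contigs[ci].sequence[pos : pos + ln], "", support)

    polished = []
    for ci, c in enumerate(contigs):
        if ci not in edits:
            polished.append(c)
            continue
        seq = c.sequence
        for pos, kind, old, new, d, support in sorted(edits[ci], reverse=True):
            if kind == "SUB":
                seq = seq[:pos] + new + seq[pos + 1 :]
            elif kind == "INS":
                seq = seq[:pos] + new + seq[pos:]
            else:
                seq = seq[:pos] + seq[pos + len(old) :]
            corrections.append(Correction(c.id, pos, kind, old, new, d, support))
        polished.append(Contig(c.id, seq, c.mean_cov, c.source_bin))
    return polished, corrections
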