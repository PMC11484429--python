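"""Guide-haplotype assignment, read binning, and superblock construction.

An individual's two first-field class II alleles select one or two guide
haplotypes (one when the genotype is first-field homozygous or both alleles
belong to the same structural class).  QC-surviving read pairs are then
aligned to every assigned guide and partitioned: each pair lands in exactly
one of mapped(guide A), mapped(guide B) or unmapped.  When two guides are
assigned the mapped bins are competitive — a pair that maps to both guides
is binned with the better-scoring one — which is what lets the per-guide
assemblies stay haplotype-pure wherever the guides are distinguishable.

Mapped placements are finally grouped into overlapping *blocks* and merged
into bounded *superblocks*, the units of local de novo assembly.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

from ._align import Hit, SeqIndex, best_hit
from .simforge import GuideHaplotype, ReadPair


@dataclass(frozen=True)
class HaplotypeMap:
    """Genotype-to-guide configuration.

    ``allele_to_class`` maps first-field allele labels (e.g. ``"03"``) to
    structural class names; ``class_to_guide`` maps class names to guide
    ids.  Alleles of classes without a dedicated guide fall back to
    ``fallback_guide`` (the generic-reference route).
    """

    allele_to_class: dict[str, str]
    class_to_guide: dict[str, str]
    fallback_guide: str

    def __post_init__(self):
        for allele, cls in self.allele_to_class.items():
            if cls not in self.class_to_guide:
                raise ValueError(f"class {cls} (allele {allele}) has no guide")

    def guide_for(self, allele: str) -> str:
        cls = self.allele_to_class.get(allele)
        if cls is None:
            return self.fallback_guide
        return self.class_to_guide[cls]


@dataclass(frozen=True)
class BMHAssignment:
    sample_id: str
    guide_ids: tuple[str, ...]  # one or two

    def __post_init__(self):
        if not (1 <= len(self.guide_ids) <= 2):
            raise ValueError("an individual is assigned one or two guides")


def assign_bmh(
    sample_id: str, allele1: str, allele2: str, hmap: HaplotypeMap, strict: bool = False
) -> BMHAssignment:
    """Assign best-matched guide haplotype(s) from a first-field genotype.

    Homozygous genotypes — and heterozygous genotypes whose alleles share a
    structural class — receive a single guide; otherwise two.  With
    ``strict`` an allele missing from the map raises instead of falling back.
    """
    if strict:
        for a in (allele1, allele2):
            if a not in hmap.allele_to_class:
                raise KeyError(f"allele {a!r} not present in the haplotype map")
    g1, g2 = hmap.guide_for(allele1), hmap.guide_for(allele2)
    guides = (g1,) if g1 == g2 else (g1, g2)
    return BMHAssignment(sample_id, guides)


def min_score(read_length: int) -> float:
    """Minimum accepted end-to-end alignment score for a read of the given
    length — the linear function 0 + (-0.6) * length."""
    if read_length <= 0:
        raise ValueError("read_length must be positive")
    return -0.6 * read_length


@dataclass(frozen=True)
class ReadPlacement:
    read_id: str
    mate: int  # 1 or 2
    guide_id: str
    pos: int
    end: int
    strand: str
    score: float
    mapped: bool


@dataclass
class BinnedReads:
    """Result of the per-individual binning stage."""

    #: guide id -> pairs binned to that guide
    mapped: dict[str, list[ReadPair]]
    #: guide id -> placements of the mapped mates of its pairs
    placements: dict[str, list[ReadPlacement]]
    #: pairs mapping to no assigned guide
    unmapped: list[ReadPair]


def map_mate(seq: str, index: SeqIndex) -> Hit | None:
    """Best placement of a single mate on a guide (raw score, unthresholded)."""
    return best_hit(seq, index)


def _pair_hits(pair: ReadPair, index: SeqIndex):
    h1 = best_hit(pair.seq1, index) if len(pair.seq1) >= index.k else None
    h2 = best_hit(pair.seq2, index) if len(pair.seq2) >= index.k else None
    return h1, h2


def _pair_score(pair: ReadPair, h1: Hit | None, h2: Hit | None) -> float:
    # missing placements contribute a hard floor so one well-mapped mate
    # cannot be outvoted by noise
    s1 = h1.score if h1 else -6.0 * len(pair.seq1)
    s2 = h2.score if h2 else -6.0 * len(pair.seq2)
    return s1 + s2


def _pair_mapped(pair: ReadPair, h1: Hit | None, h2: Hit | None) -> bool:
    if h1 and h1.score >= min_score(len(pair.seq1)):
        return True
    return bool(h2 and h2.score >= min_score(len(pair.seq2)))


def bin_pairs(
    pairs: list[ReadPair],
    guides: list[GuideHaplotype],
    k_seed: int = 21,
) -> BinnedReads:
    """Partition pairs among the assigned guides.

    A pair is *mapped* to a guide when either mate reaches the score
    threshold there.  With two guides, a pair mapping to both is assigned to
    the guide with the better summed raw score; exact ties break by a stable
    hash of the read id, so runs are reproducible.
    """
    if not (1 <= len(guides) <= 2):
        raise ValueError("binning runs against one or two guides")
    indexes = {g.id: SeqIndex(g.id, g.sequence, k=k_seed) for g in guides}
    out = BinnedReads(
        mapped={g.id: [] for g in guides},
        placements={g.id: [] for g in guides},
        unmapped=[],
    )
    for pair in pairs:
        per_guide: dict[str, tuple[Hit | None, Hit | None, float, bool]] = {}
        for gid, idx in indexes.items():
            h1, h2 = _pair_hits(pair, idx)
            per_guide[gid] = (h1, h2, _pair_score(pair, h1, h2), _pair_mapped(pair, h1, h2))
        mapped_gids = [gid for gid, v in per_guide.items() if v[3]]
        if not mapped_gids:
            out.unmapped.append(pair)
            continue
        if len(mapped_gids) == 1:
            chosen = mapped_gids[0]
        else:
            scores = {gid: per_guide[gid][2] for gid in mapped_gids}
            best = max(scores.values())
            top = sorted(gid for gid, s in scores.items() if s == best)
            chosen = top[zlib.crc32(pair.id.encode()) % len(top)]
        h1, h2, _, _ = per_guide[chosen]
        out.mapped[chosen].append(pair)
        for mate, h, seq in ((1, h1, pair.seq1), (2, h2, pair.seq2)):
            if h is not None:
                out.placements[chosen].append(
                    ReadPlacement(
                        pair.id, mate, chosen, h.pos, h.end, h.strand,
                        h.score, h.score >= min_score(len(seq)),
                    )
                )
    for gid in out.placements:
        out.placements[gid].sort(key=lambda p: (p.pos, p.end, p.read_id, p.mate))
    return out


@dataclass(frozen=True)
class Superblock:
    guide_id: str
    interval: tuple[int, int]
    member_read_ids: frozenset[str]


def build_superblocks(
    placements: list[ReadPlacement],
    guide: GuideHaplotype,
    max_block: int = 50_000,
    flank: int = 300,
) -> list[Superblock]:
    """Group mapped placements into blocks (maximal transitively-overlapping
    runs), merge blocks separated by at most ``flank`` bases, and split the
    merged regions into superblocks of at most ``max_block`` bases with a
    ``flank``-bp overlap between consecutive superblocks."""
    mapped = [p for p in placements if p.mapped]
    if not mapped:
        return []
    mapped.sort(key=lambda p: (p.pos, p.end))
    # merged regions: union of placement intervals, bridging gaps <= flank
    regions: list[list[int]] = []
    for p in mapped:
        if regions and p.pos <= regions[-1][1] + flank:
            regions[-1][1] = max(regions[-1][1], p.end)
        else:
            regions.append([p.pos, p.end])

    windows: list[tuple[int, int]] = []
    for start, end in regions:
        s = start
        while True:
            e = min(end, s + max_block)
            windows.append((s, min(e, len(guide.sequence))))
            if e >= end:
                break
            s = e - flank

    blocks = []
    for w in windows:
        members = frozenset(
            p.read_id for p in mapped if p.pos < w[1] and p.end > w[0]
        )
        blocks.append(Superblock(guide.id, w, members))
    return blocks
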