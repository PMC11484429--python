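"""Synthetic diploid-region and short-read simulation.

This module fabricates the three inputs the assembler consumes in a
validation experiment:

* a set of *guide haplotypes* — structurally distinct reference sequences
  sharing a common backbone, differing by a large class-defining insertion
  block (the class II DR-region analogue) and optional point divergence;
* *truth haplotypes* — individual-specific sequences derived from a guide by
  introducing novel SNVs and INDELs/SVs, with a complete variant ledger so
  recovery can be scored exactly;
* Illumina-like 150 bp paired-end reads at a requested fold coverage with a
  Gaussian fragment-length model (426 +/- 109 by default) and a uniform
  per-base substitution error model.

All randomness flows through :class:`numpy.random.Generator` seeded
explicitly, so every artefact is byte-reproducible.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field, replace

import numpy as np

from ._seq import BASES, phred_to_ascii, random_dna, revcomp

# --------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class GuideHaplotype:
    """A named guide (reference) haplotype with a structural class label."""

    id: str
    sequence: str
    dr_class: str
    #: 0-based half-open interval of the class-defining insertion block,
    #: or None for classes without one.
    class_insert_interval: tuple[int, int] | None = None

    def __post_init__(self):
        if not self.sequence:
            raise ValueError("guide sequence must be non-empty")
        if self.class_insert_interval is not None:
            s, e = self.class_insert_interval
            if not (0 <= s <= e <= len(self.sequence)):
                raise ValueError("class_insert_interval outside sequence")


@dataclass(frozen=True)
class Variant:
    """One novel difference of a truth haplotype relative to its guide.

    ``pos0`` is 0-based on the *guide*.  SNV: ref/alt are single differing
    bases.  INS: alt is inserted before guide[pos0] (ref empty).  DEL: ref is
    the deleted guide substring (alt empty).
    """

    pos0: int
    type: str  # SNV | INS | DEL
    ref: str
    alt: str

    @property
    def footprint(self) -> tuple[int, int]:
        """Guide interval consumed by this variant (half-open)."""
        if self.type == "DEL":
            return (self.pos0, self.pos0 + len(self.ref))
        return (self.pos0, self.pos0 + 1)

    @property
    def length(self) -> int:
        """Affected length: 1 for SNV, inserted/deleted length otherwise."""
        return 1 if self.type == "SNV" else max(len(self.ref), len(self.alt))


@dataclass(frozen=True)
class TruthHaplotype:
    id: str
    guide_id: str
    sequence: str
    ledger: tuple[Variant, ...]


@dataclass(frozen=True)
class ClassSpec:
    """Specification of one structural haplotype class.

    ``divergence`` is the per-bp substitution rate applied to the shared
    backbone for this class (0 keeps the backbone verbatim); ``insert_len``
    is the length of the class-defining insertion block (0 for the short
    class); ``insert_pos`` defaults to the backbone midpoint.
    """

    name: str
    insert_len: int = 0
    divergence: float = 0.0
    insert_pos: int | None = None


@dataclass(frozen=True)
class SVSpec:
    type: str  # INS | DEL
    length: int
    count: int = 1


@dataclass(frozen=True)
class RepeatConfig:
    """Repeat content embedded in the generated backbone.

    Mirrors the troublesome features of real hyperpolymorphic regions:
    homopolymer runs, short tandem repeats, dispersed near-identical repeat
    copies, and one near-identical (>= 99.9 %) segmental duplication pair
    (the C4A/C4B analogue) that short-read assembly is expected to collapse
    rather than resolve.
    """

    n_homopolymers: int = 4
    homopolymer_len: tuple[int, int] = (15, 30)
    n_tandem: int = 3
    tandem_unit: tuple[int, int] = (2, 6)
    tandem_span: tuple[int, int] = (30, 60)
    n_dispersed_copies: int = 3
    dispersed_len: int = 300
    dispersed_divergence: float = 0.02
    segdup_len: int = 2000
    segdup_divergence: float = 0.0005


@dataclass(frozen=True)
class ReadSimParams:
    """Paired-end simulation parameters (HiSeq-X-like defaults)."""

    read_length: int = 150
    depth_fold: float = 30.0
    fragment_mean: int = 426
    fragment_sd: int = 109
    per_base_error: float = 0.002
    quality_mean: int = 35
    quality_sd: int = 5
    seed: int = 0
    #: "clip": fragments may straddle the region boundaries and are clipped
    #: to it (emulates reads extracted from genome-scale sequencing, uniform
    #: coverage up to the edges); "inner": fragments fall entirely inside.
    edge_mode: str = "clip"

    def __post_init__(self):
        if self.read_length > self.fragment_mean:
            raise ValueError("read_length must not exceed fragment_mean")
        if self.depth_fold <= 0:
            raise ValueError("depth_fold must be positive")
        if not (0 <= self.per_base_error < 0.1):
            raise ValueError("per_base_error must be in [0, 0.1)")


@dataclass(frozen=True)
class ReadPair:
    id: str
    seq1: str
    qual1: str
    seq2: str
    qual2: str


@dataclass(frozen=True)
class PlacementRecord:
    """Ground-truth provenance of one simulated pair."""

    read_id: str
    source_id: str
    fragment_start: int
    strand: str  # '+' : R1 is the leading fragment end on the source strand


# --------------------------------------------------------------------------
# guide construction


def _place_intervals(
    rng: np.random.Generator,
    length: int,
    sizes: list[int],
    taken: list[tuple[int, int]],
    margin: int = 500,
) -> list[tuple[int, int]]:
    """Sample non-overlapping intervals of the given sizes, away from edges."""
    placed = []
    for size in sizes:
        for _ in range(1000):
            s = int(rng.integers(margin, length - margin - size))
            iv = (s, s + size)
            if all(iv[1] + 50 <= a or iv[0] >= b + 50 for a, b in taken):
                taken.append(iv)
                placed.append(iv)
                break
        else:
            raise RuntimeError("could not place repeat interval")
    return placed


def _implant_repeats(
    rng: np.random.Generator, backbone: list[str], cfg: RepeatConfig
) -> list[tuple[int, int, str]]:
    """Overwrite windows of the backbone with repeat tracts; returns BED-style
    (start, end, label) records."""
    length = len(backbone)
    taken: list[tuple[int, int]] = []
    records: list[tuple[int, int, str]] = []

    sizes = [int(rng.integers(*cfg.homopolymer_len)) for _ in range(cfg.n_homopolymers)]
    for iv in _place_intervals(rng, length, sizes, taken):
        base = BASES[rng.integers(0, 4)]
        backbone[iv[0] : iv[1]] = base * (iv[1] - iv[0])
        records.append((*iv, "homopolymer"))

    for _ in range(cfg.n_tandem):
        unit = random_dna(rng, int(rng.integers(*cfg.tandem_unit)))
        span = int(rng.integers(*cfg.tandem_span))
        iv = _place_intervals(rng, length, [span], taken)[0]
        tract = (unit * (span // len(unit) + 1))[:span]
        backbone[iv[0] : iv[1]] = tract
        records.append((*iv, f"tandem_unit{len(unit)}"))

    if cfg.n_dispersed_copies > 0:
        element = random_dna(rng, cfg.dispersed_len)
        ivs = _place_intervals(
            rng, length, [cfg.dispersed_len] * cfg.n_dispersed_copies, taken
        )
        for iv in ivs:
            copy = _point_mutate(rng, element, cfg.dispersed_divergence)
            backbone[iv[0] : iv[1]] = copy
            records.append((*iv, "dispersed_repeat"))

    if cfg.segdup_len > 0:
        src, dst = _place_intervals(rng, length, [cfg.segdup_len] * 2, taken)
        seg = "".join(backbone[src[0] : src[1]])
        backbone[dst[0] : dst[1]] = _point_mutate(rng, seg, cfg.segdup_divergence)
        records.append((*src, "segdup_a"))
        records.append((*dst, "segdup_b"))

    return sorted(records)


def _point_mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    """Substitute bases at the given per-bp rate (always to a different base)."""
    if rate <= 0:
        return seq
    out = list(seq)
    hits = np.nonzero(rng.random(len(seq)) < rate)[0]
    for i in hits:
        out[i] = BASES[(BASES.index(out[i]) + int(rng.integers(1, 4))) % 4]
    return "".join(out)


def make_guide_set(
    seed: int,
    base_length: int,
    classes: list[ClassSpec],
    repeat_config: RepeatConfig | None = None,
) -> tuple[list[GuideHaplotype], list[tuple[int, int, str]]]:
    """Generate one guide haplotype per structural class.

    All guides share a common backbone drawn from ``seed``; each class with
    ``insert_len > 0`` carries its insertion block (generated with backbone
    base composition plus embedded repeat flavour), and ``divergence``
    point-mutates the backbone copy for that class.

    Returns the guides plus repeat-tract records on backbone coordinates.
    """
    if base_length < 20_000:
        raise ValueError("base_length must be at least 20 kb")
    if not classes:
        raise ValueError("at least one class spec required")
    for c in classes:
        if c.insert_len < 0 or base_length <= 0:
            raise ValueError("lengths must be non-negative")
        if c.insert_len >= base_length / 2:
            raise ValueError("class insertion must be shorter than half the backbone")

    cfg = repeat_config if repeat_config is not None else RepeatConfig()
    rng = np.random.default_rng(seed)
    backbone = list(random_dna(rng, base_length))
    repeat_records = _implant_repeats(rng, backbone, cfg)
    backbone_str = "".join(backbone)

    guides = []
    for c in classes:
        crng = np.random.default_rng([seed, zlib.crc32(c.name.encode()) % (2**31)])
        seq = _point_mutate(crng, backbone_str, c.divergence)
        interval = None
        if c.insert_len > 0:
            pos = c.insert_pos if c.insert_pos is not None else base_length // 2
            ins = list(random_dna(crng, c.insert_len))
            # give the insert some repeat flavour of its own
            if c.insert_len >= 2000:
                sub = np.random.default_rng([seed, 7, zlib.crc32(c.name.encode()) % (2**31)])
                _implant_repeats(
                    sub,
                    ins,
                    RepeatConfig(
                        n_homopolymers=1,
                        n_tandem=1,
                        n_dispersed_copies=0,
                        segdup_len=0,
                    ),
                )
            seq = seq[:pos] + "".join(ins) + seq[pos:]
            interval = (pos, pos + c.insert_len)
        guides.append(
            GuideHaplotype(
                id=f"guide_{c.name}",
                sequence=seq,
                dr_class=c.name,
                class_insert_interval=interval,
            )
        )
    return guides, repeat_records


def default_class_pair(insert_len: int = 20_000, divergence: float = 0.01) -> list[ClassSpec]:
    """The canonical two-class study condition: a SHORT class identical to
    the backbone and a LONG class carrying the insertion block plus ~1 %
    backbone point divergence (haplotype classes of hyperpolymorphic regions
    are among the most divergent in the genome)."""
    return [
        ClassSpec("SHORT", insert_len=0, divergence=0.0),
        ClassSpec("LONG", insert_len=insert_len, divergence=divergence),
    ]


# --------------------------------------------------------------------------
# truth haplotypes


def apply_ledger(guide_sequence: str, ledger: tuple[Variant, ...] | list[Variant]) -> str:
    """Replay a variant ledger onto a guide sequence."""
    out = []
    cursor = 0
    for v in sorted(ledger, key=lambda v: v.pos0):
        out.append(guide_sequence[cursor : v.pos0])
        if v.type == "SNV":
            out.append(v.alt)
            cursor = v.pos0 + 1
        elif v.type == "INS":
            out.append(v.alt)
            cursor = v.pos0
        elif v.type == "DEL":
            cursor = v.pos0 + len(v.ref)
        else:
            raise ValueError(f"unknown variant type {v.type}")
    out.append(guide_sequence[cursor:])
    return "".join(out)


def _draw_positions(
    rng: np.random.Generator,
    n: int,
    lo: int,
    hi: int,
    footprints: list[tuple[int, int]],
    size: int = 1,
    pad: int = 2,
) -> list[int]:
    """Draw ``n`` starts in [lo, hi) whose [start, start+size) footprints do
    not collide with existing footprints (padded)."""
    chosen = []
    tries = 0
    while len(chosen) < n:
        tries += 1
        if tries > 200 * n + 1000:
            raise RuntimeError("could not place variants without overlap")
        p = int(rng.integers(lo, hi - size))
        iv = (p - pad, p + size + pad)
        if all(iv[1] <= a or iv[0] >= b for a, b in footprints):
            footprints.append(iv)
            chosen.append(p)
    return chosen


def _make_variants(
    rng: np.random.Generator,
    guide_seq: str,
    snv_rate: float,
    indel_rate: float,
    sv_specs: list[SVSpec],
    edge_exclusion: int,
    footprints: list[tuple[int, int]] | None = None,
) -> list[Variant]:
    L = len(guide_seq)
    lo, hi = edge_exclusion, L - edge_exclusion
    fp = footprints if footprints is not None else []
    variants: list[Variant] = []

    for spec in sv_specs:
        for p in _draw_positions(rng, spec.count, lo, hi, fp, size=spec.length, pad=10):
            if spec.type == "DEL":
                variants.append(Variant(p, "DEL", guide_seq[p : p + spec.length], ""))
            elif spec.type == "INS":
                variants.append(Variant(p, "INS", "", random_dna(rng, spec.length)))
            else:
                raise ValueError(f"unknown SV type {spec.type}")

    n_indel = int(rng.binomial(L, indel_rate)) if indel_rate > 0 else 0
    for p in _draw_positions(rng, n_indel, lo, hi, fp, size=4, pad=5):
        ln = int(rng.integers(1, 4))
        if rng.random() < 0.5:
            variants.append(Variant(p, "DEL", guide_seq[p : p + ln], ""))
        else:
            variants.append(Variant(p, "INS", "", random_dna(rng, ln)))

    n_snv = int(rng.binomial(L, snv_rate)) if snv_rate > 0 else 0
    for p in _draw_positions(rng, n_snv, lo, hi, fp, size=1, pad=2):
        ref = guide_seq[p]
        alt = BASES[(BASES.index(ref) + int(rng.integers(1, 4))) % 4]
        variants.append(Variant(p, "SNV", ref, alt))

    return sorted(variants, key=lambda v: v.pos0)


def mutate_to_truth(
    guide: GuideHaplotype,
    snv_rate: float,
    indel_rate: float,
    sv_specs: list[SVSpec] | None = None,
    seed: int = 0,
    edge_exclusion: int = 150,
    truth_id: str | None = None,
) -> TruthHaplotype:
    """Derive a truth haplotype from a guide by planting novel variants.

    Every introduced difference is recorded in the ledger; replaying the
    ledger onto the guide reproduces the returned sequence exactly.  Variant
    footprints never overlap, and the first/last ``edge_exclusion`` bases are
    left untouched so every variant is coverable by reads.
    """
    for r in (snv_rate, indel_rate):
        if not (0 <= r <= 0.05):
            raise ValueError("rates must be in [0, 0.05]")
    rng = np.random.default_rng(seed)
    ledger = tuple(
        _make_variants(rng, guide.sequence, snv_rate, indel_rate, sv_specs or [], edge_exclusion)
    )
    seq = apply_ledger(guide.sequence, ledger)
    return TruthHaplotype(
        id=truth_id or f"{guide.id}_truth",
        guide_id=guide.id,
        sequence=seq,
        ledger=ledger,
    )


def make_diploid_truths(
    guides: list[GuideHaplotype],
    snv_rate: float,
    indel_rate: float,
    sv_specs: list[SVSpec] | None = None,
    shared_frac: float = 0.5,
    seed: int = 0,
    edge_exclusion: int = 150,
) -> tuple[TruthHaplotype, TruthHaplotype]:
    """Derive the two truth haplotypes of a heterozygous individual.

    A fraction ``shared_frac`` of variants is placed at homologous backbone
    positions on *both* haplotypes with the same allele, emulating the
    identical-by-state variation both chromosomes of a real individual carry
    relative to unrelated guide haplotypes; the remainder is private to one
    haplotype.  Shared positions are expressed in the coordinates of each
    guide (accounting for the class insertion offset).
    """
    if len(guides) != 2:
        raise ValueError("diploid truth generation needs exactly two guides")
    ga, gb = guides
    rng = np.random.default_rng(seed)

    def lift(pos: int, guide: GuideHaplotype) -> int:
        iv = guide.class_insert_interval
        if iv is not None and pos >= iv[0]:
            return pos + (iv[1] - iv[0])
        return pos

    # shared variants drawn in backbone coordinates (guide A has no insert by
    # convention; fall back to the shorter guide as the backbone frame)
    backbone_guide = ga if ga.class_insert_interval is None else gb
    shared_specs = [
        replace(s, count=int(rng.binomial(s.count, shared_frac))) for s in (sv_specs or [])
    ]
    shared = _make_variants(
        rng,
        backbone_guide.sequence,
        snv_rate * shared_frac,
        indel_rate * shared_frac,
        [s for s in shared_specs if s.count > 0],
        edge_exclusion,
    )

    truths = []
    for hap_idx, guide in enumerate((ga, gb)):
        lifted: list[Variant] = []
        fp: list[tuple[int, int]] = []
        for v in shared:
            p = lift(v.pos0, guide)
            if p + max(1, len(v.ref)) + 160 > len(guide.sequence):
                continue
            if v.type == "SNV":
                ref = guide.sequence[p]
                if ref == v.alt:  # class divergence already carries the allele
                    continue
                lifted.append(Variant(p, "SNV", ref, v.alt))
            elif v.type == "DEL":
                lifted.append(Variant(p, "DEL", guide.sequence[p : p + len(v.ref)], ""))
            else:
                lifted.append(Variant(p, "INS", "", v.alt))
            a, b = lifted[-1].footprint
            fp.append((a - 2, b + 2))

        private_specs = []
        for s, sh in zip(sv_specs or [], shared_specs):
            n_priv = s.count - sh.count
            if n_priv > 0:
                private_specs.append(replace(s, count=n_priv))
        private = _make_variants(
            np.random.default_rng([seed, 11 + hap_idx]),
            guide.sequence,
            snv_rate * (1 - shared_frac),
            indel_rate * (1 - shared_frac),
            private_specs,
            edge_exclusion,
            footprints=fp,
        )
        ledger = tuple(sorted(lifted + private, key=lambda v: v.pos0))
        truths.append(
            TruthHaplotype(
                id=f"{guide.id}_truth",
                guide_id=guide.id,
                sequence=apply_ledger(guide.sequence, ledger),
                ledger=ledger,
            )
        )
    return truths[0], truths[1]


# --------------------------------------------------------------------------
# read simulation

_B32 = np.frombuffer(b"ACGT", dtype=np.uint8)


def simulate_reads(
    truths: list[TruthHaplotype] | TruthHaplotype,
    params: ReadSimParams,
) -> tuple[list[ReadPair], list[PlacementRecord]]:
    """Simulate paired-end reads from one (haploid) or two (diploid) truth
    haplotypes, sampling each with equal probability.

    Pair count is ``ceil(total_length * depth / (2 * read_length))``;
    fragment lengths are Gaussian truncated to
    ``[read_length, 2 * fragment_mean]``; R1 reads the leading fragment end
    and R2 the reverse complement of the trailing end (roles swap when the
    fragment derives from the minus strand).  Substitution errors are applied
    uniformly at ``per_base_error``.
    """
    if isinstance(truths, TruthHaplotype):
        truths = [truths]
    if not (1 <= len(truths) <= 2):
        raise ValueError("simulate_reads takes one or two truth haplotypes")
    for t in truths:
        if len(t.sequence) < params.fragment_mean:
            raise ValueError(f"truth {t.id} shorter than the mean fragment length")

    rl = params.read_length
    total = sum(len(t.sequence) for t in truths)
    n_pairs = math.ceil(total * params.depth_fold / (2 * rl))
    rng = np.random.default_rng(params.seed)

    sources = rng.integers(0, len(truths), size=n_pairs)
    frag_lens = np.clip(
        np.rint(rng.normal(params.fragment_mean, params.fragment_sd, size=n_pairs)),
        rl,
        2 * params.fragment_mean,
    ).astype(np.int64)
    minus = rng.random(n_pairs) < 0.5

    pairs: list[ReadPair] = []
    ledger: list[PlacementRecord] = []
    err = params.per_base_error
    min_keep = 40  # minimum in-region fragment overlap
    for i in range(n_pairs):
        t = truths[sources[i]]
        flen = min(int(frag_lens[i]), len(t.sequence))
        if params.edge_mode == "clip":
            start0 = int(rng.integers(-(flen - min_keep), len(t.sequence) - min_keep + 1))
            start = max(0, start0)
            frag = t.sequence[start : start0 + flen]
        else:
            start = int(rng.integers(0, len(t.sequence) - flen + 1))
            frag = t.sequence[start : start + flen]
        fwd, rev = frag[:rl], revcomp(frag[-rl:])
        if minus[i]:
            # fragment sequenced from the minus strand: roles swap
            fwd, rev = revcomp(frag)[:rl], frag[:rl]
        r1, r2 = fwd, rev
        if err > 0:
            r1 = _add_errors(rng, r1, err)
            r2 = _add_errors(rng, r2, err)
        q1 = _draw_quals(rng, len(r1), params.quality_mean, params.quality_sd)
        q2 = _draw_quals(rng, len(r2), params.quality_mean, params.quality_sd)
        rid = f"sim_{i}"
        pairs.append(ReadPair(rid, r1, q1, r2, q2))
        ledger.append(PlacementRecord(rid, t.id, start, "-" if minus[i] else "+"))
    return pairs, ledger


def _add_errors(rng: np.random.Generator, seq: str, rate: float) -> str:
    hits = np.nonzero(rng.random(len(seq)) < rate)[0]
    if len(hits) == 0:
        return seq
    out = list(seq)
    for i in hits:
        out[i] = BASES[(BASES.index(out[i]) + int(rng.integers(1, 4))) % 4]
    return "".join(out)


def _draw_quals(rng: np.random.Generator, n: int, mean: int, sd: int) -> str:
    q = np.clip(np.rint(rng.normal(mean, sd, size=n)), 2, 41).astype(np.int64)
    return phred_to_ascii(q)
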