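"""Read-level quality control: poly-G artifact removal, seeded subsampling
and sliding-window quality trimming.

The stage assumes sequencing adapters were removed upstream.  Filters only
drop or truncate reads; sequence content is never rewritten.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .simforge import ReadPair


@dataclass(frozen=True)
class QCParams:
    """Thresholds for the QC stage.

    ``polyg_min_run``: minimum run of consecutive G (or C on the opposite
    sense) that marks a poly-G artifact.  ``lead_trail_q``: phred floor for
    leading/trailing base stripping.  ``window_len``/``window_meanq``:
    sliding-window truncation (cut at the first window whose mean quality
    drops below the threshold).  ``min_len``: shortest surviving mate.
    """

    polyg_min_run: int = 20
    sample_pairs: int | None = None  # None = keep all
    sample_seed: int = 0
    lead_trail_q: int = 3
    window_len: int = 4
    window_meanq: int = 15
    min_len: int = 40
    polyg_both_senses: bool = True

    def __post_init__(self):
        if self.window_len < 1:
            raise ValueError("window_len must be >= 1")
        for v in (self.polyg_min_run, self.lead_trail_q, self.window_meanq, self.min_len):
            if v < 0:
                raise ValueError("thresholds must be non-negative")


@dataclass
class QCSummary:
    pairs_in: int = 0
    pairs_polyg_removed: int = 0
    pairs_sampled_out: int = 0
    pairs_out: int = 0
    orphans: int = 0


#: an orphan is a surviving single mate: (read_id, mate_index 1|2, seq, qual)
Orphan = tuple[str, int, str, str]


def _has_polyg(seq: str, min_run: int, both_senses: bool) -> bool:
    if "G" * min_run in seq:
        return True
    return both_senses and "C" * min_run in seq


def filter_polyg(pairs: list[ReadPair], params: QCParams) -> list[ReadPair]:
    """Drop any pair where either mate contains a poly-G (or poly-C) run of
    at least ``polyg_min_run`` bases; survivor order is preserved."""
    n = params.polyg_min_run
    return [
        p
        for p in pairs
        if not (
            _has_polyg(p.seq1, n, params.polyg_both_senses)
            or _has_polyg(p.seq2, n, params.polyg_both_senses)
        )
    ]


def subsample(pairs: list[ReadPair], n_pairs: int, seed: int) -> list[ReadPair]:
    """Uniform sample of ``min(n_pairs, len(pairs))`` pairs without
    replacement, mates kept together, original order preserved."""
    if n_pairs < 0:
        raise ValueError("n_pairs must be non-negative")
    if n_pairs >= len(pairs):
        return list(pairs)
    rng = np.random.default_rng(seed)
    keep = np.sort(rng.choice(len(pairs), size=n_pairs, replace=False))
    return [pairs[i] for i in keep]


def _trim_mate(seq: str, qual: str, params: QCParams) -> tuple[str, str]:
    """Strip low-quality/N ends, then truncate at the first sliding window
    whose mean quality falls below the threshold, then re-strip the tail."""
    q = np.frombuffer(qual.encode(), dtype=np.uint8).astype(np.int32) - 33
    lo, hi = 0, len(seq)
    while lo < hi and (q[lo] < params.lead_trail_q or seq[lo] == "N"):
        lo += 1
    while hi > lo and (q[hi - 1] < params.lead_trail_q or seq[hi - 1] == "N"):
        hi -= 1
    seq, q = seq[lo:hi], q[lo:hi]

    w = params.window_len
    if len(q) >= w:
        means = np.convolve(q, np.ones(w), mode="valid") / w
        bad = np.nonzero(means < params.window_meanq)[0]
        if len(bad):
            cut = int(bad[0])
            seq, q = seq[:cut], q[:cut]

    hi = len(seq)
    while hi > 0 and (q[hi - 1] < params.lead_trail_q or seq[hi - 1] == "N"):
        hi -= 1
    return seq[:hi], qual[lo : lo + hi]


def trim(
    pairs: list[ReadPair], params: QCParams
) -> tuple[list[ReadPair], list[Orphan]]:
    """Quality-trim both mates of every pair.

    Mates falling below ``min_len`` are dropped; when exactly one mate of a
    pair survives it is routed to the orphan stream.
    """
    kept: list[ReadPair] = []
    orphans: list[Orphan] = []
    for p in pairs:
        if len(p.seq1) != len(p.qual1) or len(p.seq2) != len(p.qual2):
            raise ValueError(f"malformed record {p.id}: sequence/quality length mismatch")
        s1, q1 = _trim_mate(p.seq1, p.qual1, params)
        s2, q2 = _trim_mate(p.seq2, p.qual2, params)
        ok1 = len(s1) >= params.min_len
        ok2 = len(s2) >= params.min_len
        if ok1 and ok2:
            kept.append(ReadPair(p.id, s1, q1, s2, q2))
        elif ok1:
            orphans.append((p.id, 1, s1, q1))
        elif ok2:
            orphans.append((p.id, 2, s2, q2))
    return kept, orphans


def run_qc(
    pairs: list[ReadPair], params: QCParams | None = None
) -> tuple[list[ReadPair], list[Orphan], QCSummary]:
    """Full QC stage: poly-G filter, optional seeded subsampling, trimming."""
    params = params or QCParams()
    summary = QCSummary(pairs_in=len(pairs))
    pairs = filter_polyg(pairs, params)
    summary.pairs_polyg_removed = summary.pairs_in - len(pairs)
    if params.sample_pairs is not None:
        before = len(pairs)
        pairs = subsample(pairs, params.sample_pairs, params.sample_seed)
        summary.pairs_sampled_out = before - len(pairs)
    pairs, orphans = trim(pairs, params)
    summary.pairs_out = len(pairs)
    summary.orphans = len(orphans)
    return pairs, orphans, summary
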