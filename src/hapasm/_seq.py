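"""Low-level sequence helpers shared across modules.

Everything here operates on plain upper-case ``str`` sequences over the
alphabet ``ACGT`` (plus ``N`` where noted); coordinates are 0-based
half-open throughout the package.
"""

from __future__ import annotations

import numpy as np

_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")

BASES = "ACGT"


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (case preserved)."""
    return seq.translate(_COMP)[::-1]


def canonical(kmer: str) -> str:
    """Lexicographically smaller of a kmer and its reverse complement."""
    rc = kmer.translate(_COMP)[::-1]
    return kmer if kmer <= rc else rc


def random_dna(rng: np.random.Generator, length: int) -> str:
    """Uniform random DNA of the given length."""
    return "".join(np.array(list(BASES))[rng.integers(0, 4, size=length)])


def kmer_index(seq: str, k: int, step: int = 1) -> dict[str, list[int]]:
    """Map every ``k``-mer of ``seq`` (forward strand, every ``step`` bases)
    to the sorted list of its start positions."""
    idx: dict[str, list[int]] = {}
    for i in range(0, len(seq) - k + 1, step):
        idx.setdefault(seq[i : i + k], []).append(i)
    return idx


def phred_to_ascii(quals) -> str:
    """Phred scores (iterable of int) to a Sanger-encoded quality string."""
    return "".join(chr(min(int(q), 60) + 33) for q in quals)


def ascii_to_phred(qstr: str) -> list[int]:
    return [ord(c) - 33 for c in qstr]
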