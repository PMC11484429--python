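"""File-format plumbing: FASTA/FASTQ, ledger/genotype TSV, BED, PAF.

FASTA goes through Biopython; FASTQ uses a minimal four-line reader/writer
(kept in-house for speed on large simulated read sets).  Gzip is inferred
from the ``.gz`` suffix.
"""

from __future__ import annotations

import gzip
import json
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .simforge import GuideHaplotype, PlacementRecord, ReadPair, TruthHaplotype, Variant


def _open(path, mode="rt"):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


# --------------------------------------------------------------------------
# FASTA


def write_fasta(records: list[tuple[str, str]], path, description: str = "") -> None:
    SeqIO.write(
        (SeqRecord(Seq(seq), id=name, description=description) for name, seq in records),
        str(path),
        "fasta",
    )


def read_fasta(path) -> list[tuple[str, str]]:
    return [(r.id, str(r.seq)) for r in SeqIO.parse(str(path), "fasta")]


def read_guides(path, class_table: dict[str, str] | None = None) -> list[GuideHaplotype]:
    """Load guide haplotypes; ``class_table`` maps record id -> class name
    (id used as class when absent)."""
    guides = []
    for name, seq in read_fasta(path):
        cls = (class_table or {}).get(name, name)
        guides.append(GuideHaplotype(name, seq.upper(), cls))
    return guides


# --------------------------------------------------------------------------
# FASTQ


def write_paired_fastq(pairs: list[ReadPair], path1, path2) -> None:
    with _open(path1, "wt") as f1, _open(path2, "wt") as f2:
        for p in pairs:
            f1.write(f"@{p.id}/1\n{p.seq1}\n+\n{p.qual1}\n")
            f2.write(f"@{p.id}/2\n{p.seq2}\n+\n{p.qual2}\n")


def _read_fastq(path):
    with _open(path) as fh:
        while True:
            header = fh.readline()
            if not header:
                return
            seq = fh.readline().rstrip("\n")
            fh.readline()
            qual = fh.readline().rstrip("\n")
            yield header[1:].split()[0], seq, qual


def _strip_mate(name: str) -> str:
    return name[:-2] if name.endswith(("/1", "/2")) else name


def read_paired_fastq(path1, path2) -> list[ReadPair]:
    """Read synchronized paired FASTQ; mate id mismatch is a hard error."""
    pairs = []
    it2 = _read_fastq(path2)
    for name1, seq1, qual1 in _read_fastq(path1):
        try:
            name2, seq2, qual2 = next(it2)
        except StopIteration:
            raise ValueError("R2 file ended before R1") from None
        id1, id2 = _strip_mate(name1), _strip_mate(name2)
        if id1 != id2:
            raise ValueError(f"desynchronized mates: {name1!r} vs {name2!r}")
        pairs.append(ReadPair(id1, seq1, qual1, seq2, qual2))
    if next(it2, None) is not None:
        raise ValueError("R1 file ended before R2")
    return pairs


# --------------------------------------------------------------------------
# tables


def write_ledger_tsv(truths: list[TruthHaplotype], path) -> None:
    with open(path, "w") as fh:
        fh.write("truth_id\tguide_id\tpos0\ttype\tref\talt\n")
        for t in truths:
            for v in t.ledger:
                fh.write(f"{t.id}\t{t.guide_id}\t{v.pos0}\t{v.type}\t{v.ref}\t{v.alt}\n")


def read_ledger_tsv(path) -> dict[str, list[Variant]]:
    out: dict[str, list[Variant]] = {}
    with open(path) as fh:
        next(fh)
        for line in fh:
            tid, gid, pos0, vtype, ref, alt = (line.rstrip("\n").split("\t") + [""] * 6)[:6]
            out.setdefault(tid, []).append(Variant(int(pos0), vtype, ref, alt))
    return out


def write_placement_tsv(records: list[PlacementRecord], path) -> None:
    with open(path, "w") as fh:
        fh.write("read_id\tsource_id\tfragment_start\tstrand\n")
        for r in records:
            fh.write(f"{r.read_id}\t{r.source_id}\t{r.fragment_start}\t{r.strand}\n")


def read_genotypes(path) -> dict[str, tuple[str, str]]:
    """Genotype table TSV: sample_id, allele1, allele2 (header optional)."""
    out = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3 or parts[0] in ("sample_id", "sample"):
                continue
            out[parts[0]] = (parts[1], parts[2])
    return out


def write_bed(intervals: list[tuple], path, name: str = "region") -> None:
    """Intervals as (start, end[, label]) on one reference record."""
    with open(path, "w") as fh:
        for iv in intervals:
            label = iv[2] if len(iv) > 2 else "."
            fh.write(f"{name}\t{iv[0]}\t{iv[1]}\t{label}\n")


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def read_control_file(path) -> dict[str, str]:
    """key=value control file; blank lines and ``#`` comments ignored."""
    out = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#") or "=" not in line:
            continue
        k, v = line.split("=", 1)
        out[k.strip()] = v.strip()
    return out
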