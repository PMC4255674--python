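"""Tn-tag extraction from raw INSeq reads.

An MmeI-adapted mariner read carries a fixed transposon prefix whose last
27 bp are the inverted repeat (IR), followed by 15-16 bp of genomic DNA
captured by the MmeI digest, followed by library adapter.  This module
quality-trims reads (Q20 floor, standard 3' partial-sum rule), locates and
strips the transposon portion, keeps the 15-16 bp genomic tag, and enforces
the leading-TA rule — a genuine transposon-genome junction always starts at
the TA the transposon inserted into.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

from Bio.SeqIO.QualityIO import FastqGeneralIterator

__all__ = [
    "ReadStructure",
    "ProcessedTag",
    "ProcessingStats",
    "DEFAULT_IR",
    "quality_trim",
    "extract_tag",
    "process_fastq",
    "write_tags_tsv",
    "read_tags_tsv",
]

#: himar1-type 27 bp mariner inverted repeat, the default junction anchor.
#: Configurable: any construct-specific IR can be supplied via ReadStructure.
DEFAULT_IR = "ACAGGTTGGATGATAAGTCCCCGGTCT"


@dataclass(frozen=True)
class ReadStructure:
    """Anatomy of one sequencing read and the trimming policy.

    The transposon contributes ``transposon_tag_len`` bases ending in the
    ``ir_len``-bp inverted repeat; the genomic tag that follows is 15-16 bp
    (MmeI cuts 20/18 nt from its site, so tag length varies by one).
    """

    ir_sequence: str = DEFAULT_IR
    transposon_tag_len: int = 53
    genomic_tag_len_min: int = 15
    genomic_tag_len_max: int = 16
    template_len: int = 187
    quality_floor: int = 20
    ir_mismatches: int = 0  # 0 = exact IR match; 1 allows one substitution

    def __post_init__(self):
        if self.genomic_tag_len_min > self.genomic_tag_len_max:
            raise ValueError("tag length min exceeds max")

    @property
    def ir_len(self) -> int:
        return len(self.ir_sequence)


@dataclass(frozen=True)
class ProcessedTag:
    """A validated 15-16 bp genomic tag starting with TA."""

    read_id: str
    tag: str
    source_read_len: int


@dataclass
class ProcessingStats:
    """Attrition accounting; every input read lands in exactly one bucket."""

    n_input: int = 0
    n_quality_fail: int = 0
    n_no_ir: int = 0
    n_bad_length: int = 0
    n_no_ta: int = 0
    n_tags: int = 0

    def check(self) -> None:
        assert self.n_input == (self.n_quality_fail + self.n_no_ir +
                                self.n_bad_length + self.n_no_ta + self.n_tags)


def quality_trim(seq: str, quals: list[int] | tuple[int, ...], floor: int) -> str:
    """Trim the 3' suffix maximizing sum(floor - q), the standard rule
    (as used by BWA and cutadapt).  Returns a possibly empty sequence."""
    if len(seq) != len(quals):
        raise ValueError("sequence and quality lengths differ")
    best, running, cut = 0, 0, len(seq)
    for i in range(len(seq) - 1, -1, -1):
        running += floor - quals[i]
        if running > best:
            best, cut = running, i
    return seq[:cut]


def extract_tag(
    read_id: str,
    seq: str,
    structure: ReadStructure,
) -> ProcessedTag | str:
    """Strip the transposon portion and return the genomic tag.

    Returns a :class:`ProcessedTag`, or a rejection reason string among
    ``no_ir`` (IR absent), ``bad_length`` (fewer than 15 bases follow the
    IR), ``no_ta`` (tag does not start with the TA junction motif).
    If >= 16 bases remain after the IR the 16-mer is emitted; the mapper
    falls back to its 15-mer prefix when the 16-mer fails to map.
    """
    hit = seq.find(structure.ir_sequence)
    if hit < 0 and structure.ir_mismatches >= 1:
        hit = _find_one_mismatch(seq, structure.ir_sequence)
    if hit < 0:
        return "no_ir"
    start = hit + structure.ir_len
    rest = seq[start:]
    if len(rest) < structure.genomic_tag_len_min:
        return "bad_length"
    tag = rest[:structure.genomic_tag_len_max] \
        if len(rest) >= structure.genomic_tag_len_max \
        else rest[:structure.genomic_tag_len_min]
    if not tag.startswith("TA"):
        return "no_ta"
    return ProcessedTag(read_id=read_id, tag=tag, source_read_len=len(seq))


def _find_one_mismatch(seq: str, ir: str) -> int:
    """Leftmost position where ir matches seq with at most one mismatch."""
    n, m = len(seq), len(ir)
    for i in range(n - m + 1):
        mismatches = 0
        for a, b in zip(seq[i:i + m], ir):
            if a != b:
                mismatches += 1
                if mismatches > 1:
                    break
        else:
            return i
    return -1


def _open_maybe_gzip(path: str | Path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def iter_fastq(path: str | Path) -> Iterator[tuple[str, str, str]]:
    """Yield (id, sequence, quality-string) triples; gzip-transparent."""
    with _open_maybe_gzip(path) as fh:
        yield from FastqGeneralIterator(fh)


def process_fastq(
    fastq_path: str | Path,
    structure: ReadStructure | None = None,
) -> tuple[list[ProcessedTag], ProcessingStats]:
    """Stream a FASTQ through quality trimming then tag extraction.

    A read whose quality-trimmed length cannot hold IR plus a minimum tag
    is a quality failure; other rejections are per :func:`extract_tag`.
    """
    structure = structure or ReadStructure()
    stats = ProcessingStats()
    tags: list[ProcessedTag] = []
    min_useful = structure.ir_len + structure.genomic_tag_len_min
    for read_id, seq, qual in iter_fastq(fastq_path):
        stats.n_input += 1
        quals = [ord(c) - 33 for c in qual]
        trimmed = quality_trim(seq.upper(), quals, structure.quality_floor)
        if len(trimmed) < min_useful:
            stats.n_quality_fail += 1
            continue
        result = extract_tag(read_id, trimmed, structure)
        if isinstance(result, ProcessedTag):
            stats.n_tags += 1
            tags.append(result)
        elif result == "no_ir":
            stats.n_no_ir += 1
        elif result == "bad_length":
            stats.n_bad_length += 1
        else:
            stats.n_no_ta += 1
    stats.check()
    return tags, stats


def write_tags_tsv(tags: Iterable[ProcessedTag], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("read_id\ttag\n")
        for t in tags:
            fh.write(f"{t.read_id}\t{t.tag}\n")


def read_tags_tsv(path: str | Path) -> list[ProcessedTag]:
    tags = []
    with open(path) as fh:
        header = fh.readline()
        for line in fh:
            read_id, tag = line.rstrip("\n").split("\t")
            tags.append(ProcessedTag(read_id=read_id, tag=tag,
                                     source_read_len=len(tag)))
    return tags
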