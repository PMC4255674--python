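"""Exact mapping of 15-16 bp Tn-tags to unique TA sites.

Tags are too short for a mismatch-tolerant aligner to add value: with zero
mismatches allowed, mapping is exact dictionary lookup against every
TA-anchored 15/16-mer of the genome, on both strands.  A tag that matches
more than one site is a multi-mapper and is discarded; a tag whose only
match is not anchored at a TA site cannot be a mariner junction and counts
as unmapped.  Counts from the two strands of a site are pooled (the TA
motif is its own reverse complement; saturation statistics are per site).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np

from .genome import Replicon, TASiteIndex
from .tags import ProcessedTag

__all__ = [
    "TagIndex",
    "InsertionProfile",
    "MappingStats",
    "SiteHit",
    "build_index",
    "map_tag",
    "accumulate_profile",
    "write_wig",
    "read_wig",
]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


#: sentinel for k-mers occurring at more than one site
_AMBIGUOUS = ("*", -1, "*")


@dataclass(frozen=True)
class SiteHit:
    replicon_id: str
    position: int  # 1-based position of the site's T
    strand: str


class TagIndex:
    """Hash of every TA-anchored genomic 15/16-mer to its unique site.

    Keys of both lengths coexist; a key seen at two distinct sites is
    flagged ambiguous.  Forward and reverse-complement contexts through the
    same TA map to the same site and are not ambiguous with each other.
    """

    def __init__(self):
        self._lookup: dict[str, tuple[str, int, str]] = {}

    def _insert(self, kmer: str, replicon_id: str, pos: int, strand: str) -> None:
        existing = self._lookup.get(kmer)
        if existing is None:
            self._lookup[kmer] = (replicon_id, pos, strand)
        elif existing is not _AMBIGUOUS and existing[:2] != (replicon_id, pos):
            self._lookup[kmer] = _AMBIGUOUS

    def get(self, kmer: str) -> tuple[str, int, str] | None:
        """Site tuple, the ambiguity sentinel, or None."""
        return self._lookup.get(kmer)

    def is_ambiguous(self, entry) -> bool:
        return entry is _AMBIGUOUS

    def __len__(self) -> int:
        return len(self._lookup)


@dataclass
class InsertionProfile:
    """Read count at every TA site of a replicon, ordered as TASiteIndex."""

    replicon_id: str
    counts: np.ndarray  # int array, len == number of TA sites

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if (self.counts < 0).any():
            raise ValueError("negative counts")

    @property
    def n_sites(self) -> int:
        return int(self.counts.size)


@dataclass
class MappingStats:
    n_tags: int = 0
    n_unique: int = 0
    n_multi: int = 0
    n_unmapped: int = 0

    def check(self) -> None:
        assert self.n_tags == self.n_unique + self.n_multi + self.n_unmapped


def build_index(
    replicons: Iterable[Replicon],
    ta_indexes: dict[str, TASiteIndex],
    tag_lengths: tuple[int, ...] = (15, 16),
) -> TagIndex:
    """Index forward and reverse-complement tag contexts at every TA site.

    For a site whose T is at 1-based p (0-based i), the forward context of
    length L is seq[i : i+L] and the reverse-strand context is the reverse
    complement of seq[i-L+2 : i+2] — the window ending at the A, so that
    read from the opposite strand it begins with the same TA.  Contexts
    running off a replicon end are indexed only for lengths that fit.
    """
    index = TagIndex()
    for rep in replicons:
        seq = rep.sequence
        n = len(seq)
        for p in ta_indexes[rep.id].positions:
            i = p - 1
            for L in tag_lengths:
                if i + L <= n:
                    index._insert(seq[i:i + L], rep.id, p, "+")
                if i - L + 2 >= 0:
                    index._insert(revcomp(seq[i - L + 2:i + 2]), rep.id, p, "-")
    return index


def map_tag(tag: str, index: TagIndex) -> SiteHit | str:
    """Exact lookup of one tag; returns a SiteHit, "multi" or "unmapped".

    A 16-mer with no exact match is retried as its 15-mer prefix (the MmeI
    digest leaves the true tag length uncertain by one base).
    """
    if not tag.startswith("TA"):
        raise ValueError(f"tag does not start with TA: {tag!r}")
    entry = index.get(tag)
    if entry is None and len(tag) == 16:
        entry = index.get(tag[:15])
    if entry is None:
        return "unmapped"
    if index.is_ambiguous(entry):
        return "multi"
    return SiteHit(replicon_id=entry[0], position=entry[1], strand=entry[2])


def accumulate_profile(
    tags: Iterable[ProcessedTag],
    index: TagIndex,
    ta_indexes: dict[str, TASiteIndex],
) -> tuple[dict[str, InsertionProfile], MappingStats]:
    """Map every tag and accumulate per-site read counts, strands pooled."""
    stats = MappingStats()
    pos_to_idx = {
        rid: {p: j for j, p in enumerate(idx.positions)}
        for rid, idx in ta_indexes.items()
    }
    counts = {rid: np.zeros(len(idx), dtype=np.int64)
              for rid, idx in ta_indexes.items()}
    for t in tags:
        stats.n_tags += 1
        hit = map_tag(t.tag, index)
        if hit == "unmapped":
            stats.n_unmapped += 1
        elif hit == "multi":
            stats.n_multi += 1
        else:
            stats.n_unique += 1
            counts[hit.replicon_id][pos_to_idx[hit.replicon_id][hit.position]] += 1
    stats.check()
    profiles = {rid: InsertionProfile(replicon_id=rid, counts=c)
                for rid, c in counts.items()}
    return profiles, stats


def write_wig(
    profiles: dict[str, InsertionProfile],
    ta_indexes: dict[str, TASiteIndex],
    path: str | Path,
) -> None:
    """variableStep WIG, one track per replicon, one line per TA site
    (zeros included) so the site universe round-trips."""
    with open(path, "w") as fh:
        for rid, profile in profiles.items():
            fh.write(f"variableStep chrom={rid}\n")
            positions = ta_indexes[rid].positions
            fh.writelines(
                f"{p}\t{c}\n" for p, c in zip(positions, profile.counts))


def read_wig(path: str | Path) -> tuple[dict[str, InsertionProfile],
                                        dict[str, TASiteIndex]]:
    """Companion reader for :func:`write_wig`; rebuilds profiles and the
    site index they are aligned to."""
    profiles: dict[str, InsertionProfile] = {}
    indexes: dict[str, TASiteIndex] = {}
    rid = None
    positions: list[int] = []
    counts: list[int] = []

    def flush():
        if rid is not None:
            indexes[rid] = TASiteIndex(replicon_id=rid,
                                       positions=tuple(positions))
            profiles[rid] = InsertionProfile(
                replicon_id=rid, counts=np.array(counts, dtype=np.int64))

    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("track"):
                continue
            if line.startswith("variableStep"):
                flush()
                fields = dict(kv.split("=") for kv in line.split()[1:])
                rid = fields["chrom"]
                positions, counts = [], []
            else:
                p, c = line.split()
                positions.append(int(p))
                counts.append(int(float(c)))
    flush()
    return profiles, indexes
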