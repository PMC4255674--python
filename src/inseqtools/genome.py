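"""Genome model: replicons, TA insertion sites, and gene annotations.

mariner-family (himar1) transposons insert exclusively at TA dinucleotides,
so the universe of possible insertion sites in a genome is finite and
enumerable.  This module loads multi-replicon genomes (FASTA) and gene
annotations (GFF3), enumerates every TA site, and intersects sites with gene
boundaries.  Coordinates are 1-based inclusive throughout (GFF3 convention);
a TA site's coordinate is the position of its T.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass
from pathlib import Path

import gffutils
from Bio import SeqIO

__all__ = [
    "Replicon",
    "TASiteIndex",
    "GeneAnnotation",
    "GeneSiteMap",
    "GenomeFormatError",
    "load_genome",
    "enumerate_ta_sites",
    "load_annotation",
    "sites_per_gene",
    "write_sites_bed",
    "write_sites_tsv",
]

_IUPAC = set("ACGTNRYSWKMBDHV")
_TA_RE = re.compile(r"(?=TA)")


class GenomeFormatError(ValueError):
    """Raised for malformed FASTA/GFF3 input."""


@dataclass(frozen=True)
class Replicon:
    """One independently replicating element (chromosome or plasmid)."""

    id: str
    sequence: str

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def gc_fraction(self) -> float:
        """G+C proportion over unambiguous bases."""
        n = sum(self.sequence.count(b) for b in "ACGT")
        gc = self.sequence.count("G") + self.sequence.count("C")
        return gc / n if n else 0.0


@dataclass(frozen=True)
class TASiteIndex:
    """Sorted 1-based positions of the T of every TA dinucleotide."""

    replicon_id: str
    positions: tuple[int, ...]

    def __len__(self) -> int:
        return len(self.positions)


@dataclass(frozen=True)
class GeneAnnotation:
    """A gene feature with 1-based inclusive coordinates."""

    locus: str
    replicon_id: str
    start: int
    end: int
    strand: str = "+"
    product: str = ""

    def __post_init__(self):
        if not (1 <= self.start <= self.end):
            raise ValueError(f"invalid coordinates for {self.locus}: "
                             f"{self.start}..{self.end}")


@dataclass(frozen=True)
class GeneSiteMap:
    """Indices into a replicon's TASiteIndex that fall inside a gene."""

    locus: str
    site_indices: tuple[int, ...]

    @property
    def n_sites(self) -> int:
        return len(self.site_indices)


def load_genome(fasta_path: str | Path) -> list[Replicon]:
    """Load a (multi-)replicon genome from FASTA, in file order.

    Sequences are uppercased.  Characters outside the IUPAC nucleotide
    alphabet raise :class:`GenomeFormatError`.
    """
    fasta_path = Path(fasta_path)
    replicons: list[Replicon] = []
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        seq = str(rec.seq).upper()
        bad = set(seq) - _IUPAC
        if bad:
            raise GenomeFormatError(
                f"record {rec.id!r}: non-nucleotide characters {sorted(bad)}")
        replicons.append(Replicon(id=rec.id, sequence=seq))
    if not replicons:
        raise GenomeFormatError(f"no FASTA records in {fasta_path}")
    return replicons


def enumerate_ta_sites(replicon: Replicon) -> TASiteIndex:
    """Every 1-based position p with sequence[p]=="T" and sequence[p+1]=="A".

    Overlapping occurrences count separately ("TATA" yields positions 1 and
    3, the motif being its own reverse complement).  Sites containing an
    ambiguity code are by construction excluded (only literal T followed by
    literal A qualifies).
    """
    positions = tuple(m.start() + 1 for m in _TA_RE.finditer(replicon.sequence))
    return TASiteIndex(replicon_id=replicon.id, positions=positions)


def load_annotation(
    gff_path: str | Path,
    replicon_lengths: dict[str, int],
    feature_type: str = "gene",
) -> list[GeneAnnotation]:
    """Load gene features from GFF3.

    ``replicon_lengths`` maps replicon id to length; features on unknown
    replicons are dropped with a warning, features with coordinates outside
    their replicon raise :class:`GenomeFormatError` naming the feature.
    The locus is taken from the ``locus_tag`` attribute, falling back to
    ``ID``; ``product`` is carried through when present.
    """
    db = gffutils.create_db(
        str(gff_path), dbfn=":memory:", force=True,
        merge_strategy="create_unique", keep_order=True)
    genes: list[GeneAnnotation] = []
    for feat in db.features_of_type(feature_type, order_by=("seqid", "start")):
        if feat.seqid not in replicon_lengths:
            warnings.warn(
                f"feature {feat.id!r} on unknown replicon {feat.seqid!r}; skipped")
            continue
        length = replicon_lengths[feat.seqid]
        if not (1 <= feat.start <= feat.end <= length):
            raise GenomeFormatError(
                f"feature {feat.id!r}: {feat.start}..{feat.end} outside "
                f"replicon {feat.seqid!r} of length {length}")
        locus = feat.attributes.get("locus_tag", feat.attributes.get("ID", [feat.id]))[0]
        product = feat.attributes.get("product", [""])[0]
        genes.append(GeneAnnotation(
            locus=locus, replicon_id=feat.seqid,
            start=feat.start, end=feat.end,
            strand=feat.strand if feat.strand in "+-" else "+",
            product=product))
    return genes


def sites_per_gene(
    ta_index: TASiteIndex,
    genes: list[GeneAnnotation],
) -> list[GeneSiteMap]:
    """Map each gene to the TA sites lying fully inside it.

    A site at position p is inside [start, end] iff start <= p and
    p + 1 <= end: both bases of the dinucleotide must lie within the gene
    for an insertion there to disrupt it.  Genes with no TA site get an
    empty map (the downstream "No Data" class).  Overlapping genes share
    sites independently.
    """
    import bisect

    pos = ta_index.positions
    maps: list[GeneSiteMap] = []
    for gene in genes:
        if gene.replicon_id != ta_index.replicon_id:
            raise ValueError(
                f"gene {gene.locus} is on {gene.replicon_id!r}, "
                f"index is for {ta_index.replicon_id!r}")
        lo = bisect.bisect_left(pos, gene.start)
        hi = bisect.bisect_right(pos, gene.end - 1)  # p+1 <= end
        maps.append(GeneSiteMap(locus=gene.locus,
                                site_indices=tuple(range(lo, hi))))
    return maps


def write_sites_bed(indexes: list[TASiteIndex], path: str | Path) -> None:
    """Write TA sites as BED (0-based half-open, one 2 bp interval each)."""
    with open(path, "w") as fh:
        for idx in indexes:
            for p in idx.positions:
                fh.write(f"{idx.replicon_id}\t{p - 1}\t{p + 1}\tTA\n")


def write_sites_tsv(indexes: list[TASiteIndex], path: str | Path) -> None:
    """Write TA sites as TSV of (replicon, 1-based position of the T)."""
    with open(path, "w") as fh:
        fh.write("replicon\tposition\n")
        for idx in indexes:
            for p in idx.positions:
                fh.write(f"{idx.replicon_id}\t{p}\n")
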