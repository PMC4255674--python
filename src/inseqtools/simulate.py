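"""Synthetic saturating-mutagenesis experiments with known ground truth.

Generates a multi-replicon genome, a gene annotation with per-gene fitness
classes, per-TA-site read counts, and raw INSeq reads, so that every
pipeline stage is testable end to end without external data.  Defaults
emulate a saturating mariner library in a multi-replicon alpha-
proteobacterial genome: 88% of permissive (neutral) TA sites occupied —
which, with essential genes at zero and growth-defective genes depleted,
realizes an overall genome density near 0.83 — geometric read counts with
occupied-site mean ~19.4, class proportions ES 5.6% / GD 4.0% / GA 0.5%,
and one small replicon at 1.14x copy number whose read depth is elevated
while its insertion density is not, mirroring a high-copy plasmid.

Randomness: one master seed; independent deterministic substreams per
(purpose, replicon), so adding a replicon never perturbs earlier ones.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from .genome import (GeneAnnotation, Replicon, enumerate_ta_sites,
                     sites_per_gene)
from .mapping import InsertionProfile, revcomp
from .tags import ReadStructure

__all__ = ["SimConfig", "SimTruth", "simulate_genome", "simulate_counts",
           "simulate_reads", "write_genome_fasta", "write_annotation_gff3",
           "write_truth_tsv", "simulate_experiment"]

#: transposon bases 5' of the inverted repeat in each read (filler between
#: sequencing primer and IR; any fixed sequence works, this one is TA-free)
TRANSPOSON_FILLER = "GCCAGTCCGGCTGCAGGTCGACGGCC"
#: library adapter used to pad reads to template length
ADAPTER = "CTGAGTCGGAGACACGCAGGGATGAGATGG"

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

CLASSES = ("ES", "GD", "NE", "GA")
#: occupancy multiplier per class relative to target_occupancy
OCCUPANCY_FACTOR = {"ES": 0.0, "GD": 0.4, "NE": 1.0, "GA": 1.0}
#: occupied-site mean multiplier per class relative to mean_reads_per_site
MEAN_FACTOR = {"ES": 0.0, "GD": 0.1, "NE": 1.0, "GA": 5.0}


@dataclass
class SimConfig:
    """All knobs of one synthetic experiment; seed-complete."""

    seed: int = 0
    replicon_lengths: tuple[int, ...] = (500_000, 150_000)
    gc_fractions: tuple[float, ...] = (0.61, 0.576)
    gene_density: float = 0.95  # genes per kb
    gene_length_range: tuple[int, int] = (300, 1500)
    class_proportions: dict[str, float] = field(default_factory=lambda: {
        "ES": 0.056, "GD": 0.040, "NE": 0.899, "GA": 0.005})
    # neutral-site saturation; with ES genes at zero and GD reduced this
    # yields a realized genome-wide density near 0.83
    target_occupancy: float = 0.88
    mean_reads_per_site: float = 19.4
    copy_number_factors: tuple[float, ...] = (1.0, 1.14)
    read_error_rate: float = 0.0
    n_reads: int | None = None  # cap; None = one read per counted insertion
    es_edge_permissive: bool = False

    def __post_init__(self):
        if abs(sum(self.class_proportions.values()) - 1.0) > 1e-9:
            raise ValueError("class proportions must sum to 1")
        if len(self.gc_fractions) != len(self.replicon_lengths):
            raise ValueError("one gc_fraction per replicon required")
        if len(self.copy_number_factors) != len(self.replicon_lengths):
            raise ValueError("one copy_number_factor per replicon required")


@dataclass
class SimTruth:
    """Ground truth of one simulated experiment."""

    config: SimConfig
    gene_class: dict[str, str]  # locus -> true class
    genes: list[GeneAnnotation]
    site_counts: dict[str, np.ndarray] = field(default_factory=dict)


def _rng(config: SimConfig, purpose: int, replicon: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, purpose, replicon])


def simulate_genome(config: SimConfig) -> tuple[list[Replicon],
                                                list[GeneAnnotation],
                                                SimTruth]:
    """I.i.d. bases at the requested GC; non-overlapping genes tiled with
    intergenic gaps; true classes drawn from class_proportions."""
    replicons: list[Replicon] = []
    genes: list[GeneAnnotation] = []
    gene_class: dict[str, str] = {}
    props = np.array([config.class_proportions[c] for c in CLASSES])
    for i, (length, gc) in enumerate(zip(config.replicon_lengths,
                                         config.gc_fractions)):
        rng = _rng(config, 0, i)
        rid = f"repl{i + 1:02d}"
        p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
        seq = _BASES[rng.choice(4, size=length, p=p)].tobytes().decode()
        replicons.append(Replicon(id=rid, sequence=seq))

        n_genes = int(round(config.gene_density * length / 1000))
        if n_genes == 0:
            continue
        pitch = length // n_genes
        lo, hi = config.gene_length_range
        if pitch < lo + 50:
            raise ValueError(
                f"gene_density {config.gene_density}/kb infeasible for "
                f"replicon of {length} bp with genes >= {lo} bp")
        for g in range(n_genes):
            gene_len = int(rng.integers(lo, min(hi, pitch - 50) + 1))
            offset = int(rng.integers(0, pitch - gene_len - 20 + 1))
            start = g * pitch + offset + 1
            end = start + gene_len - 1
            locus = f"{rid}_g{g + 1:04d}"
            cls = CLASSES[int(rng.choice(4, p=props))]
            genes.append(GeneAnnotation(
                locus=locus, replicon_id=rid, start=start, end=end,
                strand="+" if rng.random() < 0.5 else "-",
                product=f"simulated {cls} gene"))
            gene_class[locus] = cls
    return replicons, genes, SimTruth(config=config, gene_class=gene_class,
                                      genes=genes)


def simulate_counts(
    replicons: list[Replicon],
    truth: SimTruth,
) -> dict[str, InsertionProfile]:
    """Per-site occupancy and read counts from the true gene classes.

    Site occupancy is Bernoulli with a class-specific probability (ES
    sites never occupied by default; terminal 10% of ES genes behave as
    NE in edge-permissive mode); counts at occupied sites are geometric
    (support >= 1) with the class mean scaled by the replicon's copy-number
    factor, so depth rises with copy number while density does not.
    Intergenic sites behave as NE — saturating flanks are what make the
    decoder's context informative.
    """
    config = truth.config
    profiles: dict[str, InsertionProfile] = {}
    for i, rep in enumerate(replicons):
        rng = _rng(config, 1, i)
        cnf = config.copy_number_factors[i]
        ta = enumerate_ta_sites(rep)
        site_cls = np.full(len(ta), CLASSES.index("NE"), dtype=np.int8)
        gmaps = sites_per_gene(ta, [g for g in truth.genes
                                    if g.replicon_id == rep.id])
        for gm in gmaps:
            cls = truth.gene_class[gm.locus]
            idx = np.array(gm.site_indices, dtype=np.int64)
            if idx.size == 0:
                continue
            site_cls[idx] = CLASSES.index(cls)
            if cls == "ES" and config.es_edge_permissive and idx.size >= 10:
                k = max(1, idx.size // 10)
                site_cls[idx[:k]] = CLASSES.index("NE")
                site_cls[idx[-k:]] = CLASSES.index("NE")
        counts = np.zeros(len(ta), dtype=np.int64)
        for ci, cls in enumerate(CLASSES):
            mask = site_cls == ci
            if not mask.any():
                continue
            occ_p = OCCUPANCY_FACTOR[cls] * config.target_occupancy
            mu = MEAN_FACTOR[cls] * config.mean_reads_per_site * cnf
            if occ_p <= 0 or mu <= 0:
                continue
            occupied = rng.random(int(mask.sum())) < occ_p
            c = np.zeros(int(mask.sum()), dtype=np.int64)
            p_geom = min(1.0, 1.0 / max(mu, 1.0))
            c[occupied] = rng.geometric(p_geom, size=int(occupied.sum()))
            counts[mask] = c
        truth.site_counts[rep.id] = counts
        profiles[rep.id] = InsertionProfile(replicon_id=rep.id, counts=counts)
    return profiles


def simulate_reads(
    replicons: list[Replicon],
    profiles: dict[str, InsertionProfile],
    truth: SimTruth,
    fastq_path: str | Path,
    structure: ReadStructure | None = None,
) -> int:
    """Emit one read per counted insertion: transposon prefix ending in the
    IR, then 16 bp of genomic context from a uniformly chosen strand of the
    TA, then adapter padding to template length, with substitution errors
    at read_error_rate and constant high base qualities.  Returns the
    number of reads written."""
    structure = structure or ReadStructure()
    config = truth.config
    prefix_len = structure.transposon_tag_len - structure.ir_len
    filler = (TRANSPOSON_FILLER * (prefix_len // len(TRANSPOSON_FILLER) + 1))[:prefix_len]
    prefix = filler + structure.ir_sequence
    tag_len = structure.genomic_tag_len_max
    n_written = 0
    cap = config.n_reads
    with open(fastq_path, "w") as fh:
        for i, rep in enumerate(replicons):
            rng = _rng(config, 2, i)
            seq = rep.sequence
            ta = enumerate_ta_sites(rep)
            counts = profiles[rep.id].counts
            for j in np.nonzero(counts)[0]:
                p = ta.positions[j]
                k = p - 1
                can_fwd = k + tag_len <= len(seq)
                can_rev = k - tag_len + 2 >= 0
                for r in range(int(counts[j])):
                    if cap is not None and n_written >= cap:
                        return n_written
                    fwd = rng.random() < 0.5
                    # a site near a replicon edge emits from whichever
                    # side still has a full-length context
                    if fwd and not can_fwd:
                        fwd = False
                    elif not fwd and not can_rev:
                        fwd = True
                    if fwd and not can_fwd:
                        warnings.warn(f"site {rep.id}:{p} too close to both "
                                      "replicon edges; read skipped")
                        continue
                    tag = (seq[k:k + tag_len] if fwd
                           else revcomp(seq[k - tag_len + 2:k + 2]))
                    read = prefix + tag
                    pad = structure.template_len - len(read)
                    if pad > 0:
                        read += (ADAPTER * (pad // len(ADAPTER) + 1))[:pad]
                    if config.read_error_rate > 0:
                        read = _add_errors(read, config.read_error_rate, rng)
                    qual = "I" * len(read)
                    strand = "+" if fwd else "-"
                    fh.write(f"@{rep.id}:{p}:{strand}:{r}\n{read}\n+\n{qual}\n")
                    n_written += 1
    return n_written


def _add_errors(read: str, rate: float, rng: np.random.Generator) -> str:
    n_err = rng.binomial(len(read), rate)
    if n_err == 0:
        return read
    arr = list(read)
    for pos in rng.choice(len(read), size=n_err, replace=False):
        alternatives = [b for b in "ACGT" if b != arr[pos]]
        arr[pos] = alternatives[int(rng.integers(3))]
    return "".join(arr)


def write_genome_fasta(replicons: list[Replicon], path: str | Path,
                       width: int = 70) -> None:
    with open(path, "w") as fh:
        for rep in replicons:
            fh.write(f">{rep.id}\n")
            for i in range(0, len(rep.sequence), width):
                fh.write(rep.sequence[i:i + width] + "\n")


def write_annotation_gff3(genes: list[GeneAnnotation], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            attrs = f"ID={g.locus};locus_tag={g.locus};product={g.product}"
            fh.write(f"{g.replicon_id}\tinseqtools_sim\tgene\t{g.start}\t"
                     f"{g.end}\t.\t{g.strand}\t.\t{attrs}\n")


def write_truth_tsv(truth: SimTruth, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("locus\treplicon\tstart\tend\ttrue_class\n")
        for g in truth.genes:
            fh.write(f"{g.locus}\t{g.replicon_id}\t{g.start}\t{g.end}\t"
                     f"{truth.gene_class[g.locus]}\n")


def write_config_yaml(config: SimConfig, path: str | Path) -> None:
    d = asdict(config)
    for key in ("replicon_lengths", "gc_fractions", "copy_number_factors",
                "gene_length_range"):
        d[key] = list(d[key])
    with open(path, "w") as fh:
        yaml.safe_dump(d, fh, sort_keys=False)


def simulate_experiment(
    config: SimConfig,
    outdir: str | Path,
    structure: ReadStructure | None = None,
    with_reads: bool = True,
) -> SimTruth:
    """Write the full bundle: FASTA, GFF3, truth TSV, true-count WIG,
    config echo, and (optionally) FASTQ."""
    from .mapping import write_wig

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    replicons, genes, truth = simulate_genome(config)
    profiles = simulate_counts(replicons, truth)
    write_genome_fasta(replicons, outdir / "genome.fasta")
    write_annotation_gff3(genes, outdir / "annotation.gff3")
    write_truth_tsv(truth, outdir / "truth.tsv")
    ta = {r.id: enumerate_ta_sites(r) for r in replicons}
    write_wig(profiles, ta, outdir / "true_counts.wig")
    write_config_yaml(config, outdir / "sim_config.yaml")
    if with_reads:
        simulate_reads(replicons, profiles, truth, outdir / "reads.fastq",
                       structure)
    return truth
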