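"""End-to-end orchestration: FASTA + GFF3 + FASTQ -> per-gene calls.

Stage order: TA-site enumeration, read processing, tag mapping, replicon
saturation statistics, HMM decoding, gene classification, report.  Every
intermediate is plain text (TSV/WIG/BED) and each stage is independently
re-runnable from the previous stage's files via the CLI.  The pipeline is
a pure function of (inputs, config): reruns are byte-identical.
"""

from __future__ import annotations

import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import genome as gm
from . import hmm as hm
from . import mapping as mp
from . import stats as st
from . import tags as tg

__all__ = ["PipelineConfig", "run_pipeline"]

log = logging.getLogger("inseqtools")


@dataclass
class PipelineConfig:
    genome: str
    annotation: str
    reads: str
    outdir: str = "inseq_out"
    ir_sequence: str = tg.DEFAULT_IR
    quality_floor: int = 20
    ir_mismatches: int = 0
    feature_type: str = "gene"
    seed: int = 0  # reserved for stages with sampling; analysis is exact

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def read_structure(self) -> tg.ReadStructure:
        return tg.ReadStructure(ir_sequence=self.ir_sequence,
                                quality_floor=self.quality_floor,
                                ir_mismatches=self.ir_mismatches)


def _setup_logging(outdir: Path) -> None:
    log.setLevel(logging.INFO)
    log.handlers.clear()
    # no timestamps: the run log is part of the reproducible output bundle
    fmt = logging.Formatter("%(levelname)s %(message)s")
    for handler in (logging.StreamHandler(sys.stderr),
                    logging.FileHandler(outdir / "run.log", mode="w")):
        handler.setFormatter(fmt)
        log.addHandler(handler)


def run_pipeline(config: PipelineConfig) -> dict[str, Path]:
    """Run every stage; returns a dict of output names to paths.

    Aborts with a RuntimeError naming the failing stage.  The run log
    records the read count surviving each attrition point (input reads,
    quality failures, missing IR, bad tag length, missing TA, unique /
    multi / unmapped alignments).
    """
    for name in ("genome", "annotation", "reads"):
        p = Path(getattr(config, name))
        if not p.exists():
            raise FileNotFoundError(f"{name} file not found: {p}")
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    _setup_logging(outdir)
    outputs: dict[str, Path] = {}
    stage = "ta-sites"
    try:
        replicons = gm.load_genome(config.genome)
        ta = {r.id: gm.enumerate_ta_sites(r) for r in replicons}
        gm.write_sites_bed(list(ta.values()), outdir / "ta_sites.bed")
        gm.write_sites_tsv(list(ta.values()), outdir / "ta_sites.tsv")
        outputs["ta_sites_bed"] = outdir / "ta_sites.bed"
        outputs["ta_sites_tsv"] = outdir / "ta_sites.tsv"
        log.info("ta-sites: %d replicons, %d TA sites",
                 len(replicons), sum(len(i) for i in ta.values()))

        stage = "annotation"
        lengths = {r.id: r.length for r in replicons}
        genes = gm.load_annotation(config.annotation, lengths,
                                   config.feature_type)
        gene_maps = {rid: gm.sites_per_gene(
            ta[rid], [g for g in genes if g.replicon_id == rid])
            for rid in ta}
        log.info("annotation: %d genes", len(genes))

        stage = "process-reads"
        structure = config.read_structure()
        tags, pstats = tg.process_fastq(config.reads, structure)
        tg.write_tags_tsv(tags, outdir / "tags.tsv")
        outputs["tags"] = outdir / "tags.tsv"
        log.info("process-reads: %d input, %d quality-fail, %d no-IR, "
                 "%d bad-length, %d no-TA, %d tags",
                 pstats.n_input, pstats.n_quality_fail, pstats.n_no_ir,
                 pstats.n_bad_length, pstats.n_no_ta, pstats.n_tags)

        stage = "map"
        index = mp.build_index(replicons, ta)
        profiles, mstats = mp.accumulate_profile(tags, index, ta)
        mp.write_wig(profiles, ta, outdir / "counts.wig")
        outputs["counts_wig"] = outdir / "counts.wig"
        pd.DataFrame([{
            "n_tags": mstats.n_tags, "n_unique": mstats.n_unique,
            "n_multi": mstats.n_multi, "n_unmapped": mstats.n_unmapped,
        }]).to_csv(outdir / "mapping_stats.tsv", sep="\t", index=False)
        outputs["mapping_stats"] = outdir / "mapping_stats.tsv"
        log.info("map: %d tags -> %d unique, %d multi, %d unmapped",
                 mstats.n_tags, mstats.n_unique, mstats.n_multi,
                 mstats.n_unmapped)

        stage = "stats"
        summaries = []
        for r in replicons:
            genes_r = [g for g in genes if g.replicon_id == r.id]
            summaries.append(st.summarize_replicon(
                profiles[r.id], ta[r.id], genes_r, size_bp=r.length,
                gc_percent=100.0 * r.gc_fraction))
        summaries.append(st.summarize_genome(summaries))
        st.write_summary_tsv(summaries, outdir / "replicon_summary.tsv")
        st.write_summary_json(summaries, outdir / "replicon_summary.json")
        outputs["replicon_summary"] = outdir / "replicon_summary.tsv"
        log.info("stats: genome density %.2f",
                 summaries[-1].insertion_density or float("nan"))

        stage = "hmm+classify"
        calls, paths, class_summaries = hm.classify_genome(
            profiles, ta, gene_maps)
        hm.write_state_wig(paths, ta, outdir / "site_states.wig")
        outputs["site_states"] = outdir / "site_states.wig"
        all_calls = [c for rid in sorted(calls) for c in calls[rid]]
        hm.classifications_to_frame(all_calls, genes).to_csv(
            outdir / "gene_classification.tsv", sep="\t", index=False)
        outputs["gene_classification"] = outdir / "gene_classification.tsv"
        pd.DataFrame([{
            "replicon": s.replicon_id, "mapped_reads": s.mapped_reads,
            **s.counts,
        } for s in class_summaries]).to_csv(
            outdir / "class_summary.tsv", sep="\t", index=False)
        outputs["class_summary"] = outdir / "class_summary.tsv"
        for s in class_summaries:
            log.info("classify %s: %s", s.replicon_id, s.counts)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    return outputs
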