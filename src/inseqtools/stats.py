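"""Per-replicon and genome-wide saturation statistics.

For each replicon: potential TA sites, observed (occupied) sites, insertion
density = observed / potential, and the mean and median read count over
occupied sites only.  The genome row pools sizes, gene counts and site
counts; for read counts it reports the unweighted mean of per-replicon means
and the median of per-replicon medians — the convention under which the
published genome-level figures for the R. leguminosarum 3841 dataset are
arithmetically consistent with their per-replicon rows — alongside the
pooled (count-weighted) alternatives.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .genome import GeneAnnotation, TASiteIndex
from .mapping import InsertionProfile

__all__ = ["RepliconSummary", "summarize_replicon", "summarize_genome",
           "write_summary_tsv", "write_summary_json"]

GENOME_ROW_ID = "Genome"


@dataclass
class RepliconSummary:
    replicon_id: str
    size_bp: int
    gc_percent: float
    gene_count: int
    potential_sites: int
    observed_sites: int
    insertion_density: float | None
    mean_read_count: float | None
    median_read_count: float | None
    # pooled (count-weighted) alternatives, populated on the genome row
    pooled_mean_read_count: float | None = None
    pooled_median_read_count: float | None = None


def summarize_replicon(
    profile: InsertionProfile,
    ta_index: TASiteIndex,
    genes: list[GeneAnnotation] | None = None,
    size_bp: int | None = None,
    gc_percent: float | None = None,
) -> RepliconSummary:
    """Saturation statistics for one replicon.

    Density is the fraction of TA sites carrying >= 1 read; mean and median
    read counts are over occupied sites only (an unoccupied site says the
    mutant is absent, not that it was sequenced zero times).  With zero
    potential sites density is undefined (None).
    """
    counts = profile.counts
    potential = len(ta_index)
    occupied = counts[counts > 0]
    observed = int(occupied.size)
    density = observed / potential if potential else None
    mean = float(occupied.mean()) if observed else None
    median = float(np.median(occupied)) if observed else None
    return RepliconSummary(
        replicon_id=profile.replicon_id,
        size_bp=size_bp if size_bp is not None else 0,
        gc_percent=gc_percent if gc_percent is not None else float("nan"),
        gene_count=len(genes) if genes is not None else 0,
        potential_sites=potential,
        observed_sites=observed,
        insertion_density=density,
        mean_read_count=mean,
        median_read_count=median,
    )


def summarize_genome(summaries: list[RepliconSummary]) -> RepliconSummary:
    """Genome row: sums for sizes/genes/sites, pooled density, and the
    mean-of-means / median-of-medians read-count convention."""
    if not summaries:
        raise ValueError("no replicon summaries")
    potential = sum(s.potential_sites for s in summaries)
    observed = sum(s.observed_sites for s in summaries)
    sizes = sum(s.size_bp for s in summaries)
    means = [s.mean_read_count for s in summaries if s.mean_read_count is not None]
    medians = [s.median_read_count for s in summaries if s.median_read_count is not None]
    # count-weighted pooling for the conventional alternative
    w = [s.observed_sites for s in summaries if s.mean_read_count is not None]
    pooled_mean = (float(np.average(means, weights=w))
                   if means and sum(w) else None)
    # unweighted, like the read-count columns: the genome row summarizes
    # replicons, not bases
    gcs = [s.gc_percent for s in summaries if not np.isnan(s.gc_percent)]
    gc = float(np.mean(gcs)) if gcs else float("nan")
    return RepliconSummary(
        replicon_id=GENOME_ROW_ID,
        size_bp=sizes,
        gc_percent=gc,
        gene_count=sum(s.gene_count for s in summaries),
        potential_sites=potential,
        observed_sites=observed,
        insertion_density=observed / potential if potential else None,
        mean_read_count=float(np.mean(means)) if means else None,
        median_read_count=float(np.median(medians)) if medians else None,
        pooled_mean_read_count=pooled_mean,
        pooled_median_read_count=None,
    )


def _round(v, nd=2):
    return None if v is None else round(v, nd)


def summaries_to_frame(summaries: list[RepliconSummary]) -> pd.DataFrame:
    """Report table: densities, means and medians rounded to 2 decimals."""
    rows = []
    for s in summaries:
        d = asdict(s)
        for key in ("insertion_density", "mean_read_count",
                    "median_read_count", "pooled_mean_read_count",
                    "gc_percent"):
            d[key] = _round(d[key])
        rows.append(d)
    return pd.DataFrame(rows)


def write_summary_tsv(summaries: list[RepliconSummary], path: str | Path) -> None:
    summaries_to_frame(summaries).to_csv(path, sep="\t", index=False)


def write_summary_json(summaries: list[RepliconSummary], path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump([asdict(s) for s in summaries], fh, indent=2)
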