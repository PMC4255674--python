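"""Bundled published summary statistics for the R. leguminosarum bv. viciae
3841 (RLV3841) saturating mariner mutagenesis dataset.

The raw sequencing reads for that experiment are not publicly deposited, so
these per-replicon summary tables (seven replicons: the chromosome and six
plasmids) serve as a reference point for the report layer: the genome-level
figures — total potential and observed TA sites, pooled insertion density,
genome mean and median read count, total mapped reads and phenotypic-class
totals — are all recomputed here from the per-replicon rows rather than
stored.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .stats import RepliconSummary, summarize_genome

__all__ = [
    "load_replicon_summary",
    "load_class_summary",
    "rlv3841_genome_row",
]

CLASS_COLUMNS = ("ES", "GD", "NE", "GA", "NoData")


def _read(name: str) -> pd.DataFrame:
    with resources.files("inseqtools.data").joinpath(name).open() as fh:
        return pd.read_csv(fh, sep="\t")


def load_replicon_summary() -> pd.DataFrame:
    """Per-replicon saturation statistics (sizes, GC%, gene counts, TA-site
    counts, densities, occupied-site read-count means and medians)."""
    return _read("rlv3841_replicon_summary.tsv")


def load_class_summary() -> pd.DataFrame:
    """Per-replicon mapped-read totals and gene counts per phenotypic class
    (ES, GD, NE, GA, NoData)."""
    return _read("rlv3841_class_summary.tsv")


def rlv3841_genome_row() -> RepliconSummary:
    """Recompute the genome-level summary from the per-replicon rows."""
    df = load_replicon_summary()
    summaries = [
        RepliconSummary(
            replicon_id=r.replicon,
            size_bp=int(r.size_bp),
            gc_percent=float(r.gc_percent),
            gene_count=int(r.gene_count),
            potential_sites=int(r.potential_sites),
            observed_sites=int(r.observed_sites),
            insertion_density=float(r.insertion_density),
            mean_read_count=float(r.mean_read_count),
            median_read_count=float(r.median_read_count),
        )
        for r in df.itertuples()
    ]
    return summarize_genome(summaries)
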