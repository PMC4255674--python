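"""Four-state essentiality HMM over TA-site read counts.

Each TA site of a replicon emits its mapped-read count; the hidden state is
the local fitness effect of disruption: ES (essential — insertions lost
from the pool), GD (growth-defective — underrepresented), NE (neutral), GA
(growth-advantage — overrepresented).  Emissions are geometric on counts
c >= 0 with state means anchored to the replicon's occupied-site mean m
(mu = m/100, m/10, m, 5m), so each replicon is fitted independently and
copy-number differences in read depth cancel.  Transitions are sticky
(self-probability 0.999) — fitness effects are constant over runs of many
consecutive TA sites, and at ~80% site occupancy a cheaper state switch
lets short sampling gaps in neutral regions masquerade as essential runs —
and the most probable state path is found by Viterbi decoding, independent
of gene boundaries.

Genes are then classified by the modal state of their TA sites (ties broken
toward severity ES > GD > GA > NE), except that a gene containing a run of
ES sites longer than expected by chance — judged against the extreme-value
(Gumbel) approximation to the longest-success-run null — is called ES even
when the mode says otherwise.  Genes with no TA site are NoData.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .genome import GeneAnnotation, GeneSiteMap, TASiteIndex
from .mapping import InsertionProfile

__all__ = [
    "STATES",
    "HMMParams",
    "SiteStatePath",
    "GeneClassification",
    "ClassSummary",
    "fit_emission_params",
    "viterbi_decode",
    "longest_es_run_test",
    "classify_gene",
    "classify_replicon",
    "classify_genome",
    "classifications_to_frame",
    "write_state_wig",
]

#: state order; also the tie-break order for Viterbi path ties
STATES = ("ES", "GD", "NE", "GA")
#: tie-break order for modal gene classification (decreasing severity)
SEVERITY = ("ES", "GD", "GA", "NE")

MIN_FIT_SITES = 100
MIN_FIT_OCCUPANCY = 0.01


@dataclass
class HMMParams:
    """Emission means, transition matrix and initial distribution.

    ``emission_means[s]`` is the expected read count in state s; geometric
    emissions use success probability 1 / (1 + mu) so the mean is mu.
    """

    emission_means: dict[str, float]
    transition_matrix: np.ndarray = field(
        default_factory=lambda: _sticky_transitions(0.999))
    initial_probs: np.ndarray = field(
        default_factory=lambda: np.full(4, 0.25))

    def __post_init__(self):
        self.transition_matrix = np.asarray(self.transition_matrix, float)
        self.initial_probs = np.asarray(self.initial_probs, float)
        if not np.allclose(self.transition_matrix.sum(axis=1), 1, atol=1e-12):
            raise ValueError("transition rows must sum to 1")
        mus = [self.emission_means[s] for s in STATES]
        if not all(a < b for a, b in zip(mus, mus[1:])):
            raise ValueError("emission means must increase ES < GD < NE < GA")

    def geometric_p(self) -> np.ndarray:
        return np.array([1.0 / (1.0 + self.emission_means[s]) for s in STATES])


def _sticky_transitions(self_p: float) -> np.ndarray:
    off = (1.0 - self_p) / 3.0
    t = np.full((4, 4), off)
    np.fill_diagonal(t, self_p)
    return t


@dataclass
class SiteStatePath:
    replicon_id: str
    states: list[str]  # one of STATES per TA site, ordered as TASiteIndex


@dataclass
class GeneClassification:
    locus: str
    phenotypic_class: str  # ES/GD/NE/GA/NoData
    n_sites: int
    insertion_density: float | None
    mean_read_count: float | None
    modal_state: str | None
    es_run_length: int
    es_run_significant: bool


@dataclass
class ClassSummary:
    replicon_id: str
    counts: dict[str, int]  # keys ES, GD, NE, GA, NoData
    mapped_reads: int


class InsufficientSaturationError(ValueError):
    """Profile too sparse to anchor emission means."""


def fit_emission_params(profile: InsertionProfile) -> HMMParams:
    """Anchor the four emission means to the replicon's occupied-site mean.

    m = mean count over occupied sites; mu_NE = m, mu_GD = m/10,
    mu_GA = 5m, mu_ES = m/100 floored at 0.01.  Requires >= 100 sites and
    >= 1% occupancy: below that the anchor itself is meaningless and the
    library is not a saturating one.
    """
    counts = profile.counts
    occupied = counts[counts > 0]
    if counts.size < MIN_FIT_SITES or occupied.size < MIN_FIT_OCCUPANCY * counts.size:
        raise InsufficientSaturationError(
            f"replicon {profile.replicon_id!r}: {occupied.size} occupied of "
            f"{counts.size} TA sites; the library is not saturating enough "
            "to fit emission parameters — check insertion density")
    m = float(occupied.mean())
    return HMMParams(emission_means={
        "ES": max(m / 100.0, 0.01),
        "GD": m / 10.0,
        "NE": m,
        "GA": 5.0 * m,
    })


def viterbi_decode(profile: InsertionProfile, params: HMMParams) -> SiteStatePath:
    """Most probable state path in log space.

    Ties break toward the earlier state in the order ES, GD, NE, GA, both
    in the running maximisation and in the final backtrack.  Geometric
    emissions make the per-site log-likelihood linear in the count:
    log P(c | s) = log p_s + c * log(1 - p_s).
    """
    counts = profile.counts
    n = counts.size
    if n == 0:
        raise ValueError("empty profile")
    p = params.geometric_p()
    log_p = np.log(p)
    log_q = np.log1p(-p)  # log(1 - p)
    log_trans = np.log(params.transition_matrix)
    log_init = np.log(params.initial_probs)

    # emission log-likelihood matrix would be n x 4; compute per step to
    # keep memory flat on multi-megabase replicons
    back = np.empty((n, 4), dtype=np.int8)
    score = log_init + (log_p + counts[0] * log_q)
    for t in range(1, n):
        # cand[i, j] = score[i] + log_trans[i, j]
        cand = score[:, None] + log_trans
        best = np.argmax(cand, axis=0)  # first index wins ties
        back[t] = best
        score = cand[best, np.arange(4)] + log_p + counts[t] * log_q
    states = np.empty(n, dtype=np.int8)
    states[-1] = int(np.argmax(score))
    for t in range(n - 1, 0, -1):
        states[t - 1] = back[t, states[t]]
    return SiteStatePath(replicon_id=profile.replicon_id,
                         states=[STATES[s] for s in states])


def longest_run(values: list[str] | tuple[str, ...], target: str) -> int:
    best = run = 0
    for v in values:
        run = run + 1 if v == target else 0
        best = max(best, run)
    return best


def longest_es_run_test(
    states_in_gene: list[str],
    p_es_genomewide: float,
    n_sites: int | None = None,
) -> tuple[int, bool]:
    """Significance of the longest consecutive ES stretch in a gene.

    Under independent Bernoulli(p) site states, the longest success run R
    in n trials satisfies the extreme-value (Gumbel) tail approximation
    P(R >= r) ~= 1 - exp(-lambda) with lambda = (1 + (n-r)(1-p)) * p^r,
    the expected number of run start positions (position one, plus a
    failure-preceded start at each of the n-r later positions).  This
    tracks the exact run-length distribution to within ~1% for r >= 5,
    where the cruder rate n(1-p)p^r overstates the tail by up to n/(n-r).
    The run is significant at alpha = 0.05; a run of zero never is.
    """
    if not (0.0 < p_es_genomewide < 1.0):
        raise ValueError("p_es_genomewide must lie in (0, 1)")
    n = len(states_in_gene) if n_sites is None else n_sites
    r = longest_run(states_in_gene, "ES")
    if r == 0 or n == 0:
        return 0, False
    p = p_es_genomewide
    lam = (1.0 + (n - r) * (1.0 - p)) * p ** r
    tail = 1.0 - math.exp(-lam)
    return r, tail <= 0.05


def classify_gene(
    gene_map: GeneSiteMap,
    site_states: SiteStatePath,
    profile: InsertionProfile,
    p_es_genomewide: float,
) -> GeneClassification:
    """Modal-state gene call with the ES-run override.

    Density is the fraction of the gene's TA sites with >= 1 read; mean
    read count is over the gene's occupied sites (0 when none, matching
    how fully uninserted genes are reported).
    """
    idx = list(gene_map.site_indices)
    if not idx:
        return GeneClassification(
            locus=gene_map.locus, phenotypic_class="NoData", n_sites=0,
            insertion_density=None, mean_read_count=None, modal_state=None,
            es_run_length=0, es_run_significant=False)
    states = [site_states.states[i] for i in idx]
    counts = profile.counts[idx]
    occupied = counts[counts > 0]
    density = float(occupied.size) / len(idx)
    mean = float(occupied.mean()) if occupied.size else 0.0
    tallies = {s: states.count(s) for s in STATES}
    modal = max(SEVERITY, key=lambda s: (tallies[s], -SEVERITY.index(s)))
    run_len, significant = longest_es_run_test(states, p_es_genomewide)
    call = "ES" if significant else modal
    return GeneClassification(
        locus=gene_map.locus, phenotypic_class=call, n_sites=len(idx),
        insertion_density=density, mean_read_count=mean, modal_state=modal,
        es_run_length=run_len, es_run_significant=significant)


def classify_replicon(
    profile: InsertionProfile,
    ta_index: TASiteIndex,
    gene_maps: list[GeneSiteMap],
    params: HMMParams | None = None,
) -> tuple[list[GeneClassification], SiteStatePath, ClassSummary]:
    """Fit (unless given), decode, and classify every gene of one replicon."""
    if params is None:
        params = fit_emission_params(profile)
    path = viterbi_decode(profile, params)
    n_es = sum(1 for s in path.states if s == "ES")
    # genome-scale null for the run test: fraction of sites decoded ES,
    # clamped into (0, 1) so fully ES-free replicons stay testable
    p_es = min(max(n_es / len(path.states), 1e-9), 1.0 - 1e-9)
    calls = [classify_gene(gm, path, profile, p_es) for gm in gene_maps]
    counts = {s: 0 for s in (*STATES, "NoData")}
    for c in calls:
        counts[c.phenotypic_class] += 1
    summary = ClassSummary(replicon_id=profile.replicon_id, counts=counts,
                           mapped_reads=int(profile.counts.sum()))
    return calls, path, summary


def classify_genome(
    profiles: dict[str, InsertionProfile],
    ta_indexes: dict[str, TASiteIndex],
    gene_maps: dict[str, list[GeneSiteMap]],
) -> tuple[dict[str, list[GeneClassification]],
           dict[str, SiteStatePath],
           list[ClassSummary]]:
    """Classify every replicon independently (per-replicon emission fits
    absorb depth and copy-number differences between replicons)."""
    all_calls: dict[str, list[GeneClassification]] = {}
    paths: dict[str, SiteStatePath] = {}
    summaries: list[ClassSummary] = []
    for rid, profile in profiles.items():
        calls, path, summary = classify_replicon(
            profile, ta_indexes[rid], gene_maps.get(rid, []))
        all_calls[rid] = calls
        paths[rid] = path
        summaries.append(summary)
    return all_calls, paths, summaries


def classifications_to_frame(
    calls: list[GeneClassification],
    genes: list[GeneAnnotation] | None = None,
) -> pd.DataFrame:
    """Per-gene report table: locus, annotation, potential insertions,
    insertion density, mean read count, phenotypic class."""
    products = {g.locus: g.product for g in genes} if genes else {}
    rows = []
    for c in calls:
        rows.append({
            "locus": c.locus,
            "annotation": products.get(c.locus, ""),
            "potential_insertions": c.n_sites,
            "insertion_density": (None if c.insertion_density is None
                                  else round(c.insertion_density, 3)),
            "mean_read_count": (None if c.mean_read_count is None
                                else round(c.mean_read_count, 3)),
            "phenotypic_class": c.phenotypic_class,
        })
    return pd.DataFrame(rows)


_STATE_CODE = {s: i for i, s in enumerate(STATES)}


def write_state_wig(
    paths: dict[str, SiteStatePath],
    ta_indexes: dict[str, TASiteIndex],
    out_path: str | Path,
) -> None:
    """Integer-coded site states (ES=0, GD=1, NE=2, GA=3) as variableStep
    WIG for genome-browser viewing."""
    with open(out_path, "w") as fh:
        for rid, path in paths.items():
            fh.write(f"variableStep chrom={rid}\n")
            for p, s in zip(ta_indexes[rid].positions, path.states):
                fh.write(f"{p}\t{_STATE_CODE[s]}\n")
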