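# Methods

## Scope and data model

The package analyzes single-condition saturating mutagenesis experiments
with a *mariner* (himar1-type) transposon: one pooled mutant library, one
growth condition, reads sequenced from transposon–genome junctions. It
does not do comparative (input vs output pool) fitness analysis, Bayesian
gene-level posteriors, or Baum–Welch re-estimation.

Coordinates are 1-based inclusive throughout (GFF3/WIG convention). A TA
site is identified by the position of its T. Overlapping TA occurrences
(as in TATA) are distinct sites; dinucleotides containing an ambiguity
code are not sites, since no read can be mapped to them with zero
mismatches. A site belongs to a gene only if both of its bases lie inside
the gene's [start, end] — an insertion must fall fully inside a gene to
disrupt it — and a site shared by overlapping genes contributes to each
gene independently. Circular replicons are treated as linear; the only
effect is at most one wrap-around site per replicon.

## Read anatomy and tag extraction

A library read consists of a 53 bp transposon prefix whose final 27 bp are
the inverted repeat (IR), then 15–16 bp of genomic DNA captured by the
MmeI digest (MmeI cuts 20/18 nt from its recognition site, hence the
one-base uncertainty), then library adapter padding to the 187 bp
template. The default IR is the himar1-type repeat
`ACAGGTTGGATGATAAGTCCCCGGTCT`; any construct-specific IR can be supplied,
and the simulator and the processor share the constant through
`ReadStructure`.

Processing order is quality trimming, then IR search, then tag
validation. Quality trimming removes the 3′ suffix maximizing
Σ(floor − q) (the standard partial-sum rule used by BWA and cutadapt)
with floor Q20. The IR is located by exact substring search; an optional
mode (`ir_mismatches: 1`) tolerates one substitution. If at least 16
bases follow the IR, a 16-mer tag is taken and the mapper falls back to
its 15-mer prefix when the 16-mer has no exact genomic match; 15 bases
yield a 15-mer; fewer are a length failure. A valid tag must begin with
TA — the junction motif the transposon inserted into. Every read lands in
exactly one attrition category (quality fail, no IR, bad length, no TA,
tag), and the accounting is asserted on every run.

## Exact mapping

Tags are too short for mismatch-tolerant alignment to be meaningful, and
the zero-mismatch contract makes mapping a dictionary lookup. The index
holds, for every TA site, the forward 15/16-mers starting at the T and
the reverse-complement 15/16-mers of the windows ending at the A (which
also begin with TA, the motif being its own reverse complement); contexts
running off a replicon end are indexed only for lengths that fit. A k-mer
seen at two distinct sites is flagged ambiguous; tags hitting it are
multi-mappers and are discarded, and tags with no TA-anchored match are
unmapped, even if the sequence occurs elsewhere in the genome without a
TA. Both strands of a site pool into one count: saturation statistics and
the HMM operate per site, not per strand. Duplicate reads are not
collapsed — read counts, not fragment counts, are the abundance signal.

## Saturation statistics

Per replicon: insertion density = occupied sites / potential sites; mean
and median read count over occupied sites only (an unoccupied site means
the mutant is absent from the pool, not a zero measurement). The genome
row sums sizes, gene counts, and site counts, and pools density; for the
read-count and GC columns it reports the unweighted mean of per-replicon
means (and median of medians), the convention under which the published
genome-level figures for the RLV3841 dataset are arithmetically consistent
with their per-replicon rows. The count-weighted pooled mean is also
computed and emitted in a separate column, as the statistically
conventional alternative. Reported densities, means and medians are
rounded to 2 decimals; full precision is retained internally.

## Essentiality HMM

States ES < GD < NE < GA with geometric emissions on counts c ≥ 0,
P(c | s) = p_s(1 − p_s)^c, p_s = 1/(1 + μ_s). Emission means are anchored
to each replicon's occupied-site mean m: μ = (max(m/100, 0.01), m/10, m,
5m). Anchoring is per replicon, so copy-number-driven depth differences
between replicons (e.g. a high-copy plasmid) cancel out of the
classification; fitting requires ≥ 100 sites and ≥ 1% occupancy, below
which the library is not saturating and an error is raised. The geometric
family keeps the per-site log-likelihood linear in the count, and the
whole decode is exact dynamic programming (Viterbi) in log space over all
TA sites of a replicon, ignoring gene boundaries; ties break toward the
earlier state in the order ES, GD, NE, GA.

Transition self-probability defaults to 0.999, uniform off-diagonal,
uniform initial distribution. The stickiness was chosen from the decode
economics: a state switch costs ~8 nats, and at ~85% site occupancy a
run of k empty sites in a neutral region gains ~2.9 k nats toward ES, so
runs shorter than ~6 sites — common sampling gaps — do not flip, while
genuine essential stretches (tens of sites) flip decisively. A cheaper
switch (e.g. self-probability 0.98) lets 4-site gaps decode as ES, and
the run-test override below then promotes those genes to ES, which in
simulation at the default conditions caps gene-class recovery near 94%;
with 0.999 recovery is ~98%. The cost is a sensitivity floor: an isolated
essential segment shorter than ~6 TA sites with fully saturated flanks
may decode NE. All parameters are config-overridable.

A gene's class is the modal Viterbi state of its sites, ties broken
toward severity (ES > GD > GA > NE), a conservative flagging choice. A
gene is overridden to ES when its longest consecutive ES run r is
significant against the longest-run null: with p the replicon-wide
fraction of ES-decoded sites and n the gene's site count,
P(R ≥ r) ≈ 1 − exp(−λ), λ = (1 + (n − r)(1 − p)) p^r — the expected
number of run start positions (Feller's extreme-value/Poisson clumping
form). The cruder rate n(1 − p)p^r overstates the tail by up to
n/(n − r), violating 10% agreement with the exact run-length distribution
precisely in the r ≈ n cases the override exists for; the corrected rate
agrees with an exact dynamic-programming oracle to better than 1% for
r ≥ 5 across n ≤ 50, p ≤ 0.3. Significance is α = 0.05; a run of zero is
never significant; the override applies only to ES (depletion that is
locally total is the signature of essentiality; no analogous test is
applied to GD or GA). Genes with no TA sites are NoData. Genes at
replicon edges are classified from whatever sites they contain; there is
no edge padding.

## Synthetic data generator

The generator emulates the statistical structure of a saturating screen
in a multi-replicon alpha-proteobacterial genome. Defaults: two replicons
(500 kb + 150 kb) of i.i.d. bases at GC 0.61/0.576; non-overlapping genes
tiled at 0.95 genes/kb with lengths uniform in 300–1500 bp; true classes
drawn with proportions ES 5.6%, GD 4.0%, NE 89.9%, GA 0.5%; neutral-site
occupancy 0.88; occupied-site counts geometric (support ≥ 1) with mean
19.4; GD genes at 0.4× occupancy and 0.1× mean; ES genes at exactly zero
(an optional edge-permissive mode lets the terminal 10% of an ES gene's
sites behave neutrally, to stress the run-based classifier); the small
replicon at 1.14× copy number, which elevates its occupied-site mean but
not its density. Intergenic sites behave neutrally — saturated flanks are
what make context informative for the decoder. Note the two density
notions: 0.88 is the saturation of *permissive* sites; with essential and
depleted genes included, the realized genome-wide density comes out near
0.83, matching the published genome-level figure for this experiment
class.

Reads are emitted one per counted insertion: transposon prefix ending in
the IR, 16 bp of genomic context from a uniformly chosen strand of the TA
(falling back to the side whose full context fits at replicon edges),
adapter padding to 187 bp, constant Q40 qualities, and uniform
substitution errors at a configurable rate (default 0). At error rate 0
the full circle — simulate reads, process, map — reproduces the simulated
per-site counts exactly. At error rate e, a read survives processing and
unique mapping iff its 27 IR bases and first 15 tag bases are error-free
(an error in tag base 16 is rescued by the 15-mer retry), i.e. with
probability (1 − e)^42 ≈ 0.66 at e = 0.01; tests assert that derived
expectation.

Randomness is one master seed with deterministic per-(purpose, replicon)
substreams, so outputs are byte-identical across runs and adding a
replicon does not perturb earlier ones.

What the generator does not emulate: PCR/GC amplification bias,
positional bias within genes, read-length variation, indels, chimeric
reads, or biological growth dynamics beyond the class-conditional count
distributions. Passing recovery tests therefore demonstrate correctness
of the inference machinery under the stated statistical model, not
robustness to every artifact of real libraries.

## Known limitations

- ES and GD are only partially identifiable at these parameters: a GD
  site (occupancy ~0.35, occupied mean ~2 reads) has nearly the same
  expected log-likelihood under the ES and GD emission models, so roughly
  half of true GD genes decode as ES; the combined ES+GD (fitness-
  impaired) proportion is recovered to well within 2 percentage points at
  5,000 genes, and NE/GA proportions individually. Deeper sequencing
  separates the two classes.
- The per-gene recovery benchmark runs on a 650 kb, ~620-gene genome; the
  statistics that matter (occupancy, depth, class proportions, per-gene
  site counts) match the full-genome setting, and gene-level recovery
  depends on those, not on total genome size.
- The mapper is exact by design; genomes with extensive recent repeats
  will discard more tags as multi-mappers rather than mis-assign them.
- No correction is applied for replicon copy number beyond the
  per-replicon emission anchoring; absolute read counts across replicons
  are not comparable.
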