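# Methods

## The measurement model

Chemical-conversion m⁶A sequencing reads methylation as a mutation signal
during reverse transcription.  At a genomic adenosine covered by `n` reads
with true methylated fraction `f`, the observed mutated-read count is
modeled as

    mut ~ Binomial(n, bg_m + f · (full_m − bg_m))

where `bg_m` is the background mutation rate of unmodified A and `full_m`
the conversion rate of fully methylated A, both specific to the 5-mer
NNANN motif `m` around the site.  Both rates are estimated per library
from spike-in probes carrying known m⁶A fractions: the observed mutation
rate is regressed on the known fraction by ordinary least squares, and
the fitted values at f = 0 and f = 1 (clipped to [0, 1]) become
`bg_m` and `full_m`.  Linearity in `f` is the minimal model consistent
with a two-state (A vs m⁶A) conversion chemistry; the inverse

    f̂ = clip((raw − bg_m) / (full_m − bg_m), 0, 1)

is monotone in the raw rate with fixed points at background (0) and full
conversion (1).  Motifs absent from the spike-in panel borrow the mean
rates of motifs sharing their central 3-mer, falling back to the global
mean (logged; can be disabled, in which case such records fail with
`missing_motif`).

**Detection.**  A site passes when depth ≥ 20 and the *uncalibrated*
mutation rate is ≥ 5% — the cutoff is contrasted against raw background
noise (~0.5% on unmodified A), so it is applied before calibration; the
calibrated fraction is reported for every record regardless.  At depth
exactly 20 a single mutated read clears 5%, so one library alone has a
~9.5% false-positive rate on unmodified sites at 0.5% background
(binomial tail); the intended ≤1% operating point is reached by
intersecting two biological replicates (0.095² ≈ 0.9%), which is how the
tissue-atlas stage consumes calls.  The retained fraction of a
replicate-intersected site is the mean of the replicate fractions.
Sample comparability is summarized by the relative conversion ratio: the
mean over shared motifs of `full_m(sample) / full_m(reference)`.

## Exon-architecture statistics

* **Level** of an exon: sum of calibrated fractions of passed sites in
  its half-open genomic interval.  A site count (`level_mode="count"`
  style analysis) can be obtained by setting all fractions to 1.
* **Density**: `1000 · level / length` — an exact identity maintained by
  computing both from the same floats.
* **Length bins**: exons sorted by (length, transcript_id, index) and cut
  into equal-count bins (sizes differ by ≤ 1, larger bins first).
  Equal-count rather than equal-width binning keeps every bin populated
  under the strongly right-skewed exon-length distributions of plant
  genomes.
* **Junction profiles**: exons are anchored and laid on a signed offset
  axis in exon-relative coordinates (windows never cross introns).
  Internal exons contribute two copies — the 5′ junction with positive
  offsets running into the exon, and the 3′ junction with negative
  offsets running into the exon; last exons anchor at their 5′ junction;
  the stop-codon anchor is the first base after the stop.  For each
  window `[d, d + w)`: `raw_level` sums site fractions, `coverage` counts
  exon copies overlapping by ≥ 1 nt, and `covered_bases` sums the
  overlapping bases.
* **Likelihood**: `raw_level / coverage` (exon-count mode, the default)
  or `raw_level / covered_bases` (base-pileup mode), undefined at zero
  coverage.

The likelihood exists to remove the coverage confound: raw windowed
levels decay with |offset| simply because fewer exons extend that far.
The two normalizations are not equivalent at window boundaries.  In
exon-count mode a copy that overlaps a 25-nt window by a single base
still counts fully in the denominator, so windows partially overlapping
many segments — worst of all the windows straddling the dual-anchored
junction itself — are biased low by up to ~2× even under perfectly
uniform deposition.  Base-pileup mode divides by exactly the number of
bases at risk and is unbiased at every offset (under a uniform per-base
deposition probability `p` its expectation is `p` everywhere).  The
flatness checks therefore use base-pileup mode; exon-count mode remains
the default output because its scale (level per covering exon,
≈ `p · w` away from boundaries) matches how windowed levels are usually
read.

**Peak and breakpoint detection** operates on the likelihood restricted
to defined offsets: a centered, edge-truncated moving average (default 5
windows) smooths the track; the smoothed maximum is reported as a peak if
its prominence over the track median exceeds a threshold.  The largest
jump between consecutive unsmoothed values is reported as the breakpoint
candidate, at the offset where the new value starts.  Because a window
statistic localizes a signal to its midpoint, peak positions are best
compared to deposition coordinates after adding `window // 2`.

## Tissue atlas and differential methylation

Commonness requires *measured* presence: a site unmeasured in a tissue
(insufficient depth) is missing, not zero, and a "common" site must be
present in every tissue.  Phase analysis groups tissues into reproductive
vs vegetative panels (supplied as configuration; the Arabidopsis
convention groups flower, seed and silique as reproductive).  Windowed
overlap between two site sets counts a site as overlapped when the other
set has a site within ±w nt on the same chromosome and strand (default
w = 5; the counts are directional).  The variance profile aggregates
per-tissue fraction sums per metagene bin and reports the coefficient of
variation (sample SD / mean) across tissues; rank normalization maps each
site's tissue fractions to [0, 1] via average ranks, making levels
comparable across species before a PCA.

Two-condition comparison pools replicate counts per condition and applies
a two-sided Fisher exact test per site, with verdicts requiring both
p < α (default 0.05) and an effect-size floor |Δf| ≥ 0.1; sites with
pooled depth < 20 in either condition are `undertested`.  Fisher on
binomial counts is exact and conservative, so the empirical type-I error
sits below nominal.

## Conservation

Ortholog pairs (one-to-one, duplicates rejected) are compared at the
spliced-transcript level — where m⁶A lives — using global affine-gap
alignment (match 2, mismatch −1, gap open −5, gap extend −1; a gap of
length L costs open + (L−1)·extend; T ≡ U).  An aligned column is a
conserved A when both rows carry A, its ±1 columns exist and are gap-free
in both rows, and the −1 bases agree across rows as do the +1 bases.
Flank consistency is cross-species base equality (not consensus-based).
A conserved A methylated (passed site) in both species is a conserved m⁶A
pair; pairs whose full 5-mer contexts also match are flagged.  Motif
classes from the shared flanks: RAC (left ∈ {A, G}, right = C), GAT
(left = G, right = T/U), else other.  In the substitution-only recovery
experiment the aligner is run with a prohibitive gap penalty (ungapped
global alignment): when the divergence process is known to contain no
indels, any gapped optimum is an alignment artifact, and with default
penalties roughly 0.5% of 300-nt pairs at ~19% pairwise divergence hit
one.

## Phenotype association

Transcripts are grouped by where their passed sites sit (3′UTR-only /
non-3′UTR / mixed / none; mixed transcripts are excluded from the
two-group contrast and reported separately).  Fraction sums are
stratified into five left-open right-closed bins
(0,0.2], (0.2,0.4], …, (0.8,1]; sums above 1 — possible for multi-site
transcripts — are clamped into the top bin and flagged; non-positive sums
are excluded.  Group contrasts use the one-tailed Wilcoxon rank-sum test
(exact null distribution when both groups have ≤ 25 tie-free values,
normal approximation otherwise) plus ECDF exports.  Lifetimes are
analyzed on the log scale in the simulation oracle; the rank-based test
itself is scale-free.  Writer dependence classifies each WT-passed site
with adequate mutant depth as `abolished` (mutant raw rate below the
detection cutoff), `reduced` (mutant passes but fraction fold-change
≤ 0.5 with Fisher p < 0.05) or `independent`; the reduced/abolished
thresholds are explicit configuration, as no standard convention exists.

## The synthetic-data generator

Defaults (one chromosome, non-overlapping genes of alternating strand):

| parameter | default | rationale |
|---|---|---|
| exons per gene | uniform 2–8 | plant multi-exon genes |
| internal exon length | log-normal(meanlog 5.0, sdlog 0.6), min 30 nt | median ~150 nt, plant-like |
| last exon length | log-normal(meanlog 6.2, sdlog 0.4) | carries the 100–400 nt 3′UTR |
| depth | NB(mean 100, dispersion 0.3) | uneven coverage |
| background rate | uniform [0.002, 0.01] per motif | brackets the ~0.5% regime |
| full conversion | uniform [0.70, 0.95] per motif | realistic conversion spread |
| conversion jitter | ±5% per library | read out by the spike-ins as conversion ratios near 1 |
| deposition | 3′UTR 0.10 / CDS 0.02 / 5′UTR 0.01 per candidate A | 3′UTR enrichment |
| site fractions | Beta(2, 2) | broad unimodal stoichiometries |
| tissues | 4 × 2 replicates; shared-site probability 0.5 | shared + specific sites |
| ortholog divergence | substitution rate 0.1/species, no indels | conserved-site truth stays positional |
| phenotype | log-value = 1 + 0.5·(3′UTR fraction sum) + N(0, 0.3) | the dependency the association stage assumes |

Alternative deposition models: uniform per-base probability, and a
Gaussian bump (`stop_peak`) of configurable amplitude/σ anchored at the
last-exon junction or the first base after the stop codon, used to test
peak recovery (probabilities above 1 are rejected).

A master seed spawns named child streams (genome, truth, pileup,
orthologs, phenotypes, peaks), so extending one stage never perturbs the
draws of another; identical configurations produce byte-identical files,
and the ground truth (per-site fractions, tissue membership, per-motif
rates, conserved columns) is serialized beside the data.

What the generator does *not* emulate — and hence what passing tests do
not establish about real data: read-level error profiles and UMI
structure, isoform diversity (one transcript per gene), strand- or
GC-dependent coverage bias, indel evolution, correlated deposition along
a transcript, and motif-dependent deposition preferences beyond region
weights.

## Numerical choices and degenerate inputs

* Coordinates are 0-based half-open internally; all emitted tables are
  1-based.  The stop codon counts as CDS; the first base after `cds_end`
  opens the 3′UTR.
* One canonical transcript per gene: longest CDS, then longest
  transcript, then lexicographically smallest ID.
* Single-exon transcripts are labelled `single` and excluded from
  internal/last-exon analyses but included in metagene profiles.
* Fitted calibration rates are clipped to [0, 1]; motifs with a single
  spike-in level are dropped with a warning, inverted fits are flagged
  invalid; `estimate_fraction` refuses bg ≥ full.
* Fail-reason precedence: missing_motif > low_depth > below_cutoff.
* Zero-depth pileup rows get raw rate 0.
* Equal-count binning breaks length ties by (transcript_id, index), so
  bin assignment is order-independent.
* Alignment ties break by Biopython's deterministic enumeration order.
* Rank normalization requires ≥ 2 measured entries per row; CV bins with
  zero mean are missing, not zero.

## Problem sizes used by the checks

The verification suite uses 2,000 sites at depth 500 for estimator
recovery; 5,000 null + 2,000 modified sites for the detection operating
point; 10,000 exons for the density identity and likelihood-flatness
nulls (flatness measured where ≥ 50 exons cover the window, with the
exon-length log-normal widened to meanlog 6.0, sdlog 0.45 so that deep
coverage extends across the ±500 nt span under study); 500 genes × 10
seeds for stop-peak recovery; 200 ortholog pairs of 300 nt; 1,000 random
sites for the overlap oracle; n = 2,000 with 200 null replicates for the
phenotype association; 1,000 sites at depth 100 for the differential
test; and 50 genes × 4 tissues × 2 replicates for the end-to-end run.

## Known limitations

* The calibration inverse assumes the linear two-state model; saturation
  or motif-by-fraction interactions in real chemistry would bias `f̂`.
* Sites are assigned to transcripts by span containment; overlapping
  genes (not generated synthetically) would need an explicit assignment
  policy.
* The exact Wilcoxon path is limited to small tie-free samples; large
  groups use the normal approximation with tie correction.
* `compare_conditions` pools replicates, ignoring between-replicate
  overdispersion; a beta-binomial test is the natural extension point.
* Peak detection reports a single global maximum and one breakpoint; it
  is not a general multi-peak caller.
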