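# Methods

This note documents the models, rules and numerical choices behind each
stage, the assumptions of the synthetic-data generator, and the limits of
what the test suite demonstrates.

## Coordinates and formats

All internal coordinates are 0-based half-open (BED convention).  BED input
is taken verbatim; VCF positions are decremented exactly once on input and
incremented once on output, and INFO `END` (1-based inclusive) maps to the
internal second-breakpoint position as `END − 1`.  Bulk site tables
(bedMethyl CpG calls, depth intervals) are pandas DataFrames with fixed
schemas; record dataclasses carry per-record invariants (e.g.
`0 ≤ n_mod ≤ n_valid`).  The bedMethyl reader accepts both the full
18-column modkit layout and a minimal BED9+2 dialect, with haplotype tags
taken from an explicit argument, a designated trailing column, or
modkit-partition-style file naming, in that order of precedence.

## Consensus SV merging

Two calls match when they have the same SV type and chromosome pair and
both breakpoints lie within a tolerance (default 500 bp per end, roughly
the placement jitter of long-read callers; exposed as a flag).  Insertions
additionally require a length ratio ≥ 0.5, since both of their breakpoints
collapse to one locus.  Duplications and insertions are never cross-matched
(conservative; cross-type equivalence is caller-specific).  The match graph
is reduced by single-linkage connected components — deterministic,
order-free, and standard for SV merging; chain merging is mitigated by the
tolerance.  A component is retained when it contains ≥ 2 distinct callers
and its representative length is ≥ 50 bp; translocations carry no
meaningful length and are exempt from the size filter (their counts are
reported alongside the other types).  Representative breakpoints and length
are per-field lower medians over members, so integer coordinates stay
integers and ties resolve deterministically.  Type equality is enforced
across callers; matching on breakpoints alone was the open alternative and
is deliberately not offered, because it silently merges biologically
distinct events at shared hotspots.

## Signature refitting

SBS96 channels are pyrimidine-strand substitution × trinucleotide context
in COSMIC order; purine-reference substitutions are reverse-complemented
together with their flanking bases.  SV32 channels are
{clustered, non-clustered} × {del, tds, inv} × five size bins
(1–10 kb, 10–100 kb, 100 kb–1 Mb, 1–10 Mb, > 10 Mb) plus clustered and
non-clustered translocations; events below 1 kb fall in the smallest bin,
and insertions are skipped with a counted warning (the scheme has no
channel for them).  "Clustered" uses a breakpoint-density rule — an event
is clustered when ≥ 10 consensus breakpoints fall within a 5-Mb window
around one of its breakpoints on the same chromosome (both thresholds
configurable).  This is a deliberate simplification of the
piecewise-constant-fit clustering used by the full COSMIC derivation, which
is out of scope here.

Exposures solve min‖c − S e‖₂ subject to e ≥ 0 with the Lawson–Hanson
active-set solver (`scipy.optimize.nnls`); all signatures in the supplied
matrix are fit, with no sparsity penalty or forward selection.  Percent
contributions divide by total fitted exposure (not total mutations), so
they always sum to 100 when any exposure is positive; an all-zero catalog
returns all-zero exposures with percents defined as 0.  The tests verify
the KKT conditions by perturbation, scale equivariance, and
channel-permutation invariance, and cross-check recovery of planted
multinomial mixtures.

## Binned coverage

Regions are tiled into 1-kb bins; a final remainder ≤ width/2 is merged
into the previous bin, a longer one is kept (a region shorter than one
width is a single bin).  The alternative dialect that keeps every partial
bin is available (`partial="keep"`) because published bin totals depend on
this choice.  Bin and genome-wide depth summaries are per-base medians,
computed length-weighted over depth intervals without materializing
per-base arrays; on even counts the lower median is taken, keeping integer
depths integral.  Bin values are normalized by the sample's genome-wide
per-base median (median of per-bin medians was the open alternative; the
per-base reading matches the stated normalization and is scale-invariant
either way).  Bins with no overlapping depth data are missing (NaN), never
zero: zero-imputation would fabricate hypo-coverage.  AluY elements are
summarized per insertion rather than per bin, because most insertions
(~300 bp) are much shorter than a bin.

Full-length TE selection uses strict length thresholds (> 6 kb L1HS,
> 300 bp AluY, > 1 kb SVA, > 1 kb ERV).  Group dispersion is compared with
Levene's test centered at the group mean (classic Levene, as stated;
Brown–Forsythe median centering is a config switch), with W referred to
F(1, n₁+n₂−2).  Degenerate inputs where the deviation spread is 0/0 return
(W = 0, p = 1).

## Satellite methylome comparison

The bin-level quantity is the coverage-weighted pooled ratio
Σ n_mod / Σ n_valid over CpG sites in the bin — "methylated reads over
total reads" — with an unweighted mean-of-site-ratios variant available,
since the two differ when coverage varies within a bin.  Sites with zero
coverage contribute nothing; a bin whose sites are all uncovered is
missing.  Site-level genome-wide summaries default to a minimum read
support of 1; the ≥ 3-read filter applies only to haplotype-resolved
promoter profiles, where per-haplotype coverage is halved.

The cohort matrix pools active- and inactive-HOR bins into one matrix with
per-bin class labels (matching a single heatmap with a class side bar);
rows missing in any sample are dropped complete-case, with the dropped
count logged — imputation would invent methylation.  PCA treats samples as
observations and bins as centered, unscaled features (ratios share a scale;
unit-variance scaling would inflate near-constant bins); component signs
are fixed by making the largest-magnitude loading positive, and a constant
matrix yields all-zero coordinates rather than an error.  Sample clustering
is agglomerative with Ward linkage on Euclidean distances between sample
columns (scipy linkage; its deterministic tie handling is relied on, and
partitions are label-normalized by first appearance so sample order does
not matter).  Tumors split into high/low HRD groups at score ≥ 63, the
published optimal cutoff for HRD positivity in this tumor type.  Group
comparisons are two-sided Student t-tests (equal-variance unpaired, or
paired); the degenerate zero-variance-equal-means case returns p = 1.

## Haplotype-resolved THOR classification

Within the locus, phased CpG calls are split by haplotype; a site with
fewer than 3 supporting reads on a haplotype is dropped from that haplotype
only, and unphased records are ignored.  Site ratios are smoothed with a
centered 100-bp sliding window evaluated at retained CpG positions (edge
windows shrink; no padding; a fixed-step grid variant is configurable).
A haplotype is hypermethylated when its mean smoothed value inside the THOR
span is ≥ 0.6; a call is biallelic when both are, monoallelic when exactly
one is and the other's mean is ≤ 0.3, and none otherwise — a
hyper/intermediate pair is "none" flagged indeterminate.  The 0.6/0.3
thresholds are package defaults chosen to separate the visually unambiguous
regimes, not published constants; every call records the thresholds used.
Fewer than 3 retained THOR sites on a haplotype is an error, not a "none":
silence and absence of evidence must not be conflated.  Read haplotagging
itself is upstream; the module consumes tags.

## Synthetic-data generator

The generator's defaults define the study-like conditions used throughout
the tests: six tumor/normal pairs; a 1.6-Mb two-chromosome reference with
satellite arrays (active HOR 200 kb, inactive HOR 50 kb, HSat and other
pericentromeric classes) and TE insertions whose lengths straddle the
full-length filters; ~30× coverage; four callers with sensitivities
0.95/0.90/0.85/0.80; 200 truth SVs with 100-bp breakpoint jitter; catalogs
of 5,000 mutations.

* **Depth** is gamma-Poisson (negative binomial, var = m + φm², φ = 0.05)
  per 100-bp interval; tumors have φ multiplied by an inflation factor
  (default 4) inside TE spans.  A single dispersion parameter makes the
  planted variance effect interpretable.
* **Methylomes** draw per-site means from a Beta around the planted
  class/group mean (concentration 30) and counts binomially at Poisson(30)
  coverage with 1% site dropout.  Planted satellite means are
  0.75 (normal) / 0.55 (high-HRD tumor) / 0.35 (low-HRD tumor); L1HS and
  ERV hypomethylate strongly in tumors, AluY and SVA mildly, and the
  genomic background moderately.  Effect sizes are chosen for test power,
  not biological calibration — no quantitative group gaps are published.
* **SV call sets** derive from a truth table.  Truth breakpoints sit on a
  2.5-kb grid consumed without replacement, and per-caller jitter is a
  normal truncated at ±2.4 SD, so calls of the same event always fall
  within the 500-bp tolerance and calls of different events never do;
  intra-chromosomal jitter shifts both breakpoints by one offset, so the
  reported length equals the truth length (long-read callers agree on
  length far more than on placement).  False positives are caller-private
  singletons from the same exclusive grid.  Consensus output is therefore
  exactly predictable from the truth table — the pipeline's strongest
  oracle.
* **Catalogs** are Multinomial(n, S·w) draws for known weights w.
* **Phased loci** place CpGs with ~15-bp mean spacing over a 3-kb promoter
  containing a 1-kb THOR span, with per-haplotype planted means and a 10%
  sparse-coverage regime so sub-3-read sites genuinely occur.

Randomness: one master seed; each (operation, sample) pair derives its own
stream by stable hashing, so adding a sample never reshuffles another's
data, and all generators are byte-deterministic.

What the generator does **not** emulate: read-level sequence content, SV
breakpoint homology and adjacency structure (no complex rearrangements),
spatially correlated methylation, copy-number-driven coverage steps,
purity/ploidy mixtures, and caller-specific error profiles.  Passing tests
therefore demonstrate that the implementations are correct for data obeying
the stated models — not that the statistical conclusions transfer to any
particular real cohort.

## Problem sizes and runtime

Tests and the acceptance script run on the mini genome (1.6 Mb; ~100k CpGs
per sample) with the cohort sizes above: 20 cohorts for consensus-vs-truth
agreement, 200 replicates for NNLS recovery, 100/1,000 replicates for
Levene power/type-I calibration (on a dedicated 200-bin TE genome), and
300 phased loci for THOR accuracy.  These sizes keep the full suite in the
low tens of seconds while leaving Monte-Carlo margins far from their
thresholds.

## Known limitations

* Same-chromosome breakend pairs without a declared simple type are skipped
  rather than re-interpreted; orientation-based classification is future
  work.
* The SV32 clustering rule is a density heuristic, not the full
  segmentation-based derivation.
* Ward tie-breaking follows scipy's implementation rather than an explicit
  lowest-index rule; ties are measure-zero for continuous data.
* The published annotation-count checks (full-length TE counts and HOR bin
  totals on the complete human assembly) require the published annotation
  files; the shipped tests verify the same rules on constructed annotations
  with known counts.
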