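# Methods

`omnicall` detects SNVs, indels, structural variants and read-depth CNVs
from one pass over a coordinate-sorted BAM. This note records the model,
its assumptions, the parameters that matter, the numerical choices, what
the bundled simulator does and does not emulate, and known limitations.

## Insert-size model

All discordance and matching tolerances derive from the library's insert
distribution, estimated from a sample of proper pairs (default cap
10,000,000; at least 1,000 required, else a hard error). Template length
is the BAM TLEN absolute value, taken once per pair from the leftmost
mate; TLEN = 0 pairs are excluded. Because insert distributions are
right-skewed, thresholds are rank-based rather than moment-based:

1. compute the sample median;
2. drop values above 5× the median (library-prep chimeras, mismapped tails);
3. set `i_min`, `i_max` to the empirical quantiles at Φ(−3) ≈ 0.0013499 and
   Φ(3), the levels at which a normal distribution would sit three
   standard deviations from the median. Quantiles use linear interpolation
   between order statistics (numpy's default), fixed and documented
   because any rank rule differing by one order statistic moves the
   thresholds by well under a base at realistic sample sizes.

The read length `L_r` is the modal length of sampled reads (robust for
fixed-length Illumina libraries; for trimmed libraries the mode tracks
the dominant length). A crude bimodality check (density at the median vs
the quartiles) warns when the sample looks like a mixed library, which
should be analysed in separate runs.

Pairs are classified from mapping geometry only (flags are not trusted):
same-chromosome FR pairs inside `[i_min, i_max]` are concordant; larger
inserts are deletion evidence; smaller inserts are treated as insertion
evidence (a documented choice — short fragments can also be artifacts);
RF (everted) pairs indicate tandem duplication, same-strand pairs
inversion, cross-chromosome pairs translocation.

SV-dense genomes contaminate the insert sample: fragments spanning an
uncompensated homozygous deletion inflate TLEN by the deletion length. At
realistic SV density the contaminated mass stays well below the 0.135%
tail and the thresholds are unaffected; the simulation used by the
end-to-end tests was laid out so the contaminated fraction is under the
tail mass (roughly 150 of ~180,000 sampled pairs).

## Evidence pass

One sweep per chromosome over primary alignments (secondary records are
ignored; supplementary records are used only through the primary's SA tag
so depth is never double-counted). Per base the scan accumulates:

- **physical depth** — sequenced read spans, the unsequenced gap between
  concordant mates, the feasibility extents of discordant pairs, and the
  junction bases of clip/split evidence. This approximates fragment
  (physical) coverage and is the binomial `n` for significance;
- **allele counts** per A/C/G/T with base-quality and MAPQ sums, from
  aligned pairs with base quality ≥13;
- soft-clip boundary counts and unmapped-mate counts.

MAPQ 0 reads count toward depth but produce no candidates (threshold
configurable): they cannot be told apart from mismappings.

Breakpoint candidates:

- a CIGAR deletion of length k at position p yields exact start/end
  candidates at p and p+k (weight 1.0); an insertion yields candidates at
  the insertion point carrying the inserted sequence;
- a split alignment (primary + SA, both segments ≥20 aligned bases)
  yields exact candidates at the two junction-facing segment edges, typed
  by relative placement and orientation (colinear gap → DEL, reversed
  order → DUP, strand flip → INV, different chromosomes → breakend pair);
- a discordant pair votes at every base at which a breakpoint would have
  let it form a concordant fragment. The window width is `i_max − i_min`;
  placement per orientation: deletion windows open after the left read's
  end and before the right read's start; duplication windows sit outside
  the everted pair; inversion windows follow the junction the pair spans
  (FF: left junction, RR: right). Implied lengths: insert − i_median
  (deletion), i_median − insert (insertion), outer span + i_median − 2L_r
  (duplication), outer span (inversion — approximately unbiased at the
  junctions; no exact single-pair estimator exists because the reflected
  read's offset is unobservable). The mate's clipping is unknown in a
  single pass, so its extent is taken as one read length.
- clip anchoring: when a ≥5-base soft-clip boundary falls inside a
  window, candidates at boundary bases keep weight 1.0 and all others
  drop to 0.5 (all boundary bases keep full weight when several exist).
  This gives base resolution while a single aberrant read cannot
  redefine the breakpoint.

Cross-chromosome split candidates are used only on the primary's
chromosome, keeping per-chromosome processing independent (each junction
side is anchored by reads whose primary maps there).

## Clustering

Clusters are keyed by (position, side, SV type); the length dimension is
realized through the adaptive tolerance: a candidate with implied length
`L_disc` may join a cluster with running weighted mean `L_bc` and support
`x_bc` when `|L_bc − L_disc| ≤ (i_max − i_min + i_median − 2L_r)(1 + 1/x_bc)`.
Among eligible clusters the one with the most support wins; ties go to
the closest mean length, then creation order. A read id can appear at most
once per cluster (it may support many positions). Candidates are processed
in position order with exact evidence first at each position; the order is
part of the contract because greedy clustering is order-sensitive.

Within-read indel candidates are base- and length-exact, so their joining
tolerance is exact agreement (±0.5): conflicting 2- and 3-base deletions
at one base remain separate clusters, as they are genuinely distinct
alleles.

## Significance

A cluster with weighted support `x` (rounded half-up to an integer — the
tables are integer-indexed) at physical depth `n` gets
`p_bc = Pr(Binomial(n, p) ≥ x)` with `p = 10^(−m/10)`, `m` the MAPQ
threshold (default 20, `p` = 0.01). Tails are computed by log-space
summation (`lgamma`-based, clamped to [0, 1]); rows up to `n_max`
(default 1000) are precomputed per `m` and cached as a JSON file with a
checksum; a corrupt cache is rebuilt with a warning; deeper positions
fall through to direct computation. Clusters with `p_bc ≤ α` survive;
α defaults to 1e-5 (a genome-wide multiplicity allowance; never stated
upstream, exposed as `--alpha`).

## Matching

Per chromosome and SV type, surviving clusters are reduced by
non-maximum suppression within a radius of `i_max − i_min` (the
feasibility-window scale): the strongest cluster represents the
breakpoint, anchored clusters winning ties. Without this step every base
of a feasibility window would yield a near-duplicate call.

Start/end pairs must satisfy both `|B_s + L_s − B_e| ≤ c(i_max − i_min)`
and `|B_e − L_e − B_s| ≤ c(i_max − i_min)` with `c = 3/8`; pairing is
greedy by descending combined support, each cluster used once. Reported
length: the span `B_e − B_s` when both sides are clip-anchored (then the
span is base-exact), otherwise the mean of `L_s`, `L_e` and the span.
Small indels (<50 bases) match at a ±2-base window, the same resolution
at which indels are benchmarked. Insertions occupy one locus and pair by
position proximity and length agreement. Translocation clusters carry
mean mate coordinates and pair genome-wide after all chromosomes under
the analogous two-sided criterion, emitted as reciprocal breakends.

## SNVs

Bases with ≥`k_min` (default 3) alternate observations are scored with
the same binomial tail (`n` = physical depth, `x` = alt count) and kept
when `p_bc ≤ α`, mean alt base quality ≥ `Q_min` (default 20) and mean
alt MAPQ ≥ `m`. These filter values are this package's own defaults — the
filter set is deliberately simple and fully configurable. Genotypes use
an allele-fraction heuristic (≥0.8 of sequenced depth → 1/1), flagged as
heuristic. Reads supporting an SV still count toward SNV depth,
consistent with the single-pass design.

## Read-depth CNVs

A transparent windowed method: fixed-width windows (default 100 bases) of
mean aligned-read depth, GC-corrected by median scaling within 1% GC bins
(bins with <20 windows borrow neighbours), then hysteresis segmentation —
runs extend over windows beyond weak thresholds (0.8×/1.2× median) and
are emitted as DEL/DUP when they contain ≥5 windows beyond the calling
thresholds (0.6×/1.4×), spanning first-to-last strong window. Hysteresis
prevents a 3-copy duplication (1.5× depth) from fragmenting at the 1.4×
boundary. Windows use aligned-read depth rather than full physical depth:
fragment-gap coverage collapses around SV junctions (spanning pairs are
discordant), which would fabricate deletion dips at every junction.
All-N windows are excluded. CNV calls are written separately (BED +
symbolic VCF, IMPRECISE); overlaps with paired-end/split-read calls are
left to the consumer — the two representations are complementary, not
merged.

## Duplicate filtering

Optional (`--dup-filter`, on by default), via a per-chromosome prescan so
pair decisions are global before evidence collection. The key is
(chromosome, external coordinate, strand) for both mates, canonicalized
under mate swap; the read's own external coordinate is its soft-clip
adjusted 5′ end, the mate's is taken from the record's mate fields
without clip adjustment (single-pass constraint). Cross-chromosome pairs
are eligible. Within a key group the pair with the highest summed MAPQ
survives (mate MAPQ from the MQ tag when present, else twice the own
MAPQ), ties broken by encounter order. Single-end reads deduplicate on
(chromosome, adjusted coordinate, strand).

Note that coincidental coordinate collisions between independent
fragments are genuine key collisions, not an error: at 30× over a
megabase, a few dozen such collisions are expected and are filtered like
PCR duplicates, exactly as a coordinate-based filter on real data would.

## Simulator

The fixture generator builds a random reference (uniform or per-10kb
variable GC), applies the planted variant list to construct diploid
haplotypes as block mappings (deletion = skipped block, duplication =
repeated block, inversion = reverse-strand block, insertion = unanchored
block, translocation = spliced chromosome compositions), draws fragments
with normal inserts, and maps each read back to the reference through the
blocks. Alignment is synthesized, not produced by an aligner: CIGARs,
clips at SV breakpoints, supplementary split records (segments ≥20
bases, SA tags), discordant TLEN and orientation all follow
deterministically from the block structure — idealized mapping with
uniform MAPQ 60 and flat base quality 35, plus uniform substitution
errors at the configured rate. Duplicate fragments are re-emitted copies
with fresh errors. Identical spec + seed give byte-identical outputs.

What this does **not** emulate — and therefore what passing tests do not
show about real data: repeat-induced mismapping and MAPQ degradation,
reference bias, quality decay along reads, indel sequencing errors,
chimeric library artifacts, coverage waves beyond the optional GC bias.
Recovery rates on simulator output are upper bounds on real-data
performance; the statistical machinery (thresholds, clustering, matching)
is what the tests validate.

## Problem sizes used in the tests

Unit tests run on constructed records and ≤150 kb simulations; the
end-to-end recovery test uses a ~1.2 Mb diploid genome at 30× (insert
N(500, 50), read length 100, 0.1% error, 5% duplicates) with 100 SNVs,
8 indels (3–40 bases), 7 SVs (300–5000 bases) and one translocation —
sizes chosen so every evidence path (including the 0.135% insert-tail
estimation, which needs ~10⁵ pairs) is exercised by a suite that runs in
a couple of minutes on one CPU.

## Known limitations

- Greedy clustering and greedy matching are order-dependent and not
  globally optimal; both are deterministic and documented.
- No realignment, local assembly, base-quality recalibration or genotype
  likelihoods; SV genotypes are not estimated.
- Insertion lengths beyond read-scale evidence are lower bounds from
  insert-size deficit (at most about `i_median − 2L_r`).
- Single-end mode covers CIGAR/split evidence, SNVs and depth CNVs only;
  tolerances then derive from the read length.
- Mate-pair (long-insert) libraries and mixed libraries are out of scope;
  the latter trigger a warning.
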