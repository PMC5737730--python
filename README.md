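# omnicall

Single-pass comprehensive variant detection from aligned short reads:
SNVs, indels, structural variants (deletions, duplications, insertions,
inversions, translocations) and read-depth CNVs from one sweep over a
coordinate-sorted BAM, with optional inline duplicate filtering.

Most WGS workflows run a separate caller per variant class, re-reading and
re-analysing the same alignments several times. `omnicall` collects every
line of evidence — mismatches, within-read indels, soft-clips, split
alignments, discordant pairs, unmapped mates, and physical read depth — at
each reference base in a single pass, then turns that evidence into typed
variant calls with a shared statistical model.

## The model

**Insert-size thresholds.** From a sample of proper pairs the library's
concordant insert range `[i_min, i_max]` is estimated rank-based: values
above 5× the median are discarded, then `i_min`/`i_max` are the empirical
quantiles at Φ(±3) ≈ 0.00135/0.99865 — the levels a normal distribution
would place three standard deviations from the median. Pairs outside this
range, or with aberrant orientation or mates on different chromosomes, are
discordant and vote for SV breakpoints at every reference base at which a
breakpoint would make them concordant; a soft-clip (≥5 bases) or split
alignment (each segment ≥20 bases) inside such a window pins the exact
base, and all unpinned votes are half-weighted.

**Breakpoint clustering.** At each base, candidate reads are clustered by
SV type and implied length `L_disc`. A read joins a cluster with mean
length `L_bc` and weighted support `x_bc` when

```
|L_bc − L_disc| ≤ (i_max − i_min + i_median − 2·L_r) · (1 + 1/x_bc)
```

so the admissible spread tightens as support accumulates and the running
mean converges to the true length.

**Significance.** A cluster with support `x` at a base with physical depth
`n` (reads, inter-mate gaps of concordant pairs, and potential-breakpoint
extents) is scored by the probability that all supporting reads are
mismappings, the binomial tail

```
p_bc = Pr(X ≥ x) = 1 − Σ_{k<x} C(n,k) p^k q^(n−k),   p = 10^(−m/10)
```

with `m` the mapping-quality threshold (default 20, so `p = 0.01`).
Tail probabilities are precomputed into cached tables. SNVs are scored
with the same machinery using per-base allele counts.

**Calling.** Significant start and end clusters of each type are paired
when both length-consistency criteria hold with `c = 3/8`:

```
|B_s + L_s − B_e| ≤ c·(i_max − i_min)     |B_e − L_e − B_s| ≤ c·(i_max − i_min)
```

Translocation breakpoints pair across chromosomes through the mean mate
coordinates (`|M_s − B_e|`, `|M_e − B_s|` under the same window). Small
indels (<50 bases, base-precise evidence) match at a ±2-base window.
A windowed, GC-normalised read-depth segmentation adds CNV calls.

**Duplicates.** Pairs with identical orientation and external mapping
coordinates (the read's own coordinate soft-clip-adjusted, the mate's not)
are collapsed to the pair with the highest summed MAPQ — including pairs
with mates on different chromosomes.

## Worked example

The bundled simulator plants variants in a random diploid genome and
writes the reference, a coordinate-sorted BAM with idealized alignments,
and a truth VCF/BED:

```bash
cat > spec.json <<'EOF'
{
  "chromosomes": {"chr1": 200000},
  "coverage": 30.0, "seed": 7, "duplicate_fraction": 0.05,
  "variants": [
    {"kind": "SNV", "chrom": "chr1", "pos": 20000, "zygosity": "het"},
    {"kind": "DEL", "chrom": "chr1", "pos": 60000, "length": 12, "zygosity": "het"},
    {"kind": "DEL", "chrom": "chr1", "pos": 100000, "length": 1000, "zygosity": "hom"},
    {"kind": "DUP", "chrom": "chr1", "pos": 150000, "length": 2000, "zygosity": "het"}
  ]
}
EOF
omnicall sim --spec spec.json -o example
omnicall call -b example/reads.bam -r example/ref.fa -o example/calls.vcf
omnicall bench --calls example/calls.vcf --truth example/truth.vcf
```

The run log reports one line per chromosome and a class count summary:

```
chr1: reads=59986 discordant=82 snvs=1 calls=3
{"SNV": 1, "DEL": 2, "DUP": 1, "INS": 0, "INV": 0, "TRA": 0, "CNV": 2}
```

and the emitted calls land base-exactly on the planted variants:

```
chr1  20001   . G  C      157.4  PASS  SVTYPE=SNV;SUPPORT=16;PBC=1.82e-16          GT  0/1
chr1  60000   . TTACAGTTACCCT T  103.4 PASS SVTYPE=DEL;END=60012;SVLEN=-12;...     GT  ./.
chr1  100001  . G  <DEL>  389.6  PASS  SVTYPE=DEL;END=101000;SVLEN=-1000;...       GT  ./.
chr1  150001  . G  <DUP>  275.6  PASS  SVTYPE=DUP;END=152000;SVLEN=2000;...        GT  ./.
```

`QUAL` is `−10·log10(p_bc)`; `SUPPORT` the weighted evidence;
the benchmark harness scores sensitivity and precision per class
(here 1.000/1.000 for all four planted variants). Indel matching uses a
2-base tolerance, SV insertions 10 bases, and other SV types 50%
reciprocal overlap, with calls outside the truth set's size range excluded
rather than counted as false positives.

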