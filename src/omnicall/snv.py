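"""SNV calling from the per-base allele counts of the evidence scan.

Each base with alternate-allele observations is scored with the same
binomial mismapping tail as breakpoint clusters: the probability that at
least alt_count of the n fragments covering the base (physical depth) are
mismappings.  Candidates passing the significance threshold and simple
quality filters (mean alt base quality, mean alt MAPQ, minimum alt count)
are emitted.

The upstream model gives no SNV filter specifics; the defaults here
(Q_min = 20, k_min = 3, per-base inclusion at base quality >= 13) are this
package's own documented choices, all configurable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .evidence import BASES, ChromEvidence
from .significance import SignificanceModel


@dataclass
class SnvFilters:
    q_min: float = 20.0  # mean base quality of alt reads
    k_min: int = 3  # minimum alt observations
    mapq_min: float | None = None  # defaults to the significance MAPQ threshold
    hom_fraction: float = 0.8  # allele-fraction heuristic for genotype


@dataclass
class SnvCandidate:
    chrom: str
    pos: int  # 0-based
    ref_base: str
    alt_base: str
    alt_count: int
    depth: int  # physical depth (binomial n)
    read_depth: int
    mean_baseq: float
    mean_mapq: float
    p_bc: float
    genotype: str  # "0/1" or "1/1" (allele-fraction heuristic)


def call_snvs(
    evidence: ChromEvidence,
    ref_seq: str,
    sig: SignificanceModel,
    filters: SnvFilters | None = None,
) -> list[SnvCandidate]:
    """Score and filter candidate SNVs on one chromosome.

    ``ref_seq`` must cover the chromosome; a length mismatch with the
    evidence arrays is a hard error (reference/BAM contig mismatch).
    """
    f = filters or SnvFilters()
    mapq_min = f.mapq_min if f.mapq_min is not None else sig.mapq_threshold
    L = evidence.length
    if len(ref_seq) != L:
        raise ValueError(
            f"reference length {len(ref_seq)} != BAM contig length {L} "
            f"for {evidence.chrom}"
        )
    ref_codes = np.frombuffer(ref_seq.upper().encode(), dtype=np.uint8)
    code_of = np.full(256, -1, dtype=np.int8)
    for i, b in enumerate(b"ACGT"):
        code_of[b] = i
    ref_idx = code_of[ref_codes]

    counts = evidence.allele_counts
    alt_counts = counts.copy()
    valid = ref_idx >= 0
    cols = np.nonzero(valid)[0]
    alt_counts[ref_idx[cols], cols] = 0
    hit_alleles, hit_pos = np.nonzero(alt_counts >= f.k_min)

    depth = evidence.physical_depth
    read_depth = evidence.read_depth
    out: list[SnvCandidate] = []
    for ai, pos in zip(hit_alleles.tolist(), hit_pos.tolist()):
        x = int(alt_counts[ai, pos])
        n = int(depth[pos])
        p_bc = sig.lookup(n, x)
        if p_bc > sig.alpha:
            continue
        mean_bq = float(evidence.allele_bq_sum[ai, pos] / counts[ai, pos])
        mean_mq = float(evidence.allele_mq_sum[ai, pos] / counts[ai, pos])
        if mean_bq < f.q_min or mean_mq < mapq_min:
            continue
        rd = int(read_depth[pos])
        af = x / rd if rd else 0.0
        out.append(
            SnvCandidate(
                chrom=evidence.chrom,
                pos=pos,
                ref_base=chr(ref_codes[pos]),
                alt_base=BASES[ai],
                alt_count=x,
                depth=n,
                read_depth=rd,
                mean_baseq=mean_bq,
                mean_mapq=mean_mq,
                p_bc=p_bc,
                genotype="1/1" if af >= f.hom_fraction else "0/1",
            )
        )
    out.sort(key=lambda c: (c.pos, c.alt_base))
    return out
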