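"""Pairing significant start and end breakpoint clusters into variant calls.

A start cluster (position B_s, mean length L_s) and an end cluster
(B_e, L_e) of the same SV type match when both length-consistency
criteria hold:

    |B_s + L_s - B_e| <= c * (i_max - i_min)
    |B_e - L_e - B_s| <= c * (i_max - i_min),        c = 3/8.

Translocation breakpoints live on different chromosomes and are matched
through the mean mate coordinates M_s, M_e instead:

    |M_s - B_e| <= c * (i_max - i_min)
    |M_e - B_s| <= c * (i_max - i_min).

Matching is greedy by descending combined support; each cluster is used at
most once.  Small indels (< 50 bases, base-precision evidence) use a fixed
+-2 base window instead of the insert-scaled one.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from .clustering import BreakpointCluster
from .insertsize import InsertSizeModel

MATCH_C = 3.0 / 8.0
INDEL_SV_BOUNDARY = 50  # <50 bases: indel; >=50: SV
INDEL_WINDOW = 2.0


def match_window(model: InsertSizeModel) -> float:
    """c * (i_max - i_min), the breakpoint-consistency tolerance."""
    return MATCH_C * (model.i_max - model.i_min)


@dataclass
class VariantCall:
    """A typed variant call with its supporting breakpoint statistics."""

    chrom: str
    start: int  # 0-based inclusive
    end: int  # 0-based exclusive (start of unaffected sequence)
    sv_type: str
    length: float
    start_support: float
    end_support: float
    p_bc_start: float
    p_bc_end: float
    mate_chrom: Optional[str] = None
    mate_pos: Optional[int] = None
    inserted_seq: Optional[str] = None

    @property
    def p_bc(self) -> float:
        return max(self.p_bc_start, self.p_bc_end)

    @property
    def support(self) -> float:
        return self.start_support + self.end_support


def _pair_matches(s: BreakpointCluster, e: BreakpointCluster, window: float) -> bool:
    return (
        abs(s.pos + s.mean_length - e.pos) <= window
        and abs(e.pos - e.mean_length - s.pos) <= window
    )


def _call_from(s: BreakpointCluster, e: BreakpointCluster, chrom: str, sv_type: str) -> VariantCall:
    span = float(e.pos - s.pos)
    if s.anchored and e.anchored:
        length = span
    else:
        length = (s.mean_length + e.mean_length + span) / 3.0
    return VariantCall(
        chrom=chrom,
        start=s.pos,
        end=e.pos,
        sv_type=sv_type,
        length=length,
        start_support=s.support,
        end_support=e.support,
        p_bc_start=s.p_bc if s.p_bc is not None else 1.0,
        p_bc_end=e.p_bc if e.p_bc is not None else 1.0,
        inserted_seq=s.inserted_seq or e.inserted_seq,
    )


def match_breakpoints(
    start_clusters: list[BreakpointCluster],
    end_clusters: list[BreakpointCluster],
    model: InsertSizeModel,
    sv_type: str,
    chrom: str,
    window: Optional[float] = None,
) -> list[VariantCall]:
    """Greedy start/end pairing for one chromosome and SV type."""
    w = match_window(model) if window is None else window
    pairs = []
    for si, s in enumerate(start_clusters):
        for ei, e in enumerate(end_clusters):
            if e.pos <= s.pos:
                continue
            if _pair_matches(s, e, w):
                pairs.append((-(s.support + e.support), s.pos, e.pos, si, ei))
    pairs.sort()
    used_s: set[int] = set()
    used_e: set[int] = set()
    calls: list[VariantCall] = []
    for _, _, _, si, ei in pairs:
        if si in used_s or ei in used_e:
            continue
        used_s.add(si)
        used_e.add(ei)
        calls.append(_call_from(start_clusters[si], end_clusters[ei], chrom, sv_type))
    calls.sort(key=lambda c: (c.start, c.end))
    return calls


def match_translocations(
    clusters: list[tuple[str, BreakpointCluster]],
    model: InsertSizeModel,
) -> list[VariantCall]:
    """Genome-wide pairing of translocation clusters via mate coordinates.

    Each item is (chrom, cluster); the cluster's mate_chrom/mate_mean point
    at the partner junction.  Emitted as reciprocal breakend pairs (one
    call per pair, carrying both coordinates).
    """
    w = match_window(model)
    pairs = []
    for i, (ca, a) in enumerate(clusters):
        for j in range(i + 1, len(clusters)):
            cb, b = clusters[j]
            if ca == cb:
                continue
            if a.mate_chrom != cb or b.mate_chrom != ca:
                continue
            if abs(a.mate_mean - b.pos) <= w and abs(b.mate_mean - a.pos) <= w:
                pairs.append((-(a.support + b.support), ca, a.pos, i, j))
    pairs.sort()
    used: set[int] = set()
    calls: list[VariantCall] = []
    for _, _, _, i, j in pairs:
        if i in used or j in used:
            continue
        used.add(i)
        used.add(j)
        ca, a = clusters[i]
        cb, b = clusters[j]
        if (cb, b.pos) < (ca, a.pos):
            (ca, a), (cb, b) = (cb, b), (ca, a)
        calls.append(
            VariantCall(
                chrom=ca,
                start=a.pos,
                end=a.pos + 1,
                sv_type="TRA",
                length=0.0,
                start_support=a.support,
                end_support=b.support,
                p_bc_start=a.p_bc if a.p_bc is not None else 1.0,
                p_bc_end=b.p_bc if b.p_bc is not None else 1.0,
                mate_chrom=cb,
                mate_pos=b.pos,
            )
        )
    calls.sort(key=lambda c: (c.chrom, c.start))
    return calls


def match_insertion_sites(
    start_clusters: list[BreakpointCluster],
    end_clusters: list[BreakpointCluster],
    model: InsertSizeModel,
    chrom: str,
) -> list[VariantCall]:
    """Pair insertion-site clusters (>= 50 bases inserted, no reference span).

    An insertion occupies a single reference locus, so the start/end
    length-consistency criteria degenerate: clusters are paired by locus
    proximity (the usual window) and length agreement (the clustering base
    term).
    """
    w = match_window(model)
    base = model.cluster_base_term
    pairs = []
    for si, s in enumerate(start_clusters):
        for ei, e in enumerate(end_clusters):
            if abs(e.pos - s.pos) <= w and abs(s.mean_length - e.mean_length) <= 2 * base:
                pairs.append((-(s.support + e.support), s.pos, si, ei))
    pairs.sort()
    used_s: set[int] = set()
    used_e: set[int] = set()
    calls = []
    for _, _, si, ei in pairs:
        if si in used_s or ei in used_e:
            continue
        used_s.add(si)
        used_e.add(ei)
        s, e = start_clusters[si], end_clusters[ei]
        calls.append(
            VariantCall(
                chrom=chrom, start=s.pos, end=s.pos + 1, sv_type="INS",
                length=(s.mean_length + e.mean_length) / 2.0,
                start_support=s.support, end_support=e.support,
                p_bc_start=s.p_bc if s.p_bc is not None else 1.0,
                p_bc_end=e.p_bc if e.p_bc is not None else 1.0,
                inserted_seq=s.inserted_seq or e.inserted_seq,
            )
        )
    calls.sort(key=lambda c: c.start)
    return calls


def call_small_indels(
    start_clusters: list[BreakpointCluster],
    end_clusters: list[BreakpointCluster],
    model: InsertSizeModel,
    sv_type: str,
    chrom: str,
) -> list[VariantCall]:
    """Match base-precision indel clusters (< 50 bases) at a +-2 base window.

    Insertions occupy a single locus: a start/end cluster pair at the same
    base with consistent lengths.
    """
    if sv_type == "INS":
        w = INDEL_WINDOW
        pairs = []
        for si, s in enumerate(start_clusters):
            for ei, e in enumerate(end_clusters):
                if abs(e.pos - s.pos) <= w and abs(s.mean_length - e.mean_length) <= w:
                    pairs.append((-(s.support + e.support), s.pos, si, ei))
        pairs.sort()
        used_s: set[int] = set()
        used_e: set[int] = set()
        calls = []
        for _, _, si, ei in pairs:
            if si in used_s or ei in used_e:
                continue
            used_s.add(si)
            used_e.add(ei)
            s, e = start_clusters[si], end_clusters[ei]
            call = VariantCall(
                chrom=chrom, start=s.pos, end=s.pos, sv_type="INS",
                length=(s.mean_length + e.mean_length) / 2.0,
                start_support=s.support, end_support=e.support,
                p_bc_start=s.p_bc if s.p_bc is not None else 1.0,
                p_bc_end=e.p_bc if e.p_bc is not None else 1.0,
                inserted_seq=s.inserted_seq or e.inserted_seq,
            )
            calls.append(call)
        calls.sort(key=lambda c: c.start)
        return calls
    return match_breakpoints(
        start_clusters, end_clusters, model, sv_type, chrom, window=INDEL_WINDOW
    )
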