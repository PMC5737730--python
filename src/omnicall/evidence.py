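"""Single-pass per-chromosome evidence collection.

One sweep over the coordinate-sorted alignments of a chromosome gathers,
at every reference base: physical depth (sequenced bases, the unsequenced
gap between concordant mates, and the breakpoint feasibility extents of
discordant pairs), per-allele counts with quality sums, soft-clip
boundaries, and unmapped-mate counts.  The same sweep emits weighted
potential-breakpoint candidates from within-read indels, split alignments
and discordant pairs.

A discordant pair does not pinpoint its breakpoint: a candidate is recorded
at every reference base at which a breakpoint would let the pair form a
concordant fragment, a window of width i_max - i_min.  When a soft-clip or
split boundary falls inside such a window, the boundary base keeps full
weight and all other bases of the window are half-weighted, giving base
resolution while a lone aberrant read cannot hijack the breakpoint.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np

from .insertsize import InsertSizeModel, PairClass, PairGeometry, classify_pair

MIN_CLIP = 5  # soft-clip length that marks a breakpoint boundary
MIN_SPLIT = 20  # minimum aligned length of each split segment
DEFAULT_CANDIDATE_MAPQ = 1  # MAPQ 0 reads count toward depth only

_BASE_CODE = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate(b"ACGT"):
    _BASE_CODE[_b] = _i
    _BASE_CODE[_b + 32] = _i

BASES = "ACGT"


@dataclass
class BreakpointCandidate:
    """One read's vote for a breakpoint at one reference base."""

    chrom: str
    pos: int
    side: str  # "start" | "end" | "bnd" (translocation)
    sv_type: str  # DEL | DUP | INS | INV | TRA
    length: float
    weight: float
    read_id: str
    exact: bool = False  # base-resolution evidence (CIGAR indel / split)
    mate_chrom: Optional[str] = None
    mate_pos: Optional[int] = None
    inserted_seq: Optional[str] = None


@dataclass
class ClipBoundary:
    """Boundary of a >=MIN_CLIP soft-clip: the exact aligned edge."""

    pos: int
    side: str  # "left": clip precedes the alignment; "right": follows it
    read_id: str


@dataclass
class BaseEvidence:
    """Evidence accumulated at a single reference base (accessor view)."""

    position: int
    physical_depth: int
    read_depth: int
    allele_counts: dict
    mean_mapq: float
    mean_baseq: dict
    clip_left: int
    clip_right: int
    unmapped_mate_count: int


class ChromEvidence:
    """Array-backed per-base evidence for one chromosome."""

    def __init__(self, chrom: str, length: int) -> None:
        self.chrom = chrom
        self.length = length
        self._depth_diff = np.zeros(length + 1, dtype=np.int32)
        self._frag_diff = np.zeros(length + 1, dtype=np.int32)
        self.allele_counts = np.zeros((4, length), dtype=np.int32)
        self.allele_bq_sum = np.zeros((4, length), dtype=np.float32)
        self.allele_mq_sum = np.zeros((4, length), dtype=np.float32)
        self.clip_left = np.zeros(length, dtype=np.int32)
        self.clip_right = np.zeros(length, dtype=np.int32)
        self.unmapped_mate = np.zeros(length, dtype=np.int32)
        self._depth: np.ndarray | None = None

    def add_depth(self, start: int, end: int, fragment: bool = False) -> None:
        """Record physical-depth cover; ``fragment=True`` additionally counts
        toward the fragment depth (sequenced reads + concordant inter-mate
        gaps, excluding discordant feasibility extents) used by the
        read-depth CNV stage."""
        a, b = max(0, start), min(self.length, end)
        if b > a:
            self._depth_diff[a] += 1
            self._depth_diff[b] -= 1
            if fragment:
                self._frag_diff[a] += 1
                self._frag_diff[b] -= 1
            self._depth = None

    @property
    def physical_depth(self) -> np.ndarray:
        if self._depth is None:
            self._depth = np.cumsum(self._depth_diff[:-1]).astype(np.int32)
        return self._depth

    @property
    def fragment_depth(self) -> np.ndarray:
        return np.cumsum(self._frag_diff[:-1]).astype(np.int32)

    @property
    def read_depth(self) -> np.ndarray:
        """Sequenced-base depth (sum of allele observations per base)."""
        return self.allele_counts.sum(axis=0)

    def base_evidence(self, pos: int) -> BaseEvidence:
        counts = {BASES[i]: int(self.allele_counts[i, pos]) for i in range(4)}
        mean_bq = {}
        mq_tot, n_tot = 0.0, 0
        for i, b in enumerate(BASES):
            c = self.allele_counts[i, pos]
            if c:
                mean_bq[b] = float(self.allele_bq_sum[i, pos] / c)
                mq_tot += float(self.allele_mq_sum[i, pos])
                n_tot += int(c)
        return BaseEvidence(
            position=pos,
            physical_depth=int(self.physical_depth[pos]),
            read_depth=int(self.read_depth[pos]),
            allele_counts=counts,
            mean_mapq=mq_tot / n_tot if n_tot else 0.0,
            mean_baseq=mean_bq,
            clip_left=int(self.clip_left[pos]),
            clip_right=int(self.clip_right[pos]),
            unmapped_mate_count=int(self.unmapped_mate[pos]),
        )


# ---------------------------------------------------------------------------
# Candidate generation from single reads
# ---------------------------------------------------------------------------

def _sa_segments(read) -> list[tuple[str, int, int, str, int, int]]:
    """Primary + SA-tag alignment segments.

    Each entry: (chrom, ref_start, ref_end, strand, q_start, q_end) with
    query coordinates expressed in the original sequencing orientation of
    the read, so segments can be ordered along the read.
    """
    import re

    def seg_from(chrom, pos0, strand, cigartuples, readlen):
        ref = pos0
        q = 0
        qs = None
        qe = None
        for op, ln in cigartuples:
            if op in (0, 7, 8):  # M/=/X
                if qs is None:
                    qs = q
                qe = q + ln
                ref += ln
                q += ln
            elif op == 1:  # I
                q += ln
            elif op == 2:  # D
                ref += ln
            elif op in (4, 5):  # S/H
                q += ln
        if qs is None:
            return None
        if strand == "-":
            qs, qe = readlen - qe, readlen - qs
        return (chrom, pos0, ref, strand, qs, qe)

    readlen = read.infer_read_length() or len(read.query_sequence or "")
    segs = []
    own = seg_from(
        read.reference_name,
        read.reference_start,
        "-" if read.is_reverse else "+",
        read.cigartuples,
        readlen,
    )
    if own:
        segs.append(own)
    sa = read.get_tag("SA") if read.has_tag("SA") else ""
    cig_re = re.compile(r"(\d+)([MIDNSHP=X])")
    opcode = {"M": 0, "I": 1, "D": 2, "N": 3, "S": 4, "H": 5, "P": 6, "=": 7, "X": 8}
    for part in sa.rstrip(";").split(";"):
        if not part:
            continue
        rname, pos, strand, cigar, _mapq, _nm = part.split(",")
        tuples = [(opcode[m.group(2)], int(m.group(1))) for m in cig_re.finditer(cigar)]
        s = seg_from(rname, int(pos) - 1, strand, tuples, readlen)
        if s:
            segs.append(s)
    return segs


def _split_candidates(read, min_split: int) -> list[BreakpointCandidate]:
    """Breakpoint candidates from a split (chimeric) alignment.

    The two mapped segments' inner (junction-facing) edges define the
    breakpoints; relative placement and orientation give the type.
    """
    segs = _sa_segments(read)
    if len(segs) < 2:
        return []
    segs.sort(key=lambda s: s[4])  # order along the read
    s1, s2 = segs[0], segs[1]
    if (s1[2] - s1[1]) < min_split or (s2[2] - s2[1]) < min_split:
        return []
    rid = read.query_name
    # junction-facing reference coordinate of each segment
    j1 = s1[2] if s1[3] == "+" else s1[1]
    j2 = s2[1] if s2[3] == "+" else s2[2]
    out: list[BreakpointCandidate] = []
    if s1[0] != s2[0]:
        out.append(
            BreakpointCandidate(s1[0], j1, "bnd", "TRA", 0.0, 1.0, rid, exact=True,
                                mate_chrom=s2[0], mate_pos=j2)
        )
        out.append(
            BreakpointCandidate(s2[0], j2, "bnd", "TRA", 0.0, 1.0, rid, exact=True,
                                mate_chrom=s1[0], mate_pos=j1)
        )
        return out
    chrom = s1[0]
    lo, hi = min(j1, j2), max(j1, j2)
    if hi <= lo:
        return []
    length = float(hi - lo)
    if s1[3] == s2[3]:
        forward_del = (s1[3] == "+" and j2 > j1) or (s1[3] == "-" and j1 > j2)
        sv = "DEL" if forward_del else "DUP"
    else:
        sv = "INV"
    out.append(BreakpointCandidate(chrom, lo, "start", sv, length, 1.0, rid, exact=True))
    out.append(BreakpointCandidate(chrom, hi, "end", sv, length, 1.0, rid, exact=True))
    return out


def candidates_from_cigar(
    read, min_clip: int = MIN_CLIP, min_split: int = MIN_SPLIT
) -> tuple[list[BreakpointCandidate], list[ClipBoundary]]:
    """Candidates and clip boundaries from one primary alignment record.

    Within-read deletions/insertions give exact, full-weight candidates;
    soft-clips of >= min_clip bases give boundary anchors; a split
    alignment with both segments >= min_split gives exact SV candidates.
    """
    cands: list[BreakpointCandidate] = []
    clips: list[ClipBoundary] = []
    chrom = read.reference_name
    rid = read.query_name
    ref = read.reference_start
    q = 0
    seq = read.query_sequence or ""
    cigartuples = read.cigartuples or []
    for i, (op, ln) in enumerate(cigartuples):
        if op in (0, 7, 8):
            ref += ln
            q += ln
        elif op == 2:  # deletion of ln reference bases at ref
            cands.append(
                BreakpointCandidate(chrom, ref, "start", "DEL", float(ln), 1.0, rid, exact=True)
            )
            cands.append(
                BreakpointCandidate(chrom, ref + ln, "end", "DEL", float(ln), 1.0, rid, exact=True)
            )
            ref += ln
        elif op == 1:  # insertion of ln read bases before ref
            ins = seq[q : q + ln] if seq else None
            cands.append(
                BreakpointCandidate(chrom, ref, "start", "INS", float(ln), 1.0, rid,
                                    exact=True, inserted_seq=ins)
            )
            cands.append(
                BreakpointCandidate(chrom, ref, "end", "INS", float(ln), 1.0, rid,
                                    exact=True, inserted_seq=ins)
            )
            q += ln
        elif op == 4:
            if ln >= min_clip:
                if i == 0:
                    clips.append(ClipBoundary(read.reference_start, "left", rid))
                else:
                    clips.append(ClipBoundary(read.reference_end, "right", rid))
            q += ln
        # N (3), H (5), P (6): no evidence
    if read.has_tag("SA") and not read.is_supplementary:
        cands.extend(_split_candidates(read, min_split))
    return cands, clips


# ---------------------------------------------------------------------------
# Discordant-pair feasibility windows
# ---------------------------------------------------------------------------

@dataclass
class PairWindows:
    """Start/end candidate windows implied by one discordant pair."""

    sv_type: str
    start_window: tuple[int, int]  # half-open
    end_window: tuple[int, int]
    length: float
    read_id: str
    mate_chrom: Optional[str] = None
    mate_pos: Optional[int] = None


def candidates_from_discordant_pair(
    geom: PairGeometry, pair_class: PairClass, model: InsertSizeModel
) -> Optional[PairWindows]:
    """Feasibility windows for a discordant pair (seen from the leftmost mate).

    The implied length is the insert's excess over the median (deletions),
    the deficit (insertions), the everted span plus median minus two read
    lengths (tandem duplications), or the outer span (inversions).  The
    mate's soft-clipping is unknown in a single pass; its extent is taken
    as one read length.
    """
    W = model.window_width
    L_r = model.read_length
    e1 = geom.end
    s1 = geom.start
    s2 = geom.mate_start
    mate_end = s2 + L_r
    if pair_class is PairClass.DISCORDANT_DELETION:
        length = geom.insert - model.i_median
        if length <= 0:
            return None
        return PairWindows("DEL", (e1, e1 + W), (s2 - W, s2), length, "")
    if pair_class is PairClass.DISCORDANT_INSERTION:
        length = model.i_median - geom.insert
        if length <= 0:
            return None
        return PairWindows("INS", (e1, e1 + W), (s2 - W, s2), length, "")
    if pair_class is PairClass.DISCORDANT_DUPLICATION:
        span = mate_end - s1
        length = span + model.i_median - 2 * L_r
        if length <= 0:
            return None
        return PairWindows("DUP", (s1 - W, s1), (mate_end, mate_end + W), length, "")
    if pair_class is PairClass.DISCORDANT_INVERSION:
        span = max(e1, mate_end) - min(s1, s2)
        if span <= 0:
            return None
        if not geom.is_reverse:  # FF: spans the left inversion junction
            return PairWindows("INV", (e1, e1 + W), (s2, s2 + W), float(span), "")
        # RR: spans the right junction
        return PairWindows("INV", (e1 - W, e1), (s2 - W, s2), float(span), "")
    return None


def apply_clip_anchoring(
    candidates: list[BreakpointCandidate], boundaries: Iterable[int]
) -> list[BreakpointCandidate]:
    """Half-weight a window's candidates when a clip/split anchor is present.

    With at least one boundary inside the region, candidates at a boundary
    base keep weight 1.0 and all others drop to 0.5 (all anchored bases
    keep full weight when several boundaries exist); without boundaries all
    weights are unchanged.
    """
    bset = set(boundaries)
    if not bset:
        return candidates
    positions = {c.pos for c in candidates}
    if not (bset & positions):
        return candidates
    for c in candidates:
        c.weight = 1.0 if c.pos in bset else 0.5
    return candidates


def expand_windows(
    windows: list[PairWindows],
    clip_positions: np.ndarray,
    chrom: str,
    chrom_len: int,
) -> list[BreakpointCandidate]:
    """Materialize per-base candidates from pair windows, with anchoring."""
    out: list[BreakpointCandidate] = []
    for w in windows:
        for side, (a, b) in (("start", w.start_window), ("end", w.end_window)):
            a = max(0, a)
            b = min(chrom_len, b)
            if b <= a:
                continue
            lo = int(np.searchsorted(clip_positions, a, side="left"))
            hi = int(np.searchsorted(clip_positions, b, side="left"))
            anchors = set(int(p) for p in clip_positions[lo:hi])
            cands = [
                BreakpointCandidate(
                    chrom, pos, side, w.sv_type, w.length, 1.0, w.read_id,
                    mate_chrom=w.mate_chrom, mate_pos=w.mate_pos,
                )
                for pos in range(a, b)
            ]
            if anchors:
                apply_clip_anchoring(cands, anchors)
            out.extend(cands)
    return out


# ---------------------------------------------------------------------------
# The chromosome scan
# ---------------------------------------------------------------------------

@dataclass
class ScanOptions:
    candidate_mapq: int = DEFAULT_CANDIDATE_MAPQ
    baseq_min: int = 13
    min_clip: int = MIN_CLIP
    min_split: int = MIN_SPLIT


@dataclass
class ScanResult:
    evidence: ChromEvidence
    candidates: list[BreakpointCandidate]
    n_reads: int = 0
    n_discordant_pairs: int = 0


def scan_chromosome(
    bam,
    chrom: str,
    model: Optional[InsertSizeModel],
    options: ScanOptions | None = None,
    exclude_qnames: frozenset | set | None = None,
) -> ScanResult:
    """One pass over a chromosome's primary alignments.

    ``bam`` is an open pysam.AlignmentFile (coordinate-sorted, indexed).
    ``model`` is None in single-end mode (no pair evidence).  Reads whose
    name is in ``exclude_qnames`` (duplicate filtering) are skipped
    entirely.  Returns per-base evidence plus the position-ordered
    candidate stream (exact evidence first within a position).
    """
    opts = options or ScanOptions()
    so = dict(bam.header.get("HD", {})).get("SO")
    if so is not None and so != "coordinate":
        raise ValueError(f"BAM must be coordinate-sorted (SO={so})")
    if chrom not in bam.references:
        raise ValueError(f"unknown chromosome {chrom!r}")
    length = bam.get_reference_length(chrom)
    ev = ChromEvidence(chrom, length)
    cands: list[BreakpointCandidate] = []
    windows: list[PairWindows] = []
    clip_pos: list[int] = []
    excl = exclude_qnames or frozenset()

    idx_chunks: list[np.ndarray] = []
    bq_chunks: list[np.ndarray] = []
    mq_chunks: list[np.ndarray] = []
    n_reads = 0
    n_disc = 0

    for read in bam.fetch(chrom):
        if read.is_unmapped or read.is_secondary or read.is_supplementary:
            continue
        if read.query_name in excl:
            continue
        n_reads += 1
        start, end = read.reference_start, read.reference_end
        ev.add_depth(start, end, fragment=True)
        # --- allele observations -------------------------------------
        seq = read.query_sequence
        if seq:
            quals = read.query_qualities
            cig = read.cigartuples
            if cig and len(cig) == 1 and cig[0][0] == 0:
                qpos = np.arange(len(seq))
                rpos = qpos + start
            else:
                pairs = read.get_aligned_pairs(matches_only=True)
                if pairs:
                    qpos = np.fromiter((p[0] for p in pairs), dtype=np.int64, count=len(pairs))
                    rpos = np.fromiter((p[1] for p in pairs), dtype=np.int64, count=len(pairs))
                else:
                    qpos = rpos = np.empty(0, dtype=np.int64)
            if qpos.size:
                codes = _BASE_CODE[np.frombuffer(seq.encode(), dtype=np.uint8)][qpos]
                bq = np.asarray(quals, dtype=np.float32)[qpos] if quals is not None else np.full(qpos.size, 30.0, dtype=np.float32)
                keep = (codes >= 0) & (bq >= opts.baseq_min)
                if keep.any():
                    rp = rpos[keep]
                    idx_chunks.append(rp * 4 + codes[keep])
                    bq_chunks.append(bq[keep])
                    mq_chunks.append(np.full(rp.size, read.mapping_quality, dtype=np.float32))
        # --- candidate evidence --------------------------------------
        if read.mapping_quality >= opts.candidate_mapq:
            cig_str = read.cigarstring or ""
            if ("D" in cig_str or "I" in cig_str or "S" in cig_str
                    or read.has_tag("SA")):
                rc, rclips = candidates_from_cigar(read, opts.min_clip, opts.min_split)
                cands.extend(rc)
                for c in rc:
                    # a split segment's junction base is a potential breakpoint
                    # of this fragment even when the primary span misses it
                    if c.exact and c.chrom == chrom and not (start <= c.pos < end):
                        ev.add_depth(c.pos, c.pos + 1)
                for cb in rclips:
                    clip_pos.append(cb.pos)
                    if cb.side == "left":
                        if cb.pos < length:
                            ev.clip_left[cb.pos] += 1
                    else:
                        if cb.pos - 1 >= 0:
                            ev.clip_right[cb.pos - 1] += 1
                        # the boundary base itself is a potential breakpoint
                        # of this fragment: count it toward physical depth
                        ev.add_depth(cb.pos, cb.pos + 1)
            # --- pair evidence ---------------------------------------
            if model is not None and read.is_paired:
                if read.mate_is_unmapped:
                    p = min(end, length - 1)
                    ev.unmapped_mate[p] += 1
                elif read.reference_id != read.next_reference_id:
                    # translocation: each mate handles its own side
                    geom = PairGeometry.from_record(read)
                    W = model.window_width
                    if read.is_reverse:
                        a, b = start - W, start
                    else:
                        a, b = end, end + W
                    windows.append(
                        PairWindows("TRA", (a, b), (b, b), 0.0, read.query_name,
                                    mate_chrom=read.next_reference_name,
                                    mate_pos=read.next_reference_start)
                    )
                    ev.add_depth(a, b)
                    n_disc += 1
                elif read.reference_start < read.next_reference_start or (
                    read.reference_start == read.next_reference_start and read.is_read1
                ):
                    # leftmost mate: handle the pair once
                    geom = PairGeometry.from_record(read)
                    cls = classify_pair(geom, model)
                    if cls is PairClass.CONCORDANT:
                        ev.add_depth(end, read.next_reference_start, fragment=True)
                    else:
                        pw = candidates_from_discordant_pair(geom, cls, model)
                        if pw is not None:
                            pw.read_id = read.query_name
                            windows.append(pw)
                            for a, b in (pw.start_window, pw.end_window):
                                ev.add_depth(a, b)
                            n_disc += 1

    # flush allele accumulators
    if idx_chunks:
        idx = np.concatenate(idx_chunks)
        bq = np.concatenate(bq_chunks)
        mq = np.concatenate(mq_chunks)
        minlength = 4 * length
        ev.allele_counts += np.bincount(idx, minlength=minlength)[:minlength].reshape(length, 4).T.astype(np.int32)
        ev.allele_bq_sum += np.bincount(idx, weights=bq, minlength=minlength)[:minlength].reshape(length, 4).T.astype(np.float32)
        ev.allele_mq_sum += np.bincount(idx, weights=mq, minlength=minlength)[:minlength].reshape(length, 4).T.astype(np.float32)

    clip_arr = np.array(sorted(set(clip_pos)), dtype=np.int64)
    tra_windows = [w for w in windows if w.sv_type == "TRA"]
    other_windows = [w for w in windows if w.sv_type != "TRA"]
    cands.extend(expand_windows(other_windows, clip_arr, chrom, length))
    # translocation windows: single-sided, carry the mate coordinate
    for w in tra_windows:
        a = max(0, w.start_window[0])
        b = min(length, w.start_window[1])
        lo = int(np.searchsorted(clip_arr, a))
        hi = int(np.searchsorted(clip_arr, b))
        anchors = set(int(p) for p in clip_arr[lo:hi])
        wc = [
            BreakpointCandidate(chrom, pos, "bnd", "TRA", 0.0, 1.0, w.read_id,
                                mate_chrom=w.mate_chrom, mate_pos=w.mate_pos)
            for pos in range(a, b)
        ]
        if anchors:
            apply_clip_anchoring(wc, anchors)
        cands.extend(wc)

    cands.sort(key=lambda c: (c.pos, -c.weight, not c.exact))
    return ScanResult(evidence=ev, candidates=cands, n_reads=n_reads, n_discordant_pairs=n_disc)
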