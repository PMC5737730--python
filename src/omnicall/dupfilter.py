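"""Inline duplicate read-pair filtering.

Read pairs with identical orientation and external mapping coordinates are
duplicates of one source fragment; among them only the pair with the
highest summed mapping quality is retained (ties: first encountered).
The read's own external coordinate is soft-clip adjusted (the unclipped 5'
end); the mate's is taken from the record's mate fields and is NOT
clip-adjusted, which keeps the filter single-pass.  Pairs with mates on
different chromosomes are eligible.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, NamedTuple


class DuplicateKey(NamedTuple):
    chrom1: str
    coord1: int
    strand1: bool  # is_reverse
    chrom2: str
    coord2: int
    strand2: bool


def external_coordinate(read) -> int:
    """Soft-clip-adjusted 5'-most coordinate of a read."""
    cig = read.cigartuples or []
    if read.is_reverse:
        tail = cig[-1][1] if cig and cig[-1][0] == 4 else 0
        return read.reference_end + tail
    head = cig[0][1] if cig and cig[0][0] == 4 else 0
    return read.reference_start - head


def duplicate_key(read) -> DuplicateKey | None:
    """Canonical pair key, symmetric under mate swap; None for unusable reads."""
    if read.is_unmapped or read.is_secondary or read.is_supplementary:
        return None
    own = (read.reference_name, external_coordinate(read), read.is_reverse)
    if read.is_paired and not read.mate_is_unmapped:
        # mate external coordinate from mate fields, not clip-adjusted
        if read.mate_is_reverse:
            # 5' end of a reverse mate is its alignment end; unknown single-pass,
            # approximated as mate start + read length
            mlen = read.infer_read_length() or read.query_length or 0
            mate_coord = read.next_reference_start + mlen
        else:
            mate_coord = read.next_reference_start
        mate = (read.next_reference_name, mate_coord, read.mate_is_reverse)
    else:
        mate = ("", -1, False)
    a, b = sorted([own, mate])
    return DuplicateKey(a[0], a[1], a[2], b[0], b[1], b[2])


def _pair_score(read) -> int:
    own = read.mapping_quality
    mate = read.get_tag("MQ") if read.has_tag("MQ") else own
    return own + mate


@dataclass
class DedupeResult:
    removed_qnames: frozenset
    n_pairs: int
    n_duplicates: int


def find_duplicates(reads: Iterable) -> DedupeResult:
    """Identify duplicate pairs in a record stream.

    Keys are computed from the leftmost mate of each pair (both mates for
    cross-chromosome pairs resolve to the same canonical key).  Returns the
    read names to drop; exactly one pair per key survives.
    """
    best: dict[DuplicateKey, tuple[int, str]] = {}
    removed: set[str] = set()
    for read in reads:
        key = duplicate_key(read)
        if key is None:
            continue
        if read.is_paired and not read.mate_is_unmapped:
            # count each pair once: leftmost mate (canonical tie-break)
            own = (read.reference_name, read.reference_start)
            mate = (read.next_reference_name, read.next_reference_start)
            if own > mate or (own == mate and not read.is_read1):
                continue
        score = _pair_score(read)
        prev = best.get(key)
        if prev is None:
            best[key] = (score, read.query_name)
        elif score > prev[0]:
            removed.add(prev[1])
            best[key] = (score, read.query_name)
        else:
            removed.add(read.query_name)
    return DedupeResult(
        removed_qnames=frozenset(removed),
        n_pairs=len(best) + len(removed),
        n_duplicates=len(removed),
    )


def dedupe(reads: list) -> tuple[list, int]:
    """Filter a materialized record list; returns (retained, n_duplicates)."""
    res = find_duplicates(reads)
    kept = [r for r in reads if r.query_name not in res.removed_qnames]
    return kept, res.n_duplicates
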