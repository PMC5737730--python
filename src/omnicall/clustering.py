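"""Greedy breakpoint clustering with an adaptive length tolerance.

At each reference base, reads supporting the same variant type are grouped
into clusters by implied variant length. A candidate read joins an existing
cluster when its implied length L_disc is close to the cluster's running
mean length L_bc:

    |L_bc - L_disc| <= (i_max - i_min + i_median - 2*L_r) * (1 + 1/x_bc)

where x_bc is the cluster's current (weighted) support. The tolerance
shrinks toward the base term as support accumulates and the mean length
estimate tightens. Among multiple eligible clusters the one with the most
support wins (ties: closest length, then creation order).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from .insertsize import InsertSizeModel


def cluster_tolerance(model: InsertSizeModel, x_bc: float) -> float:
    """Maximum |L_bc - L_disc| for joining a cluster with support x_bc."""
    if x_bc <= 0:
        raise ValueError("x_bc must be positive")
    base = model.cluster_base_term
    if base <= 0:
        raise ValueError(
            f"non-positive cluster base term ({base}); inconsistent insert model"
        )
    return base * (1.0 + 1.0 / x_bc)


@dataclass
class BreakpointCluster:
    """Reads supporting one breakpoint (position, side, type) at a common length.

    ``mean_length`` is the support-weighted running mean of member implied
    lengths; ``support`` the summed member weights (half-weighted members
    count 0.5). ``mate_mean`` tracks the weighted mean partner coordinate
    for translocation clusters.
    """

    pos: int
    side: str  # "start" | "end"
    sv_type: str  # DEL | DUP | INS | INV | TRA
    mean_length: float = 0.0
    support: float = 0.0
    read_ids: set = field(default_factory=set)
    p_bc: Optional[float] = None
    anchored: bool = False  # any exact (clip/split/CIGAR) full-weight member
    mate_chrom: Optional[str] = None
    mate_mean: float = 0.0
    inserted_seq: Optional[str] = None

    def add(self, candidate) -> None:
        w = candidate.weight
        tot = self.support + w
        self.mean_length = (self.support * self.mean_length + w * candidate.length) / tot
        if candidate.mate_pos is not None:
            self.mate_mean = (self.support * self.mate_mean + w * candidate.mate_pos) / tot
            self.mate_chrom = candidate.mate_chrom
        self.support = tot
        self.read_ids.add(candidate.read_id)
        if candidate.exact and w >= 1.0:
            self.anchored = True
        if self.inserted_seq is None and getattr(candidate, "inserted_seq", None):
            self.inserted_seq = candidate.inserted_seq


INDEL_PRECISE = 50  # within-read indel evidence is length-exact below this


def assign_read(candidate, clusters: list[BreakpointCluster], model: InsertSizeModel) -> BreakpointCluster:
    """Place one candidate into the cluster list (mutated in place).

    Eligible clusters share (pos, side, type), do not already contain the
    read, and satisfy the adaptive tolerance at their *current* support.
    Within-read indel candidates (exact, < 50 bases) carry base-accurate
    lengths, so their tolerance is exact agreement: conflicting small
    lengths at one base stay in separate clusters.
    Returns the cluster the candidate joined (possibly new).
    """
    precise = candidate.exact and candidate.length < INDEL_PRECISE
    best: BreakpointCluster | None = None
    best_key: tuple | None = None
    for idx, cl in enumerate(clusters):
        if candidate.read_id in cl.read_ids:
            continue
        diff = abs(cl.mean_length - candidate.length)
        tol = 0.5 if precise else cluster_tolerance(model, cl.support)
        if diff <= tol:
            key = (-cl.support, diff, idx)
            if best_key is None or key < best_key:
                best, best_key = cl, key
    if best is None:
        best = BreakpointCluster(
            pos=candidate.pos, side=candidate.side, sv_type=candidate.sv_type
        )
        clusters.append(best)
    best.add(candidate)
    return best


def cluster_candidates(
    candidates, model: InsertSizeModel
) -> dict[tuple[int, str, str], list[BreakpointCluster]]:
    """Cluster a position-ordered candidate stream.

    Returns {(pos, side, sv_type): [clusters]}. Candidates are processed in
    stream order (position-ordered, exact full-weight evidence first at each
    position); greedy clustering is order-sensitive, so the order is part of
    the contract.
    """
    out: dict[tuple[int, str, str], list[BreakpointCluster]] = {}
    for cand in candidates:
        key = (cand.pos, cand.side, cand.sv_type)
        assign_read(cand, out.setdefault(key, []), model)
    return out
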