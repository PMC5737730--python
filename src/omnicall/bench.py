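"""Benchmark evaluation: matching a call set against a truth set.

Matching rules follow standard SV-benchmarking practice: indel calls must
place both breakpoints within 2 bases of the truth entry; insertion SVs
within 10 bases; all other SV types need 50% reciprocal overlap (10% for
low-resolution truth sets).  Calls smaller or larger than the truth set's
shortest or longest variant of that type are ignored rather than counted
as false positives, since the truth set cannot adjudicate them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from .matching import INDEL_SV_BOUNDARY
from .vcfio import SimpleVariant, load_variants


@dataclass
class BenchmarkRules:
    indel_tolerance: int = 2  # bases, both breakpoints
    insertion_tolerance: int = 10  # bases, SV insertions
    reciprocal: float = 0.5  # reciprocal-overlap fraction for DEL/DUP/INV
    tra_tolerance: int = 100  # bases, each breakend of a translocation
    size_clamp: bool = True  # ignore calls outside the truth size range

    def __post_init__(self) -> None:
        if self.indel_tolerance < 0 or self.insertion_tolerance < 0:
            raise ValueError("tolerances must be >= 0")
        if not (0.0 < self.reciprocal <= 1.0):
            raise ValueError("reciprocal overlap fraction must be in (0, 1]")


PRESETS = {
    "default": BenchmarkRules(),
    "low-resolution": BenchmarkRules(reciprocal=0.1),
}


def reciprocal_overlap(a: tuple[int, int], b: tuple[int, int]) -> float:
    """min(overlap/|a|, overlap/|b|); 0 when disjoint."""
    if a[1] <= a[0] or b[1] <= b[0]:
        raise ValueError("zero-length interval")
    ov = min(a[1], b[1]) - max(a[0], b[0])
    if ov <= 0:
        return 0.0
    return min(ov / (a[1] - a[0]), ov / (b[1] - b[0]))


def _matches(call: SimpleVariant, truth: SimpleVariant, rules: BenchmarkRules) -> bool:
    if call.chrom != truth.chrom:
        return False
    if call.vtype == "SNV":
        return call.start == truth.start and (
            truth.alt is None or call.alt is None or call.alt == truth.alt
        )
    if call.vtype == "TRA":
        ends_a = abs(call.start - truth.start) <= rules.tra_tolerance
        if call.pos2 is None or truth.pos2 is None or call.chrom2 != truth.chrom2:
            return ends_a
        return ends_a and abs(call.pos2 - truth.pos2) <= rules.tra_tolerance
    if call.vtype == "INS":
        tol = (
            rules.indel_tolerance
            if call.length < INDEL_SV_BOUNDARY
            else rules.insertion_tolerance
        )
        return abs(call.start - truth.start) <= tol
    if call.length < INDEL_SV_BOUNDARY and truth.length < INDEL_SV_BOUNDARY:
        return (
            abs(call.start - truth.start) <= rules.indel_tolerance
            and abs(call.end - truth.end) <= rules.indel_tolerance
        )
    return reciprocal_overlap((call.start, call.end), (truth.start, truth.end)) >= rules.reciprocal


@dataclass
class TypeResult:
    vtype: str
    tp: list = field(default_factory=list)
    fp: list = field(default_factory=list)
    fn: list = field(default_factory=list)
    excluded: list = field(default_factory=list)

    @property
    def sensitivity(self) -> float:
        denom = len(self.tp) + len(self.fn)
        return len(self.tp) / denom if denom else 1.0

    @property
    def precision(self) -> float:
        denom = len(self.tp) + len(self.fp)
        return len(self.tp) / denom if denom else 1.0


@dataclass
class EvalResult:
    by_type: dict

    @property
    def sensitivity(self) -> float:
        tp = sum(len(r.tp) for r in self.by_type.values())
        fn = sum(len(r.fn) for r in self.by_type.values())
        return tp / (tp + fn) if tp + fn else 1.0

    @property
    def precision(self) -> float:
        tp = sum(len(r.tp) for r in self.by_type.values())
        fp = sum(len(r.fp) for r in self.by_type.values())
        return tp / (tp + fp) if tp + fp else 1.0

    def summary(self) -> str:
        rows = [f"{'type':6s} {'sens':>6s} {'prec':>6s} {'TP':>5s} {'FP':>5s} {'FN':>5s}"]
        for t, r in sorted(self.by_type.items()):
            rows.append(
                f"{t:6s} {r.sensitivity:6.3f} {r.precision:6.3f} "
                f"{len(r.tp):5d} {len(r.fp):5d} {len(r.fn):5d}"
            )
        rows.append(
            f"{'ALL':6s} {self.sensitivity:6.3f} {self.precision:6.3f}"
        )
        return "\n".join(rows)


def evaluate(
    calls: list[SimpleVariant] | str,
    truth: list[SimpleVariant] | str,
    rules: BenchmarkRules | None = None,
) -> EvalResult:
    """Match calls against truth, per variant type, each truth used once."""
    rules = rules or BenchmarkRules()
    if isinstance(calls, (str,)) or hasattr(calls, "__fspath__"):
        calls = load_variants(calls)
    if isinstance(truth, (str,)) or hasattr(truth, "__fspath__"):
        truth = load_variants(truth)
    call_contigs = {c.chrom for c in calls}
    truth_contigs = {t.chrom for t in truth}
    if calls and truth and not (call_contigs & truth_contigs):
        raise ValueError(
            f"no shared contigs between calls ({sorted(call_contigs)}) "
            f"and truth ({sorted(truth_contigs)})"
        )
    types = sorted({t.vtype for t in truth} | {c.vtype for c in calls})
    out = {}
    for vt in types:
        tcalls = sorted(
            (c for c in calls if c.vtype == vt), key=lambda c: (c.chrom, c.start)
        )
        ttruth = [t for t in truth if t.vtype == vt]
        res = TypeResult(vt)
        lengths = [t.length for t in ttruth if t.length > 0]
        lo = min(lengths) if lengths else None
        hi = max(lengths) if lengths else None
        matched: set[int] = set()
        for c in tcalls:
            if (
                rules.size_clamp
                and vt in ("DEL", "DUP", "INV")
                and lo is not None
                and not (lo <= c.length <= hi)
            ):
                res.excluded.append(c)
                continue
            hit = None
            for i, t in enumerate(ttruth):
                if i in matched:
                    continue
                if _matches(c, t, rules):
                    hit = i
                    break
            if hit is None:
                res.fp.append(c)
            else:
                matched.add(hit)
                res.tp.append(c)
        res.fn = [t for i, t in enumerate(ttruth) if i not in matched]
        out[vt] = res
    return EvalResult(by_type=out)
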