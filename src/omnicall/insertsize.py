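"""Insert-size library model and read-pair classification.

The paired-end insert-size distribution governs every tolerance used
downstream: which pairs are discordant, how wide a discordant pair's
breakpoint feasibility window is, and the adaptive clustering tolerance.
Thresholds are rank-based: the concordant range [i_min, i_max] is taken at
the empirical quantiles that a normal distribution would place three
standard deviations from the median, after removing gross outliers
(> 5x the median insert).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, asdict
from enum import Enum
from typing import Iterable, Sequence

import numpy as np

# Phi(-3) / Phi(3) of the standard normal: quantile levels equivalent to
# "three standard deviations from the median".
Q_LOW = 0.0013499
Q_HIGH = 1.0 - Q_LOW

OUTLIER_FOLD = 5.0
DEFAULT_MAX_PAIRS = 10_000_000
DEFAULT_MIN_PAIRS = 1_000


class InsufficientPairsError(RuntimeError):
    pass


@dataclass(frozen=True)
class InsertSizeModel:
    """Concordant insert-size range and read length for one library.

    i_min/i_max are the minimum/maximum concordant insert sizes; inserts
    outside this range mark a pair as discordant.
    """

    i_min: float
    i_median: float
    i_max: float
    read_length: int
    n_sampled: int = 0
    outliers_removed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.i_min <= self.i_median <= self.i_max):
            raise ValueError(
                f"inconsistent insert model: i_min={self.i_min} "
                f"i_median={self.i_median} i_max={self.i_max}"
            )

    @property
    def cluster_base_term(self) -> float:
        """i_max - i_min + i_median - 2*read_length, the clustering tolerance scale."""
        return self.i_max - self.i_min + self.i_median - 2.0 * self.read_length

    @property
    def window_width(self) -> int:
        """Width of a discordant pair's breakpoint feasibility window."""
        return max(1, int(round(self.i_max - self.i_min)))

    def to_json(self) -> str:
        d = asdict(self)
        d["L_r"] = d.pop("read_length")
        return json.dumps(d, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "InsertSizeModel":
        d = json.loads(text)
        d["read_length"] = d.pop("L_r")
        return cls(**d)


def sample_insert_sizes(
    alignment_source: Iterable,
    max_pairs: int = DEFAULT_MAX_PAIRS,
    min_pairs: int = DEFAULT_MIN_PAIRS,
) -> list[int]:
    """Collect absolute template lengths from proper same-chromosome pairs.

    ``alignment_source`` yields pysam AlignedSegment records (or any object
    with the same flag/tlen attributes).  Each pair contributes once (the
    leftmost mate, positive TLEN).  Returns an empty list for a single-end
    library; raises InsufficientPairsError when pairs exist but are too few
    to estimate a model.
    """
    if max_pairs < 1:
        raise ValueError("max_pairs must be >= 1")
    sizes: list[int] = []
    saw_paired = False
    for read in alignment_source:
        if read.is_unmapped or read.is_secondary or read.is_supplementary:
            continue
        if not read.is_paired:
            continue
        saw_paired = True
        if read.mate_is_unmapped or read.reference_id != read.next_reference_id:
            continue
        tlen = read.template_length
        if tlen <= 0:  # count each pair once, from the leftmost mate
            continue
        sizes.append(tlen)
        if len(sizes) >= max_pairs:
            break
    if not saw_paired:
        return []
    if len(sizes) < min_pairs:
        raise InsufficientPairsError(
            f"insufficient pairs for insert model ({len(sizes)} < {min_pairs})"
        )
    return sizes


def fit_insert_model(
    sizes: Sequence[float], read_length: int, n_sampled: int | None = None
) -> InsertSizeModel:
    """Fit the concordant-range model from sampled insert sizes.

    Median first; values above 5x the median are dropped as outliers;
    i_min/i_max are then the linearly interpolated empirical quantiles of
    the filtered sample at the normal +-3 SD levels.
    """
    arr = np.asarray(sizes, dtype=float)
    if arr.size == 0:
        raise ValueError("cannot fit insert model from an empty sample")
    median = float(np.median(arr))
    kept = arr[arr <= OUTLIER_FOLD * median]
    n_out = int(arr.size - kept.size)
    if kept.size == 0:
        raise ValueError("all insert sizes removed as outliers (pathological library)")
    i_min, i_med, i_max = np.quantile(kept, [Q_LOW, 0.5, Q_HIGH], method="linear")
    _warn_if_bimodal(kept, float(i_med))
    return InsertSizeModel(
        i_min=float(i_min),
        i_median=float(i_med),
        i_max=float(i_max),
        read_length=int(read_length),
        n_sampled=int(n_sampled if n_sampled is not None else arr.size),
        outliers_removed=n_out,
    )


def _warn_if_bimodal(sizes: np.ndarray, median: float) -> None:
    """Crude dip check: a mixed library shows a density trough at the median
    relative to the quartiles. Warn only; mixed libraries need separate runs."""
    if sizes.size < 1000:
        return
    q1, q3 = np.quantile(sizes, [0.25, 0.75])
    if q3 - q1 <= 0:
        return
    h = (q3 - q1) / 10.0
    d_med = np.count_nonzero(np.abs(sizes - median) <= h)
    d_q = max(
        np.count_nonzero(np.abs(sizes - q1) <= h),
        np.count_nonzero(np.abs(sizes - q3) <= h),
    )
    if d_q > 0 and d_med < 0.5 * d_q:
        warnings.warn(
            "insert-size distribution looks bimodal (mixed library?); "
            "mixed libraries should be analysed in separate runs",
            stacklevel=3,
        )


class PairClass(Enum):
    CONCORDANT = "concordant"
    DISCORDANT_DELETION = "discordant_deletion"
    DISCORDANT_INSERTION = "discordant_insertion"
    DISCORDANT_DUPLICATION = "discordant_duplication"
    DISCORDANT_INVERSION = "discordant_inversion"
    DISCORDANT_TRANSLOCATION = "discordant_translocation"
    UNMAPPED_MATE = "unmapped_mate"


@dataclass(frozen=True)
class PairGeometry:
    """Mapping geometry of one read pair, seen from one (mapped) record.

    Coordinates are 0-based; ``insert`` is the absolute outer template
    length. ``mate_chrom`` is None for an unmapped mate.
    """

    chrom: str
    start: int
    end: int
    is_reverse: bool
    mate_chrom: str | None
    mate_start: int
    mate_is_reverse: bool
    insert: int

    @classmethod
    def from_record(cls, read) -> "PairGeometry":
        mate_chrom = None
        if read.is_paired and not read.mate_is_unmapped:
            mate_chrom = read.next_reference_name
        return cls(
            chrom=read.reference_name,
            start=read.reference_start,
            end=read.reference_end,
            is_reverse=read.is_reverse,
            mate_chrom=mate_chrom,
            mate_start=read.next_reference_start or 0,
            mate_is_reverse=read.mate_is_reverse,
            insert=abs(read.template_length),
        )


def classify_pair(geom: PairGeometry, model: InsertSizeModel) -> PairClass:
    """Assign exactly one concordance label to a mapped pair."""
    if geom.mate_chrom is None:
        return PairClass.UNMAPPED_MATE
    if geom.mate_chrom != geom.chrom:
        return PairClass.DISCORDANT_TRANSLOCATION
    if geom.is_reverse == geom.mate_is_reverse:
        return PairClass.DISCORDANT_INVERSION
    # leftmost read of the pair; orientation FR (innie) vs RF (outie)
    if geom.start <= geom.mate_start:
        left_reverse = geom.is_reverse
    else:
        left_reverse = geom.mate_is_reverse
    if left_reverse:
        return PairClass.DISCORDANT_DUPLICATION
    if geom.insert > model.i_max:
        return PairClass.DISCORDANT_DELETION
    if geom.insert < model.i_min:
        return PairClass.DISCORDANT_INSERTION
    return PairClass.CONCORDANT
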