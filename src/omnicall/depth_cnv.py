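"""Windowed read-depth CNV detection.

A deliberately transparent stand-in for a full read-depth pipeline: the
chromosome is tiled into fixed-width windows of mean physical depth,
GC-corrected by median scaling within 1% GC bins, and consecutive runs of
windows beyond depth-ratio thresholds become deletion (low) or duplication
(high) calls.  Sustained loss or gain of physical coverage is the CNV
evidence; breakpoint refinement is left to the paired-end/split-read path.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

DEFAULT_WINDOW = 100
DEFAULT_MIN_WINDOWS = 5
DEL_RATIO = 0.6
DUP_RATIO = 1.4
MIN_GC_BIN_WINDOWS = 20


@dataclass
class DepthWindow:
    chrom: str
    start: int
    end: int
    depth: float
    gc_fraction: float
    corrected: float | None = None


@dataclass
class CnvCall:
    chrom: str
    start: int
    end: int
    cnv_type: str  # DEL | DUP
    mean_depth: float
    ratio: float
    z_score: float
    n_windows: int


def make_windows(
    chrom: str, depth: np.ndarray, ref_seq: str, width: int = DEFAULT_WINDOW
) -> list[DepthWindow]:
    """Tile a chromosome into fixed-width windows of mean physical depth."""
    L = len(depth)
    seq = np.frombuffer(ref_seq.upper().encode(), dtype=np.uint8)
    is_gc = (seq == ord("G")) | (seq == ord("C"))
    is_n = ~((seq == ord("A")) | (seq == ord("T")) | is_gc)
    out = []
    for a in range(0, L, width):
        b = min(L, a + width)
        if is_n[a:b].all():
            continue  # all-N window: no alignable sequence
        out.append(
            DepthWindow(
                chrom=chrom,
                start=a,
                end=b,
                depth=float(depth[a:b].mean()),
                gc_fraction=float(is_gc[a:b].sum() / (b - a)),
            )
        )
    return out


def gc_normalize(windows: list[DepthWindow], min_windows: int = 1000) -> list[DepthWindow]:
    """Median-scale depth within 1% GC bins (bins with few windows borrow neighbours)."""
    if not windows:
        raise ValueError("empty window set")
    if len(windows) < min_windows:
        # too few windows for stable GC bins: identity correction
        for w in windows:
            w.corrected = w.depth
        return windows
    depth = np.array([w.depth for w in windows])
    gc = np.array([w.gc_fraction for w in windows])
    global_med = float(np.median(depth))
    bins = np.clip((gc * 100).astype(int), 0, 100)
    bin_median = np.full(101, np.nan)
    for b in range(101):
        mask = bins == b
        n = int(mask.sum())
        if n >= MIN_GC_BIN_WINDOWS:
            bin_median[b] = np.median(depth[mask])
        else:  # borrow neighbours until enough windows accumulate
            for r in range(1, 101):
                mask = (bins >= b - r) & (bins <= b + r)
                if int(mask.sum()) >= MIN_GC_BIN_WINDOWS:
                    bin_median[b] = np.median(depth[mask])
                    break
    for w, b in zip(windows, bins):
        m = bin_median[b]
        w.corrected = w.depth * (global_med / m) if m and np.isfinite(m) and m > 0 else w.depth
    return windows


def segment_cnv(
    windows: list[DepthWindow],
    min_windows: int = DEFAULT_MIN_WINDOWS,
    del_ratio: float = DEL_RATIO,
    dup_ratio: float = DUP_RATIO,
) -> list[CnvCall]:
    """Merge runs of extreme-depth windows into DEL/DUP CNV calls.

    Hysteresis segmentation: a run extends over consecutive windows beyond
    the *weak* thresholds (halfway between normal and the calling ratio) and
    is emitted only if it contains >= min_windows windows beyond the strong
    (calling) threshold; the reported interval spans the first to last
    strong window.  This keeps a single event from fragmenting when its
    depth straddles the calling ratio (e.g. a 3-copy duplication at 1.5x).
    """
    if not windows:
        return []
    corr = np.array([w.corrected if w.corrected is not None else w.depth for w in windows])
    med = float(np.median(corr))
    sd = float(corr.std()) or 1.0
    if med <= 0:
        return []
    weak_del = (1.0 + del_ratio) / 2.0
    weak_dup = (1.0 + dup_ratio) / 2.0
    state = np.zeros(len(windows), dtype=int)
    state[corr < weak_del * med] = -1
    state[corr > weak_dup * med] = 1
    strong = (corr < del_ratio * med) | (corr > dup_ratio * med)
    calls: list[CnvCall] = []
    i = 0
    while i < len(windows):
        if state[i] == 0:
            i += 1
            continue
        j = i
        while j < len(windows) and state[j] == state[i] and windows[j].chrom == windows[i].chrom:
            j += 1
        strong_idx = [k for k in range(i, j) if strong[k]]
        if len(strong_idx) >= min_windows:
            a, b = strong_idx[0], strong_idx[-1] + 1
            seg = corr[a:b]
            calls.append(
                CnvCall(
                    chrom=windows[a].chrom,
                    start=windows[a].start,
                    end=windows[b - 1].end,
                    cnv_type="DEL" if state[i] < 0 else "DUP",
                    mean_depth=float(seg.mean()),
                    ratio=float(seg.mean() / med),
                    z_score=float((seg.mean() - med) / (sd / np.sqrt(len(seg)))),
                    n_windows=b - a,
                )
            )
        i = j
    return calls
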