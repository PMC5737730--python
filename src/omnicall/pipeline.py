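"""End-to-end calling pipeline.

Per-chromosome order of operations: optional duplicate prescan, the
single evidence pass, SNV filtering, breakpoint clustering and
significance scoring, start/end matching per indel and SV type, and
read-depth CNV windows.  Translocation breakpoints are matched after all
chromosomes, genome-wide.  Output is deterministic for a fixed input.
"""

from __future__ import annotations

import time
from concurrent.futures import ProcessPoolExecutor
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pysam

from . import depth_cnv
from .clustering import BreakpointCluster, cluster_candidates
from .dupfilter import find_duplicates
from .evidence import ScanOptions, scan_chromosome
from .insertsize import InsertSizeModel, fit_insert_model, sample_insert_sizes
from .matching import (
    INDEL_SV_BOUNDARY,
    VariantCall,
    call_small_indels,
    match_breakpoints,
    match_insertion_sites,
    match_translocations,
)
from .significance import SignificanceModel
from .snv import SnvFilters, call_snvs
from .vcfio import write_cnv_outputs, write_vcf


@dataclass
class PipelineConfig:
    bam: str
    reference: str
    out_vcf: Optional[str] = None
    out_cnv_vcf: Optional[str] = None
    out_cnv_bed: Optional[str] = None
    alpha: float = 1e-5
    mapq_threshold: float = 20.0
    dup_filter: bool = True
    sample_pairs: int = 10_000_000
    min_pairs: int = 1_000
    regions: Optional[list[str]] = None
    threads: int = 1
    snv_filters: SnvFilters = field(default_factory=SnvFilters)
    scan_options: ScanOptions = field(default_factory=ScanOptions)
    cnv_window: int = depth_cnv.DEFAULT_WINDOW
    cnv_min_windows: int = depth_cnv.DEFAULT_MIN_WINDOWS
    emit_single_breakends: bool = False
    table_cache_dir: Optional[str] = None


@dataclass
class PipelineResult:
    model: Optional[InsertSizeModel]
    snvs: list
    calls: list  # indel + SV + TRA VariantCalls
    cnvs: list
    report: dict


def _modal_read_length(bam, max_reads: int = 50_000) -> int:
    from collections import Counter

    counts: Counter = Counter()
    for i, read in enumerate(bam.fetch()):
        if read.is_secondary or read.is_supplementary or read.is_unmapped:
            continue
        n = read.infer_read_length() or read.query_length
        if n:
            counts[n] += 1
        if i >= max_reads:
            break
    if not counts:
        return 0
    return max(counts.items(), key=lambda kv: (kv[1], kv[0]))[0]


def _single_end_fallback_model(read_length: int) -> InsertSizeModel:
    """Tolerances for libraries without pairs, scaled from the read length."""
    L = max(50, read_length)
    return InsertSizeModel(
        i_min=float(L), i_median=float(2 * L + 10), i_max=float(2 * L + 20),
        read_length=L, n_sampled=0,
    )


def _nms(clusters: list[BreakpointCluster], radius: float) -> list[BreakpointCluster]:
    """Greedy non-maximum suppression: within ``radius``, the cluster with
    the most support represents the breakpoint (anchored clusters win ties)."""
    ranked = sorted(clusters, key=lambda c: (-c.support, not c.anchored, c.pos))
    kept: list[BreakpointCluster] = []
    for c in ranked:
        if all(abs(c.pos - k.pos) > radius for k in kept):
            kept.append(c)
    kept.sort(key=lambda c: c.pos)
    return kept


def _dedupe_calls(calls: list[VariantCall]) -> list[VariantCall]:
    """Suppress same-type calls reciprocally overlapping a stronger call."""
    out: list[VariantCall] = []
    for c in sorted(calls, key=lambda c: (-c.support, c.start)):
        dup = False
        for k in out:
            if k.sv_type != c.sv_type or k.chrom != c.chrom:
                continue
            lo = max(c.start, k.start)
            hi = min(c.end, k.end)
            if hi <= lo:
                continue
            la, lb = max(1, c.end - c.start), max(1, k.end - k.start)
            if min((hi - lo) / la, (hi - lo) / lb) >= 0.5:
                dup = True
                break
        if not dup:
            out.append(c)
    out.sort(key=lambda c: (c.start, c.end))
    return out


def _process_chromosome(args):
    (bam_path, ref_path, chrom, model, cfg_dict) = args
    cfg = cfg_dict["config"]
    excluded = cfg_dict["excluded"]
    sig = SignificanceModel(
        cfg.mapq_threshold, alpha=cfg.alpha, cache_dir=cfg.table_cache_dir
    )
    with pysam.AlignmentFile(bam_path) as bam, pysam.FastaFile(ref_path) as fa:
        if chrom not in fa.references:
            raise ValueError(f"reference/BAM contig mismatch: {chrom} not in FASTA")
        res = scan_chromosome(bam, chrom, model, cfg.scan_options, excluded)
        ref_seq = fa.fetch(chrom)
    ev = res.evidence
    depth = ev.physical_depth
    snvs = call_snvs(ev, ref_seq, sig, cfg.snv_filters)

    work_model = model if model is not None else _single_end_fallback_model(
        cfg.scan_options.min_split * 5
    )
    cands = [c for c in res.candidates if c.chrom == chrom]
    cluster_map = cluster_candidates(cands, work_model)
    significant: list[BreakpointCluster] = []
    for clist in cluster_map.values():
        for cl in clist:
            n = int(depth[cl.pos]) if 0 <= cl.pos < ev.length else 0
            if sig.score_cluster(cl, n) <= sig.alpha:
                significant.append(cl)

    tra = [cl for cl in significant if cl.sv_type == "TRA"]
    indel = [
        cl for cl in significant
        if cl.sv_type in ("DEL", "INS") and cl.mean_length < INDEL_SV_BOUNDARY
    ]
    sv = [
        cl for cl in significant
        if cl.sv_type != "TRA" and cl.mean_length >= INDEL_SV_BOUNDARY
    ]

    radius = work_model.window_width
    calls: list[VariantCall] = []
    used: set[int] = set()
    for sv_type in ("DEL", "DUP", "INV", "INS"):
        starts = _nms([c for c in sv if c.sv_type == sv_type and c.side == "start"], radius)
        ends = _nms([c for c in sv if c.sv_type == sv_type and c.side == "end"], radius)
        if sv_type == "INS":
            tcalls = match_insertion_sites(starts, ends, work_model, chrom)
        else:
            tcalls = match_breakpoints(starts, ends, work_model, sv_type, chrom)
        calls.extend(tcalls)
        if cfg.emit_single_breakends:
            matched_pos = {c.start for c in tcalls} | {c.end for c in tcalls}
            for cl in starts + ends:
                if cl.pos not in matched_pos:
                    calls.append(
                        VariantCall(
                            chrom, cl.pos, cl.pos + 1, sv_type, cl.mean_length,
                            cl.support if cl.side == "start" else 0.0,
                            cl.support if cl.side == "end" else 0.0,
                            cl.p_bc or 1.0, cl.p_bc or 1.0,
                        )
                    )
    for sv_type in ("DEL", "INS"):
        starts = [c for c in indel if c.sv_type == sv_type and c.side == "start"]
        ends = [c for c in indel if c.sv_type == sv_type and c.side == "end"]
        calls.extend(call_small_indels(starts, ends, work_model, sv_type, chrom))

    calls = _dedupe_calls(calls)
    tra_kept = _nms(tra, radius)
    # CNV windows measure aligned-read depth: fragment-gap coverage collapses
    # around SV junctions (spanning pairs are discordant) and would fake dips
    windows = depth_cnv.make_windows(chrom, ev.read_depth, ref_seq, cfg.cnv_window)
    stats = {
        "chrom": chrom,
        "n_reads": res.n_reads,
        "n_discordant_pairs": res.n_discordant_pairs,
        "n_snvs": len(snvs),
        "n_calls": len(calls),
        "n_tra_clusters": len(tra_kept),
    }
    return calls, snvs, windows, [(chrom, cl) for cl in tra_kept], stats


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    t0 = time.time()
    report: dict = {"config": {
        "alpha": config.alpha,
        "mapq_threshold": config.mapq_threshold,
        "dup_filter": config.dup_filter,
    }}
    with pysam.AlignmentFile(config.bam) as bam:
        contigs = [(c, bam.get_reference_length(c)) for c in bam.references]
        chroms = config.regions or list(bam.references)
        for c in chroms:
            if c not in bam.references:
                raise ValueError(f"unknown chromosome {c!r}")
        sizes = sample_insert_sizes(
            bam.fetch(), max_pairs=config.sample_pairs, min_pairs=config.min_pairs
        )
        read_length = _modal_read_length(bam)
        if sizes:
            model = fit_insert_model(sizes, read_length)
        else:
            model = None  # single-end mode
        report["insert_model"] = (
            {
                "i_min": model.i_min,
                "i_median": model.i_median,
                "i_max": model.i_max,
                "read_length": model.read_length,
                "n_sampled": model.n_sampled,
            }
            if model
            else None
        )
        # duplicate prescan (cross-chromosome pairs decided once, globally)
        excluded: frozenset = frozenset()
        n_dup = 0
        if config.dup_filter:
            removed: set = set()
            n_pairs = 0
            for chrom in chroms:
                r = find_duplicates(bam.fetch(chrom))
                removed |= set(r.removed_qnames)
                n_pairs += r.n_pairs
            excluded = frozenset(removed)
            n_dup = len(removed)
            report["n_pairs_seen"] = n_pairs
        report["duplicates_removed"] = n_dup

    cfg_dict = {"config": config, "excluded": excluded}
    args = [(config.bam, config.reference, c, model, cfg_dict) for c in chroms]
    if config.threads > 1 and len(chroms) > 1:
        with ProcessPoolExecutor(max_workers=config.threads) as ex:
            results = list(ex.map(_process_chromosome, args))
    else:
        results = [_process_chromosome(a) for a in args]

    all_calls: list[VariantCall] = []
    all_snvs = []
    all_windows = []
    tra_clusters = []
    report["chromosomes"] = []
    for calls, snvs, windows, tra, stats in results:
        all_calls.extend(calls)
        all_snvs.extend(snvs)
        all_windows.extend(windows)
        tra_clusters.extend(tra)
        report["chromosomes"].append(stats)

    work_model = model if model is not None else _single_end_fallback_model(100)
    all_calls.extend(match_translocations(tra_clusters, work_model))

    cnvs = []
    if all_windows:
        depth_cnv.gc_normalize(all_windows)
        cnvs = depth_cnv.segment_cnv(all_windows, config.cnv_min_windows)

    order = {c: i for i, (c, _) in enumerate(contigs)}
    all_calls.sort(key=lambda c: (order[c.chrom], c.start, c.end))
    all_snvs.sort(key=lambda s: (order[s.chrom], s.pos))
    report["counts"] = {
        "SNV": len(all_snvs),
        **{
            t: sum(1 for c in all_calls if c.sv_type == t)
            for t in ("DEL", "DUP", "INS", "INV", "TRA")
        },
        "CNV": len(cnvs),
    }
    report["runtime_s"] = round(time.time() - t0, 2)

    if config.out_vcf:
        with pysam.FastaFile(config.reference) as fa:
            write_vcf(
                config.out_vcf, contigs, all_snvs, all_calls,
                ref_fetch=lambda c, a, b: fa.fetch(c, a, b),
            )
    if config.out_cnv_vcf or config.out_cnv_bed:
        vcf_p = config.out_cnv_vcf or str(Path(config.out_cnv_bed).with_suffix(".vcf"))
        bed_p = config.out_cnv_bed or str(Path(config.out_cnv_vcf).with_suffix(".bed"))
        write_cnv_outputs(vcf_p, bed_p, contigs, cnvs)
    return PipelineResult(model=model, snvs=all_snvs, calls=all_calls, cnvs=cnvs, report=report)
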