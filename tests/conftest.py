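"""Shared fixtures: in-memory BAM construction and reusable simulations."""

from __future__ import annotations

from pathlib import Path

import pysam
import pytest

from omnicall.insertsize import InsertSizeModel
from omnicall.simulate import SimSpec, Variant, simulate

DEFAULT_CHROMS = {"chr1": 100_000, "chr2": 50_000}


def make_header(chroms: dict | None = None) -> pysam.AlignmentHeader:
    chroms = chroms or DEFAULT_CHROMS
    return pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "coordinate"},
            "SQ": [{"SN": c, "LN": L} for c, L in chroms.items()],
        }
    )


def make_read(
    header,
    qname: str,
    chrom: str,
    pos: int,
    cigar: str = "100M",
    *,
    is_reverse: bool = False,
    is_read2: bool = False,
    paired: bool = True,
    mate_chrom: str | None = None,
    mate_pos: int = 0,
    mate_reverse: bool = True,
    mate_unmapped: bool = False,
    tlen: int = 0,
    mapq: int = 60,
    seq: str | None = None,
    baseq: int = 35,
    tags: list | None = None,
) -> pysam.AlignedSegment:
    """Build one aligned record with sensible defaults."""
    r = pysam.AlignedSegment(header)
    r.query_name = qname
    r.reference_id = header.get_tid(chrom)
    r.reference_start = pos
    r.cigarstring = cigar
    r.mapping_quality = mapq
    qlen = r.infer_read_length()
    r.query_sequence = seq if seq is not None else "A" * qlen
    r.query_qualities = pysam.qualitystring_to_array(chr(baseq + 33) * qlen)
    flag = 0
    if paired:
        flag |= 0x1 | (0x80 if is_read2 else 0x40)
        if mate_unmapped:
            flag |= 0x8
            r.next_reference_id = r.reference_id
            r.next_reference_start = pos
        else:
            if mate_reverse:
                flag |= 0x20
            r.next_reference_id = header.get_tid(mate_chrom or chrom)
            r.next_reference_start = mate_pos
    if is_reverse:
        flag |= 0x10
    r.flag = flag
    r.template_length = tlen
    if tags:
        r.set_tags(tags)
    return r


def make_pair(header, qname, chrom, pos1, pos2, read_len=100, *, cigar1=None,
              cigar2=None, mapq=60, chrom2=None, reverse1=False, reverse2=True,
              tags=None):
    """An FR pair by default; orientation/contigs overridable."""
    chrom2 = chrom2 or chrom
    if chrom == chrom2:
        lo = min(pos1, pos2)
        hi = max(pos1 + read_len, pos2 + read_len)
        t1 = (hi - lo) if pos1 <= pos2 else -(hi - lo)
    else:
        t1 = 0
    r1 = make_read(header, qname, chrom, pos1, cigar1 or f"{read_len}M",
                   is_reverse=reverse1, mate_chrom=chrom2, mate_pos=pos2,
                   mate_reverse=reverse2, tlen=t1, mapq=mapq,
                   tags=(tags or []) + [("MQ", mapq)])
    r2 = make_read(header, qname, chrom2, pos2, cigar2 or f"{read_len}M",
                   is_reverse=reverse2, is_read2=True, mate_chrom=chrom,
                   mate_pos=pos1, mate_reverse=reverse1, tlen=-t1, mapq=mapq,
                   tags=(tags or []) + [("MQ", mapq)])
    return r1, r2


def write_bam(path: Path, header, records) -> Path:
    recs = sorted(records, key=lambda r: (r.reference_id, r.reference_start))
    with pysam.AlignmentFile(str(path), "wb", header=header) as bf:
        for r in recs:
            bf.write(r)
    pysam.index(str(path))
    return path


@pytest.fixture()
def header():
    return make_header()


@pytest.fixture()
def model():
    """Insert model with round numbers: concordant range [350, 650]."""
    return InsertSizeModel(
        i_min=350.0, i_median=500.0, i_max=650.0, read_length=100, n_sampled=10_000
    )


@pytest.fixture(scope="session")
def mixed_sim(tmp_path_factory):
    """A 150 kb + 60 kb diploid library with every variant class planted."""
    spec = SimSpec(
        chromosomes={"chr1": 150_000, "chr2": 60_000},
        variants=[
            Variant("SNV", "chr1", 10_000, zygosity="het"),
            Variant("SNV", "chr1", 20_000, zygosity="hom"),
            Variant("SNV", "chr1", 30_000, zygosity="het"),
            Variant("DEL", "chr1", 40_000, length=12, zygosity="het"),
            Variant("INS", "chr1", 50_000, length=7, zygosity="hom"),
            Variant("DEL", "chr1", 65_000, length=1_000, zygosity="het"),
            Variant("DUP", "chr1", 90_000, length=2_000, zygosity="het"),
            Variant("INV", "chr1", 115_000, length=3_000, zygosity="hom"),
            Variant("TRA", "chr1", 140_000, dest_chrom="chr2", dest_pos=30_000,
                    zygosity="het"),
        ],
        coverage=30.0,
        duplicate_fraction=0.05,
        seed=11,
    )
    out = simulate(spec, tmp_path_factory.mktemp("mixed_sim"))
    return spec, out


@pytest.fixture(scope="session")
def mixed_result(mixed_sim, tmp_path_factory):
    """Pipeline output on the mixed simulation (computed once)."""
    from omnicall.pipeline import PipelineConfig, run_pipeline

    spec, out = mixed_sim
    outdir = tmp_path_factory.mktemp("mixed_calls")
    cfg = PipelineConfig(
        bam=str(out.bam),
        reference=str(out.reference),
        out_vcf=str(outdir / "calls.vcf"),
        out_cnv_vcf=str(outdir / "cnv.vcf"),
        out_cnv_bed=str(outdir / "cnv.bed"),
        table_cache_dir=str(outdir / "tables"),
    )
    return cfg, run_pipeline(cfg)
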