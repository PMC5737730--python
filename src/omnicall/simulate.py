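"""Synthetic paired-end library generator with planted variants.

Generates a random reference, builds diploid haplotypes by applying the
planted variant list (SNVs, indels, deletions, tandem duplications,
inversions, balanced translocations), samples normally distributed
fragments from the haplotypes, and maps each read back to the reference
through the haplotype block structure.  Mapping is synthesized directly
(idealized: no external aligner), so CIGARs, soft-clips at SV breakpoints,
split/supplementary records for junction-spanning reads, and discordant
template lengths are all exact consequences of the planted variants.

Identical spec + seed give byte-identical outputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np
import pysam

_COMP = str.maketrans("ACGTN", "TGCAN")
INDEL_SV_BOUNDARY = 50
SPLIT_MIN = 20  # minimum aligned length for a supplementary record
BASEQ = 35
MAPQ = 60


def revcomp(s: str) -> str:
    return s.translate(_COMP)[::-1]


@dataclass
class Variant:
    """One planted variant. ``pos`` is 0-based on the reference.

    kind: SNV | INS | DEL | DUP | INV | TRA.  ``length`` is the affected
    reference span (DEL/DUP/INV), the inserted length (INS), or 0 (SNV).
    TRA is a balanced translocation joining (chrom, pos) to
    (dest_chrom, dest_pos).
    """

    kind: str
    chrom: str
    pos: int
    length: int = 0
    zygosity: str = "het"  # het | hom
    alt: Optional[str] = None  # SNV alternate base (chosen if None)
    ins_seq: Optional[str] = None  # INS sequence (drawn if None)
    dest_chrom: Optional[str] = None
    dest_pos: Optional[int] = None

    def interval(self) -> tuple[int, int]:
        if self.kind in ("SNV", "INS", "TRA"):
            return (self.pos, self.pos + 1)
        return (self.pos, self.pos + self.length)


@dataclass
class SimSpec:
    """Full description of a synthetic library."""

    chromosomes: dict = field(default_factory=lambda: {"chr1": 1_000_000})
    variants: list = field(default_factory=list)
    coverage: float = 30.0
    read_length: int = 100
    insert_mean: float = 500.0
    insert_sd: float = 50.0
    error_rate: float = 0.001
    duplicate_fraction: float = 0.0
    gc_content: float = 0.45
    gc_profile: str = "uniform"  # uniform | variable (per-10kb)
    gc_bias: float = 0.0  # fragment-sampling log-weight per GC unit
    seed: int = 1

    def validate(self) -> None:
        by_chrom: dict[str, list[tuple[int, int, Variant]]] = {}
        for v in self.variants:
            if v.kind not in ("SNV", "INS", "DEL", "DUP", "INV", "TRA"):
                raise ValueError(f"unknown variant kind {v.kind}")
            if v.chrom not in self.chromosomes:
                raise ValueError(f"variant on unknown chromosome {v.chrom}")
            a, b = v.interval()
            by_chrom.setdefault(v.chrom, []).append((a, b, v))
            if v.kind == "TRA":
                if v.dest_chrom is None or v.dest_pos is None:
                    raise ValueError("TRA requires dest_chrom/dest_pos")
                by_chrom.setdefault(v.dest_chrom, []).append(
                    (v.dest_pos, v.dest_pos + 1, v)
                )
        conflicts = []
        for chrom, ivals in by_chrom.items():
            ivals.sort()
            for (a1, b1, v1), (a2, b2, v2) in zip(ivals, ivals[1:]):
                if a2 < b1:
                    conflicts.append(f"{chrom}: {v1.kind}@{a1} overlaps {v2.kind}@{a2}")
        if conflicts:
            raise ValueError("overlapping variants: " + "; ".join(conflicts))


@dataclass
class SimOutput:
    reference: Path
    bam: Path
    truth_vcf: Path
    truth_bed: Path
    spec_json: Path


# ---------------------------------------------------------------------------
# Haplotype construction
# ---------------------------------------------------------------------------

@dataclass
class Block:
    """One haplotype block: hap [hap_start, hap_end) maps to the reference
    interval (or carries inserted sequence when chrom is None)."""

    hap_start: int
    hap_end: int
    chrom: Optional[str]
    ref_start: int
    ref_end: int
    strand: str = "+"
    ins_seq: Optional[str] = None


def _apply_translocations(chrom_lens: dict, variants: list[Variant]):
    """Span composition per haplotype chromosome after balanced TRAs."""
    comp = {c: [(c, 0, L)] for c, L in chrom_lens.items()}

    def locate(point_chrom, point_pos):
        for name, spans in comp.items():
            off = 0
            for i, (c, a, b) in enumerate(spans):
                if c == point_chrom and a <= point_pos < b:
                    return name, i, off + (point_pos - a)
                off += b - a
        raise ValueError(f"translocation point {point_chrom}:{point_pos} not found")

    for v in variants:
        if v.kind != "TRA":
            continue
        n1, i1, _ = locate(v.chrom, v.pos)
        n2, i2, _ = locate(v.dest_chrom, v.dest_pos)
        if n1 == n2:
            raise ValueError("translocation endpoints collapsed onto one haplotype chromosome")
        s1, s2 = comp[n1], comp[n2]
        c1, a1, b1 = s1[i1]
        c2, a2, b2 = s2[i2]
        pre1 = s1[:i1] + [(c1, a1, v.pos)]
        suf1 = [(c1, v.pos, b1)] + s1[i1 + 1 :]
        pre2 = s2[:i2] + [(c2, a2, v.dest_pos)]
        suf2 = [(c2, v.dest_pos, b2)] + s2[i2 + 1 :]
        comp[n1] = pre1 + suf2
        comp[n2] = pre2 + suf1
    return comp


def build_haplotype(ref: dict, chrom_lens: dict, variants: list[Variant]):
    """Blocks and sequence for every haplotype chromosome.

    Returns {hap_chrom_name: (blocks, sequence)}.
    """
    comp = _apply_translocations(chrom_lens, variants)
    per_chrom: dict[str, list[Variant]] = {}
    for v in variants:
        if v.kind not in ("TRA", "SNV"):
            per_chrom.setdefault(v.chrom, []).append(v)
    out = {}
    for name, spans in comp.items():
        blocks: list[Block] = []
        parts: list[str] = []
        hap_off = 0

        def emit(chrom, a, b, strand="+", ins_seq=None):
            nonlocal hap_off
            if ins_seq is not None:
                ln = len(ins_seq)
                blocks.append(Block(hap_off, hap_off + ln, None, 0, 0, "+", ins_seq))
                parts.append(ins_seq)
                hap_off += ln
                return
            if b <= a:
                return
            seq = ref[chrom][a:b]
            if strand == "-":
                seq = revcomp(seq)
            blocks.append(Block(hap_off, hap_off + (b - a), chrom, a, b, strand))
            parts.append(seq)
            hap_off += b - a

        for chrom, sa, sb in spans:
            vs = sorted(
                [v for v in per_chrom.get(chrom, []) if sa <= v.pos < sb],
                key=lambda v: v.pos,
            )
            cur = sa
            for v in vs:
                a, b = v.interval()
                emit(chrom, cur, a)
                if v.kind == "DEL":
                    pass  # skip the deleted reference bases
                elif v.kind == "INS":
                    emit(chrom, a, a + 1)  # anchor base precedes the insertion
                    emit(None, 0, 0, ins_seq=v.ins_seq)
                elif v.kind == "DUP":
                    emit(chrom, a, b)
                    emit(chrom, a, b)
                elif v.kind == "INV":
                    emit(chrom, a, b, strand="-")
                cur = b if v.kind != "INS" else a + 1
            emit(chrom, cur, sb)
        seq = "".join(parts)
        # SNVs: substitute in every block copy containing the position
        snvs = [v for v in variants if v.kind == "SNV"]
        if snvs:
            buf = list(seq)
            for v in snvs:
                for blk in blocks:
                    if blk.chrom == v.chrom and blk.ref_start <= v.pos < blk.ref_end:
                        if blk.strand == "+":
                            hp = blk.hap_start + (v.pos - blk.ref_start)
                            buf[hp] = v.alt
                        else:
                            hp = blk.hap_start + (blk.ref_end - 1 - v.pos)
                            buf[hp] = v.alt.translate(_COMP)
            seq = "".join(buf)
        out[name] = (blocks, seq)
    return out


# ---------------------------------------------------------------------------
# Read mapping through blocks
# ---------------------------------------------------------------------------

@dataclass
class AlignedGroup:
    chrom: str
    strand: str
    qa: int  # query (hap-forward) range within the read
    qb: int
    ops: list  # hap-order CIGAR ops [(op_char, length), ...]
    ref_lo: int
    ref_hi: int

    @property
    def aligned_len(self) -> int:
        return sum(ln for op, ln in self.ops if op == "M")


def _map_read(blocks: list[Block], starts: list[int], a: int, b: int) -> list[AlignedGroup]:
    """Alignment groups for the hap interval [a, b) of one read."""
    import bisect

    groups: list[AlignedGroup] = []
    i = bisect.bisect_right(starts, a) - 1
    cur: AlignedGroup | None = None
    pending_ins = 0
    while i < len(blocks) and blocks[i].hap_start < b:
        blk = blocks[i]
        qa = max(a, blk.hap_start)
        qb = min(b, blk.hap_end)
        i += 1
        if qb <= qa:
            continue
        if blk.chrom is None:
            pending_ins += qb - qa
            continue
        if blk.strand == "+":
            rs = blk.ref_start + (qa - blk.hap_start)
            re_ = rs + (qb - qa)
        else:
            re_ = blk.ref_end - (qa - blk.hap_start)
            rs = re_ - (qb - qa)
        joined = False
        if cur is not None and blk.chrom == cur.chrom and blk.strand == cur.strand:
            gap = (rs - cur.ref_hi) if blk.strand == "+" else (cur.ref_lo - re_)
            if 0 <= gap < INDEL_SV_BOUNDARY and pending_ins < INDEL_SV_BOUNDARY:
                if pending_ins:
                    cur.ops.append(("I", pending_ins))
                if gap:
                    cur.ops.append(("D", gap))
                cur.ops.append(("M", qb - qa))
                cur.qb = qb - a
                cur.ref_lo = min(cur.ref_lo, rs)
                cur.ref_hi = max(cur.ref_hi, re_)
                joined = True
        if not joined:
            cur = AlignedGroup(blk.chrom, blk.strand, qa - a, qb - a, [("M", qb - qa)], rs, re_)
            groups.append(cur)
        pending_ins = 0
    return groups


def _cigar_string(group: AlignedGroup, read_len: int) -> str:
    ops = group.ops if group.strand == "+" else list(reversed(group.ops))
    left = group.qa if group.strand == "+" else read_len - group.qb
    right = read_len - group.qb if group.strand == "+" else group.qa
    parts = []
    if left:
        parts.append(f"{left}S")
    parts.extend(f"{ln}{op}" for op, ln in ops)
    if right:
        parts.append(f"{right}S")
    return "".join(parts)


# ---------------------------------------------------------------------------
# Simulation driver
# ---------------------------------------------------------------------------

def _random_reference(spec: SimSpec, rng: np.random.Generator) -> dict:
    ref = {}
    for chrom, L in spec.chromosomes.items():
        if spec.gc_profile == "variable":
            seq_parts = []
            for a in range(0, L, 10_000):
                b = min(L, a + 10_000)
                gc = rng.uniform(0.3, 0.6)
                seq_parts.append(_draw_seq(rng, b - a, gc))
            ref[chrom] = "".join(seq_parts)
        else:
            ref[chrom] = _draw_seq(rng, L, spec.gc_content)
    return ref


def _draw_seq(rng: np.random.Generator, n: int, gc: float) -> str:
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(np.array(list("ACGT"))[rng.choice(4, size=n, p=p)])


def _prepare_variants(spec: SimSpec, ref: dict, rng: np.random.Generator) -> None:
    """Fill in SNV alternates and insertion sequences deterministically."""
    for v in sorted(spec.variants, key=lambda v: (v.chrom, v.pos, v.kind)):
        if v.kind == "SNV" and v.alt is None:
            r = ref[v.chrom][v.pos].upper()
            choices = [b for b in "ACGT" if b != r]
            v.alt = choices[int(rng.integers(3))]
        if v.kind == "INS" and v.ins_seq is None:
            v.ins_seq = _draw_seq(rng, v.length, 0.5)
        if v.kind == "INS" and v.length == 0:
            v.length = len(v.ins_seq)


def simulate(spec: SimSpec, outdir: str | Path) -> SimOutput:
    """Run the simulation; writes FASTA (+fai), sorted BAM (+bai), truth VCF/BED."""
    spec.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed)
    ref = _random_reference(spec, rng)
    _prepare_variants(spec, ref, rng)
    spec.validate()

    hap0_vars = list(spec.variants)  # hap0 carries het + hom
    hap1_vars = [v for v in spec.variants if v.zygosity == "hom"]
    haps = [build_haplotype(ref, spec.chromosomes, vs) for vs in (hap0_vars, hap1_vars)]

    header = pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "coordinate"},
            "SQ": [{"SN": c, "LN": L} for c, L in spec.chromosomes.items()],
        }
    )
    tid = {c: i for i, c in enumerate(spec.chromosomes)}
    records = []
    rl = spec.read_length
    cov_per_hap = spec.coverage / 2.0

    for hap_idx, hap in enumerate(haps):
        for name in sorted(hap):
            blocks, seq = hap[name]
            hap_len = len(seq)
            n_frag = int(round(cov_per_hap * hap_len / (2.0 * rl)))
            starts_idx = [blk.hap_start for blk in blocks]
            gc_mask = None
            if spec.gc_bias:
                arr = np.frombuffer(seq.encode(), dtype=np.uint8)
                gc_mask = ((arr == ord("G")) | (arr == ord("C"))).astype(np.float32)
                gc_cum = np.concatenate([[0.0], np.cumsum(gc_mask)])
            made = 0
            frag_i = 0
            max_tries = n_frag * 20 + 1000
            tries = 0
            while made < n_frag and tries < max_tries:
                tries += 1
                insert = int(round(rng.normal(spec.insert_mean, spec.insert_sd)))
                insert = max(2 * rl, insert)
                if hap_len <= insert:
                    continue
                s = int(rng.integers(0, hap_len - insert))
                if spec.gc_bias:
                    gc_frac = (gc_cum[s + insert] - gc_cum[s]) / insert
                    w = np.exp(spec.gc_bias * (gc_frac - 0.5) - abs(spec.gc_bias) * 0.5)
                    if rng.random() > w:
                        continue
                made += 1
                frag_i += 1
                base_name = f"h{hap_idx}_{name}_f{frag_i:07d}"
                n_copies = 1
                if spec.duplicate_fraction and rng.random() < spec.duplicate_fraction:
                    n_copies = 2
                for copy in range(n_copies):
                    qname = base_name if copy == 0 else f"{base_name}_dup{copy}"
                    records.extend(
                        _make_pair(
                            header, tid, blocks, starts_idx, seq, s, insert, rl,
                            qname, spec.error_rate, rng,
                        )
                    )

    records.sort(key=lambda r: (r.reference_id, r.reference_start, r.query_name, r.flag))
    ref_path = outdir / "ref.fa"
    with open(ref_path, "w") as fh:
        for chrom, seq in spec.chromosomes.items():
            fh.write(f">{chrom}\n")
            s = ref[chrom]
            for i in range(0, len(s), 80):
                fh.write(s[i : i + 80] + "\n")
    pysam.faidx(str(ref_path))

    bam_path = outdir / "reads.bam"
    with pysam.AlignmentFile(bam_path, "wb", header=header) as bf:
        for r in records:  # pre-sorted by (tid, pos)
            bf.write(r)
    pysam.index(str(bam_path))

    vcf_path = outdir / "truth.vcf"
    bed_path = outdir / "truth.bed"
    _write_truth(spec, ref, vcf_path, bed_path)
    spec_path = outdir / "sim_spec.json"
    spec_path.write_text(
        json.dumps(
            {**{k: v for k, v in asdict(spec).items() if k != "variants"},
             "variants": [asdict(v) for v in spec.variants]},
            indent=2,
        )
    )
    return SimOutput(ref_path, bam_path, vcf_path, bed_path, spec_path)


def _make_pair(header, tid, blocks, starts_idx, hapseq, s, insert, rl, qname, err, rng):
    """SAM records (primary + supplementary) for one fragment.

    BAM stores SEQ and CIGAR in reference-forward orientation: both depend
    only on the block strand; read1/read2 only decides the strand flag.
    """
    intervals = [(s, s + rl, False), (s + insert - rl, s + insert, True)]
    reads = []
    for a, b, is_read2 in intervals:
        raw = hapseq[a:b]  # hap-forward orientation
        if err > 0:
            mask = rng.random(rl) < err
            if mask.any():
                buf = list(raw)
                for i in np.nonzero(mask)[0]:
                    alts = [c for c in "ACGT" if c != buf[i]]
                    buf[i] = alts[int(rng.integers(3))]
                raw = "".join(buf)
        groups = [g for g in _map_read(blocks, starts_idx, a, b) if g.aligned_len > 0]
        primary = max(groups, key=lambda g: g.aligned_len) if groups else None
        supp = [g for g in groups if g is not primary and g.aligned_len >= SPLIT_MIN]
        reads.append(
            {"seq": raw, "primary": primary, "supp": supp, "is_read2": is_read2}
        )

    out = []
    p0, p1 = reads[0]["primary"], reads[1]["primary"]
    for ri, rd in enumerate(reads):
        mate = reads[1 - ri]
        pg = rd["primary"]
        if pg is None:
            continue  # fully unaligned read (e.g. inside a long insertion): dropped
        is_read2 = rd["is_read2"]
        mate_pg = mate["primary"]
        for g in [pg] + rd["supp"]:
            rec = pysam.AlignedSegment(header)
            rec.query_name = qname
            g_rev = (g.strand == "-") != is_read2  # alignment strand flag
            rec.query_sequence = rd["seq"] if g.strand == "+" else revcomp(rd["seq"])
            rec.query_qualities = pysam.qualitystring_to_array(chr(BASEQ + 33) * rl)
            rec.cigarstring = _cigar_string(g, rl)
            rec.reference_id = tid[g.chrom]
            rec.reference_start = g.ref_lo
            rec.mapping_quality = MAPQ
            flag = 0x1 | (0x80 if is_read2 else 0x40)
            if g_rev:
                flag |= 0x10
            if g is not pg:
                flag |= 0x800
            if mate_pg is None:
                flag |= 0x8
                rec.next_reference_id = tid[g.chrom]
                rec.next_reference_start = g.ref_lo
            else:
                if (mate_pg.strand == "-") != mate["is_read2"]:
                    flag |= 0x20
                rec.next_reference_id = tid[mate_pg.chrom]
                rec.next_reference_start = mate_pg.ref_lo
            rec.flag = flag
            if (
                g is pg
                and mate_pg is not None
                and p0 is not None
                and p1 is not None
                and p0.chrom == p1.chrom
            ):
                lo = min(p0.ref_lo, p1.ref_lo)
                hi = max(p0.ref_hi, p1.ref_hi)
                own_first = (pg.ref_lo, ri) < (mate_pg.ref_lo, 1 - ri)
                rec.template_length = (hi - lo) if own_first else -(hi - lo)
            else:
                rec.template_length = 0
            tags = [("MQ", MAPQ)]
            allg = [pg] + rd["supp"]
            if len(allg) > 1:
                sa_parts = [
                    f"{og.chrom},{og.ref_lo + 1},"
                    f"{'-' if (og.strand == '-') != is_read2 else '+'},"
                    f"{_cigar_string(og, rl)},{MAPQ},0"
                    for og in allg
                    if og is not g
                ]
                tags.append(("SA", ";".join(sa_parts) + ";"))
            rec.set_tags(tags)
            out.append(rec)
    return out


# ---------------------------------------------------------------------------
# Truth output
# ---------------------------------------------------------------------------

def _write_truth(spec: SimSpec, ref: dict, vcf_path: Path, bed_path: Path) -> None:
    lines = [
        "##fileformat=VCFv4.2",
        '##INFO=<ID=SVTYPE,Number=1,Type=String,Description="Variant type">',
        '##INFO=<ID=END,Number=1,Type=Integer,Description="End position">',
        '##INFO=<ID=SVLEN,Number=1,Type=Integer,Description="Variant length">',
        '##INFO=<ID=CHR2,Number=1,Type=String,Description="Partner chromosome">',
        '##INFO=<ID=POS2,Number=1,Type=Integer,Description="Partner position">',
        '##INFO=<ID=ZYG,Number=1,Type=String,Description="Planted zygosity">',
    ]
    for c, L in spec.chromosomes.items():
        lines.append(f"##contig=<ID={c},length={L}>")
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO")
    bed = []
    order = {c: i for i, c in enumerate(spec.chromosomes)}
    for i, v in enumerate(
        sorted(spec.variants, key=lambda v: (order[v.chrom], v.pos))
    ):
        vid = f"truth{i}"
        info = f"ZYG={v.zygosity}"
        if v.kind == "SNV":
            r = ref[v.chrom][v.pos]
            lines.append(
                f"{v.chrom}\t{v.pos + 1}\t{vid}\t{r}\t{v.alt}\t.\tPASS\tSVTYPE=SNV;{info}"
            )
            bed.append(f"{v.chrom}\t{v.pos}\t{v.pos + 1}\tSNV")
        elif v.kind == "DEL" and v.length < INDEL_SV_BOUNDARY:
            r = ref[v.chrom][v.pos - 1 : v.pos + v.length]
            lines.append(
                f"{v.chrom}\t{v.pos}\t{vid}\t{r}\t{r[0]}\t.\tPASS\t"
                f"SVTYPE=DEL;END={v.pos + v.length};SVLEN=-{v.length};{info}"
            )
            bed.append(f"{v.chrom}\t{v.pos}\t{v.pos + v.length}\tDEL")
        elif v.kind == "INS" and v.length < INDEL_SV_BOUNDARY:
            r = ref[v.chrom][v.pos]
            lines.append(
                f"{v.chrom}\t{v.pos + 1}\t{vid}\t{r}\t{r}{v.ins_seq}\t.\tPASS\t"
                f"SVTYPE=INS;END={v.pos + 1};SVLEN={v.length};{info}"
            )
            bed.append(f"{v.chrom}\t{v.pos}\t{v.pos + 1}\tINS")
        elif v.kind == "TRA":
            r = ref[v.chrom][v.pos]
            lines.append(
                f"{v.chrom}\t{v.pos + 1}\t{vid}\t{r}\t<TRA>\t.\tPASS\t"
                f"SVTYPE=TRA;CHR2={v.dest_chrom};POS2={v.dest_pos + 1};{info}"
            )
            bed.append(f"{v.chrom}\t{v.pos}\t{v.pos + 1}\tTRA")
        else:
            r = ref[v.chrom][v.pos]
            end = v.pos + (v.length if v.kind != "INS" else 1)
            svlen = -v.length if v.kind == "DEL" else v.length
            lines.append(
                f"{v.chrom}\t{v.pos + 1}\t{vid}\t{r}\t<{v.kind}>\t.\tPASS\t"
                f"SVTYPE={v.kind};END={end};SVLEN={svlen};{info}"
            )
            bed.append(f"{v.chrom}\t{v.pos}\t{end}\t{v.kind}")
    vcf_path.write_text("\n".join(lines) + "\n")
    bed_path.write_text("\n".join(bed) + "\n")
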