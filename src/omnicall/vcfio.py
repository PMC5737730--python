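"""VCF 4.2 emission and parsing.

Dialect: SNVs and small indels are sequence records (indels anchored at
the preceding base); SVs >= 50 bases use symbolic ALTs <DEL>/<DUP>/<INS>/
<INV> with POS at the first affected base and INFO END/SVLEN/SUPPORT/PBC;
translocations are paired BND records with MATEID.  QUAL is
-10*log10(p_bc), capped at 3000.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

from .matching import INDEL_SV_BOUNDARY, VariantCall
from .snv import SnvCandidate

_HEADER_META = [
    "##fileformat=VCFv4.2",
    '##INFO=<ID=SVTYPE,Number=1,Type=String,Description="Variant type">',
    '##INFO=<ID=END,Number=1,Type=Integer,Description="End of the affected interval">',
    '##INFO=<ID=SVLEN,Number=1,Type=Integer,Description="Signed variant length">',
    '##INFO=<ID=SUPPORT,Number=1,Type=Float,Description="Weighted supporting evidence">',
    '##INFO=<ID=PBC,Number=1,Type=Float,Description="Binomial mismapping probability">',
    '##INFO=<ID=MATEID,Number=1,Type=String,Description="Partner breakend">',
    '##INFO=<ID=CHR2,Number=1,Type=String,Description="Partner chromosome">',
    '##INFO=<ID=POS2,Number=1,Type=Integer,Description="Partner position (1-based)">',
    '##INFO=<ID=IMPRECISE,Number=0,Type=Flag,Description="Imprecise breakpoints">',
    '##INFO=<ID=DEPTHRATIO,Number=1,Type=Float,Description="Depth ratio vs genome median">',
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype (allele-fraction heuristic)">',
    '##ALT=<ID=DEL,Description="Deletion">',
    '##ALT=<ID=DUP,Description="Duplication">',
    '##ALT=<ID=INS,Description="Insertion">',
    '##ALT=<ID=INV,Description="Inversion">',
]


def _qual(p_bc: float) -> str:
    if p_bc <= 0:
        return "3000"
    return f"{min(3000.0, -10.0 * math.log10(p_bc)):.1f}"


def write_vcf(
    path: str | Path,
    contigs: list[tuple[str, int]],
    snvs: list[SnvCandidate],
    calls: list[VariantCall],
    ref_fetch=None,
    sample: str = "SAMPLE",
) -> None:
    """Write the combined SNV/indel/SV call set.

    ``ref_fetch(chrom, start, end)`` returns reference sequence; indel
    records need it for REF/ALT alleles (falls back to N when absent).
    """
    order = {c: i for i, (c, _) in enumerate(contigs)}
    rows = []

    def fetch(chrom, a, b):
        if ref_fetch is None:
            return "N" * (b - a)
        return ref_fetch(chrom, a, b).upper()

    for s in snvs:
        rows.append(
            (
                order[s.chrom], s.pos,
                f"{s.chrom}\t{s.pos + 1}\t.\t{s.ref_base}\t{s.alt_base}\t{_qual(s.p_bc)}"
                f"\tPASS\tSVTYPE=SNV;SUPPORT={s.alt_count};PBC={s.p_bc:.3g}\tGT\t{s.genotype}",
            )
        )
    bnd_i = 0
    for c in calls:
        info = f"SUPPORT={c.support:.1f};PBC={c.p_bc:.3g}"
        if c.sv_type == "TRA":
            bnd_i += 1
            id_a, id_b = f"bnd_{bnd_i}a", f"bnd_{bnd_i}b"
            ref_a = fetch(c.chrom, c.start, c.start + 1)
            ref_b = fetch(c.mate_chrom, c.mate_pos, c.mate_pos + 1)
            alt_a = f"{ref_a}[{c.mate_chrom}:{c.mate_pos + 1}["
            alt_b = f"]{c.chrom}:{c.start + 1}]{ref_b}"
            q = _qual(c.p_bc)
            rows.append(
                (
                    order[c.chrom], c.start,
                    f"{c.chrom}\t{c.start + 1}\t{id_a}\t{ref_a}\t{alt_a}\t{q}\tPASS\t"
                    f"SVTYPE=BND;MATEID={id_b};CHR2={c.mate_chrom};POS2={c.mate_pos + 1};{info}\tGT\t./.",
                )
            )
            rows.append(
                (
                    order[c.mate_chrom], c.mate_pos,
                    f"{c.mate_chrom}\t{c.mate_pos + 1}\t{id_b}\t{ref_b}\t{alt_b}\t{q}\tPASS\t"
                    f"SVTYPE=BND;MATEID={id_a};CHR2={c.chrom};POS2={c.start + 1};{info}\tGT\t./.",
                )
            )
            continue
        length = int(round(c.length))
        if c.sv_type in ("DEL", "INS") and length < INDEL_SV_BOUNDARY:
            # sequence-explicit indel anchored at the preceding base
            if c.sv_type == "DEL":
                a = c.start - 1
                ref = fetch(c.chrom, a, c.end)
                alt = ref[0]
                pos1 = a + 1
                end = c.end
                svlen = -length
            else:
                a = c.start - 1
                anchor = fetch(c.chrom, a, c.start)
                ins = c.inserted_seq or ("N" * length)
                ref = anchor
                alt = anchor + ins
                pos1 = a + 1
                end = c.start
                svlen = length
            rows.append(
                (
                    order[c.chrom], a,
                    f"{c.chrom}\t{pos1}\t.\t{ref}\t{alt}\t{_qual(c.p_bc)}\tPASS\t"
                    f"SVTYPE={c.sv_type};END={end};SVLEN={svlen};{info}\tGT\t./.",
                )
            )
        else:
            svlen = -length if c.sv_type == "DEL" else length
            end = c.end if c.sv_type != "INS" else c.start + 1
            ref = fetch(c.chrom, c.start, c.start + 1)
            rows.append(
                (
                    order[c.chrom], c.start,
                    f"{c.chrom}\t{c.start + 1}\t.\t{ref}\t<{c.sv_type}>\t{_qual(c.p_bc)}\tPASS\t"
                    f"SVTYPE={c.sv_type};END={end};SVLEN={svlen};{info}\tGT\t./.",
                )
            )
    rows.sort(key=lambda r: (r[0], r[1]))
    lines = list(_HEADER_META)
    lines.extend(f"##contig=<ID={c},length={L}>" for c, L in contigs)
    lines.append(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{sample}")
    lines.extend(r[2] for r in rows)
    Path(path).write_text("\n".join(lines) + "\n")


def write_cnv_outputs(
    vcf_path: str | Path,
    bed_path: str | Path,
    contigs: list[tuple[str, int]],
    cnvs,
    sample: str = "SAMPLE",
) -> None:
    """Windowed read-depth CNV calls: symbolic VCF (IMPRECISE) + BED."""
    order = {c: i for i, (c, _) in enumerate(contigs)}
    lines = list(_HEADER_META)
    lines.extend(f"##contig=<ID={c},length={L}>" for c, L in contigs)
    lines.append(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{sample}")
    bed = []
    for c in sorted(cnvs, key=lambda c: (order[c.chrom], c.start)):
        svlen = (c.end - c.start) * (-1 if c.cnv_type == "DEL" else 1)
        lines.append(
            f"{c.chrom}\t{c.start + 1}\t.\tN\t<{c.cnv_type}>\t.\tPASS\t"
            f"IMPRECISE;SVTYPE={c.cnv_type};END={c.end};SVLEN={svlen};"
            f"DEPTHRATIO={c.ratio:.3f}\tGT\t./."
        )
        bed.append(f"{c.chrom}\t{c.start}\t{c.end}\t{c.cnv_type}\t{c.ratio:.3f}")
    Path(vcf_path).write_text("\n".join(lines) + "\n")
    Path(bed_path).write_text("\n".join(bed) + ("\n" if bed else ""))


# ---------------------------------------------------------------------------
# Parsing (benchmark harness input)
# ---------------------------------------------------------------------------

@dataclass
class SimpleVariant:
    """Normalized variant for benchmarking: 0-based half-open interval."""

    chrom: str
    start: int
    end: int
    vtype: str  # SNV | DEL | DUP | INS | INV | TRA
    length: int
    alt: Optional[str] = None
    chrom2: Optional[str] = None
    pos2: Optional[int] = None
    record_id: Optional[str] = None


def load_variants(path: str | Path) -> list[SimpleVariant]:
    """Load calls or a truth set from VCF (this dialect) or BED."""
    path = Path(path)
    if path.suffix.lower() == ".bed":
        out = []
        for line in path.read_text().splitlines():
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            chrom, a, b = f[0], int(f[1]), int(f[2])
            vt = f[3] if len(f) > 3 else "DEL"
            out.append(SimpleVariant(chrom, a, b, vt, b - a))
        return out
    import pysam

    out = []
    seen_bnd: set[str] = set()
    with pysam.VariantFile(str(path)) as vf:
        for rec in vf:
            info = dict(rec.info)
            svtype = info.get("SVTYPE")
            alts = rec.alts or ()
            alt = alts[0] if alts else None
            if svtype == "BND":
                if rec.id and rec.id in seen_bnd:
                    continue
                mate = info.get("MATEID")
                if isinstance(mate, tuple):
                    mate = mate[0]
                if mate:
                    seen_bnd.add(mate)
                out.append(
                    SimpleVariant(
                        rec.chrom, rec.start, rec.start + 1, "TRA", 0,
                        chrom2=info.get("CHR2"),
                        pos2=(info.get("POS2") - 1) if info.get("POS2") else None,
                        record_id=rec.id,
                    )
                )
                continue
            if svtype == "TRA" or (alt == "<TRA>"):
                out.append(
                    SimpleVariant(
                        rec.chrom, rec.start, rec.start + 1, "TRA", 0,
                        chrom2=info.get("CHR2"),
                        pos2=(info.get("POS2") - 1) if info.get("POS2") else None,
                        record_id=rec.id,
                    )
                )
                continue
            if alt and alt.startswith("<"):
                vt = alt.strip("<>")
                end = info.get("END", rec.stop)
                svlen = info.get("SVLEN", end - rec.start)
                if isinstance(svlen, tuple):
                    svlen = svlen[0]
                length = abs(int(svlen)) if svlen is not None else end - rec.start
                # POS is the first affected base in this dialect
                start = rec.pos - 1
                if vt == "INS":
                    out.append(SimpleVariant(rec.chrom, start, start + 1, "INS", length, record_id=rec.id))
                else:
                    out.append(SimpleVariant(rec.chrom, start, end, vt, length, record_id=rec.id))
                continue
            if alt is None:
                continue
            ref = rec.ref
            if len(ref) == 1 and len(alt) == 1:
                out.append(
                    SimpleVariant(rec.chrom, rec.start, rec.start + 1, "SNV", 1,
                                  alt=alt, record_id=rec.id)
                )
            elif len(ref) > len(alt):
                k = len(ref) - len(alt)
                out.append(
                    SimpleVariant(rec.chrom, rec.start + 1, rec.start + 1 + k, "DEL", k,
                                  record_id=rec.id)
                )
            elif len(alt) > len(ref):
                k = len(alt) - len(ref)
                out.append(
                    SimpleVariant(rec.chrom, rec.start + 1, rec.start + 2, "INS", k,
                                  alt=alt[len(ref):], record_id=rec.id)
                )
    return out
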