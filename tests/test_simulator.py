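"""The synthetic-library generator: planted variants must leave exactly the
alignment signatures a caller keys on."""

import hashlib

import numpy as np
import pysam
import pytest

from omnicall.dupfilter import duplicate_key
from omnicall.bench import evaluate
from omnicall.simulate import SimSpec, Variant, simulate


def md5(path):
    return hashlib.md5(path.read_bytes()).hexdigest()


class TestSpecValidation:
    def test_overlapping_variants_rejected_with_conflict_list(self, tmp_path):
        spec = SimSpec(
            chromosomes={"chr1": 50_000},
            variants=[
                Variant("DEL", "chr1", 10_000, length=500),
                Variant("INV", "chr1", 10_200, length=300),
            ],
        )
        with pytest.raises(ValueError, match="overlapping"):
            simulate(spec, tmp_path)

    def test_translocation_requires_destination(self):
        spec = SimSpec(variants=[Variant("TRA", "chr1", 1_000)])
        with pytest.raises(ValueError, match="dest"):
            spec.validate()


@pytest.fixture(scope="module")
def flat(tmp_path_factory):
    spec = SimSpec(chromosomes={"chr1": 100_000}, coverage=30.0, seed=5)
    return spec, simulate(spec, tmp_path_factory.mktemp("flat"))


class TestFlatLibrary:
    def test_mean_read_depth_within_5_percent(self, flat):
        spec, out = flat
        with pysam.AlignmentFile(str(out.bam)) as bam:
            total = sum(
                r.reference_length
                for r in bam.fetch()
                if not (r.is_secondary or r.is_supplementary)
            )
        mean_depth = total / 100_000
        assert abs(mean_depth - spec.coverage) / spec.coverage < 0.05

    def test_insert_sizes_match_specification(self, flat):
        spec, out = flat
        tlens = []
        with pysam.AlignmentFile(str(out.bam)) as bam:
            for r in bam.fetch():
                if r.template_length > 0 and not r.is_supplementary:
                    tlens.append(r.template_length)
        assert abs(np.mean(tlens) - spec.insert_mean) < 2.0
        assert abs(np.std(tlens) - spec.insert_sd) < 2.0

    def test_error_rate_matches_specification(self, flat):
        spec, out = flat
        ref = pysam.FastaFile(str(out.reference)).fetch("chr1")
        mismatches = bases = 0
        with pysam.AlignmentFile(str(out.bam)) as bam:
            for r in bam.fetch():
                if r.is_supplementary:
                    continue
                seq = r.query_sequence
                for qpos, rpos in r.get_aligned_pairs(matches_only=True):
                    bases += 1
                    if seq[qpos] != ref[rpos]:
                        mismatches += 1
        rate = mismatches / bases
        assert rate == pytest.approx(spec.error_rate, rel=0.15)


class TestDeterminism:
    def test_identical_spec_and_seed_byte_identical(self, tmp_path):
        def build(d):
            spec = SimSpec(
                chromosomes={"chr1": 30_000},
                variants=[Variant("DEL", "chr1", 15_000, length=700, zygosity="hom")],
                coverage=10.0,
                seed=99,
            )
            return simulate(spec, d)

        o1 = build(tmp_path / "a")
        o2 = build(tmp_path / "b")
        assert md5(o1.reference) == md5(o2.reference)
        assert md5(o1.bam) == md5(o2.bam)
        assert md5(o1.truth_vcf) == md5(o2.truth_vcf)


class TestPlantedSignatures:
    def test_homozygous_deletion_inflates_spanning_inserts(self, tmp_path):
        k = 1_000
        spec = SimSpec(
            chromosomes={"chr1": 60_000},
            variants=[Variant("DEL", "chr1", 30_000, length=k, zygosity="hom")],
            coverage=20.0,
            error_rate=0.0,
            seed=13,
        )
        out = simulate(spec, tmp_path)
        spanning = []
        with pysam.AlignmentFile(str(out.bam)) as bam:
            for r in bam.fetch():
                if r.is_supplementary or r.template_length <= 0:
                    continue
                if r.reference_end <= 30_000 and r.next_reference_start >= 30_000 + k - 100:
                    spanning.append(r.template_length)
        assert len(spanning) > 10
        assert abs(np.mean(spanning) - (spec.insert_mean + k)) < 60.0

    def test_deletion_junction_reads_are_clipped_or_split(self, tmp_path):
        spec = SimSpec(
            chromosomes={"chr1": 40_000},
            variants=[Variant("DEL", "chr1", 20_000, length=500, zygosity="hom")],
            coverage=20.0,
            error_rate=0.0,
            seed=21,
        )
        out = simulate(spec, tmp_path)
        clip_bounds = set()
        with pysam.AlignmentFile(str(out.bam)) as bam:
            for r in bam.fetch():
                if r.is_supplementary:
                    continue
                cig = r.cigartuples
                if cig and cig[-1][0] == 4 and cig[-1][1] >= 5:
                    clip_bounds.add(r.reference_end)
                if cig and cig[0][0] == 4 and cig[0][1] >= 5:
                    clip_bounds.add(r.reference_start)
        assert 20_000 in clip_bounds  # right-clips end exactly at the breakpoint
        assert 20_500 in clip_bounds  # left-clips start exactly after it

    def test_small_indels_appear_in_cigars(self, tmp_path):
        spec = SimSpec(
            chromosomes={"chr1": 30_000},
            variants=[
                Variant("DEL", "chr1", 10_000, length=3, zygosity="hom"),
                Variant("INS", "chr1", 20_000, length=6, zygosity="hom"),
            ],
            coverage=15.0,
            error_rate=0.0,
            seed=31,
        )
        out = simulate(spec, tmp_path)
        ops = set()
        with pysam.AlignmentFile(str(out.bam)) as bam:
            for r in bam.fetch():
                for op, ln in r.cigartuples or []:
                    if op in (1, 2):
                        ops.add((op, ln))
        assert (2, 3) in ops  # 3-base deletion
        assert (1, 6) in ops  # 6-base insertion

    def test_duplicate_fraction_produces_shared_keys(self, tmp_path):
        spec = SimSpec(
            chromosomes={"chr1": 80_000}, coverage=20.0,
            duplicate_fraction=0.1, seed=17,
        )
        out = simulate(spec, tmp_path)
        keys = []
        with pysam.AlignmentFile(str(out.bam)) as bam:
            for r in bam.fetch():
                if r.template_length > 0 and not r.is_supplementary:
                    keys.append(duplicate_key(r))
        n = len(keys)
        dup_frac = (n - len(set(keys))) / n
        # planted fraction 0.1 of source fragments => 0.1/1.1 of pairs
        assert 0.07 <= dup_frac <= 0.12

    def test_truth_roundtrips_against_itself(self, mixed_sim):
        _, out = mixed_sim
        res = evaluate(str(out.truth_vcf), str(out.truth_vcf))
        assert res.sensitivity == 1.0
        assert res.precision == 1.0
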