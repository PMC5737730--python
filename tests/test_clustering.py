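"""Adaptive-tolerance greedy breakpoint clustering."""

import numpy as np
import pytest

from omnicall.clustering import (
    BreakpointCluster,
    assign_read,
    cluster_candidates,
    cluster_tolerance,
)
from omnicall.evidence import BreakpointCandidate
from omnicall.insertsize import InsertSizeModel

# the worked configuration: base term 550 - 250 + 500 - 2*150 = 500
WORKED = InsertSizeModel(i_min=250.0, i_median=500.0, i_max=550.0, read_length=150)


def cand(length, read_id, weight=1.0, pos=1000, side="start", sv_type="DEL", exact=False):
    return BreakpointCandidate("chr1", pos, side, sv_type, float(length), weight,
                               read_id, exact=exact)


class TestClusterTolerance:
    def test_single_read_cluster_allows_twice_the_base_term(self):
        # one supporting read: the next read's length may differ by 1000
        assert cluster_tolerance(WORKED, 1) == pytest.approx(1000.0)

    def test_limit_is_the_base_term(self):
        assert cluster_tolerance(WORKED, 1e9) == pytest.approx(500.0, abs=1e-5)

    def test_strictly_decreasing_in_support(self):
        vals = [cluster_tolerance(WORKED, x) for x in (1, 2, 3, 5, 10, 100, 1000)]
        assert all(a > b for a, b in zip(vals, vals[1:]))

    def test_inconsistent_model_rejected(self):
        bad = InsertSizeModel(i_min=400.0, i_median=450.0, i_max=500.0, read_length=300)
        with pytest.raises(ValueError, match="base term"):
            cluster_tolerance(bad, 1)
        with pytest.raises(ValueError):
            cluster_tolerance(WORKED, 0)


class TestAssignRead:
    def test_first_candidate_seeds_a_singleton(self):
        clusters = []
        cl = assign_read(cand(1700, "r1"), clusters, WORKED)
        assert len(clusters) == 1
        assert cl.mean_length == 1700.0
        assert cl.support == 1.0

    def test_second_read_within_1000_joins(self):
        # first discordant pair says 1700; a 1200 candidate is within 1000
        clusters = []
        assign_read(cand(1700, "r1"), clusters, WORKED)
        assign_read(cand(1200, "r2"), clusters, WORKED)
        assert len(clusters) == 1
        assert clusters[0].mean_length == pytest.approx(1450.0)
        assert clusters[0].support == 2.0

    def test_tight_cluster_rejects_distant_length(self):
        # at support 100 the tolerance is 500 * 1.01 = 505 < 600
        clusters = [BreakpointCluster(1000, "start", "DEL", mean_length=1200.0,
                                      support=100.0, read_ids={f"m{i}" for i in range(100)})]
        assign_read(cand(1800, "new"), clusters, WORKED)
        assert len(clusters) == 2
        assert clusters[1].mean_length == 1800.0

    def test_most_reads_wins_then_closest_length(self):
        a = BreakpointCluster(1000, "start", "DEL", mean_length=1000.0, support=5.0,
                              read_ids={"a1", "a2", "a3", "a4", "a5"})
        b = BreakpointCluster(1000, "start", "DEL", mean_length=1195.0, support=2.0,
                              read_ids={"b1", "b2"})
        clusters = [a, b]
        joined = assign_read(cand(1200, "x"), clusters, WORKED)
        assert joined is a  # larger support wins although b is closer
        c1 = BreakpointCluster(1000, "start", "DEL", mean_length=900.0, support=3.0,
                               read_ids={"c1", "c2", "c3"})
        c2 = BreakpointCluster(1000, "start", "DEL", mean_length=1100.0, support=3.0,
                               read_ids={"d1", "d2", "d3"})
        joined = assign_read(cand(1150, "y"), [c1, c2], WORKED)
        assert joined is c2  # tie on support: closest mean length

    def test_duplicate_read_id_skips_that_cluster(self):
        clusters = []
        assign_read(cand(1000, "r1"), clusters, WORKED)
        assign_read(cand(1000, "r1"), clusters, WORKED)
        assert len(clusters) == 2  # same read cannot support one cluster twice

    def test_weighted_running_mean(self):
        clusters = []
        assign_read(cand(1000, "r1", weight=1.0), clusters, WORKED)
        assign_read(cand(1300, "r2", weight=0.5), clusters, WORKED)
        cl = clusters[0]
        assert cl.support == 1.5
        assert cl.mean_length == pytest.approx((1000 * 1.0 + 1300 * 0.5) / 1.5)

    def test_precise_indel_lengths_do_not_merge(self):
        clusters = []
        assign_read(cand(2, "r1", exact=True), clusters, WORKED)
        assign_read(cand(3, "r2", exact=True), clusters, WORKED)
        assign_read(cand(2, "r3", exact=True), clusters, WORKED)
        assert len(clusters) == 2
        assert sorted(c.mean_length for c in clusters) == [2.0, 3.0]


def oracle_greedy(candidates, model):
    """Independent re-implementation: clusters kept as raw member lists;
    mean/support recomputed from scratch at every decision."""
    clusters: list[list] = []
    for c in candidates:
        best = None
        for idx, members in enumerate(clusters):
            if any(m.read_id == c.read_id for m in members):
                continue
            support = sum(m.weight for m in members)
            mean = sum(m.weight * m.length for m in members) / support
            tol = (
                0.5
                if (c.exact and c.length < 50)
                else (model.i_max - model.i_min + model.i_median - 2 * model.read_length)
                * (1 + 1 / support)
            )
            d = abs(mean - c.length)
            if d <= tol:
                key = (-support, d, idx)
                if best is None or key < best[0]:
                    best = (key, idx)
        if best is None:
            clusters.append([c])
        else:
            clusters[best[1]].append(c)
    return [sorted(m.read_id for m in members) for members in clusters]


class TestAgainstBruteForceOracle:
    def test_partitions_identical_on_random_streams(self):
        rng = np.random.default_rng(2024)
        for trial in range(100):
            n = int(rng.integers(1, 21))
            cands = [
                cand(
                    float(rng.choice([100, 400, 800, 1200, 1500, 3000])
                          + rng.normal(0, 120)),
                    f"r{i}",
                    weight=float(rng.choice([0.5, 1.0])),
                )
                for i in range(n)
            ]
            clusters = []
            for c in cands:
                assign_read(c, clusters, WORKED)
            got = [sorted(cl.read_ids) for cl in clusters]
            assert got == oracle_greedy(cands, WORKED), f"trial {trial}"

    def test_mean_and_support_recompute(self):
        rng = np.random.default_rng(8)
        cands = [cand(float(rng.normal(1000, 200)), f"r{i}",
                      weight=float(rng.choice([0.5, 1.0]))) for i in range(50)]
        clusters = []
        for c in cands:
            assign_read(c, clusters, WORKED)
        by_id = {c.read_id: c for c in cands}
        for cl in clusters:
            members = [by_id[r] for r in cl.read_ids]
            support = sum(m.weight for m in members)
            mean = sum(m.weight * m.length for m in members) / support
            assert cl.support == pytest.approx(support)
            assert cl.mean_length == pytest.approx(mean)


class TestRecoveryAndDeterminism:
    def test_replaying_members_reproduces_cluster(self):
        rng = np.random.default_rng(4)
        cands = [cand(float(rng.normal(1200, 100)), f"r{i}") for i in range(30)]
        c1, c2 = [], []
        for c in cands:
            assign_read(c, c1, WORKED)
        for c in cands:
            assign_read(c, c2, WORKED)
        assert [(x.mean_length, x.support) for x in c1] == [
            (x.mean_length, x.support) for x in c2
        ]

    def test_dominant_cluster_recovers_true_length(self):
        rng = np.random.default_rng(99)
        true_len = 1200.0
        sd = 500.0 / 4.0  # base term / 4
        n = 200
        cands = [cand(float(rng.normal(true_len, sd)), f"r{i}") for i in range(n)]
        clusters = []
        for c in cands:
            assign_read(c, clusters, WORKED)
        top = max(clusters, key=lambda c: c.support)
        assert top.support >= 0.9 * n
        se = sd / np.sqrt(top.support)
        assert abs(top.mean_length - true_len) <= 3 * se

    def test_cluster_candidates_keys_by_locus(self):
        cands = [
            cand(1000, "r1", pos=500),
            cand(1000, "r2", pos=500),
            cand(1000, "r3", pos=600),
            cand(1000, "r4", pos=500, side="end"),
        ]
        out = cluster_candidates(cands, WORKED)
        assert set(out) == {(500, "start", "DEL"), (600, "start", "DEL"),
                            (500, "end", "DEL")}
        assert out[(500, "start", "DEL")][0].support == 2.0
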