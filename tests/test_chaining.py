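import math

import numpy as np
import pytest

from oracles import brute_best_chain_score
from wgalign.chaining import (
    INFEASIBLE,
    Anchor,
    ChainParams,
    chain_all,
    chain_partition,
    chain_reference,
    gap_cost,
    partition_anchors,
)
from wgalign.errors import PreconditionError
from wgalign.seeding import ANCHOR_DTYPE


def make_anchors(rows):
    """rows: (seqid, strand, tpos, qpos, span), already sorted."""
    arr = np.empty(len(rows), ANCHOR_DTYPE)
    for i, (seqid, strand, tpos, qpos, span) in enumerate(rows):
        arr[i] = (seqid, strand, tpos, qpos, span)
    return arr


def random_anchor_set(rng, n_seqs, n_anchors, coord_range=2000, span=15):
    rows = []
    for _ in range(n_anchors):
        rows.append(
            (
                int(rng.integers(0, n_seqs)),
                int(rng.integers(0, 2)),
                int(rng.integers(0, coord_range)),
                int(rng.integers(0, coord_range)),
                span,
            )
        )
    rows.sort()
    return make_anchors(rows)


class TestPartitionAnchors:
    def test_both_strands_of_three_sequences_give_six_partitions(self):
        rows = [
            (s, st, t * 10, t * 10, 15)
            for s in range(3)
            for st in range(2)
            for t in range(4)
        ]
        parts = partition_anchors(make_anchors(rows), T=3)
        assert len(parts) == 6  # twice the number of reference sequences
        assert [(p.seqid, p.strand) for p in parts] == [
            (s, st) for s in range(3) for st in range(2)
        ]

    def test_empty_input(self):
        assert partition_anchors(np.empty(0, ANCHOR_DTYPE), T=5) == []

    def test_single_group(self):
        a = make_anchors([(0, 0, i * 20, i * 20, 15) for i in range(10)])
        parts = partition_anchors(a, T=1)
        assert len(parts) == 1
        assert parts[0].anchors.shape[0] == 10

    def test_slices_tile_the_input(self, rng):
        a = random_anchor_set(rng, 4, 200)
        parts = partition_anchors(a, T=4)
        assert len(parts) <= 8
        rebuilt = np.concatenate([p.anchors for p in parts])
        assert np.array_equal(rebuilt, a)

    def test_unsorted_input_rejected(self):
        a = make_anchors([(1, 0, 0, 0, 15), (0, 0, 0, 0, 15)])
        with pytest.raises(PreconditionError):
            partition_anchors(a, T=2)


class TestGapCost:
    params = ChainParams()

    def a(self, qpos, tpos, strand=0, span=15):
        return Anchor(qpos=qpos, seqid=0, tpos=tpos, strand=strand, span=span)

    def test_colinear_anchors_cost_zero(self):
        assert gap_cost(self.a(0, 0), self.a(40, 40), self.params) == 0.0

    def test_same_target_start_infeasible(self):
        assert gap_cost(self.a(0, 0), self.a(10, 0), self.params) is INFEASIBLE

    def test_skew_bound(self):
        assert gap_cost(self.a(0, 0), self.a(10, 600), self.params) is INFEASIBLE

    def test_reverse_strand_query_direction(self):
        # on strand 1 the query coordinate must decrease along the chain
        assert gap_cost(
            self.a(100, 0, strand=1), self.a(60, 40, strand=1), self.params
        ) == 0.0
        assert gap_cost(
            self.a(60, 0, strand=1), self.a(100, 40, strand=1), self.params
        ) is INFEASIBLE

    def test_gap_cost_formula(self):
        # dq=30, dt=20 -> g=10: 0.01 * 15 * 10 + 0.5*log2(11)
        got = gap_cost(self.a(0, 0), self.a(30, 20), self.params)
        assert got == pytest.approx(1.5 + 0.5 * math.log2(11))


class TestChainPartition:
    def test_single_anchor_base_case(self):
        params = ChainParams(min_anchors=1, min_chain_score=10)
        parts = partition_anchors(make_anchors([(0, 0, 5, 7, 15)]), T=1)
        chains = chain_partition(parts[0], params)
        assert len(chains) == 1
        assert chains[0].score == 15.0
        assert (chains[0].qs, chains[0].qe) == (7, 22)

    def test_two_colinear_anchors_score(self):
        params = ChainParams(min_anchors=1, min_chain_score=1)
        parts = partition_anchors(
            make_anchors([(0, 0, 0, 0, 15), (0, 0, 20, 20, 15)]), T=1
        )
        chains = chain_partition(parts[0], params)
        assert chains[0].score == 30.0  # 15 + min(20, 20, 15)
        assert chains[0].n_anchors == 2

    def test_anchor_disjointness_and_score_floor(self, rng):
        params = ChainParams(min_anchors=2, min_chain_score=20)
        for _ in range(30):
            a = random_anchor_set(rng, 1, 40, coord_range=800)
            for p in partition_anchors(a, T=1):
                chains = chain_partition(p, params)
                seen = set()
                for c in chains:
                    assert c.score >= params.min_chain_score
                    members = {
                        (int(r["tpos"]), int(r["qpos"])) for r in c.anchors
                    }
                    assert not (members & seen)
                    seen |= members

    def test_dp_matches_exhaustive_enumeration(self, rng):
        """Best chain score equals brute force on small instances."""
        params = ChainParams(
            min_anchors=1, min_chain_score=1e-9, lookback=20,
            max_gap=300, max_skew_bandwidth=100,
        )
        for _ in range(120):
            n = int(rng.integers(1, 13))
            strand = int(rng.integers(0, 2))
            rows = sorted(
                (0, strand, int(rng.integers(0, 250)), int(rng.integers(0, 250)), 10)
                for _ in range(n)
            )
            a = make_anchors(rows)
            parts = partition_anchors(a, T=1)
            best = max(
                (c.score for p in parts for c in chain_partition(p, params)),
                default=0.0,
            )
            oracle = brute_best_chain_score(a, params, strand)
            assert best == pytest.approx(oracle, abs=1e-9)


class TestChainAll:
    params = ChainParams(min_anchors=2, min_chain_score=15)

    def test_worker_invariance(self, rng):
        for _ in range(15):
            a = random_anchor_set(rng, int(rng.integers(1, 5)), 150)
            base = chain_all(a, 8, self.params, workers=1)
            for workers in (2, 4, 8):
                assert chain_all(a, 8, self.params, workers=workers) == base

    def test_equals_unpartitioned_sequential_reference(self, rng):
        for _ in range(15):
            a = random_anchor_set(rng, int(rng.integers(1, 5)), 120)
            assert chain_all(a, 8, self.params, workers=4) == chain_reference(
                a, 8, self.params
            )

    def test_single_partition_matches_chain_partition(self, rng):
        a = random_anchor_set(rng, 1, 100)
        a = a[a["strand"] == 0]
        parts = partition_anchors(a, T=1)
        direct = chain_partition(parts[0], self.params) if parts else []
        from wgalign.chaining import sort_chains

        assert chain_all(a, 1, self.params, workers=8) == sort_chains(direct)

    def test_duplicated_seqid_chains_never_mix(self, rng):
        rows = [(0, 0, i * 20, i * 20, 15) for i in range(10)]
        rows += [(1, 0, i * 20, i * 20, 15) for i in range(10)]
        a = make_anchors(sorted(rows))
        chains = chain_all(a, 2, self.params, workers=4)
        assert len(chains) == 2
        assert {c.seqid for c in chains} == {0, 1}
        for c in chains:
            assert (c.anchors["seqid"] == c.seqid).all()
            assert (c.anchors["strand"] == c.strand).all()

    def test_global_order_descending_score(self, rng):
        a = random_anchor_set(rng, 3, 300)
        chains = chain_all(a, 3, self.params, workers=2)
        scores = [c.score for c in chains]
        assert scores == sorted(scores, reverse=True)
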