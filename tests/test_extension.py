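import numpy as np
import pytest

from conftest import random_dna
from oracles import cigar_score, exhaustive_align_score
from wgalign._util import revcomp
from wgalign.chaining import Chain, ChainFlag, ChainParams, chain_all
from wgalign.errors import BandExceededError, InternalConsistencyError
from wgalign.extension import (
    AlignParams,
    affine_align,
    cigar_spans,
    compute_mapq,
    extend_chain,
)
from wgalign.genome_io import SequenceRecord
from wgalign.seeding import ANCHOR_DTYPE, IndexParams, build_index, collect_anchors

P = AlignParams()


class TestAffineAlign:
    def test_identical_sequences(self):
        assert affine_align("ACGT", "ACGT", P) == (8.0, [("M", 4)])

    def test_pure_gap(self):
        score, cigar = affine_align("", "AC", P)
        assert (score, cigar) == (-8.0, [("D", 2)])
        score, cigar = affine_align("AC", "", P)
        assert (score, cigar) == (-8.0, [("I", 2)])

    def test_band_precondition(self):
        with pytest.raises(BandExceededError):
            affine_align("A" * 600, "A", AlignParams(band=500))

    def test_matches_exhaustive_enumeration(self, rng):
        for _ in range(200):
            a = random_dna(rng, int(rng.integers(0, 13)))
            b = random_dna(rng, int(rng.integers(0, 13)))
            score, cigar = affine_align(a, b, P)
            assert score == pytest.approx(exhaustive_align_score(a, b, P))
            # the traceback must realize the claimed score
            assert cigar_score(a, b, cigar, P) == pytest.approx(score)

    def test_matches_biopython_on_longer_pairs(self, rng):
        from Bio import Align

        aligner = Align.PairwiseAligner()
        aligner.mode = "global"
        aligner.match_score = P.match
        aligner.mismatch_score = -P.mismatch
        aligner.open_gap_score = -(P.gap_open + P.gap_extend)
        aligner.extend_gap_score = -P.gap_extend
        for _ in range(40):
            a = random_dna(rng, int(rng.integers(1, 60)))
            b = random_dna(rng, int(rng.integers(1, 60)))
            score, _ = affine_align(a, b, P)
            assert score == pytest.approx(aligner.score(a, b))

    def test_score_symmetry_with_ops_swapped(self, rng):
        for _ in range(50):
            a = random_dna(rng, int(rng.integers(0, 12)))
            b = random_dna(rng, int(rng.integers(0, 12)))
            sa, ca = affine_align(a, b, P)
            sb, cb = affine_align(b, a, P)
            assert sa == pytest.approx(sb)
            swap = {"I": "D", "D": "I", "M": "M"}
            assert sorted((swap[op], l) for op, l in ca) == sorted(cb)

    def test_banded_equals_unbanded_when_not_binding(self, rng):
        wide = AlignParams(band=500)
        narrow = AlignParams(band=12)
        for _ in range(40):
            a = random_dna(rng, int(rng.integers(1, 30)))
            b = random_dna(rng, int(rng.integers(max(1, len(a) - 5), len(a) + 6)))
            assert affine_align(a, b, narrow)[0] == affine_align(a, b, wide)[0]

    def test_cigar_consistency(self, rng):
        for _ in range(100):
            a = random_dna(rng, int(rng.integers(0, 25)))
            b = random_dna(rng, int(rng.integers(0, 25)))
            _, cigar = affine_align(a, b, P)
            q, t = cigar_spans(cigar)
            assert (q, t) == (len(a), len(b))
            assert all(l > 0 for _, l in cigar)
            assert all(x[0] != y[0] for x, y in zip(cigar, cigar[1:]))


def chains_for(query, ref, **chain_kw):
    idx = build_index([ref], IndexParams())
    anchors = collect_anchors(query, idx)
    params = ChainParams(**chain_kw) if chain_kw else ChainParams()
    return chain_all(anchors, 1, params, workers=1)


class TestExtendChain:
    def test_self_alignment_is_all_match(self, rng):
        seq = random_dna(rng, 1000)
        ref = SequenceRecord("r", seq)
        chains = chains_for(ref, ref)
        assert len(chains) == 1
        rec = extend_chain(chains[0], ref, ref)
        assert rec.nmatch == rec.alnlen
        cg = dict((t, v) for t, _, v in rec.tags)["cg"]
        assert cg == f"{rec.qend - rec.qstart}M"

    def test_insertion_in_query(self, rng):
        seq = random_dna(rng, 2000)
        query = SequenceRecord("q", seq[:1000] + random_dna(rng, 10) + seq[1000:])
        ref = SequenceRecord("r", seq)
        chains = chains_for(query, ref)
        rec = extend_chain(chains[0], query, ref)
        cg = dict((t, v) for t, _, v in rec.tags)["cg"]
        assert "10I" in cg
        assert (rec.qend - rec.qstart) == (rec.tend - rec.tstart) + 10

    def test_deletion_in_query(self, rng):
        seq = random_dna(rng, 2000)
        query = SequenceRecord("q", seq[:1000] + seq[1010:])
        ref = SequenceRecord("r", seq)
        rec = extend_chain(chains_for(query, ref)[0], query, ref)
        cg = dict((t, v) for t, _, v in rec.tags)["cg"]
        assert "10D" in cg

    def test_reverse_complement_query(self, rng):
        seq = random_dna(rng, 1500)
        ref = SequenceRecord("r", seq)
        query = SequenceRecord("q", revcomp(seq))
        chains = chains_for(query, ref)
        assert chains[0].strand == 1
        rec = extend_chain(chains[0], query, ref)
        assert rec.strand == "-"
        assert rec.nmatch == rec.alnlen

    def test_cigar_columns_match_record_intervals(self, rng):
        # CIGAR consistency invariant on snp-mutated alignments
        from wgalign.synthetic import MutationSpec, mutate, random_genome

        ref = random_genome(1, [3000], seed=9)
        query, _, _ = mutate(ref, MutationSpec(snp_rate=0.01, indel_rate=0.001, seed=2))
        for chain in chains_for(query[0], ref[0]):
            rec = extend_chain(chain, query[0], ref[0])
            cg = dict((t, v) for t, _, v in rec.tags)["cg"]
            cigar = [
                (op, int(n))
                for n, op in __import__("re").findall(r"(\d+)([MID])", cg)
            ]
            q, t = cigar_spans([(op, n) for op, n in cigar])
            assert q == rec.qend - rec.qstart
            assert t == rec.tend - rec.tstart

    def test_inconsistent_anchor_detected(self):
        arr = np.empty(3, ANCHOR_DTYPE)
        for i in range(3):
            arr[i] = (0, 0, i * 20, i * 20, 15)
        chain = Chain(
            anchors=arr, score=45.0, seqid=0, strand=0,
            qs=0, qe=55, ts=0, te=55, n_anchors=3, flag=ChainFlag.PRIMARY,
        )
        rng = np.random.default_rng(0)
        query = SequenceRecord("q", random_dna(rng, 80))
        ref = SequenceRecord("r", random_dna(rng, 80))
        with pytest.raises(InternalConsistencyError):
            extend_chain(chain, query, ref)


class TestComputeMapq:
    @pytest.mark.parametrize(
        "s1,s2,expected",
        [(100, None, 60), (100, 100, 0), (100, 50, 30), (100, 75, 15)],
    )
    def test_linear_rule(self, s1, s2, expected):
        assert compute_mapq(s1, s2) == expected

    def test_clamped(self):
        assert 0 <= compute_mapq(10, 9.999) <= 60
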