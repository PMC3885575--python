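import itertools
import math
import random

import numpy as np
import pytest

from oracles import enum_global_score, enum_local_score
from sdrforest.annotation import SiteSets, build_pssm
from sdrforest.io import MultipleAlignment, ProfileMatrix, SequenceRecord
from sdrforest.models import EnzymeModelSpec
from sdrforest.scoring import (
    KA_K,
    KA_LAMBDA,
    PairwiseAlignment,
    align_global,
    build_attribute_vector,
    build_schema,
    full_length_score,
    global_identity,
    local_bitscore,
    local_score,
    position_score,
    top_hit_score,
)


class TestGlobalAlignment:
    def test_identical_sequences_identity_mapping(self, b62):
        seq = "MKTWCAVEDA"
        aln = align_global(seq, seq)
        assert aln.rep_to_query == list(seq)
        assert aln.score == sum(b62.score(c, c) for c in seq)

    def test_matches_enumeration_oracle(self, b62):
        rng = random.Random(0)
        for _ in range(30):
            a = "".join(rng.choice("ACDW") for _ in range(rng.randint(1, 6)))
            b = "".join(rng.choice("ACDW") for _ in range(rng.randint(1, 6)))
            assert align_global(a, b).score == pytest.approx(enum_global_score(a, b, b62))

    def test_spec_pair_matches_oracle(self, b62):
        assert align_global("HEAGAWGHEE", "PAWHEAE").score == pytest.approx(
            enum_global_score("HEAGAWGHEE", "PAWHEAE", b62)
        )

    def test_mapping_total_for_short_query(self):
        aln = align_global("MKT", "MKTWCAVEDA")
        assert len(aln.rep_to_query) == 10
        assert all(q is None or len(q) == 1 for q in aln.rep_to_query)

    def test_identity_duplicate_invariance(self):
        assert global_identity("MKTW", "MKTW") == 100


class TestLocalBitscore:
    def test_self_comparison_follows_formula(self, b62):
        seq = "MKTWCAVEDA"
        raw = sum(b62.score(c, c) for c in seq)
        assert local_score(seq, seq) == raw
        bits, ok = local_bitscore(seq, seq)
        assert ok
        assert bits == pytest.approx((KA_LAMBDA * raw - math.log(KA_K)) / math.log(2))

    def test_matches_enumeration_oracle(self, b62):
        rng = random.Random(1)
        for _ in range(10):
            a = "".join(rng.choice("ACDW") for _ in range(rng.randint(1, 5)))
            b = "".join(rng.choice("ACDW") for _ in range(rng.randint(1, 5)))
            assert local_score(a, b) == pytest.approx(enum_local_score(a, b, b62))

    def test_no_positive_alignment_masked(self):
        bits, ok = local_bitscore("A", "W")  # sim(A,W) = -3 -> raw score 0
        assert bits == 0.0 and not ok

    def test_appending_identical_block_never_lowers_bits(self):
        a, b = "MKTW", "MKVW"
        bits0, _ = local_bitscore(a, b)
        bits1, _ = local_bitscore(a + "CCAVED", b + "CCAVED")
        assert bits1 >= bits0


class TestTopHit:
    def _recs(self):
        return [
            SequenceRecord(id="t1", sequence="MKTWCAVEDA"),
            SequenceRecord(id="t2", sequence="MKTWCAVEDV"),
        ]

    def test_prediction_mode_self_like_hit(self):
        q = SequenceRecord(id="q", sequence="MKTWCAVEDA")
        bits, ok = top_hit_score(q, self._recs(), mode="prediction")
        assert ok and bits == local_bitscore(q, self._recs()[0])[0]

    def test_training_mode_excludes_self(self):
        recs = self._recs()
        bits, _ = top_hit_score(recs[0], recs, mode="training")
        assert bits == local_bitscore(recs[0], recs[1])[0]
        with pytest.raises(ValueError, match="no training sequences"):
            top_hit_score(recs[0], [recs[0]], mode="training")

    def test_blast_tabular_pass_through(self):
        q = SequenceRecord(id="q", sequence="MKT")
        table = {("q", "t1"): 40.0, ("q", "t2"): 60.0}
        bits, ok = top_hit_score(q, self._recs(), blast_table=table)
        assert ok and bits == 60.0


class TestPositionAndFullLength:
    def test_matrix_mode_w_w(self, b62):
        aln = align_global("W", "W")
        score, ok = position_score(aln, 0, b62)
        assert ok and score == 11

    def test_query_gap_filled_with_minimum_and_masked(self, b62):
        aln = PairwiseAlignment(
            query_id="q", rep_id="r", aligned_query="M-T", aligned_rep="MKT", score=0
        )
        score, ok = position_score(aln, 1, b62, rep_sequence="MKT")
        assert not ok and score == b62.min_for("K")

    def test_matrix_mode_symmetric(self, b62):
        a1 = align_global("W", "C")
        a2 = align_global("C", "W")
        assert position_score(a1, 0, b62)[0] == position_score(a2, 0, b62)[0]

    def test_pssm_all_w_column_chains_to_eleven(self, b62):
        m = MultipleAlignment(ids=list("abcde"), rows=["W"] * 5)
        pssm = build_pssm(m, b62)
        aln = align_global("W", "W")
        score, ok = position_score(aln, 0, pssm.profile)
        assert ok and score == pytest.approx(11.0)

    def test_out_of_range_position_errors(self, b62):
        aln = align_global("MKT", "MKT")
        with pytest.raises(IndexError):
            position_score(aln, 3, b62)

    def test_full_length_identical_is_mean_diagonal(self, b62):
        seq = "MKTWCAVEDA"
        aln = align_global(seq, seq)
        expected = sum(b62.score(c, c) for c in seq) / len(seq)
        assert full_length_score(aln, b62) == pytest.approx(expected)

    def test_padding_moves_mean_toward_diagonal(self, b62):
        # closed form: ((s*n) + d*k) / (n+k) where d = score(W,W)
        base, pad = "MKTA", "W" * 6
        s = full_length_score(align_global(base, base), b62) * len(base)
        padded = full_length_score(align_global(base + pad, base + pad), b62)
        assert padded == pytest.approx((s + 11 * 6) / (len(base) + 6))

    def test_all_gap_alignment_errors(self, b62):
        aln = PairwiseAlignment(
            query_id="q", rep_id="r", aligned_query="---WWW", aligned_rep="MKT---", score=0
        )
        with pytest.raises(ValueError, match="no aligned residue columns"):
            full_length_score(aln, b62)


class TestSchemaAndVector:
    def _spec(self, b62, matrices=("blosum62", "pssm"), esst=None):
        rep = SequenceRecord(id="rep", sequence="MKTWCAVEDA")
        others = [
            SequenceRecord(id="t1", sequence="MKTWCAVEDA"),
            SequenceRecord(id="t2", sequence="MKTWCAVEDV"),
        ]
        m = MultipleAlignment(ids=["rep", "t1", "t2"], rows=[rep.sequence, others[0].sequence, others[1].sequence])
        pssm = build_pssm(m, b62)
        sites = SiteSets(asr={3}, lbr={4}, csr={0})
        schema = build_schema(sorted(sites.all_positions), matrices=matrices)
        return EnzymeModelSpec(
            ec="1.1.1.1", representative=rep, sites=sites, schema=schema,
            pssm=pssm, training_positives=[rep] + others, matrix=b62, esst=esst,
        )

    def test_three_positions_three_schemes_n13(self, b62):
        esst = ProfileMatrix(np.zeros((10, 20)), source_tag="esst")
        spec = self._spec(b62, matrices=("blosum62", "pssm", "esst"), esst=esst)
        assert spec.schema.n == 13  # 3*3 + 4

    def test_two_scheme_layout(self, b62):
        spec = self._spec(b62)
        assert spec.schema.n == 2 * 3 + 3
        assert len(set(spec.schema.names)) == spec.schema.n

    def test_self_query_hits_position_self_scores(self, b62):
        spec = self._spec(b62)
        vec = build_attribute_vector(spec.representative, spec, mode="prediction")
        names = spec.schema.names
        assert vec.values[names.index("pos4_blosum62")] == b62.score("W", "W")
        assert not vec.mask[1:].any()

    def test_locality_of_position_attributes(self, b62):
        spec = self._spec(b62)
        q1 = SequenceRecord(id="q1", sequence="MKTWCAVEDA")
        q2 = SequenceRecord(id="q2", sequence="MKTWCAVEDG")  # differs at non-annotated pos 10
        v1 = build_attribute_vector(q1, spec)
        v2 = build_attribute_vector(q2, spec)
        pos_idx = [i for i, d in enumerate(spec.schema.descriptors) if d.kind == "position"]
        full_idx = [i for i, d in enumerate(spec.schema.descriptors) if d.kind == "full_length"]
        np.testing.assert_array_equal(v1.values[pos_idx], v2.values[pos_idx])
        assert (v1.values[full_idx] != v2.values[full_idx]).all()

    def test_schema_indirection_vectors_align_by_name(self, b62):
        # the same query under two scheme orderings gives identical values by name
        spec_a = self._spec(b62, matrices=("blosum62", "pssm"))
        spec_b = self._spec(b62, matrices=("pssm", "blosum62"))
        q = SequenceRecord(id="q", sequence="MKTWCAVEDV")
        va = build_attribute_vector(q, spec_a)
        vb = build_attribute_vector(q, spec_b)
        da = dict(zip(spec_a.schema.names, va.values))
        db = dict(zip(spec_b.schema.names, vb.values))
        assert da == db
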