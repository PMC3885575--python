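import math

import numpy as np
import pytest

from oracles import entropy_oracle, pssm_score_oracle
from sdrforest.annotation import (
    SiteSets,
    assemble_sites,
    build_pssm,
    column_entropy,
    detect_ligand_contacts,
    select_csrs,
    stack_to_reference,
)
from sdrforest.io import AA20, AnnotationRow, MultipleAlignment, SequenceRecord, blosum62


def row(pos, category, ec="1.1.1.1", structure=""):
    return AnnotationRow("1.10.10.10", ec, "rep", pos, category, structure_id=structure)


def msa(*rows):
    return MultipleAlignment(ids=[f"s{i}" for i in range(len(rows))], rows=list(rows))


class TestAssembleSites:
    def test_active_and_binding_resolves_to_asr(self):
        sites = assemble_sites([row(12, "active"), row(12, "binding"), row(40, "binding")])
        assert sites.asr == {12} and sites.lbr == {40}

    def test_union_over_structures(self):
        mappings = {"pdb1": {40: 40}, "pdb2": {41: 41}}
        sites = assemble_sites(
            [row(40, "binding", structure="pdb1"), row(41, "binding", structure="pdb2")],
            mapping_alignments=mappings,
        )
        assert sites.lbr == {40, 41}

    def test_empty_annotation_gives_empty_sets(self):
        sites = assemble_sites([])
        assert sites.asr == set() and sites.lbr == set()

    def test_missing_mapping_errors_with_structure_id(self):
        with pytest.raises(ValueError, match="pdbX"):
            assemble_sites([row(5, "active", structure="pdbX")])

    def test_mapping_gap_drops_position(self, caplog):
        sites = assemble_sites(
            [row(5, "active", structure="pdb1")], mapping_alignments={"pdb1": {}}
        )
        assert sites.asr == set()

    def test_disjointness_enforced(self):
        with pytest.raises(ValueError, match="disjoint"):
            SiteSets(asr={1}, lbr={1})


class TestLigandContacts:
    def test_and_rule_on_hand_built_complex(self, contact_pdb):
        # SER has both a 3.0-A polar contact and a 3.5-A carbon contact;
        # ALA has the carbon contact only; GLY is ~85 A away.
        assert detect_ligand_contacts(contact_pdb, ["LIG"]) == {0}

    def test_distant_ligand_yields_empty_set(self, contact_pdb):
        hits = detect_ligand_contacts(contact_pdb, ["LIG"], hbond_cutoff=0.5, hydrophobic_cutoff=0.5)
        assert hits == set()

    def test_unknown_ligand_errors(self, contact_pdb):
        with pytest.raises(ValueError, match="XYZ"):
            detect_ligand_contacts(contact_pdb, ["XYZ"])


class TestColumnEntropy:
    def test_uniform_column_zero_entropy(self):
        prof = column_entropy(msa("AA", "AA", "AA", "AA"))
        assert prof.entropy[0] == 0

    def test_two_equal_symbols_ln2(self):
        prof = column_entropy(msa("A", "A", "V", "V"))
        assert prof.entropy[0] == pytest.approx(math.log(2))

    def test_gap_threshold_is_strict(self):
        # 25% gaps -> ineligible; exactly 20% -> still eligible
        prof = column_entropy(msa("A", "A", "A", "-"))
        assert not prof.eligible[0]
        prof = column_entropy(msa("A", "A", "A", "A", "-"))
        assert prof.eligible[0]

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(42)
        symbols = AA20 + "-X"
        rows = ["".join(symbols[i] for i in rng.integers(len(symbols), size=30)) for _ in range(12)]
        prof = column_entropy(MultipleAlignment(ids=[str(i) for i in range(12)], rows=rows))
        for k in range(30):
            col = "".join(r[k] for r in rows)
            assert prof.entropy[k] == pytest.approx(entropy_oracle(col), abs=1e-12)

    def test_duplicating_majority_row_never_raises_entropy(self):
        rng = np.random.default_rng(7)
        rows = ["".join(AA20[i] for i in rng.integers(4, size=15)) for _ in range(6)]
        base = MultipleAlignment(ids=[str(i) for i in range(6)], rows=rows)
        prof = column_entropy(base)
        # duplicate row 0; where it matches the column's majority symbol,
        # entropy must not increase
        bigger = MultipleAlignment(ids=[str(i) for i in range(7)], rows=rows + [rows[0]])
        prof2 = column_entropy(bigger)
        for k in range(15):
            col = base.column(k)
            majority = max(set(col), key=col.count)
            if rows[0][k] == majority:
                assert prof2.entropy[k] <= prof.entropy[k] + 1e-12

    def test_fractions_sum_to_one(self):
        prof = column_entropy(msa("AC-", "AVX", "ACW"))
        np.testing.assert_allclose(prof.fractions.sum(axis=1), 1.0)


class TestSelectCsrs:
    def _profile(self, n_cols, n_rows=4, seed=0):
        rng = np.random.default_rng(seed)
        rows = ["".join(AA20[i] for i in rng.integers(20, size=n_cols)) for _ in range(n_rows)]
        return column_entropy(MultipleAlignment(ids=[str(i) for i in range(n_rows)], rows=rows))

    def test_ten_percent_of_gap_free_columns(self):
        prof = self._profile(100)
        sites = select_csrs(prof, SiteSets())
        assert len(sites.csr) == 10

    def test_ceiling_for_tiny_alignments(self):
        prof = self._profile(5)
        sites = select_csrs(prof, SiteSets())
        assert len(sites.csr) == 1  # ceil(0.5)

    def test_asr_precedence_no_duplication(self):
        prof = column_entropy(msa("AAAB".replace("B", "V") * 5, "AAAV" * 5))
        lowest = int(np.lexsort((np.arange(prof.length), prof.entropy))[0])
        sites = select_csrs(prof, SiteSets(asr={lowest}))
        assert lowest in sites.asr and lowest not in sites.csr

    def test_equal_entropy_ties_break_by_index(self):
        prof = self._profile(20, n_rows=1)  # single row: all entropies 0
        # build_pssm needs >=2 rows but entropy works; all columns tie at 0
        sites = select_csrs(prof, SiteSets())
        assert sites.csr == set(range(2))  # ceil(0.1*20) = 2 lowest indices

    def test_no_eligible_columns_warns_empty(self):
        prof = column_entropy(msa("A-", "-A"))
        sites = select_csrs(prof, SiteSets())
        assert sites.csr == set()

    def test_sets_disjoint_and_count_exact(self, trained):
        _, _, models = trained
        for p in models.predictors.values():
            s = p.spec.sites
            assert not (s.asr & s.lbr or s.asr & s.csr or s.lbr & s.csr)


class TestPssm:
    def test_all_w_column_scores_eleven(self, b62):
        m = msa(*["W"] * 5)
        pssm = build_pssm(m, b62)
        w_idx = AA20.index("W")
        assert pssm.weights[0, w_idx] == pytest.approx(1.0)  # ln6/ln6
        assert pssm.profile.score(0, "W") == pytest.approx(11.0)

    def test_absent_residue_contributes_nothing(self, b62):
        pssm = build_pssm(msa("A", "A", "A"), b62)
        assert pssm.counts[0, AA20.index("W")] == 0
        assert pssm.weights[0, AA20.index("W")] == 0
        assert pssm.profile.score(0, "C") == pytest.approx(
            math.log(4) / math.log(4) * b62.score("A", "C")
        )

    def test_weights_bounded_and_one_iff_unanimous(self, b62):
        m = msa("AW", "AV", "AW")
        pssm = build_pssm(m, b62)
        assert np.all(pssm.weights >= 0) and np.all(pssm.weights <= 1)
        unanimous = pssm.counts == 3
        np.testing.assert_array_equal(pssm.weights == 1.0, unanimous)

    def test_matches_brute_force_oracle(self, b62):
        rng = np.random.default_rng(3)
        rows = ["".join((AA20 + "-")[i] for i in rng.integers(21, size=10)) for _ in range(7)]
        m = MultipleAlignment(ids=[str(i) for i in range(7)], rows=rows)
        pssm = build_pssm(m, b62)
        for k in range(10):
            col = m.column(k)
            for res in "AWCV":
                assert pssm.profile.score(k, res) == pytest.approx(
                    pssm_score_oracle(col, res, b62), abs=1e-10
                )

    def test_cone_bound(self, b62):
        rng = np.random.default_rng(5)
        rows = ["".join(AA20[i] for i in rng.integers(20, size=8)) for _ in range(6)]
        m = MultipleAlignment(ids=[str(i) for i in range(6)], rows=rows)
        pssm = build_pssm(m, b62)
        lo, hi = b62.scores.min(), b62.scores.max()
        for k in range(8):
            wsum = pssm.weights[k].sum()
            for j in range(20):
                assert lo * wsum - 1e-9 <= pssm.profile.scores[k, j] <= hi * wsum + 1e-9

    def test_single_sequence_rejected(self, b62):
        with pytest.raises(ValueError, match="two sequences"):
            build_pssm(msa("AW"), b62)


class TestStackToReference:
    def test_exact_for_indel_free_members(self, b62):
        ref = SequenceRecord(id="ref", sequence="MKTWCAVEDA")
        other = SequenceRecord(id="o", sequence="MKTWCAVEDV")
        m = stack_to_reference([other], ref)
        assert m.length == 10 and m.row_by_id("o") == "MKTWCAVEDV"
        assert m.row_by_id("ref") == ref.sequence
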