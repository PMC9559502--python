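import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from herdlink.pedigree import (Pedigree, PedigreeError, build_A_inverse,
                               build_A_tabular, compute_inbreeding,
                               mendelian_sampling_variances, pedigree_summary,
                               read_pedigree, write_pedigree)
from herdlink.synthetic_data import random_pedigree, scenario_presets, simulate_dataset


class TestReadValidate:
    def test_three_row_file_ordered(self, tmp_path):
        p = tmp_path / "ped.csv"
        p.write_text("animal,sire,dam,herd,birth_year,sex,breed\n"
                     "1,0,0,A,2000,M,L\n2,0,0,A,2000,F,L\n3,1,2,A,2001,F,L\n")
        ped = read_pedigree(p)
        assert list(ped.ids) == [1, 2, 3]
        assert ped.sire_pos[2] == 0 and ped.dam_pos[2] == 1

    def test_reversed_rows_same_order(self, tmp_path):
        fwd = tmp_path / "a.csv"
        rev = tmp_path / "b.csv"
        rows = ["1,0,0,A,2000,M,L", "2,0,0,A,2000,F,L", "3,1,2,A,2001,F,L"]
        hdr = "animal,sire,dam,herd,birth_year,sex,breed\n"
        fwd.write_text(hdr + "\n".join(rows) + "\n")
        rev.write_text(hdr + "\n".join(reversed(rows)) + "\n")
        assert list(read_pedigree(fwd).ids) == list(read_pedigree(rev).ids)

    def test_self_parentage_rejected(self):
        with pytest.raises(PedigreeError, match="self-parentage"):
            Pedigree.from_frame(pd.DataFrame({
                "animal": [5], "sire": [5], "dam": [0]}))

    def test_duplicate_id_rejected(self):
        with pytest.raises(PedigreeError, match="duplicate"):
            Pedigree.from_frame(pd.DataFrame({
                "animal": [1, 1], "sire": [0, 0], "dam": [0, 0]}))

    def test_cycle_rejected(self):
        with pytest.raises(PedigreeError, match="cycle"):
            Pedigree.from_frame(pd.DataFrame({
                "animal": [1, 2], "sire": [2, 1], "dam": [0, 0],
                "sex": ["M", "M"]}))

    def test_missing_parent_inserted_with_warning(self):
        with pytest.warns(UserWarning, match="inserting"):
            ped = Pedigree.from_frame(pd.DataFrame({
                "animal": [10], "sire": [1], "dam": [2]}))
        assert len(ped) == 3
        assert ped.is_base.sum() == 2

    def test_missing_parent_error_mode(self):
        with pytest.raises(PedigreeError, match="absent"):
            Pedigree.from_frame(
                pd.DataFrame({"animal": [10], "sire": [1], "dam": [2]}),
                missing_parents="error")

    def test_sex_consistency(self):
        with pytest.raises(PedigreeError, match="sire but recorded female"):
            Pedigree.from_frame(pd.DataFrame({
                "animal": [1, 2], "sire": [0, 1], "dam": [0, 0],
                "sex": ["F", "M"]}))

    def test_column_map(self, tmp_path):
        p = tmp_path / "ped.csv"
        p.write_text("id,father,mother\n1,0,0\n2,0,0\n3,1,2\n")
        ped = read_pedigree(p, column_map={"animal": "id", "sire": "father",
                                           "dam": "mother"})
        assert list(ped.ids) == [1, 2, 3]

    def test_subset_includes_ancestors(self, fullsib_mating_pedigree):
        ped = fullsib_mating_pedigree
        sub = ped.subset(ped.positions([5]))
        assert set(sub.ids) == {1, 2, 3, 4, 5}
        sub2 = ped.subset(ped.positions([3]))
        assert set(sub2.ids) == {1, 2, 3}

    def test_roundtrip(self, tmp_path, fullsib_mating_pedigree):
        path = tmp_path / "out.csv"
        write_pedigree(fullsib_mating_pedigree, path)
        again = read_pedigree(path)
        pd.testing.assert_frame_equal(
            fullsib_mating_pedigree.to_frame(), again.to_frame())


class TestInbreeding:
    def test_all_founders_zero(self):
        ped = Pedigree.from_frame(pd.DataFrame({
            "animal": [1, 2, 3], "sire": 0, "dam": 0}))
        assert np.all(compute_inbreeding(ped) == 0)

    def test_fullsib_offspring_quarter(self, fullsib_mating_pedigree):
        # oracle: F(x) = A(s, d)/2 with A from the tabular recursion
        F = compute_inbreeding(fullsib_mating_pedigree)
        A = build_A_tabular(fullsib_mating_pedigree)
        assert A[2, 3] == pytest.approx(0.5)
        assert F[4] == pytest.approx(0.5 * A[2, 3]) == pytest.approx(0.25)

    def test_parent_offspring_mating(self):
        # founder sire 1, unrelated dam 2, offspring 3; 4 = 1 x 3
        ped = Pedigree.from_frame(pd.DataFrame({
            "animal": [1, 2, 3, 4], "sire": [0, 0, 1, 1], "dam": [0, 0, 2, 3],
            "sex": ["M", "F", "F", "F"]}))
        F = compute_inbreeding(ped)
        A = build_A_tabular(ped)
        assert F[3] == pytest.approx(0.5 * A[0, 2]) == pytest.approx(0.25)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_tabular_diagonal(self, seed):
        ped = random_pedigree(80, seed=seed)
        F = compute_inbreeding(ped)
        A = build_A_tabular(ped)
        np.testing.assert_allclose(np.diag(A) - 1.0, F, atol=1e-12)


class TestRelationshipMatrices:
    def test_two_founders_identity(self):
        ped = Pedigree.from_frame(pd.DataFrame({
            "animal": [1, 2], "sire": 0, "dam": 0}))
        np.testing.assert_array_equal(build_A_tabular(ped), np.eye(2))
        np.testing.assert_array_equal(build_A_inverse(ped).toarray(), np.eye(2))

    def test_parent_offspring_half(self, trio_pedigree):
        A = build_A_tabular(trio_pedigree)
        assert A[0, 2] == pytest.approx(0.5)
        assert A[1, 2] == pytest.approx(0.5)

    def test_trio_inverse_hand_values(self, trio_pedigree):
        # oracle: dense inverse of the 3x3 tabular A
        Ainv = build_A_inverse(trio_pedigree).toarray()
        expected = np.linalg.inv(build_A_tabular(trio_pedigree))
        np.testing.assert_allclose(Ainv, expected, atol=1e-12)
        np.testing.assert_allclose(np.diag(Ainv), [1.5, 1.5, 2.0])
        assert Ainv[0, 1] == pytest.approx(0.5)
        assert Ainv[0, 2] == pytest.approx(-1.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_inverse_matches_dense_oracle(self, seed):
        ped = random_pedigree(50, seed=100 + seed)
        A = build_A_tabular(ped)
        Ainv = build_A_inverse(ped).toarray()
        err = np.max(np.abs(Ainv @ A - np.eye(len(ped))))
        assert err < 1e-8

    def test_single_unknown_parent(self):
        ped = Pedigree.from_frame(pd.DataFrame({
            "animal": [1, 2], "sire": [0, 1], "dam": [0, 0],
            "sex": ["M", "F"]}))
        A = build_A_tabular(ped)
        assert A[0, 1] == pytest.approx(0.5)
        d = mendelian_sampling_variances(ped)
        np.testing.assert_allclose(d, [1.0, 0.75])
        Ainv = build_A_inverse(ped).toarray()
        np.testing.assert_allclose(Ainv, np.linalg.inv(A), atol=1e-12)

    def test_tabular_cap(self):
        ped = random_pedigree(30, seed=0)
        with pytest.raises(PedigreeError, match="cap"):
            build_A_tabular(ped, cap=10)

    def test_block_diagonal_when_herds_disconnected(self):
        ped, _ = simulate_dataset(scenario_presets("disconnected", seed=5,
                                                   scale=0.25, years=4))
        A = build_A_tabular(ped)
        for h1 in ("A", "B"):
            for h2 in ("B", "C"):
                if h1 != h2:
                    blk = A[np.ix_(ped.herd == h1, ped.herd == h2)]
                    assert np.all(blk == 0)

    @settings(max_examples=15, deadline=None)
    @given(st.integers(min_value=5, max_value=120), st.integers(0, 10 ** 6))
    def test_property_inverse_oracle(self, n, seed):
        ped = random_pedigree(n, seed=seed)
        A = build_A_tabular(ped)
        Ainv = build_A_inverse(ped).toarray()
        assert np.max(np.abs(Ainv @ A - np.eye(n))) < 1e-8

    def test_topological_invariant(self):
        ped = random_pedigree(60, seed=7)
        for i in range(len(ped)):
            if ped.sire_pos[i] >= 0:
                assert ped.sire_pos[i] < i
            if ped.dam_pos[i] >= 0:
                assert ped.dam_pos[i] < i


class TestSummary:
    def test_pct_base_simple(self):
        ped = Pedigree.from_frame(pd.DataFrame({
            "animal": range(1, 11),
            "sire": [0, 0, 0, 1, 1, 1, 1, 1, 1, 1],
            "dam": [0, 0, 0, 2, 2, 2, 2, 2, 2, 3],
            "sex": ["M", "F", "F"] + ["F"] * 7,
        }))
        s = pedigree_summary(ped)
        assert s.loc[s.herd == "ALL", "pct_base"].iloc[0] == pytest.approx(30.0)

    def test_merged_equals_sum_of_per_herd(self):
        ped, phen = simulate_dataset(scenario_presets("ai_connected", seed=2,
                                                      scale=0.3, years=5))
        s = pedigree_summary(ped, phen)
        per_herd = s[s.herd != "ALL"]
        total = s[s.herd == "ALL"].iloc[0]
        for col in ("n_animals", "n_base", "n_litters"):
            assert per_herd[col].sum() == total[col]

    def test_default_scenario_pct_base_in_range(self):
        ped, _ = simulate_dataset(scenario_presets("ai_connected", seed=0))
        s = pedigree_summary(ped)
        pct = s.loc[s.herd == "ALL", "pct_base"].iloc[0]
        assert 10.0 < pct < 25.0
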