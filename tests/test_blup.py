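import warnings

import numpy as np
import pandas as pd
import pytest

from herdlink.blup import (assemble_mme, compute_pev_reliability, solve_mme,
                           summarize_reliability)
from herdlink.design import ModelSpec, build_design_matrices, build_model_frame
from herdlink.pedigree import build_A_inverse, build_A_tabular
from herdlink.pipeline import evaluate
from herdlink.synthetic_data import (random_pedigree, scenario_presets,
                                     simulate_dataset)
from herdlink.varcomp import VarianceComponents

from conftest import tiny_pedigree_for, tiny_phenotypes


def gls_oracle(dm, y, A, vc):
    """Dense generalized-least-squares oracle for MME solutions and PEV.

    b = (X'V^-1 X)^-1 X'V^-1 y with V = sum Z G Z' + R; random-effect
    predictions u_t = G_t Z_t' V^-1 (y - Xb).  PEV comes from the dense
    inverse of the full coefficient matrix.
    """
    X = dm.X.toarray()
    n = len(y)
    V = np.eye(n) * vc.sigma2_e
    Zs, Gs = [], []
    if vc.sigma2_l > 0:
        Zs.append(dm.Zl.toarray())
        Gs.append(np.eye(dm.Zl.shape[1]) * vc.sigma2_l)
    if vc.sigma2_p > 0:
        Zs.append(dm.Zp.toarray())
        Gs.append(np.eye(dm.Zp.shape[1]) * vc.sigma2_p)
    Zs.append(dm.Za.toarray())
    Gs.append(A * vc.sigma2_a)
    for Z, G in zip(Zs, Gs):
        V += Z @ G @ Z.T
    Vinv = np.linalg.inv(V)
    b = np.linalg.solve(X.T @ Vinv @ X, X.T @ Vinv @ y)
    resid = y - X @ b
    us = [G @ Z.T @ Vinv @ resid for Z, G in zip(Zs, Gs)]
    return b, us


def small_system(seed, n_animals=25, vc=None):
    rng = np.random.default_rng(seed)
    ped = random_pedigree(n_animals, seed=seed)
    females = ped.ids[ped.sex == "F"]
    rows = []
    for k, sow in enumerate(females):
        for p in range(1, int(rng.integers(1, 4)) + 1):
            rows.append({
                "sow": int(sow), "parity": p, "year": 2010, "month": 3,
                "genotype": "L", "litter_sire": int(ped.ids[0]),
                "herd": ped.herd[ped.order_index[int(sow)]],
                "age_days": 360 + 180 * p + int(rng.integers(0, 60)),
                "wci_days": np.nan if p == 1 else 8.0,
                "prev_lact_days": np.nan if p == 1 else 26.0,
                "birth_litter": f"L{k % 5}",
                "nba": float(rng.normal(16, 3)),
            })
    phen = pd.DataFrame(rows)
    vc = vc or VarianceComponents(1.0, 0.8, 0.3, 8.0)
    spec = ModelSpec(fixed_factors=("parity",), nested_age=False,
                     prev_lactation=False)
    frame = build_model_frame(phen, spec)
    dm = build_design_matrices(frame, ped)
    return ped, dm, frame.y, vc


class TestAssemble:
    def test_mean_only_no_random(self, trio_pedigree):
        # degenerate check done directly on the blocks: a single intercept
        # column and no records for animals means lhs[0,0] = n, rhs[0] = sum y
        phen = tiny_phenotypes()
        ped = tiny_pedigree_for(phen)
        spec = ModelSpec(fixed_factors=(), include_herd=False,
                         nested_age=False, prev_lactation=False)
        frame = build_model_frame(phen, spec)
        dm = build_design_matrices(frame, ped)
        vc = VarianceComponents(1.0, 1.0, 1.0, 8.0)
        sys = assemble_mme(dm, frame.y, build_A_inverse(ped), vc)
        assert sys.lhs[0, 0] == pytest.approx(len(phen))
        assert sys.rhs[0] == pytest.approx(frame.y.sum())

    def test_trio_animal_block_hand_assembly(self, trio_pedigree):
        phen = pd.DataFrame([{
            "sow": 3, "parity": 1, "year": 2010, "month": 3, "genotype": "L",
            "litter_sire": 1, "herd": "A", "age_days": 400,
            "wci_days": np.nan, "prev_lact_days": np.nan,
            "birth_litter": "L1", "nba": 14.0,
        }])
        spec = ModelSpec(fixed_factors=(), include_herd=False,
                         nested_age=False, prev_lactation=False,
                         random_terms=("animal",))
        frame = build_model_frame(phen, spec)
        dm = build_design_matrices(frame, trio_pedigree)
        vc = VarianceComponents(sigma2_a=2.0, sigma2_e=8.0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sys = assemble_mme(dm, frame.y, build_A_inverse(trio_pedigree), vc)
        k = vc.sigma2_e / vc.sigma2_a
        Ainv = np.linalg.inv(build_A_tabular(trio_pedigree))
        ZtZ = np.zeros((3, 3))
        ZtZ[2, 2] = 1.0
        lo, hi, _ = sys.index_map["animal"]
        block = sys.lhs.toarray()[lo:hi, lo:hi]
        np.testing.assert_allclose(block, ZtZ + Ainv * k, atol=1e-10)

    def test_doubling_sigma_a_halves_augmentation(self, trio_pedigree):
        ped, dm, y, vc = small_system(seed=0)
        Ainv = build_A_inverse(ped)
        s1 = assemble_mme(dm, y, Ainv, vc)
        vc2 = VarianceComponents(2 * vc.sigma2_a, vc.sigma2_p, vc.sigma2_l,
                                 vc.sigma2_e)
        s2 = assemble_mme(dm, y, Ainv, vc2)
        lo, hi, _ = s1.index_map["animal"]
        d1 = (s1.lhs - (s1.dm.Za.T @ s1.dm.Za +
                        0 * s1.lhs)[0, 0]) if False else None
        W1 = s1.lhs.toarray()[lo:hi, lo:hi]
        W2 = s2.lhs.toarray()[lo:hi, lo:hi]
        ZtZ = (dm.Za.T @ dm.Za).toarray()
        np.testing.assert_allclose(W1 - ZtZ, 2 * (W2 - ZtZ), atol=1e-10)

    def test_zero_variance_term_dropped(self):
        ped, dm, y, _ = small_system(seed=1)
        vc = VarianceComponents(1.0, 0.8, 0.0, 8.0)
        with pytest.warns(UserWarning, match="litter"):
            sys = assemble_mme(dm, y, build_A_inverse(ped), vc)
        assert "litter" not in sys.index_map


class TestSolve:
    def test_mean_only_model(self):
        phen = tiny_phenotypes()
        ped = tiny_pedigree_for(phen)
        spec = ModelSpec(fixed_factors=(), include_herd=False,
                         nested_age=False, prev_lactation=False)
        frame = build_model_frame(phen, spec)
        dm = build_design_matrices(frame, ped)
        vc = VarianceComponents(sigma2_a=1e-6, sigma2_e=8.0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sys = assemble_mme(dm, frame.y, build_A_inverse(ped), vc)
            res = solve_mme(sys)
        assert res.fixed_solutions.iloc[0] == pytest.approx(frame.y.mean(),
                                                            rel=1e-3)

    def test_unconnected_animal_zero_ebv(self):
        ped, dm, y, vc = small_system(seed=2)
        sys = assemble_mme(dm, y, build_A_inverse(ped), vc)
        res = solve_mme(sys)
        phenotyped = set()
        females = dm.sow_ids.tolist()
        for i, a in enumerate(ped.ids):
            rel = False
            if int(a) in females:
                rel = True
            if ped.sire_pos[i] >= 0 or ped.dam_pos[i] >= 0:
                rel = True
            if not rel and not np.any(
                    (ped.sire_pos == i) | (ped.dam_pos == i)):
                assert res.ebv.loc[int(a)] == pytest.approx(0.0, abs=1e-12)
                phenotyped.add(int(a))

    @pytest.mark.parametrize("seed", range(5))
    def test_solutions_match_gls_oracle(self, seed):
        ped, dm, y, vc = small_system(seed=seed)
        A = build_A_tabular(ped)
        b, us = gls_oracle(dm, y, A, vc)
        sys = assemble_mme(dm, y, build_A_inverse(ped), vc)
        res = solve_mme(sys)
        np.testing.assert_allclose(res.fixed_solutions.to_numpy(), b,
                                   atol=1e-6)
        np.testing.assert_allclose(res.ebv.to_numpy(), us[-1], atol=1e-6)

    def test_bitwise_reproducible(self):
        ped, dm, y, vc = small_system(seed=3)
        Ainv = build_A_inverse(ped)
        r1 = solve_mme(assemble_mme(dm, y, Ainv, vc))
        r2 = solve_mme(assemble_mme(dm, y, Ainv, vc))
        assert np.array_equal(r1.ebv.to_numpy(), r2.ebv.to_numpy())


class TestPevReliability:
    @pytest.mark.parametrize("seed", range(5))
    def test_pev_matches_dense_inverse(self, seed):
        ped, dm, y, vc = small_system(seed=40 + seed)
        sys = assemble_mme(dm, y, build_A_inverse(ped), vc)
        res = compute_pev_reliability(sys)
        Cinv = np.linalg.inv(sys.lhs.toarray())
        lo, hi, _ = sys.index_map["animal"]
        np.testing.assert_allclose(res.pev.to_numpy(),
                                   vc.sigma2_e * np.diag(Cinv)[lo:hi],
                                   atol=1e-8)

    def test_reliability_formula(self):
        ped, dm, y, vc = small_system(seed=50)
        sys = assemble_mme(dm, y, build_A_inverse(ped), vc)
        res = compute_pev_reliability(sys)
        np.testing.assert_allclose(
            res.reliability.to_numpy(),
            np.clip(1 - res.pev.to_numpy() / vc.sigma2_a, 0, 1), atol=1e-12)
        assert res.reliability.between(0, 1).all()

    def test_unphenotyped_unrelated_reliability_zero(self):
        ped, dm, y, vc = small_system(seed=51)
        sys = assemble_mme(dm, y, build_A_inverse(ped), vc)
        res = compute_pev_reliability(sys)
        has_rec = set(int(s) for s in dm.sow_ids)
        for i, a in enumerate(ped.ids):
            isolated = (ped.sire_pos[i] < 0 and ped.dam_pos[i] < 0
                        and int(a) not in has_rec
                        and not np.any((ped.sire_pos == i) | (ped.dam_pos == i)))
            if isolated:
                assert res.pev.loc[int(a)] == pytest.approx(vc.sigma2_a,
                                                            rel=1e-8)
                assert res.reliability.loc[int(a)] == pytest.approx(0.0,
                                                                    abs=1e-8)

    def test_paper_arithmetic_example(self):
        # r2 = 1 - PEV / var_a for PEV=0.2, var_a=0.825
        assert 1 - 0.2 / 0.825 == pytest.approx(0.7575757575757576)

    def test_daughter_record_never_decreases_sire_reliability(self):
        vc = VarianceComponents(1.0, 0.0, 0.0, 4.0)
        base = pd.DataFrame({
            "animal": [1, 2, 3], "sire": [0, 0, 1], "dam": [0, 0, 2],
            "sex": ["M", "F", "F"], "herd": "A", "birth_year": 2000,
            "breed": "L"})
        rel_sire = []
        for n_daughters in (1, 2, 3):
            rows = base.copy()
            for k in range(1, n_daughters):
                rows = pd.concat([rows, pd.DataFrame([{
                    "animal": 3 + k, "sire": 1, "dam": 2, "sex": "F",
                    "herd": "A", "birth_year": 2000, "breed": "L"}])],
                    ignore_index=True)
            from herdlink.pedigree import Pedigree
            ped = Pedigree.from_frame(rows)
            phen = pd.DataFrame([{
                "sow": 3 + k, "parity": 1, "year": 2010, "month": 3,
                "genotype": "L", "litter_sire": 1, "herd": "A",
                "age_days": 400, "wci_days": np.nan,
                "prev_lact_days": np.nan, "birth_litter": f"B{k}",
                "nba": 15.0 + k} for k in range(n_daughters)])
            spec = ModelSpec(fixed_factors=(), include_herd=False,
                             nested_age=False, prev_lactation=False,
                             random_terms=("animal",))
            frame = build_model_frame(phen, spec)
            dm = build_design_matrices(frame, ped)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                sys = assemble_mme(dm, frame.y, build_A_inverse(ped), vc)
                res = compute_pev_reliability(sys)
            rel_sire.append(res.reliability.loc[1])
        assert rel_sire == sorted(rel_sire)


class TestSummaries:
    def test_equal_reliabilities_zero_sd(self):
        rel = pd.Series([0.5, 0.5, 0.5], index=[1, 2, 3])
        from herdlink.blup import EvaluationResult
        res = EvaluationResult(
            fixed_solutions=pd.Series(dtype=float),
            litter_solutions=pd.Series(dtype=float),
            perm_solutions=pd.Series(dtype=float),
            ebv=rel * 0, pev=rel * 0, reliability=rel)
        out = summarize_reliability(res, pd.Series("A", index=[1, 2, 3]))
        assert out.loc[out.group == "A", "sd"].iloc[0] == 0.0

    def test_merged_N_equals_sum(self):
        ped, phen = simulate_dataset(scenario_presets("ai_connected", seed=8,
                                                      scale=0.3, years=5))
        vc = VarianceComponents(0.97, 0.727, 0.181, 8.754)
        ev = evaluate(ped, phen, vc=vc)
        out = ev.reliability_summary(phen=phen)
        per = out[out.group != "ALL"]["N"].sum()
        assert per == out.loc[out.group == "ALL", "N"].iloc[0]
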