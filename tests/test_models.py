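import numpy as np
import pandas as pd
import pytest

from crossblup import pedigree as pm
from crossblup.models import (
    VarianceComponents,
    build_fixed_design,
    pedigree_blup_ebv,
    reml_estimate,
    solve_multi_trait,
    solve_single_trait,
)
from crossblup.relationship import build_A
from conftest import random_pedigree


def gls_oracle(y, X, Zidx, A, s2u, s2e, n_ped):
    """Marginal-model GLS: b = (X'V^-1 X)^-1 X'V^-1 y, u = s2u A Z' V^-1 e."""
    Z = np.zeros((len(y), n_ped))
    Z[np.arange(len(y)), Zidx] = 1.0
    V = s2u * Z @ A @ Z.T + s2e * np.eye(len(y))
    Vi = np.linalg.inv(V)
    b = np.linalg.solve(X.T @ Vi @ X, X.T @ Vi @ y)
    u = s2u * A @ Z.T @ Vi @ (y - X @ b)
    return b, u


def toy_system(seed=0, n=6, n_f=3, n_rec=5):
    sire, dam, ped = random_pedigree(n, n_f, seed=seed)
    A = build_A(ped).values
    rng = np.random.default_rng(seed + 1)
    rec_ids = rng.choice(n, n_rec, replace=False) + 1
    rec = pd.DataFrame(
        {
            "id": rec_ids,
            "sex": rng.choice(["M", "F"], n_rec),
            "phenotype": rng.normal(0, 1, n_rec),
        }
    )
    Ainv = pm.a_inverse_from_indices(sire, dam)
    return ped, A, Ainv, rec


class TestSingleTrait:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_gls_oracle(self, seed):
        ped, A, Ainv, rec = toy_system(seed)
        s2u, s2e = 0.4, 0.6
        sol = solve_single_trait(
            rec, ped["id"].to_numpy(), Ainv, s2e / s2u, fixed_effects=("sex",)
        )
        X, _ = build_fixed_design(rec, ("sex",))
        b, u = gls_oracle(
            rec["phenotype"].to_numpy(), X, rec["id"].to_numpy() - 1, A,
            s2u, s2e, len(ped),
        )
        assert np.allclose(sol.gebv.to_numpy(), u, atol=1e-8)
        assert np.allclose(sol.fixed.to_numpy(), b, atol=1e-8)
        assert sol.convergence["relative_residual"] < 1e-8

    def test_dense_and_sparse_paths_agree(self):
        ped, A, Ainv, rec = toy_system(3)
        lam = 1.7
        s_sparse = solve_single_trait(rec, ped["id"].to_numpy(), Ainv, lam,
                                      fixed_effects=("sex",))
        s_dense = solve_single_trait(rec, ped["id"].to_numpy(), Ainv.toarray(),
                                     lam, fixed_effects=("sex",))
        assert np.allclose(s_sparse.gebv, s_dense.gebv, atol=1e-8)

    def test_full_shrinkage_limit(self):
        ped, A, Ainv, rec = toy_system(1)
        sol = solve_single_trait(rec, ped["id"].to_numpy(), Ainv, 1e10,
                                 fixed_effects=("sex",))
        assert np.allclose(sol.gebv.to_numpy(), 0.0, atol=1e-6)

    def test_noiseless_limit_recovers_records(self):
        """With phenotypes = TBV and lambda -> 0, recorded animals' GEBVs
        approach their records (after the tiny fixed-effect absorption)."""
        sire, dam, ped = random_pedigree(8, 4, seed=5)
        A = build_A(ped).values
        rng = np.random.default_rng(6)
        tbv = np.linalg.cholesky(A + 1e-9 * np.eye(8)) @ rng.normal(size=8)
        rec = pd.DataFrame({"id": ped["id"], "sex": ["M"] * 8, "phenotype": tbv})
        Ainv = pm.a_inverse_from_indices(sire, dam)
        sol = solve_single_trait(rec, ped["id"].to_numpy(), Ainv, 1e-8,
                                 fixed_effects=())
        resid = sol.gebv.to_numpy() + sol.fixed.iloc[0] - tbv
        assert np.max(np.abs(resid)) < 1e-4

    def test_order_invariance(self):
        ped, A, Ainv, rec = toy_system(7)
        sol1 = solve_single_trait(rec, ped["id"].to_numpy(), Ainv, 2.0,
                                  fixed_effects=("sex",))
        shuffled = rec.sample(frac=1.0, random_state=0).reset_index(drop=True)
        sol2 = solve_single_trait(shuffled, ped["id"].to_numpy(), Ainv, 2.0,
                                  fixed_effects=("sex",))
        assert np.allclose(sol1.gebv, sol2.gebv, atol=1e-8)


class TestMultiTrait:
    def _records(self, seed=0, n=9, n_f=4):
        sire, dam, ped = random_pedigree(n, n_f, seed=seed)
        A = build_A(ped).values
        rng = np.random.default_rng(seed + 10)
        ids = rng.permutation(n) + 1
        rec = pd.DataFrame(
            {
                "id": ids,
                "sex": rng.choice(["M", "F"], n),
                "trait": np.repeat([0, 1, 2], [3, 3, n - 6]),
                "phenotype": rng.normal(0, 1, n),
            }
        )
        Ainv = np.linalg.inv(A)
        return ped, A, Ainv, rec

    def test_diagonal_g0_decouples_into_single_trait(self):
        ped, A, Ainv, rec = self._records(1)
        G0 = np.diag([0.5, 0.3, 0.4])
        R0 = np.diag([0.6, 0.8, 0.7])
        vc = VarianceComponents(np.diag(G0), np.diag(R0), G0=G0, R0=R0)
        sol = solve_multi_trait(rec, ped["id"].to_numpy(), Ainv, vc,
                                fixed_effects=())
        for t in range(3):
            sub = rec[rec["trait"] == t]
            s1 = solve_single_trait(
                sub, ped["id"].to_numpy(),
                np.linalg.inv(A), R0[t, t] / G0[t, t], fixed_effects=(),
            )
            assert np.allclose(sol.gebv.iloc[:, t], s1.gebv, atol=1e-7)

    def test_matches_dense_gls_oracle_two_traits(self):
        sire, dam, ped = random_pedigree(6, 3, seed=4)
        A = build_A(ped).values
        rng = np.random.default_rng(2)
        rec = pd.DataFrame(
            {
                "id": [1, 2, 3, 4, 5, 6],
                "sex": ["M"] * 6,
                "trait": [0, 0, 0, 1, 1, 1],
                "phenotype": rng.normal(0, 1, 6),
            }
        )
        G0 = np.array([[0.5, 0.2], [0.2, 0.4]])
        R0 = np.diag([0.7, 0.9])
        vc = VarianceComponents(np.diag(G0), np.diag(R0), G0=G0, R0=R0)
        sol = solve_multi_trait(rec, ped["id"].to_numpy(), np.linalg.inv(A), vc,
                                fixed_effects=())
        # GLS on the stacked system: u ~ N(0, G0 (x) A), e ~ N(0, R)
        n = 6
        y = rec["phenotype"].to_numpy()
        Z = np.zeros((n, 2 * n))
        for r in range(n):
            Z[r, rec["trait"][r] * n + (rec["id"][r] - 1)] = 1.0
        K = np.kron(G0, A)
        Rv = np.diag(R0[rec["trait"], rec["trait"]])
        X = np.zeros((n, 2))
        X[rec["trait"] == 0, 0] = 1.0
        X[rec["trait"] == 1, 1] = 1.0
        V = Z @ K @ Z.T + Rv
        Vi = np.linalg.inv(V)
        b = np.linalg.solve(X.T @ Vi @ X, X.T @ Vi @ y)
        u = K @ Z.T @ Vi @ (y - X @ b)
        got = np.concatenate([sol.gebv.iloc[:, 0], sol.gebv.iloc[:, 1]])
        assert np.allclose(got, u, atol=1e-7)

    def test_unit_genetic_correlation_gives_proportional_gebvs(self):
        ped, A, Ainv, rec = self._records(3)
        v = 0.4
        G0 = np.full((3, 3), v)  # r_g = 1, equal variances
        R0 = np.diag([0.6, 0.6, 0.6])
        vc = VarianceComponents(np.diag(G0), np.diag(R0), G0=G0, R0=R0)
        sol = solve_multi_trait(rec, ped["id"].to_numpy(), Ainv, vc,
                                fixed_effects=())
        u = sol.gebv.to_numpy()
        assert np.allclose(u[:, 0], u[:, 1], atol=1e-6)
        assert np.allclose(u[:, 0], u[:, 2], atol=1e-6)


class TestReml:
    def _sim_records(self, n=400, h2=0.33, vp=0.13, seed=0):
        rng = np.random.default_rng(seed)
        n_f = 80
        sire = np.full(n, -1)
        dam = np.full(n, -1)
        for i in range(n_f, n):
            sire[i] = rng.integers(0, min(i, n_f + (i - n_f) // 2))
            dam[i] = rng.integers(0, min(i, n_f + (i - n_f) // 2))
            if dam[i] == sire[i]:
                dam[i] = -1
        A = pm.tabular_A(sire, dam)
        u = np.linalg.cholesky(A + 1e-10 * np.eye(n)) @ rng.normal(
            0, np.sqrt(h2 * vp), n
        )
        y = 0.3 + u + rng.normal(0, np.sqrt((1 - h2) * vp), n)
        rec = pd.DataFrame(
            {"id": np.arange(1, n + 1), "sex": rng.choice(["M", "F"], n),
             "phenotype": y}
        )
        return rec, A

    def test_recovers_simulated_h2_and_vp(self):
        h2s, vps = [], []
        for seed in range(4):
            rec, A = self._sim_records(seed=seed)
            vc = reml_estimate(rec, A, fixed_effects=("sex",))
            h2s.append(vc.h2[0])
            vps.append(vc.vp[0])
            assert vc.converged
        assert np.mean(h2s) == pytest.approx(0.33, abs=0.12)
        assert np.mean(vps) == pytest.approx(0.13, abs=0.02)

    def test_null_heritability_hits_boundary(self):
        rng = np.random.default_rng(1)
        n = 300
        rec, A = self._sim_records(n=n, seed=3)
        rec["phenotype"] = rng.normal(0, 1, n)  # pure noise
        vc = reml_estimate(rec, A, fixed_effects=("sex",))
        assert vc.h2[0] < 0.1

    def test_multi_trait_r_g_recovery(self):
        """Two traits generated from the same genetic values: r_g ~ 1."""
        rng = np.random.default_rng(5)
        rec, A = self._sim_records(n=360, seed=7)
        n = len(rec)
        u = np.linalg.cholesky(A + 1e-10 * np.eye(n)) @ rng.normal(0, np.sqrt(0.3), n)
        trait = rng.integers(0, 2, n)
        y = u + rng.normal(0, np.sqrt(0.5), n)
        rec = rec.assign(trait=trait, phenotype=y)
        vc = reml_estimate(rec, A, fixed_effects=("sex",), trait_col="trait",
                           n_traits=2)
        assert vc.r_g[0, 1] > 0.7
        assert vc.G0.shape == (2, 2)


class TestPedigreeBlup:
    def test_positive_information(self, toy_pop_sim1):
        """EBVs computed within a selected line correlate with true values."""
        pop = toy_pop_sim1
        ids = np.concatenate(
            [pop.ids(population="Line1", generation=g) for g in range(1, 6)]
        )
        ped = pm.truncate_generations(pop.pedigree, ids, 6)
        Ainv, labels = pm.a_inverse(ped)
        rows = ids - 1
        rec = pd.DataFrame(
            {"id": ids, "sex": pop.pedigree["sex"].to_numpy()[rows],
             "phenotype": pop.phenotype[rows]}
        )
        ebv = pedigree_blup_ebv(rec, labels, Ainv, 0.33 * 0.13, 0.67 * 0.13)
        r = np.corrcoef(ebv.loc[ids], pop.tbv[rows])[0, 1]
        assert r > 0.3

    def test_zero_heritability_gives_flat_ebvs(self):
        ped, A, Ainv, rec = toy_system(2)
        ebv = pedigree_blup_ebv(rec, ped["id"].to_numpy(), Ainv,
                                1e-12, 1.0, fixed_effects=("sex",))
        assert np.allclose(ebv.to_numpy(), 0.0, atol=1e-6)
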