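import numpy as np
import pandas as pd
import pytest

from crossblup.experiments import (
    SCENARIOS,
    ExperimentConfig,
    GridSpec,
    assemble_scenario,
    estimate_varcomp,
    evaluate_scenario,
    paired_comparison,
    qc_common_snps,
    run_experiment,
    significance_letters,
    tau_omega_grid,
    validate,
)
from crossblup.models import VarianceComponents
from crossblup.relationship import BlendParams
from crossblup.simulate import PopulationDesign


@pytest.fixture(scope="module")
def common5(toy_pop_sim5):
    return qc_common_snps(toy_pop_sim5)


def true_vc():
    return VarianceComponents(np.array([0.33 * 0.13]), np.array([0.67 * 0.13]))


class TestAssembleScenario:
    def test_sc1_training_membership(self, toy_pop_sim5, common5):
        pop = toy_pop_sim5
        d = pop.design
        data = assemble_scenario(pop, "SC1", common5)
        pops = set(data.records["population"])
        assert pops == {"Line1", "Line2", "F1"}
        gens1 = pop.pedigree.set_index("id").loc[
            data.records.loc[data.records["population"] == "Line1", "id"],
            "generation",
        ]
        assert set(gens1) == {d.line1_gens - 4, d.line1_gens - 3, d.line1_gens - 2}

    def test_purebred_only_keeps_validation_genotypes(self, toy_pop_sim5, common5):
        pop = toy_pop_sim5
        data = assemble_scenario(pop, "SC5", common5)
        assert set(data.records["population"]) == {"Line1", "Line2"}
        val_ids = np.concatenate(
            [pop.ids(population="F1-3"), pop.ids(population="F1-4")]
        )
        assert np.isin(val_ids, data.genotyped_ids).all()
        # training crossbreds are excluded entirely
        f1_train = np.concatenate(
            [pop.ids(population="F1-1"), pop.ids(population="F1-2")]
        )
        assert not np.isin(f1_train, data.genotyped_ids).any()

    def test_balanced_subsampling_matches_purebred_size(self, toy_pop_sim5, common5):
        pop = toy_pop_sim5
        full = assemble_scenario(pop, "SC1", common5)
        bal = assemble_scenario(pop, "SC1", common5, balanced=True)
        sc5 = assemble_scenario(pop, "SC5", common5)
        assert len(bal.records) == len(sc5.records) < len(full.records)

    def test_validation_phenotypes_never_read(self, toy_pop_sim5, common5):
        """Masking validation phenotypes changes nothing downstream."""
        pop = toy_pop_sim5
        res1, gebv1 = evaluate_scenario(
            pop, "SC1", common5, true_vc(), BlendParams(2.2, 0.5)
        )
        val = np.concatenate(
            [pop.ids(population="F1-3"), pop.ids(population="F1-4")]
        )
        saved = pop.phenotype.copy()
        try:
            pop.phenotype = pop.phenotype.copy()
            pop.phenotype[val - 1] = np.nan
            res2, gebv2 = evaluate_scenario(
                pop, "SC1", common5, true_vc(), BlendParams(2.2, 0.5)
            )
        finally:
            pop.phenotype = saved
        assert np.allclose(gebv1.to_numpy(), gebv2.to_numpy(), equal_nan=True)


class TestValidate:
    def test_perfect_prediction(self):
        t = np.array([0.1, -0.2, 0.3, 0.0, 0.5])
        acc, slope = validate(t, t)
        assert acc == pytest.approx(1.0)
        assert slope == pytest.approx(1.0)

    def test_doubled_gebvs_halve_slope(self):
        t = np.array([0.1, -0.2, 0.3, 0.0, 0.5])
        acc, slope = validate(2 * t, t)
        assert acc == pytest.approx(1.0)
        assert slope == pytest.approx(0.5)

    def test_hand_computed_toy(self):
        g = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        t = np.array([2.0, 1.0, 4.0, 3.0, 6.0, 5.0])
        acc, slope = validate(g, t)
        assert acc == pytest.approx(np.cov(g, t)[0, 1] / np.sqrt(np.var(g, ddof=1) * np.var(t, ddof=1)))
        assert slope == pytest.approx(np.cov(t, g)[0, 1] / np.var(g, ddof=1))

    def test_zero_variance_gebv_error(self):
        with pytest.raises(ValueError, match="variance"):
            validate(np.ones(5), np.arange(5.0))


class TestGrid:
    def test_grid_cardinality(self):
        g = GridSpec()
        assert len(g.tau_values) == 17
        assert len(g.omega_values) == 8
        assert g.n_combinations == 136

    def test_surface_and_reproducible_selection(self, toy_pop_sim5, common5):
        small = GridSpec(tau_values=(0.9, 1.5, 2.2), omega_values=(0.5, 0.9))
        s1, best1 = tau_omega_grid(toy_pop_sim5, common5, true_vc(), small)
        s2, best2 = tau_omega_grid(toy_pop_sim5, common5, true_vc(), small)
        assert len(s1) == 6
        assert best1 == best2
        pd.testing.assert_frame_equal(s1, s2)
        assert best1[0] in small.tau_values and best1[1] in small.omega_values


class TestPairedComparison:
    def _frame(self, vals_by_scenario):
        rows = []
        for sc, vals in vals_by_scenario.items():
            for r, v in enumerate(vals):
                rows.append(
                    {"sim": "SIM5", "cohort": "F1-3", "scenario": sc,
                     "replicate": r, "accuracy": v, "slope": 1.0}
                )
        return pd.DataFrame(rows)

    def test_identical_vectors_p_one(self):
        df = self._frame({"SC1": [0.4, 0.5, 0.6], "SC2": [0.4, 0.5, 0.6]})
        out = paired_comparison(df)
        assert out.loc[0, "p_value"] == pytest.approx(1.0)
        assert not out.loc[0, "degenerate"]

    def test_constant_shift_flagged_degenerate(self):
        df = self._frame({"SC1": [0.4, 0.5, 0.6], "SC2": [0.3, 0.4, 0.5]})
        out = paired_comparison(df)
        assert bool(out.loc[0, "degenerate"])

    def test_matches_textbook_formula(self):
        a = np.array([0.41, 0.45, 0.39, 0.50, 0.44])
        b = np.array([0.38, 0.46, 0.35, 0.47, 0.40])
        df = self._frame({"SC1": a, "SC2": b})
        out = paired_comparison(df)
        d = a - b
        t_expected = d.mean() / (d.std(ddof=1) / np.sqrt(len(d)))
        assert out.loc[0, "t"] == pytest.approx(t_expected)
        assert out.loc[0, "n_pairs"] == 5

    def test_unequal_replicates_rejected(self):
        df = self._frame({"SC1": [0.4, 0.5], "SC2": [0.4, 0.5]})
        df = df.drop(df[(df.scenario == "SC2") & (df.replicate == 1)].index)
        with pytest.raises(ValueError, match="pairing"):
            paired_comparison(df)

    def test_letters_share_group_when_not_significant(self):
        means = pd.Series({"SC1": 0.5, "SC2": 0.49, "SC3": 0.2})
        pvals = pd.DataFrame(
            [
                {"scenario_a": "SC1", "scenario_b": "SC2", "significant": False},
                {"scenario_a": "SC1", "scenario_b": "SC3", "significant": True},
                {"scenario_a": "SC2", "scenario_b": "SC3", "significant": True},
            ]
        )
        letters = significance_letters(means, pvals)
        assert letters["SC1"] == letters["SC2"]
        assert letters["SC3"] != letters["SC1"]


@pytest.fixture(scope="module")
def small_report():
    cfg = ExperimentConfig(
        sims=("SIM5",),
        scenarios=("SC1", "SC5"),
        n_replicates=2,
        base_seed=4,
        design=PopulationDesign.toy(),
        total_snps=200,
        reml_max_per_group=80,
    )
    return cfg, run_experiment(cfg)


class TestRunExperiment:
    def test_bookkeeping(self, small_report):
        cfg, rep = small_report
        res = rep["results"]
        assert not rep["failures"]
        assert set(res["scenario"]) == {"SC1", "SC5"}
        assert set(res["cohort"]) == {"F1-3", "F1-4"}
        assert len(res) == 2 * 2 * 2  # scenarios x replicates x cohorts
        assert "summary" in rep

    def test_determinism(self, small_report):
        cfg, rep = small_report
        rep2 = run_experiment(cfg)
        pd.testing.assert_frame_equal(
            rep["results"].reset_index(drop=True),
            rep2["results"].reset_index(drop=True),
        )

    def test_accuracy_is_meaningful(self, small_report):
        _, rep = small_report
        # with QTLs carrying all heritability, GEBVs track TBVs at toy scale
        assert rep["results"]["accuracy"].mean() > 0.2


class TestVarcompEstimation:
    def test_single_trait_reml_plausible(self, toy_pop_sim5, common5):
        vc = estimate_varcomp(toy_pop_sim5, SCENARIOS["SC1"], common5,
                              max_per_group=100)
        assert 0.02 <= vc.h2[0] <= 0.8
        assert vc.vp[0] == pytest.approx(0.13, rel=0.6)

    def test_multi_trait_reml_shapes(self, toy_pop_sim5, common5):
        vc = estimate_varcomp(toy_pop_sim5, SCENARIOS["SC2"], common5,
                              max_per_group=100)
        assert vc.G0.shape == (3, 3)
        assert np.all(np.diag(vc.R0) > 0)
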