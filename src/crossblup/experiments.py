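"""Training-design scenarios, tau/omega grid search and replicate runs.

Five scenarios are compared for predicting crossbred (F1) breeding values:

========  =====================  ==================  ===========
scenario  training phenotypes    SNP weights from    model
========  =====================  ==================  ===========
SC1       purebred + crossbred   (none, ssGBLUP)     single-trait
SC2       purebred + crossbred   (none, ssGBLUP)     multi-trait
SC3       purebred + crossbred   purebred+crossbred  single-trait
SC4       purebred               crossbred           single-trait
SC5       purebred               purebred            single-trait
========  =====================  ==================  ===========

Training purebreds are the three genotyped generations of each line
(generations 6-8 and 26-28 at the full design); training crossbreds are
F1-1 and F1-2.  F1-3 and F1-4 are validation cohorts in every scenario:
their genotypes stay in the system, their phenotypes are never used.
Accuracy is the Pearson correlation of GEBV with TBV; the dispersion slope
is the regression coefficient of TBV on GEBV (1 = unbiased).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats as st

from . import models, pedigree as pedmod, qc as qcmod
from .relationship import (
    BlendParams,
    a_inverse,
    allele_frequencies,
    build_G,
    blend_H_inverse,
    _spd_inverse,
)
from .simulate import (
    ConfigError,
    PopulationDesign,
    SimulatedPopulation,
    simulate_population,
)
from .genome import GenomeSpec, build_genome, trait_architecture
from .weights import backsolve_snp_effects, snp_weights

__all__ = [
    "ScenarioSpec",
    "SCENARIOS",
    "GridSpec",
    "ValidationResult",
    "ExperimentConfig",
    "assemble_scenario",
    "evaluate_scenario",
    "qc_common_snps",
    "estimate_varcomp",
    "significance_letters",
    "validate",
    "tau_omega_grid",
    "paired_comparison",
    "run_experiment",
]

DEFAULT_TAU = 2.2
DEFAULT_OMEGA = 0.5


@dataclass(frozen=True)
class ScenarioSpec:
    id: str
    training: str  # purebred+crossbred | purebred
    model: str  # single | multi
    method: str  # ssGBLUP | WssGBLUP
    weight_source: str  # none | pooled | crossbred | purebred

    @property
    def crossbred_in_training(self) -> bool:
        return self.training == "purebred+crossbred"


SCENARIOS: dict[str, ScenarioSpec] = {
    "SC1": ScenarioSpec("SC1", "purebred+crossbred", "single", "ssGBLUP", "none"),
    "SC2": ScenarioSpec("SC2", "purebred+crossbred", "multi", "ssGBLUP", "none"),
    "SC3": ScenarioSpec("SC3", "purebred+crossbred", "single", "WssGBLUP", "pooled"),
    "SC4": ScenarioSpec("SC4", "purebred", "single", "WssGBLUP", "crossbred"),
    "SC5": ScenarioSpec("SC5", "purebred", "single", "WssGBLUP", "purebred"),
}


@dataclass(frozen=True)
class GridSpec:
    """tau 0.9-2.5 and omega 0.5-1.2, both at steps of 0.1 (17 x 8)."""

    tau_values: tuple = tuple(np.round(np.arange(0.9, 2.55, 0.1), 1))
    omega_values: tuple = tuple(np.round(np.arange(0.5, 1.25, 0.1), 1))

    @property
    def n_combinations(self) -> int:
        return len(self.tau_values) * len(self.omega_values)


@dataclass
class ValidationResult:
    replicate: int
    scenario: str
    sim: str
    cohort: str
    accuracy: float
    slope: float
    n_validated: int


def _trait_index(population: str) -> int:
    if population == "Line1":
        return 0
    if population == "Line2":
        return 1
    if population.startswith("F1"):
        return 2
    raise ValueError(f"population {population!r} has no trait mapping")


@dataclass
class ScenarioData:
    scenario: ScenarioSpec
    records: pd.DataFrame  # training phenotypes only
    pedigree: pd.DataFrame  # truncated, topologically ordered
    ped_labels: np.ndarray
    genotyped_ids: np.ndarray
    genotyped_index: np.ndarray  # rows of genotyped animals in ped order
    dosages: np.ndarray  # genotyped x common-QC SNPs
    groups: dict[str, np.ndarray]  # population group -> ids
    validation: dict[str, pd.DataFrame]  # cohort -> (id, tbv)
    allele_freqs: np.ndarray  # per scenario's frequency source
    freq_source: str


def _training_generations(design: PopulationDesign) -> tuple[list[int], list[int]]:
    g1 = [design.line1_gens - 4 + k for k in range(0, 3)]
    g2 = [design.line2_gens - 4 + k for k in range(0, 3)]
    return g1, g2


def assemble_scenario(
    pop: SimulatedPopulation,
    scenario: ScenarioSpec | str,
    common_snps: np.ndarray,
    pedigree_depth: int = 5,
    balanced: bool = False,
    rng: np.random.Generator | None = None,
) -> ScenarioData:
    """Split a simulated population into the scenario's training/validation
    structure (phenotype sets per the design table; validation crossbred
    genotypes retained in every scenario)."""
    if isinstance(scenario, str):
        scenario = SCENARIOS[scenario]
    d = pop.design
    g1, g2 = _training_generations(d)
    line1 = pop.ids(population="Line1", generation=g1)
    line2 = pop.ids(population="Line2", generation=g2)
    f1_train = np.concatenate([pop.ids(population="F1-1"), pop.ids(population="F1-2")])
    f1_val = {c: pop.ids(population=c) for c in ("F1-3", "F1-4")}
    for name, ids in (("Line1", line1), ("Line2", line2), ("F1 training", f1_train)):
        if len(ids) == 0:
            raise ConfigError(f"cohort {name} missing from population")

    train_ids = [line1, line2]
    groups = {"Line1": line1, "Line2": line2}
    if scenario.crossbred_in_training:
        train_ids.append(f1_train)
        groups["F1_train"] = f1_train
    training = np.concatenate(train_ids)
    if balanced:
        # subsample to the purebred-only training size (design-balance check)
        target = len(line1) + len(line2)
        if len(training) > target:
            rng = rng or np.random.default_rng(0)
            training = np.sort(rng.choice(training, target, replace=False))
    groups["F1_val"] = np.concatenate(list(f1_val.values()))
    genotyped = np.concatenate(
        [line1, line2]
        + ([f1_train] if scenario.crossbred_in_training else [])
        + [groups["F1_val"]]
    )

    anchors = np.unique(np.concatenate([training, genotyped]))
    ped = pedmod.truncate_generations(pop.pedigree, anchors, pedigree_depth)
    ped_labels = ped["id"].to_numpy()
    pos = {int(v): k for k, v in enumerate(ped_labels)}
    gidx = np.array([pos[int(i)] for i in genotyped])

    rows = training - 1
    records = pd.DataFrame(
        {
            "id": training,
            "sex": pop.pedigree["sex"].to_numpy()[rows],
            "population": [
                "F1" if p.startswith("F1") else p
                for p in pop.pedigree["population"].to_numpy()[rows]
            ],
            "trait": [
                _trait_index(p) for p in pop.pedigree["population"].to_numpy()[rows]
            ],
            "phenotype": pop.phenotype[rows],
        }
    )
    validation = {
        c: pd.DataFrame({"id": ids, "tbv": pop.tbv[ids - 1]})
        for c, ids in f1_val.items()
    }

    dos = pop.dosages(genotyped)[:, common_snps]
    is_f1 = np.array([str(pop.pedigree["population"].iloc[i - 1]).startswith("F1") for i in genotyped])
    if scenario.weight_source == "crossbred" or scenario.id == "SC4":
        p = allele_frequencies(dos[is_f1])
        src = "crossbred"
    elif scenario.weight_source == "purebred" or scenario.id == "SC5":
        p = allele_frequencies(dos[~is_f1])
        src = "purebred"
    else:
        p = allele_frequencies(dos)
        src = "pooled"
    return ScenarioData(
        scenario=scenario,
        records=records,
        pedigree=ped,
        ped_labels=ped_labels,
        genotyped_ids=genotyped,
        genotyped_index=gidx,
        dosages=dos,
        groups=groups,
        validation=validation,
        allele_freqs=p,
        freq_source=src,
    )


def validate(gebv: np.ndarray, tbv: np.ndarray) -> tuple[float, float]:
    """(accuracy, dispersion slope) of GEBVs against TBVs.

    accuracy = Pearson(GEBV, TBV); slope = cov(TBV, GEBV) / var(GEBV) from
    the regression of TBV on GEBV.
    """
    g = np.asarray(gebv, dtype=float)
    t = np.asarray(tbv, dtype=float)
    if len(g) != len(t) or len(g) < 3:
        raise ValueError("need aligned vectors of length >= 3")
    vg = np.var(g, ddof=1)
    if vg <= 0:
        raise ValueError("GEBV variance is zero; slope undefined")
    acc = float(np.corrcoef(g, t)[0, 1])
    slope = float(np.cov(t, g, ddof=1)[0, 1] / vg)
    return acc, slope


def _solve(
    data: ScenarioData,
    Hinv: np.ndarray,
    varcomp: models.VarianceComponents,
) -> pd.Series:
    """Solve the scenario's MME; returns the GEBV used for F1 validation."""
    if data.scenario.model == "multi":
        sol = models.solve_multi_trait(
            data.records, data.ped_labels, Hinv, varcomp, fixed_effects=("sex",)
        )
        return sol.gebv["F1"]
    sol = models.solve_single_trait(
        data.records,
        data.ped_labels,
        Hinv,
        varcomp,
        fixed_effects=("sex", "population"),
    )
    return sol.gebv


def _weight_source_ids(data: ScenarioData) -> np.ndarray:
    src = data.scenario.weight_source
    is_f1 = np.isin(
        data.genotyped_ids,
        np.concatenate(
            [data.groups.get("F1_train", np.zeros(0, int)), data.groups["F1_val"]]
        ),
    )
    if src == "pooled":
        return np.arange(len(data.genotyped_ids))
    if src == "crossbred":
        return np.flatnonzero(is_f1)
    if src == "purebred":
        return np.flatnonzero(~is_f1)
    raise ValueError(f"scenario {data.scenario.id} has no weight source")


def evaluate_scenario(
    pop: SimulatedPopulation,
    scenario: ScenarioSpec | str,
    common_snps: np.ndarray,
    varcomp: models.VarianceComponents,
    blend: BlendParams | None = None,
    n_iterations: int = 2,
    balanced: bool = False,
    replicate: int = 0,
) -> tuple[list[ValidationResult], pd.Series]:
    """Run one scenario on one simulated replicate.

    WssGBLUP scenarios run the two-iteration schedule: identity weights,
    then weights from the back-solved SNP effects of the scenario's
    weight-source animals.
    """
    if isinstance(scenario, str):
        scenario = SCENARIOS[scenario]
    blend = blend or BlendParams(tau=DEFAULT_TAU, omega=DEFAULT_OMEGA)
    data = assemble_scenario(pop, scenario, common_snps, balanced=balanced)
    Ainv, labels = a_inverse(data.pedigree)
    assert np.array_equal(labels, data.ped_labels)
    A22 = pedmod.a_submatrix(data.pedigree, data.genotyped_ids).to_numpy()

    w = None
    n_iter = n_iterations if scenario.method == "WssGBLUP" else 1
    gebv = None
    for it in range(1, n_iter + 1):
        G = build_G(
            data.dosages,
            data.allele_freqs,
            weights=w,
            labels=data.genotyped_ids,
            freq_source=data.freq_source,
        )
        Hinv = blend_H_inverse(Ainv, A22, G, blend, data.genotyped_index)
        gebv = _solve(data, Hinv.values, varcomp)
        if it < n_iter:
            srci = _weight_source_ids(data)
            gebv_src = gebv.loc[data.genotyped_ids[srci]].to_numpy()
            w = _iterate_weights(
                data.dosages[srci],
                gebv_src,
                A22[np.ix_(srci, srci)],
                current_weights=w,
                source=data.scenario.weight_source,
                iteration=it + 1,
                blend=blend,
            )
    results = []
    for cohort, vdf in data.validation.items():
        acc, slope = validate(gebv.loc[vdf["id"]].to_numpy(), vdf["tbv"].to_numpy())
        results.append(
            ValidationResult(
                replicate=replicate,
                scenario=scenario.id,
                sim=pop.trait.name,
                cohort=cohort,
                accuracy=acc,
                slope=slope,
                n_validated=len(vdf),
            )
        )
    return results, gebv


def _iterate_weights(
    dos_src: np.ndarray,
    gebv_src: np.ndarray,
    A22_src: np.ndarray,
    current_weights: np.ndarray | None,
    source: str,
    iteration: int,
    blend: BlendParams,
) -> np.ndarray:
    """Back-solve SNP effects from the weight-source animals and return the
    normalised variance weights for the next G.

    The source-population G uses the current weights and source allele
    frequencies; when it is singular (more source animals than markers) the
    standard 0.95/0.05 blend with the source A22 is applied before
    inversion.
    """
    import warnings

    p_src = allele_frequencies(dos_src)
    Z_src = dos_src - 2.0 * p_src
    het = p_src * (1.0 - p_src)
    k_src = 2.0 * float(het.sum())
    D = current_weights if current_weights is not None else np.ones(Z_src.shape[1])
    G_src = (Z_src * D) @ Z_src.T / k_src
    try:
        u = backsolve_snp_effects(gebv_src, G_src, Z_src, weights=D, k=k_src)
    except np.linalg.LinAlgError:
        G_b = blend.g_share * G_src + blend.a_share * A22_src
        u = backsolve_snp_effects(gebv_src, G_b, Z_src, weights=D, k=k_src)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # loci fixed within the source subset
        wset = snp_weights(u, p_src, source_population=source, iteration=iteration)
    return wset.weights


def tau_omega_grid(
    pop: SimulatedPopulation,
    common_snps: np.ndarray,
    varcomp: models.VarianceComponents,
    grid: GridSpec | None = None,
    cohorts: tuple[str, ...] = ("F1-3", "F1-4"),
) -> tuple[pd.DataFrame, tuple[float, float]]:
    """Accuracy/slope surface over the tau-omega grid, evaluated on SC1.

    The blended-G inverse and A22 inverse are fixed across the grid, so
    each combination only reassembles the genotyped-block correction.  The
    selected combination minimises |1 - slope| (mean over the validation
    cohorts), breaking ties by higher accuracy, then lower tau, then lower
    omega.
    """
    grid = grid or GridSpec()
    data = assemble_scenario(pop, "SC1", common_snps)
    Ainv, labels = a_inverse(data.pedigree)
    A22 = pedmod.a_submatrix(data.pedigree, data.genotyped_ids).to_numpy()
    G = build_G(
        data.dosages, data.allele_freqs, labels=data.genotyped_ids,
        freq_source=data.freq_source,
    )
    Gb = 0.95 * G.values + 0.05 * A22
    Gb_inv = _spd_inverse(Gb, "blended G")
    A22_inv = _spd_inverse(A22, "A22")
    base = np.asarray(Ainv.todense(), dtype=float)
    gi = data.genotyped_index
    rows = []
    for tau in grid.tau_values:
        for omega in grid.omega_values:
            H = base.copy()
            H[np.ix_(gi, gi)] += tau * Gb_inv - omega * A22_inv
            try:
                gebv = _solve(data, H, varcomp)
            except Exception:
                rows.append(
                    {"tau": tau, "omega": omega, "accuracy": np.nan, "slope": np.nan}
                )
                continue
            accs, slopes = [], []
            for c in cohorts:
                vdf = data.validation[c]
                a, s = validate(gebv.loc[vdf["id"]].to_numpy(), vdf["tbv"].to_numpy())
                accs.append(a)
                slopes.append(s)
            rows.append(
                {
                    "tau": tau,
                    "omega": omega,
                    "accuracy": float(np.mean(accs)),
                    "slope": float(np.mean(slopes)),
                }
            )
    surface = pd.DataFrame(rows)
    ok = surface.dropna(subset=["slope"])
    if ok.empty:
        raise RuntimeError("no tau/omega combination could be solved")
    key = ok.assign(bias=(1.0 - ok["slope"]).abs())
    key = key.sort_values(
        ["bias", "accuracy", "tau", "omega"],
        ascending=[True, False, True, True],
        kind="stable",
    )
    best = key.iloc[0]
    return surface, (float(best["tau"]), float(best["omega"]))


def paired_comparison(
    results: pd.DataFrame,
    metric: str = "accuracy",
    by: tuple[str, ...] = ("sim", "cohort"),
) -> pd.DataFrame:
    """Paired t-tests between scenarios over shared replicates.

    Replicates are paired by simulation seed (same replicate index).  Zero
    variance of the paired differences is reported as p = 1 when the
    difference is identically zero and flagged degenerate otherwise.
    """
    out = []
    for keys, sub in results.groupby(list(by)):
        wide = sub.pivot_table(
            index="replicate", columns="scenario", values=metric
        )
        scens = list(wide.columns)
        for i, a in enumerate(scens):
            for b in scens[i + 1 :]:
                pair = wide[[a, b]].dropna()
                if len(pair) != len(wide):
                    raise ValueError(
                        f"unequal replicate sets for {a} vs {b}; pairing broken"
                    )
                diff = pair[a] - pair[b]
                if np.allclose(diff.std(ddof=1), 0.0):
                    degenerate = not np.allclose(diff.mean(), 0.0)
                    t_stat, p = (0.0, 1.0) if not degenerate else (np.inf, np.nan)
                else:
                    t_stat, p = st.ttest_rel(pair[a], pair[b])
                    degenerate = False
                row = dict(zip(by, keys if isinstance(keys, tuple) else (keys,)))
                row.update(
                    {
                        "scenario_a": a,
                        "scenario_b": b,
                        "metric": metric,
                        "t": float(t_stat),
                        "p_value": float(p) if np.isfinite(p) else np.nan,
                        "significant": bool(np.isfinite(p) and p < 0.05),
                        "degenerate": degenerate,
                        "n_pairs": len(pair),
                    }
                )
                out.append(row)
    return pd.DataFrame(out)


def significance_letters(
    means: pd.Series, pvals: pd.DataFrame
) -> dict[str, str]:
    """Compact letter display: scenarios not significantly different share a
    letter (greedy grouping in decreasing-mean order)."""
    order = means.sort_values(ascending=False).index.tolist()
    sig = {
        frozenset((r["scenario_a"], r["scenario_b"])): r["significant"]
        for _, r in pvals.iterrows()
    }
    groups: list[list[str]] = []
    for s in order:
        placed = False
        for g in groups:
            if all(not sig.get(frozenset((s, t)), False) for t in g):
                g.append(s)
                placed = True
        if not placed:
            groups.append([s])
    letters = {s: "" for s in order}
    for gi, g in enumerate(groups):
        for s in g:
            letters[s] += chr(ord("a") + gi)
    return letters


@dataclass
class ExperimentConfig:
    """Replicated simulation + evaluation study configuration."""

    sims: tuple[str, ...] = ("SIM1", "SIM5")
    scenarios: tuple[str, ...] = ("SC1", "SC2", "SC3", "SC4", "SC5")
    n_replicates: int = 3
    base_seed: int = 1
    design: PopulationDesign = field(default_factory=PopulationDesign.toy)
    n_chromosomes: int = 1
    genome_length_cM: float = 25.0
    total_snps: int = 500
    tau: float = DEFAULT_TAU
    omega: float = DEFAULT_OMEGA
    maf_min: float = qcmod.MAF_MIN
    hwe_dev_max: float = qcmod.HWE_DEV_MAX
    reml_max_per_group: int = 300
    pedigree_depth: int = 5
    balanced: bool = False

    def genome(self) -> GenomeSpec:
        return build_genome(
            self.n_chromosomes, self.genome_length_cM, self.total_snps
        )

    def seed_for(self, sim: str, replicate: int) -> int:
        sim_idx = int(sim[-1]) if sim[-1].isdigit() else 0
        return (int(self.base_seed) * 1009 + 131 * sim_idx + replicate) % (2**31 - 1)


def qc_common_snps(
    pop: SimulatedPopulation,
    maf_min: float = qcmod.MAF_MIN,
    hwe_dev_max: float = qcmod.HWE_DEV_MAX,
) -> np.ndarray:
    """Per-population QC (Line1, Line2, pooled F1) and intersection."""
    g1, g2 = _training_generations(pop.design)
    pops = {
        "Line1": pop.dosages(pop.ids(population="Line1", generation=g1)),
        "Line2": pop.dosages(pop.ids(population="Line2", generation=g2)),
        "F1": pop.dosages(
            np.concatenate(
                [
                    pop.ids(population=f"F1-{k}")
                    for k in range(1, pop.design.n_f1_cohorts + 1)
                ]
            )
        ),
    }
    _, common = qcmod.run_qc(pops, maf_min, hwe_dev_max)
    return common


def estimate_varcomp(
    pop: SimulatedPopulation,
    scenario: ScenarioSpec,
    common_snps: np.ndarray,
    max_per_group: int = 300,
    rng: np.random.Generator | None = None,
) -> models.VarianceComponents:
    """Scenario-specific REML on (a subsample of) the training records,
    using the pedigree relationship matrix."""
    rng = rng or np.random.default_rng(pop.seed + 7)
    data = assemble_scenario(pop, scenario, common_snps)
    rec = data.records
    # choose the crossbred subsample first, then prioritise its purebred
    # parents: cross-population genetic covariances are identified through
    # exactly those parent-offspring links
    f1_sub = rec.index[rec["population"] == "F1"].to_numpy()
    if len(f1_sub) > max_per_group:
        f1_sub = np.sort(rng.choice(f1_sub, max_per_group, replace=False))
    parents = set()
    if len(f1_sub):
        ped = pop.pedigree.set_index("id")
        pp = ped.loc[rec.loc[f1_sub, "id"], ["sire", "dam"]].to_numpy().ravel()
        parents = set(int(p) for p in pp if p > 0)
    keep = [f1_sub]
    for name, sub in rec.groupby("population"):
        if name == "F1":
            continue
        idx = sub.index.to_numpy()
        if len(idx) > max_per_group:
            is_par = sub["id"].isin(parents).to_numpy()
            first = idx[is_par][:max_per_group]
            rest = idx[~is_par]
            n_fill = max_per_group - len(first)
            fill = rng.choice(rest, n_fill, replace=False) if n_fill > 0 else []
            idx = np.sort(np.concatenate([first, fill]).astype(int))
        keep.append(idx)
    rec = rec.loc[np.sort(np.concatenate(keep))].reset_index(drop=True)
    # relationships from the same 5-generation pedigree the evaluations use
    A_rr = pedmod.a_submatrix(data.pedigree, rec["id"].to_numpy()).to_numpy()
    if scenario.model == "multi":
        return models.reml_estimate(
            rec, A_rr, fixed_effects=("sex",), trait_col="trait", n_traits=3
        )
    return models.reml_estimate(rec, A_rr, fixed_effects=("sex", "population"))


def run_experiment(config: ExperimentConfig) -> dict:
    """Replicated pipeline: simulate -> QC -> REML -> evaluate scenarios.

    Returns a report dict with per-replicate validation results, aggregated
    means/SDs, paired-comparison tables and the seeds used.  A failed
    replicate is recorded and excluded from aggregation.
    """
    genome = config.genome()
    rows: list[ValidationResult] = []
    failures = []
    seeds = {}
    for sim in config.sims:
        trait = trait_architecture(sim, genome)
        for rep in range(config.n_replicates):
            seed = config.seed_for(sim, rep)
            seeds[(sim, rep)] = seed
            try:
                pop = simulate_population(genome, trait, config.design, seed)
                common = qc_common_snps(pop, config.maf_min, config.hwe_dev_max)
                blend = BlendParams(tau=config.tau, omega=config.omega)
                for sc in config.scenarios:
                    spec = SCENARIOS[sc]
                    vc = estimate_varcomp(
                        pop, spec, common, config.reml_max_per_group
                    )
                    res, _ = evaluate_scenario(
                        pop, spec, common, vc, blend,
                        balanced=config.balanced, replicate=rep,
                    )
                    rows.extend(res)
            except (ConfigError, RuntimeError, np.linalg.LinAlgError) as e:
                failures.append({"sim": sim, "replicate": rep, "error": str(e)})
    results = pd.DataFrame([r.__dict__ for r in rows])
    report = {"results": results, "failures": failures, "seeds": seeds}
    if not results.empty:
        report["summary"] = (
            results.groupby(["sim", "scenario", "cohort"])[["accuracy", "slope"]]
            .agg(["mean", "std", "count"])
        )
        if results["replicate"].nunique() > 1 and results["scenario"].nunique() > 1:
            report["paired_accuracy"] = paired_comparison(results, "accuracy")
            report["paired_slope"] = paired_comparison(results, "slope")
    return report
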