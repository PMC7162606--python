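# crossblup

Genomic evaluation of crossbred animals with single-step GBLUP, on fully
simulated two-line cattle systems.

In many beef and pig production systems, selection happens in purebred
nucleus lines while profit is made on their crossbred (F1) offspring, so
the question that matters is: *which training-population design and which
single-step method best predict crossbred breeding values?* Answering it
on real data is hard because true breeding values (TBVs) are unknown.
`crossblup` therefore provides both halves of the experiment:

- a forward-in-time breeding simulator for a Zebu-like line (Line1), a
  Taurine-like line (Line2) and four F1 cohorts, with a long drift history,
  two bottlenecks, BLUP truncation selection within lines, a 50K-density
  SNP panel and five trait architectures (0 / 198 / 4,500 QTLs explaining
  h²_QTL ∈ {0, 0.11, 0.33} of a trait with h² = 0.33, Vp = 0.13);
- the evaluation stack: pedigree **A**, VanRaden's genomic **G**, the
  hybrid **H**, single- and three-trait mixed-model solvers, REML variance
  components, SNP-variance weighting (WssGBLUP), genotype QC, and
  population-connectedness diagnostics (PCA of **G**, LD, consistency of
  gametic phase, allele-frequency correlations).

## The model

Single-step evaluation replaces A⁻¹ in the mixed-model equations with

    H⁻¹ = A⁻¹ + [ 0                                   0
                  0   τ(0.95·G + 0.05·A₂₂)⁻¹ − ω·A₂₂⁻¹ ]

where A₂₂ is the pedigree relationship among genotyped animals,
G = Z D Z′ / k with Z = M − P the centred 0/1/2 dosages,
k = 2Σ pⱼ(1−pⱼ), and τ, ω are compatibility scaling factors (grid-searched
over 0.9–2.5 × 0.5–1.2; default 2.2 / 0.5). Plain ssGBLUP takes D = I;
weighted ssGBLUP back-solves SNP effects û = λ D Z′ G⁻¹ GEBV from a
designated weight-source population, sets dⱼ = ûⱼ²·2pⱼ(1−pⱼ) (normalised to
mean 1) and re-solves once. The animal model is y = Xb + Zu + e with fixed
mean, sex and population, u ~ N(0, σ²ᵤH); the three-trait variant treats
Line1, Line2 and F1 records as separate traits, u ~ N(0, G₀ ⊗ H).

Five training scenarios are compared: SC1 (ssGBLUP, purebred + crossbred
training), SC2 (ssGBLUP, three-trait model), SC3–SC5 (WssGBLUP with weights
from pooled / crossbred / purebred animals, the latter two training on
purebreds only). F1-3 and F1-4 are validation cohorts everywhere: accuracy
is Pearson(GEBV, TBV) and dispersion the slope of TBV on GEBV.

## Worked example

Simulate a toy population (minutes-free profile), run two scenarios and
compare them:

```bash
crossblup evaluate --scenario SC1 --sim SIM5 --seed 7 --profile toy \
    --chromosomes 1 --length-cm 25 --snps 300 --out out_sc1
crossblup evaluate --scenario SC5 --sim SIM5 --seed 7 --profile toy \
    --chromosomes 1 --length-cm 25 --snps 300 --out out_sc5
```

prints

```
SC1 SIM5 F1-3: accuracy=0.687 slope=1.908 (n=12)
SC1 SIM5 F1-4: accuracy=0.914 slope=2.260 (n=12)
SC5 SIM5 F1-3: accuracy=0.788 slope=2.080 (n=12)
SC5 SIM5 F1-4: accuracy=0.949 slope=2.261 (n=12)
```

Each line is one validation cohort: `accuracy` is the correlation between
the 12 validation animals' GEBVs and their true breeding values;
`slope` > 1 means their GEBVs are under-dispersed (the toy population has
only a dozen validation animals and a few hundred markers, so both numbers
are very noisy — they illustrate the interface, not the science). The same
commands with `--profile scaled --scale 0.05` run the desk-scale study
profile, and `crossblup run --config cfg.yaml` runs replicated
sim × scenario grids; `simulate`, `qc`, `grid` and `report` cover the other
stages. Everything is also available as a library:

```python
from crossblup import build_genome, trait_architecture, PopulationDesign
from crossblup import simulate_population
from crossblup.experiments import SCENARIOS, qc_common_snps, estimate_varcomp, evaluate_scenario

genome = build_genome(29, 2696.54, 52886)        # full bovine-like map
pop = simulate_population(build_genome(1, 25.0, 500),
                          trait_architecture("SIM5", build_genome(1, 25.0, 500)),
                          PopulationDesign.scaled(0.05), seed=1)
common = qc_common_snps(pop)
vc = estimate_varcomp(pop, SCENARIOS["SC1"], common)
results, gebv = evaluate_scenario(pop, "SC1", common, vc)
```

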