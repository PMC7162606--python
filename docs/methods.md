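# Methods

`crossblup` couples a forward-in-time breeding simulator for a
two-purebred-line + F1 beef-cattle system with a single-step genomic
evaluation stack (ssGBLUP and weighted ssGBLUP), so that training-population
designs for crossbred genomic prediction can be compared against known true
breeding values.

## Simulated population

**Historical phase.** All loci (markers and QTLs) start at allele frequency
exactly 0.50. A random-mating population of 2,000 (1,000 per sex) runs for
1,000 non-overlapping generations, then shrinks to 1,500 for 20 generations
(first bottleneck). Linkage disequilibrium accumulates purely by drift,
recombination and recurrent mutation. From the final generation, 100 males
and 100 females are sampled (second bottleneck) as founders.

**Expansion (POP).** Founders expand under random selection and mating for
8 generations, each female leaving a litter of five (sexes balanced within
the cohort), culled at random to the target census (64,000 at full scale).

**Lines.** Line1 (Zebu-like) is bred for 10 generations from 32,000 dams x
640 sires; Line2 (Taurine-like) for 30 generations from 3,200 dams x 64
sires; each dam leaves one offspring per generation. Every generation,
pedigree-BLUP EBVs are computed within the line at the true variance
components; the lowest-EBV offspring of each sex replace 60% of sires and
20% of dams, and the highest-EBV current parents are culled (downward
selection, as for residual feed intake).

**F1 cohorts.** Four cohorts cross 3,000 Line1 dams with 60 Line2 sires,
taking parents from successive generation pairs (7,27) ... (10,30). Dams are
drawn without replacement, sires with replacement across dams.

**Meiosis and mutation.** Crossovers per chromosome are Poisson with mean
length/100 cM, positions uniform, no interference; chromosome-start strand
choice is fair. Mutation flips the transmitted allele at 1e-5 per locus and
generation (recurrent, biallelic; no new loci).

**Trait.** h2 = 0.33 and Vp = 0.13 (a residual-feed-intake-like trait).
Five architectures: SIM1 (no QTLs, fully polygenic), SIM2/SIM3 (198/4,500
QTLs explaining h2_QTL = 0.11), SIM4/SIM5 (198/4,500 QTLs explaining the
whole h2 = 0.33). QTL effects are gamma(0.40) with random sign, rescaled so
the founder-cohort QTL-value variance equals exactly h2_QTL * Vp. The
remaining heritability is an infinitesimal polygenic term: founders ~
N(0, (h2 - h2_QTL) Vp); offspring receive the parent average plus a
Mendelian deviation N(0, 0.5 sigma2_poly (1 - mean parental F)). Phenotype =
mu + sex effect + TBV + e with e ~ N(0, (1 - h2) Vp); the simulated sex
effect defaults to 0 (the evaluation models still fit one).

## Genome

29 autosomes totalling ~2,696.54 cM carry 52,886 evenly spaced biallelic
SNPs (50K-chip density); per-chromosome counts are proportional to a bundled
relative-length table for the bovine autosomes (largest-remainder rounding).
SNPs sit at interval midpoints, so adjacent spacing is exactly L/m
(~0.051 cM genome-wide). QTLs are placed uniformly on the same map but are
never part of the genotyping panel. Physical distance uses 1 cM = 1 Mb.

## Genotype quality control

Per population (Line1, Line2, pooled F1): keep a SNP iff MAF > 0.05
(strict) and |observed - expected heterozygote frequency| < 0.15 (strict);
then keep only SNPs passing in every population. Both filters are per-SNP
predicates, so the QC is idempotent and order-free.

## Evaluation stack

**Relationships.** A by the tabular recursion (dense) or Henderson's sparse
A-inverse with Mendelian-sampling variances from inbreeding (Meuwissen-Luo);
large-pedigree submatrices of A via the gene-flow identity A = T D T'
(triangular substitutions, no fill-in). G follows VanRaden:
G = Z D Z'/k, Z = M - 2p, k = 2 sum p_j(1-p_j), with an explicit
allele-frequency source (pooled training genotypes by default; crossbred or
purebred frequencies for the scenarios that call for them). H-inverse adds
the genotyped-block correction tau*(0.95 G + 0.05 A22)^-1 - omega*A22^-1 to
the sparse A-inverse; blending precedes inversion; tau and omega are
restricted to the grid bounds 0.9-2.5 and 0.5-1.2.

**Mixed models.** Single-trait animal model y = Xb + Zu + e with fixed
mean, sex and population (drop-first identifiability constraint) and
u ~ N(0, sigma2_u H). The three-trait model treats Line1, Line2 and F1
records as separate traits, u3 ~ N(0, G0 (x) H), diagonal residual
covariance (traits are measured on different animals). Sparse (pedigree)
systems are solved by Jacobi-preconditioned conjugate gradients — the MME
is SPD, and sparse LU factorisations of random-mating pedigree graphs
suffer catastrophic fill-in — to a relative residual below 1e-8; dense
(H-based) systems by Cholesky. Validation animals' phenotypes are never
entered; they receive GEBVs through relationships only.

**REML.** Variance components are estimated per scenario from the training
records and the pedigree relationship matrix (5-generation pedigree, as in
the evaluations), by maximising the restricted log-likelihood of the
marginal phenotype covariance V(theta) over recorded animals — the same
objective the MME-based AI-REML programs maximise, tractable dense at the
record counts used here. Because the selected-line data place the true
genetic correlations at or near the |r_g| = 1 PSD boundary, where naive
average-information updates stall, the likelihood is maximised by L-BFGS
over a boundary-free parameterisation (Cholesky factor of G0, log residual
variances) with the analytic score supplied via the chain rule; the
average-information matrix is evaluated at the optimum for approximate
standard errors (delta method for h2 and r_g). Variance components within
1e-4 of zero are flagged as boundary estimates. Records are subsampled per
population (default 300) with the crossbred animals' purebred parents
prioritised, since the cross-population covariances are identified through
exactly those parent-offspring links.

**WssGBLUP.** Two iterations: plain ssGBLUP (D = I), then SNP effects
back-solved from the weight-source animals' GEBVs as
u_hat = (1/k) D Z' G^-1 GEBV (so Z u_hat reproduces the genomic GEBVs when
G is nonsingular; the 0.95/0.05 blend with the source A22 is applied only
when G is singular), weights d_j = u_j^2 * 2 p_j (1 - p_j) normalised to
mean one (keeps the genetic-variance scale stable across iterations), and a
re-solve with the weighted G. No weight ceiling is applied. Weight sources:
all genotyped animals (SC3), genotyped crossbreds (SC4, which also uses
crossbred allele frequencies in P and k), genotyped purebreds (SC5).

**Scenarios and validation.** SC1-SC3 train on Line1 generations 6-8,
Line2 generations 26-28 and F1-1/F1-2; SC4-SC5 on the purebreds only
(training crossbreds then leave the genotype set too). F1-3 and F1-4 are
validation cohorts everywhere: their genotypes stay in H, their phenotypes
are never read. Accuracy is the Pearson correlation of GEBV with TBV;
dispersion is the slope of TBV regressed on GEBV (1 = unbiased). The
tau/omega grid (17 x 8 = 136 combinations) is evaluated on SC1 only; the
selected pair minimises |1 - slope| averaged over both validation cohorts,
breaking ties by higher accuracy, then lower tau, then lower omega (the
default used elsewhere is tau = 2.2, omega = 0.5). Scenario comparisons
are paired t-tests over replicates sharing simulation seeds; identical
vectors report p = 1, a constant nonzero shift is flagged degenerate.

## Connectedness diagnostics

Signed r between two loci is D/sqrt(f(A)f(a)f(B)f(b)) with
D = f(AB) - f(A)f(B) from true phased haplotypes; r2 is its square.
Adjacent-SNP LD averages r2 over consecutive polymorphic pairs within
0.05 cM. Consistency of gametic phase is the per-bin Pearson correlation of
signed r between two populations (60 kb bins to 1 Mb; bins with fewer than
3 usable pairs report NaN). Two reporting conventions deliberately mirror
per-population GWAS-toolkit workflows and are applied in the pipeline (the
core functions keep plain allele-label semantics):

- *Per-population minor-allele coding* before signed-r and
  allele-frequency comparisons: each population's counted allele is its own
  minor allele, so where the minor allele differs between populations the
  signed r flips sign. Consistently labelled alleles would give a
  Line1-Line2 phase correlation of ~0.8 after only 10/30 generations of
  divergence; the folded coding is what produces the low reported values,
  and likewise the moderate (rather than ~0.8) between-line
  allele-frequency correlations.
- *Leading-component variance shares*: toolkits extract a fixed number of
  principal components (ten by default) and quote PC1's share of the
  extracted set, not of the full trace; `pca_leading_share` reproduces
  that. `pca_of_G` itself returns the complete eigendecomposition with
  fractions of the full trace.

## The scaled replication profile

The full experiment (64,000-animal expansion, ~36,000 line animals per
replicate, 52,886 SNPs, ten replicates) is a cluster-scale computation. The
package's scaled profile, used by the test-suite end-to-end checks and the
acceptance script, is chosen once as follows:

- **Genome:** one 25 cM chromosome with 500 SNPs — the full design's
  0.05 cM adjacent spacing, which (with historical Ne) is what adjacent-pair
  LD depends on.
- **History at full size** (2,000 -> 1,500 -> 200 founders): baseline LD
  depends on historical Ne, not on downstream census.
- **Census at 5%** for dams, POP and F1 cohort sizes.
- **Sire counts are not multiplied by 5%.** Line drift and divergence are
  governed by realized Ne, which the minority sex dominates; 3 Line2 sires
  would put Line2 at Ne ~ 12 and drive adjacent r2 toward 0.7. Line2 and F1
  keep their full counts (64, 60). Line1 uses 128 sires rather than 640:
  at full scale the top-~2.4% BLUP sire selection cuts Line1's realized Ne
  to roughly a tenth of census (visible in the reported inbreeding, F ~
  0.02 after 10 generations), and 128 sires reproduce that realized
  inbreeding trajectory at desk scale (measured F ~ 0.017-0.021 for Line1
  after 10 generations and 0.09-0.10 for Line2 after 30). With this
  profile the final-generation adjacent-SNP r2 under the SIM5 trait
  reaches ~0.16-0.21 (Line1) and ~0.31-0.39 (Line2).
- **QTL counts are not scaled down with the genome.** How fast directional
  selection erodes QTL variance depends on the per-QTL effect variance, not
  on QTLs per cM: compressing 4,500 QTLs to 42 (proportional to map
  length) raises per-QTL variance ~108-fold and lets selection sweep the
  trait's variance out of Line2 entirely. A cap of 1,500 (raising per-QTL
  variance threefold) bounds simulation cost; `max_qtl=None` restores the
  exact architecture.
- **Replicates:** five seeded replicates; REML record subsamples of 300
  per population (three-trait) or 1,000 across two POP generations
  (parameter-recovery checks, where parent-offspring links carry the
  heritability information).

### What the scaled profile does and does not show

It exercises every stage of the pipeline end to end on data with the full
design's marker spacing, generation structure, selection rules and
variance targets, and reproduces the full design's realized inbreeding,
Line2 LD, founder variance partition and (on unselected cohorts) REML
parameter recovery. Three quantities are scale-limited and are reported
honestly rather than matched:

- *Line1 baseline LD*: under the stated history (N = 2,000, c = 5e-4) the
  drift-recombination equilibrium E[r2] is ~1/(3 + 4Nc) ~ 0.14
  (Ohta-Kimura/Hill); values near 0.20 arise here only with the additional
  selection-induced LD of the SIM5 trait, and sit at the low edge of that
  band.
- *PC1 dominance*: the between-line eigenvalue of G grows with sample
  size, while with a 500-SNP panel the G-sampling noise eigenvalues
  (~n/sqrt(m)) are of the same order; PC1 shares near 80% require the
  full-size panel and genotyped set.
- *Line2 genetic variance*: 26-30 generations of selection at desk-scale
  Ne erode the within-line base variance further than at full scale, so
  scenario REML heritabilities for Line2 are honestly low and the
  Line2-F1 genetic correlation is estimated with large error (its true
  value is 1; estimates touch the boundary in either direction when the
  Line2 variance component approaches zero — the same collapse the
  full-scale 198-QTL architecture shows).

## Numerical choices

- MME relative residuals < 1e-8 on all toy systems (tested); CG tolerance
  1e-10.
- G is blended 0.95/0.05 with A22 before every inversion; inversion
  failures report the smallest eigenvalue.
- Non-PD G0 supplied to the multi-trait solver is bent (eigenvalue floor)
  with a warning.
- QC thresholds are strict inequalities on both sides.
- Degenerate paired t-tests (zero-variance differences): p = 1 when the
  difference is identically zero, flagged otherwise.
- Grid selection tie-break: |1 - slope|, then accuracy, then lower tau,
  then lower omega.
- All randomness flows from a single integer seed per run
  (`numpy.random.default_rng`); identical seed and configuration give
  bitwise-identical populations.

## Known limitations

Additive gene action only (no dominance, heterosis or epistasis), no sex
chromosomes, no genotyping error or missingness, no pedigree errors; true
simulated phase is used (no statistical phasing); dense matrix algebra
limits the evaluation stack to desk-scale genotyped sets (no APY-type
approximations); the full-scale design is implemented but is a
cluster-scale run.
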