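"""Forward-in-time breeding simulator for a two-line + F1 cattle system.

The simulated scheme: a long random-mating historical population with two
bottlenecks builds drift LD from loci all starting at allele frequency 0.50;
200 sampled founders seed an expansion population (POP); two purebred lines
are then bred with BLUP-EBV truncation selection (Line1: 10 generations,
selection intensity of a Zebu nucleus; Line2: 30 generations, Taurine-like),
and four F1 cohorts are produced from Line1 dams x Line2 sires at successive
parental generations.

Meiosis uses a Poisson crossover model without interference (expected
crossovers = map length / 100 cM) and recurrent biallelic mutation that
flips the transmitted allele at 1e-5 per locus and generation.  The trait
is additive: a finite QTL set plus an infinitesimal polygenic term
transmitted as parent average + Mendelian sampling.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .genome import GenomeSpec, TraitArchitecture
from . import pedigree as pedmod
from . import models

__all__ = [
    "ConfigError",
    "LociMap",
    "PopulationDesign",
    "SimulatedPopulation",
    "PopulationBuilder",
    "build_loci_map",
    "meiosis",
    "simulate_history",
    "sample_qtl_effects",
    "simulate_population",
    "assign_phenotypes",
]


class ConfigError(ValueError):
    pass


# ---------------------------------------------------------------------------
# loci map (markers + QTLs interleaved on one map)


@dataclass(frozen=True)
class LociMap:
    """All simulated loci (SNPs and QTLs) in (chromosome, position) order."""

    chrom: np.ndarray  # 1-based chromosome per locus
    pos_cm: np.ndarray
    is_snp: np.ndarray  # genotyping panel membership
    chrom_lengths: np.ndarray

    @property
    def n_loci(self) -> int:
        return len(self.pos_cm)

    @property
    def n_snps(self) -> int:
        return int(self.is_snp.sum())

    def chrom_slices(self) -> list[slice]:
        bounds = np.searchsorted(
            self.chrom, np.arange(1, len(self.chrom_lengths) + 2)
        )
        return [slice(bounds[c], bounds[c + 1]) for c in range(len(self.chrom_lengths))]

    def snp_index(self) -> np.ndarray:
        return np.flatnonzero(self.is_snp)


def build_loci_map(
    genome: GenomeSpec, trait: TraitArchitecture, rng: np.random.Generator
) -> tuple[LociMap, TraitArchitecture]:
    """Merge the SNP map with uniformly placed QTL positions.

    QTLs are drawn uniformly along the genome (per-chromosome counts
    multinomial in length) at non-marker positions; they are simulated like
    any other locus but excluded from the genotyping panel.
    """
    chroms = [np.full(m, c + 1) for c, m in enumerate(genome.snp_counts)]
    pos = list(genome.snp_positions)
    flags = [np.ones(m, dtype=bool) for m in genome.snp_counts]
    if trait.n_qtl > 0:
        lens = genome.chrom_lengths
        counts = rng.multinomial(trait.n_qtl, lens / lens.sum())
        qc, qp = [], []
        for c, (k, L) in enumerate(zip(counts, lens)):
            if k == 0:
                continue
            x = np.sort(rng.uniform(0.0, L, k))
            qc.append(np.full(k, c + 1))
            qp.append(x)
            chroms.append(np.full(k, c + 1))
            pos.append(x)
            flags.append(np.zeros(k, dtype=bool))
        trait = trait.with_qtls(
            np.concatenate(qc), np.concatenate(qp), trait.qtl_effects
        )
    chrom = np.concatenate(chroms)
    p = np.concatenate(pos)
    f = np.concatenate(flags)
    order = np.lexsort((p, chrom))
    return (
        LociMap(
            chrom=chrom[order],
            pos_cm=p[order],
            is_snp=f[order],
            chrom_lengths=genome.chrom_lengths,
        ),
        trait,
    )


# ---------------------------------------------------------------------------
# meiosis


def _make_gametes(
    haps: np.ndarray,
    parents: np.ndarray,
    loci: LociMap,
    mutation_rate: float,
    rng: np.random.Generator,
    return_origins: bool = False,
):
    """One gamete per entry of ``parents`` (row indices of individuals).

    Crossover count per chromosome ~ Poisson(length/100), positions uniform,
    no interference; strand choice at the chromosome start is fair.
    """
    n = len(parents)
    L = loci.n_loci
    strands = np.empty((n, L), dtype=np.uint8)
    for sl, clen in zip(loci.chrom_slices(), loci.chrom_lengths):
        m = sl.stop - sl.start
        if m == 0:
            continue
        start = rng.integers(0, 2, n, dtype=np.uint8)
        block = np.repeat(start[:, None], m, axis=1)
        if clen > 0:
            k = rng.poisson(clen / 100.0, n)
            idx = np.flatnonzero(k > 0)
            if idx.size:
                kmax = int(k[idx].max())
                x = rng.uniform(0.0, clen, (idx.size, kmax))
                x[np.arange(kmax)[None, :] >= k[idx][:, None]] = np.inf
                counts = (x[:, :, None] <= loci.pos_cm[sl][None, None, :]).sum(axis=1)
                block[idx] = (start[idx][:, None] + counts) % 2
        strands[:, sl] = block
    rows = 2 * np.asarray(parents, dtype=np.int64)[:, None] + strands
    gam = haps[rows, np.arange(L)[None, :]]
    mut = None
    if mutation_rate > 0:
        nm = rng.poisson(n * L * mutation_rate)
        if nm > 0:
            r = rng.integers(0, n, nm)
            c = rng.integers(0, L, nm)
            gam[r, c] ^= 1
            mut = (r, c)
    if return_origins:
        return gam, strands, mut
    return gam


def meiosis(
    parent_haplotypes: np.ndarray,
    loci: LociMap,
    mutation_rate: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Single gamete from one parent's phased pair of haplotypes."""
    haps = np.asarray(parent_haplotypes, dtype=np.uint8)
    if haps.shape != (2, loci.n_loci):
        raise ValueError("parent haplotypes must be (2, n_loci)")
    return _make_gametes(haps, np.array([0]), loci, mutation_rate, rng)[0]


# ---------------------------------------------------------------------------
# historical population


def simulate_history(
    loci: LociMap,
    phases: tuple[tuple[int, int], ...] = ((2000, 1000), (1500, 20)),
    mutation_rate: float = 1e-5,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Random-mating constant-size phases; returns the final haplotype pool.

    All loci start at allele frequency exactly 0.50.  LD accumulates by
    drift; the phase structure implements the two bottlenecks
    (2,000 -> 1,500 over the last 20 generations at full scale).
    Individuals are (2i, 2i+1) haplotype row pairs; the first half of each
    generation is male.
    """
    if rng is None:
        rng = np.random.default_rng()
    if not phases or phases[0][0] < 2:
        raise ConfigError("history needs an initial population of >= 2")
    N = phases[0][0]
    L = loci.n_loci
    haps = np.zeros((2 * N, L), dtype=np.uint8)
    haps[:N] = 1
    haps = rng.permuted(haps, axis=0)
    for N_next, gens in phases:
        for _ in range(gens):
            n_m = N - N // 2
            sires = rng.integers(0, n_m, N_next)
            dams = n_m + rng.integers(0, N - n_m, N_next)
            pat = _make_gametes(haps, sires, loci, mutation_rate, rng)
            mat = _make_gametes(haps, dams, loci, mutation_rate, rng)
            haps = np.empty((2 * N_next, L), dtype=np.uint8)
            haps[0::2] = pat
            haps[1::2] = mat
            N = N_next
    return haps


# ---------------------------------------------------------------------------
# QTL effects


def sample_qtl_effects(
    trait: TraitArchitecture,
    founder_qtl_dosages: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Gamma(shape) effects with random sign, rescaled so the founder QTL
    breeding-value variance equals h2_qtl * vp.  Returns an empty array for
    a purely polygenic trait."""
    if trait.n_qtl == 0:
        return np.zeros(0)
    raw = rng.gamma(trait.gamma_shape, 1.0, trait.n_qtl)
    raw *= rng.choice([-1.0, 1.0], trait.n_qtl)
    target = trait.sigma2_qtl
    if target == 0:
        return np.zeros(trait.n_qtl)
    v = np.var(founder_qtl_dosages @ raw)
    if v <= 0:
        raise ConfigError(
            "all founders monomorphic at every QTL; cannot scale effects"
        )
    return raw * math.sqrt(target / v)


# ---------------------------------------------------------------------------
# population design


@dataclass(frozen=True)
class PopulationDesign:
    """Census sizes and generation counts of the breeding scheme."""

    hist_phases: tuple[tuple[int, int], ...] = ((2000, 1000), (1500, 20))
    n_founder_males: int = 100
    n_founder_females: int = 100
    expansion_target: int = 64000
    expansion_gens: int = 8
    litter_size: int = 5
    line1_dams: int = 32000
    line1_sires: int = 640
    line1_gens: int = 10
    line2_dams: int = 3200
    line2_sires: int = 64
    line2_gens: int = 30
    sire_replacement: float = 0.60
    dam_replacement: float = 0.20
    f1_dams: int = 3000
    f1_sires: int = 60
    n_f1_cohorts: int = 4
    scale_factor: float = 1.0

    @classmethod
    def full(cls) -> "PopulationDesign":
        return cls()

    @classmethod
    def scaled(cls, f: float, scale_males: bool = False) -> "PopulationDesign":
        """Reduced design: dam/census counts scaled by ``f``.

        The historical phases stay at full size (baseline LD depends on the
        historical Ne, not on marker or animal counts).  Sire counts are not
        scaled by ``f``: line drift and divergence are governed by realized
        effective population size, which the minority sex dominates.  Line1
        sires are reduced to 4f x 640 (128 at f = 0.05) because at full
        scale intense BLUP sire selection (top ~2.4%) cuts Line1's realized
        Ne far below census; the calibration reproduces the full design's
        realized inbreeding trajectory (Line1 F ~ 0.02 after 10 generations,
        Line2 F ~ 0.12 after 30).
        """
        if not (0 < f <= 1):
            raise ConfigError("scale factor must be in (0, 1]")
        s = f if scale_males else 1.0
        l1d = max(4, round(32000 * f))
        l2d = max(4, round(3200 * f))
        l1s = max(2, round(640 * (s if scale_males else min(1.0, 4 * f))))
        l2s = max(2, round(64 * s))
        f1d = max(2, round(3000 * f))
        f1s = max(1, round(60 * s))
        demand_f = l1d + l2d
        demand_m = l1s + l2s
        target = max(round(64000 * f), math.ceil(2.2 * max(demand_f, demand_m)))
        return cls(
            expansion_target=target,
            line1_dams=l1d,
            line1_sires=l1s,
            line2_dams=l2d,
            line2_sires=l2s,
            f1_dams=f1d,
            f1_sires=f1s,
            scale_factor=f,
        )

    @classmethod
    def toy(cls) -> "PopulationDesign":
        """Minutes-free profile for unit tests and smoke runs."""
        return cls(
            hist_phases=((80, 40), (60, 8)),
            n_founder_males=15,
            n_founder_females=15,
            expansion_target=160,
            expansion_gens=4,
            line1_dams=40,
            line1_sires=8,
            line1_gens=5,
            line2_dams=30,
            line2_sires=6,
            line2_gens=7,
            f1_dams=12,
            f1_sires=4,
            scale_factor=0.0,
        )

    def f1_parent_generations(self, k: int) -> tuple[int, int]:
        """Cohort F1-k draws dams from Line1 generation l1-4+k and sires
        from Line2 generation l2-4+k (k = 1..4)."""
        if not 1 <= k <= self.n_f1_cohorts:
            raise ConfigError(f"no F1 cohort {k}")
        return self.line1_gens - 4 + k, self.line2_gens - 4 + k

    def __post_init__(self):
        if self.line1_gens < self.n_f1_cohorts or self.line2_gens < self.n_f1_cohorts:
            raise ConfigError("line generation counts too small for F1 cohorts")
        if not (0 < self.sire_replacement <= 1 and 0 < self.dam_replacement <= 1):
            raise ConfigError("replacement ratios must be in (0, 1]")


# ---------------------------------------------------------------------------
# simulated population container


@dataclass
class SimulatedPopulation:
    """Pedigree, phased genotypes, breeding values and phenotypes."""

    genome: GenomeSpec
    trait: TraitArchitecture
    design: PopulationDesign
    loci: LociMap
    pedigree: pd.DataFrame  # id, sire, dam, sex, generation, population
    haplotypes: np.ndarray  # (2n, n_loci) uint8
    inbreeding: np.ndarray
    tbv_qtl: np.ndarray
    tbv_poly: np.ndarray
    phenotype: np.ndarray
    cohorts: dict[str, np.ndarray]  # name -> ids (1-based)
    seed: int
    origins: dict | None = None

    @property
    def n_individuals(self) -> int:
        return len(self.pedigree)

    @property
    def tbv(self) -> np.ndarray:
        return self.tbv_qtl + self.tbv_poly

    def ids(self, population: str | None = None, generation=None) -> np.ndarray:
        m = np.ones(self.n_individuals, dtype=bool)
        if population is not None:
            m &= (self.pedigree["population"] == population).to_numpy()
        if generation is not None:
            gens = np.atleast_1d(generation)
            m &= self.pedigree["generation"].isin(gens).to_numpy()
        return self.pedigree.loc[m, "id"].to_numpy()

    def _rows(self, ids: np.ndarray) -> np.ndarray:
        return np.asarray(ids, dtype=np.int64) - 1

    def haplotypes_of(self, ids, loci: str = "snp") -> np.ndarray:
        """(2k, m) phased haplotypes; rows 2i, 2i+1 belong to ids[i]."""
        rows = self._rows(ids)
        hap_rows = np.empty(2 * len(rows), dtype=np.int64)
        hap_rows[0::2] = 2 * rows
        hap_rows[1::2] = 2 * rows + 1
        cols = self._loci_cols(loci)
        return self.haplotypes[np.ix_(hap_rows, cols)]

    def dosages(self, ids, loci: str = "snp") -> np.ndarray:
        rows = self._rows(ids)
        cols = self._loci_cols(loci)
        return (
            self.haplotypes[np.ix_(2 * rows, cols)].astype(np.int16)
            + self.haplotypes[np.ix_(2 * rows + 1, cols)]
        )

    def _loci_cols(self, loci: str) -> np.ndarray:
        if loci == "snp":
            return np.flatnonzero(self.loci.is_snp)
        if loci == "qtl":
            return np.flatnonzero(~self.loci.is_snp)
        if loci == "all":
            return np.arange(self.loci.n_loci)
        raise ValueError(f"unknown loci selector {loci!r}")

    def snp_map(self) -> pd.DataFrame:
        """SNP map with cM and bp positions (1 cM = 1 Mb convention)."""
        cols = np.flatnonzero(self.loci.is_snp)
        return pd.DataFrame(
            {
                "snp": [f"snp{j}" for j in range(len(cols))],
                "chrom": self.loci.chrom[cols],
                "pos_cm": self.loci.pos_cm[cols],
                "pos_bp": np.round(self.loci.pos_cm[cols] * 1e6).astype(np.int64),
            }
        )

    def phenotype_frame(self, ids) -> pd.DataFrame:
        rows = self._rows(ids)
        ped = self.pedigree.iloc[rows]
        return pd.DataFrame(
            {
                "id": ped["id"].to_numpy(),
                "sex": ped["sex"].to_numpy(),
                "population": ped["population"].to_numpy(),
                "generation": ped["generation"].to_numpy(),
                "phenotype": self.phenotype[rows],
                "tbv": self.tbv[rows],
            }
        )


# ---------------------------------------------------------------------------
# builder


class PopulationBuilder:
    """Incrementally grows the pedigree/haplotype arrays through the design
    stages.  Use :func:`simulate_population` for the full pipeline; the
    builder's stage methods are public to allow partial runs in tests."""

    def __init__(
        self,
        genome: GenomeSpec,
        trait: TraitArchitecture,
        design: PopulationDesign,
        seed: int,
        track_origins: bool = False,
        mu: float = 0.0,
        sex_effect: float = 0.0,
    ):
        self.genome = genome
        self.design = design
        self.seed = int(seed)
        self.rng = np.random.default_rng(self.seed)
        self.loci, self.trait = build_loci_map(genome, trait, self.rng)
        self.mu = mu
        self.sex_effect = sex_effect
        self.track_origins = track_origins
        self.origins: dict | None = {} if track_origins else None

        cap = self._capacity()
        L = self.loci.n_loci
        self.haps = np.zeros((2 * cap, L), dtype=np.uint8)
        self.sire = np.full(cap, -1, dtype=np.int64)  # 0-based, -1 unknown
        self.dam = np.full(cap, -1, dtype=np.int64)
        self.sex = np.zeros(cap, dtype="U1")
        self.gen = np.zeros(cap, dtype=np.int64)
        self.pop = np.zeros(cap, dtype=object)
        self.F = np.zeros(cap)
        self.tbv_qtl = np.zeros(cap)
        self.tbv_poly = np.zeros(cap)
        self.phen = np.zeros(cap)
        self.n = 0
        self.cohorts: dict[str, np.ndarray] = {}
        self._line_members: dict[str, list[int]] = {}
        self._line_parents: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        self._qtl_cols = np.flatnonzero(~self.loci.is_snp)

    # -- sizing

    def _expansion_sizes(self) -> list[int]:
        d = self.design
        sizes = []
        n = d.n_founder_males + d.n_founder_females
        n_f = d.n_founder_females
        for _ in range(d.expansion_gens):
            n = min(d.expansion_target, n_f * d.litter_size)
            n_f = n // 2
            sizes.append(n)
        if sizes and sizes[-1] < d.expansion_target:
            raise ConfigError(
                f"expansion cannot reach {d.expansion_target} in "
                f"{d.expansion_gens} generations (got {sizes[-1]})"
            )
        return sizes

    def _capacity(self) -> int:
        d = self.design
        return (
            d.n_founder_males
            + d.n_founder_females
            + sum(self._expansion_sizes())
            + d.line1_dams * d.line1_gens
            + d.line2_dams * d.line2_gens
            + d.f1_dams * d.n_f1_cohorts
        )

    # -- low-level append

    def _append(self, haps_rows, sire, dam, sex, gen, popname) -> np.ndarray:
        k = len(sex)
        i0, i1 = self.n, self.n + k
        self.haps[2 * i0 : 2 * i1] = haps_rows
        self.sire[i0:i1] = sire
        self.dam[i0:i1] = dam
        self.sex[i0:i1] = sex
        self.gen[i0:i1] = gen
        self.pop[i0:i1] = popname
        self.n = i1
        self.F[:i1] = pedmod.inbreeding_from_indices(
            self.sire[:i1], self.dam[:i1], F_prefix=self.F[:i0].copy()
        )
        return np.arange(i0, i1) + 1  # 1-based ids

    def _phenotype_cohort(self, idx: np.ndarray, founder: bool = False):
        t = self.trait
        if t.n_qtl > 0 and t.qtl_effects is not None and len(t.qtl_effects):
            dos = (
                self.haps[np.ix_(2 * idx, self._qtl_cols)].astype(np.float64)
                + self.haps[np.ix_(2 * idx + 1, self._qtl_cols)]
            )
            self.tbv_qtl[idx] = dos @ t.qtl_effects
        s2p = t.sigma2_poly
        if founder:
            self.tbv_poly[idx] = (
                self.rng.normal(0.0, math.sqrt(s2p), len(idx)) if s2p > 0 else 0.0
            )
        elif s2p > 0:
            pa = 0.5 * (self.tbv_poly[self.sire[idx]] + self.tbv_poly[self.dam[idx]])
            fbar = 0.5 * (self.F[self.sire[idx]] + self.F[self.dam[idx]])
            mend = self.rng.normal(0.0, 1.0, len(idx)) * np.sqrt(
                0.5 * s2p * (1.0 - fbar)
            )
            self.tbv_poly[idx] = pa + mend
        e = self.rng.normal(0.0, math.sqrt(t.sigma2_e), len(idx))
        sexeff = np.where(self.sex[idx] == "M", self.sex_effect, 0.0)
        self.phen[idx] = (
            self.mu + sexeff + self.tbv_qtl[idx] + self.tbv_poly[idx] + e
        )

    def _mate(self, sire_ids, dam_ids, gen, popname):
        """One offspring per (sire, dam) pair; ids are 1-based."""
        sidx = np.asarray(sire_ids, dtype=np.int64) - 1
        didx = np.asarray(dam_ids, dtype=np.int64) - 1
        pat = _make_gametes(
            self.haps, sidx, self.loci, self.trait.mutation_rate, self.rng,
            return_origins=self.track_origins,
        )
        mat = _make_gametes(
            self.haps, didx, self.loci, self.trait.mutation_rate, self.rng,
            return_origins=self.track_origins,
        )
        if self.track_origins:
            pat, pstr, pmut = pat
            mat, mstr, mmut = mat
        k = len(sidx)
        rows = np.empty((2 * k, self.loci.n_loci), dtype=np.uint8)
        rows[0::2] = pat
        rows[1::2] = mat
        n_m = k // 2
        sex = np.array(["M"] * n_m + ["F"] * (k - n_m))
        sex = self.rng.permuted(sex)
        idx0 = self.n
        ids = self._append(rows, sidx, didx, sex, gen, popname)
        if self.track_origins:
            self.origins[popname, gen] = {
                "ids": ids,
                "pat_strands": pstr,
                "mat_strands": mstr,
                "pat_mut": pmut,
                "mat_mut": mmut,
            }
        self._phenotype_cohort(np.arange(idx0, self.n))
        return ids

    # -- stages

    def found_from_history(self, pool: np.ndarray | None = None) -> np.ndarray:
        """Run (or accept) the historical phase and sample the founders."""
        d = self.design
        if pool is None:
            pool = simulate_history(
                self.loci, d.hist_phases, self.trait.mutation_rate, self.rng
            )
        N = pool.shape[0] // 2
        n_m = N - N // 2
        if d.n_founder_males > n_m or d.n_founder_females > N - n_m:
            raise ConfigError("historical pool too small to sample founders")
        males = self.rng.choice(n_m, d.n_founder_males, replace=False)
        females = n_m + self.rng.choice(N - n_m, d.n_founder_females, replace=False)
        sel = np.concatenate([males, females])
        rows = np.empty((2 * len(sel), self.loci.n_loci), dtype=np.uint8)
        rows[0::2] = pool[2 * sel]
        rows[1::2] = pool[2 * sel + 1]
        sex = np.array(["M"] * d.n_founder_males + ["F"] * d.n_founder_females)
        ids = self._append(
            rows, np.full(len(sel), -1), np.full(len(sel), -1), sex, 0, "POP"
        )
        # QTL effects are scaled to the founder cohort's realised variance
        if self.trait.n_qtl > 0:
            idx = ids - 1
            dos = (
                self.haps[np.ix_(2 * idx, self._qtl_cols)].astype(np.float64)
                + self.haps[np.ix_(2 * idx + 1, self._qtl_cols)]
            )
            eff = sample_qtl_effects(self.trait, dos, self.rng)
            self.trait = replace(self.trait, qtl_effects=eff)
        self._phenotype_cohort(ids - 1, founder=True)
        self.cohorts["POP:g0"] = ids
        return ids

    def expand_population(self) -> np.ndarray:
        """Grow POP by litters of ``litter_size`` under random selection."""
        d = self.design
        cur = self.cohorts["POP:g0"]
        for g, size in enumerate(self._expansion_sizes(), start=1):
            males = cur[self.sex[cur - 1] == "M"]
            females = cur[self.sex[cur - 1] == "F"]
            if len(males) == 0 or len(females) == 0:
                raise ConfigError("expansion generation lost one sex entirely")
            slots = np.repeat(females, d.litter_size)
            dams = self.rng.permuted(slots)[:size]
            sires = self.rng.choice(males, size, replace=True)
            cur = self._mate(sires, dams, g, "POP")
            self.cohorts[f"POP:g{g}"] = cur
        return cur

    def sample_line_bases(self):
        """Randomly split the final POP generation into the two line bases."""
        d = self.design
        cur = self.cohorts[f"POP:g{d.expansion_gens}"]
        males = self.rng.permuted(cur[self.sex[cur - 1] == "M"])
        females = self.rng.permuted(cur[self.sex[cur - 1] == "F"])
        if len(females) < d.line1_dams + d.line2_dams:
            raise ConfigError(
                f"POP has {len(females)} females; lines need "
                f"{d.line1_dams + d.line2_dams}"
            )
        if len(males) < d.line1_sires + d.line2_sires:
            raise ConfigError("POP has too few males for the line bases")
        l1f, l2f = females[: d.line1_dams], females[d.line1_dams : d.line1_dams + d.line2_dams]
        l1m, l2m = males[: d.line1_sires], males[d.line1_sires : d.line1_sires + d.line2_sires]
        for line, (m, f) in (("Line1", (l1m, l1f)), ("Line2", (l2m, l2f))):
            base = np.concatenate([m, f])
            self.cohorts[f"{line}:g0"] = base
            self._line_members[line] = list(base)
            self._line_parents[line] = (m.copy(), f.copy())
        return self._line_parents

    def breed_line(self, line: str, n_generations: int | None = None) -> None:
        """Truncation selection on pedigree-BLUP EBVs at the true variances.

        Replacements each generation: the lowest-EBV offspring of each sex
        enter; the highest-EBV current parents are culled (downward
        selection, as for residual feed intake).
        """
        d = self.design
        gens = n_generations if n_generations is not None else (
            d.line1_gens if line == "Line1" else d.line2_gens
        )
        n_sires = d.line1_sires if line == "Line1" else d.line2_sires
        n_dams = d.line1_dams if line == "Line1" else d.line2_dams
        n_new_s = max(1, round(d.sire_replacement * n_sires))
        n_new_d = max(1, round(d.dam_replacement * n_dams))
        sires, dams = self._line_parents[line]
        for g in range(1, gens + 1):
            mates = self.rng.choice(sires, n_dams, replace=True)
            ids = self._mate(mates, dams, g, line)
            self.cohorts[f"{line}:g{g}"] = ids
            self._line_members[line].extend(ids)
            ebv = self._line_ebv(line)
            young = ids
            ym = young[self.sex[young - 1] == "M"]
            yf = young[self.sex[young - 1] == "F"]
            if len(ym) < n_new_s or len(yf) < n_new_d:
                raise ConfigError(
                    f"{line} g{g}: offspring cannot supply replacements "
                    f"({len(ym)} males for {n_new_s}, {len(yf)} females for {n_new_d})"
                )
            new_s = ym[np.argsort(ebv.loc[ym].to_numpy(), kind="stable")[:n_new_s]]
            new_d = yf[np.argsort(ebv.loc[yf].to_numpy(), kind="stable")[:n_new_d]]
            keep_s = sires[
                np.argsort(ebv.loc[sires].to_numpy(), kind="stable")[: n_sires - n_new_s]
            ]
            keep_d = dams[
                np.argsort(ebv.loc[dams].to_numpy(), kind="stable")[: n_dams - n_new_d]
            ]
            sires = np.concatenate([keep_s, new_s])
            dams = np.concatenate([keep_d, new_d])
            self._line_parents[line] = (sires, dams)

    def _line_ebv(self, line: str) -> pd.Series:
        """Pedigree BLUP over the line's own pedigree and records."""
        members = np.asarray(self._line_members[line])
        midx = members - 1
        local = {int(i): k for k, i in enumerate(members)}
        lsire = np.array(
            [local.get(int(s + 1), -1) if s >= 0 else -1 for s in self.sire[midx]]
        )
        ldam = np.array(
            [local.get(int(dd + 1), -1) if dd >= 0 else -1 for dd in self.dam[midx]]
        )
        Ainv = pedmod.a_inverse_from_indices(lsire, ldam, F=self.F[midx])
        rec = pd.DataFrame(
            {
                "id": members,
                "sex": self.sex[midx],
                "phenotype": self.phen[midx],
            }
        )
        return models.pedigree_blup_ebv(
            rec, members, Ainv, self.trait.sigma2_u, self.trait.sigma2_e
        )

    def make_f1(self, k: int) -> np.ndarray:
        """F1-k cohort: Line1 dams x Line2 sires from the design's parental
        generations, random mating (sires with replacement)."""
        d = self.design
        g1, g2 = d.f1_parent_generations(k)
        try:
            l1 = self.cohorts[f"Line1:g{g1}"]
            l2 = self.cohorts[f"Line2:g{g2}"]
        except KeyError:
            raise ConfigError(
                f"parental generations Line1:g{g1} / Line2:g{g2} absent"
            ) from None
        fem = l1[self.sex[l1 - 1] == "F"]
        mal = l2[self.sex[l2 - 1] == "M"]
        if len(fem) < d.f1_dams or len(mal) < d.f1_sires:
            raise ConfigError(
                f"F1-{k}: need {d.f1_dams} dams/{d.f1_sires} sires, have "
                f"{len(fem)}/{len(mal)}"
            )
        dams = self.rng.choice(fem, d.f1_dams, replace=False)
        sires_pool = self.rng.choice(mal, d.f1_sires, replace=False)
        sires = self.rng.choice(sires_pool, d.f1_dams, replace=True)
        ids = self._mate(sires, dams, k, f"F1-{k}")
        self.cohorts[f"F1-{k}"] = ids
        return ids

    def finish(self) -> SimulatedPopulation:
        n = self.n
        ped = pd.DataFrame(
            {
                "id": np.arange(1, n + 1),
                "sire": np.where(self.sire[:n] >= 0, self.sire[:n] + 1, 0),
                "dam": np.where(self.dam[:n] >= 0, self.dam[:n] + 1, 0),
                "sex": self.sex[:n],
                "generation": self.gen[:n],
                "population": self.pop[:n].astype(str),
            }
        )
        return SimulatedPopulation(
            genome=self.genome,
            trait=self.trait,
            design=self.design,
            loci=self.loci,
            pedigree=ped,
            haplotypes=self.haps[: 2 * n],
            inbreeding=self.F[:n].copy(),
            tbv_qtl=self.tbv_qtl[:n].copy(),
            tbv_poly=self.tbv_poly[:n].copy(),
            phenotype=self.phen[:n].copy(),
            cohorts=dict(self.cohorts),
            seed=self.seed,
            origins=self.origins,
        )


def simulate_population(
    genome: GenomeSpec,
    trait: TraitArchitecture,
    design: PopulationDesign,
    seed: int,
    track_origins: bool = False,
) -> SimulatedPopulation:
    """Run the full scheme: history -> founders -> POP -> lines -> F1."""
    b = PopulationBuilder(genome, trait, design, seed, track_origins=track_origins)
    b.found_from_history()
    b.expand_population()
    b.sample_line_bases()
    b.breed_line("Line1")
    b.breed_line("Line2")
    for k in range(1, design.n_f1_cohorts + 1):
        b.make_f1(k)
    return b.finish()


def assign_phenotypes(
    pop: SimulatedPopulation,
    trait: TraitArchitecture | None = None,
    rng: np.random.Generator | None = None,
    mu: float = 0.0,
    sex_effect: float = 0.0,
) -> SimulatedPopulation:
    """Redraw phenotypes from the stored breeding values.

    phenotype = mu + sex effect + TBV + e, e ~ N(0, (1 - h2) vp).
    """
    trait = trait or pop.trait
    rng = rng or np.random.default_rng()
    e = rng.normal(0.0, math.sqrt(trait.sigma2_e), pop.n_individuals)
    sexeff = np.where(pop.pedigree["sex"].to_numpy() == "M", sex_effect, 0.0)
    pop.phenotype = mu + sexeff + pop.tbv + e
    return pop
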