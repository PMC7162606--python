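"""Genome and trait-architecture specifications.

The simulated genome mimics the bovine autosomes: 29 chromosomes totalling
~2,696.54 cM carrying 52,886 evenly spaced biallelic SNPs (a 50K-density
panel).  Causal loci (QTLs) live on the same map but are never part of the
genotyping panel; markers only observe them through linkage disequilibrium.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

__all__ = [
    "GenomeSpec",
    "TraitArchitecture",
    "build_genome",
    "trait_architecture",
    "SIM_PRESETS",
    "FULL_GENOME_LENGTH_CM",
    "FULL_TOTAL_SNPS",
    "FULL_N_CHROMOSOMES",
]

FULL_N_CHROMOSOMES = 29
FULL_GENOME_LENGTH_CM = 2696.54
FULL_TOTAL_SNPS = 52886

# Relative bovine autosome lengths (BTA1-29, approximately proportional to
# physical length; normalised to the configured genome length at build time).
_BOVINE_REL_LENGTHS = np.array(
    [
        158.3, 137.1, 121.4, 120.8, 121.2, 119.5, 112.6, 113.4, 105.7, 104.3,
        107.3, 91.2, 84.2, 84.6, 85.3, 81.7, 75.2, 66.0, 64.1, 72.0,
        71.6, 61.4, 52.5, 62.7, 42.9, 51.7, 45.4, 46.3, 51.5,
    ]
)


class InvalidSpecError(ValueError):
    """Raised for impossible genome/trait configurations."""


@dataclass(frozen=True)
class GenomeSpec:
    """Marker map: chromosome lengths (cM) and evenly spaced SNP positions.

    SNPs on a chromosome of length L carrying m markers sit at the m interval
    midpoints (L/2m, 3L/2m, ...), so adjacent spacing is exactly L/m.
    """

    chrom_lengths: np.ndarray
    snp_counts: np.ndarray
    snp_positions: tuple[np.ndarray, ...]
    scale_factor: float = 1.0

    @property
    def n_chromosomes(self) -> int:
        return len(self.chrom_lengths)

    @property
    def total_snps(self) -> int:
        return int(self.snp_counts.sum())

    @property
    def genome_length(self) -> float:
        return float(self.chrom_lengths.sum())

    def snp_chrom(self) -> np.ndarray:
        """1-based chromosome index per SNP, in map order."""
        return np.repeat(np.arange(1, self.n_chromosomes + 1), self.snp_counts)

    def snp_pos_cm(self) -> np.ndarray:
        """Within-chromosome SNP positions (cM), in map order."""
        return np.concatenate(self.snp_positions)

    def __post_init__(self):
        for c, pos in enumerate(self.snp_positions):
            if len(pos) != self.snp_counts[c]:
                raise InvalidSpecError("snp_counts inconsistent with positions")
            if len(pos) > 1 and not np.all(np.diff(pos) > 0):
                raise InvalidSpecError(
                    f"SNP positions not strictly increasing on chromosome {c + 1}"
                )


def _largest_remainder(total: int, weights: np.ndarray) -> np.ndarray:
    """Integer allocation proportional to weights, summing exactly to total."""
    quota = total * weights / weights.sum()
    base = np.floor(quota).astype(int)
    rem = total - base.sum()
    if rem > 0:
        order = np.argsort(-(quota - base), kind="stable")
        base[order[:rem]] += 1
    return base


def build_genome(
    n_chrom: int,
    genome_length_cM: float,
    total_snps: int,
    scale_factor: float = 1.0,
    rel_lengths: Sequence[float] | None = None,
) -> GenomeSpec:
    """Build an evenly spaced SNP map.

    Per-chromosome SNP counts follow proportional-to-length allocation
    (largest remainder, summing exactly to ``total_snps``).  When ``n_chrom``
    is 29 and no relative lengths are given, the bundled bovine-autosome
    table is used; otherwise chromosomes are equal-length.
    """
    if n_chrom < 1 or genome_length_cM <= 0 or total_snps < n_chrom:
        raise InvalidSpecError(
            f"invalid genome spec: n_chrom={n_chrom}, "
            f"length={genome_length_cM}, total_snps={total_snps}"
        )
    if rel_lengths is None:
        if n_chrom == FULL_N_CHROMOSOMES:
            rel = _BOVINE_REL_LENGTHS.copy()
        else:
            rel = np.ones(n_chrom)
    else:
        rel = np.asarray(rel_lengths, dtype=float)
        if len(rel) != n_chrom or np.any(rel <= 0):
            raise InvalidSpecError("relative chromosome lengths must be positive")
    lengths = rel / rel.sum() * genome_length_cM
    counts = _largest_remainder(total_snps, lengths)
    # every chromosome must carry at least one marker
    while np.any(counts < 1):
        counts[np.argmin(counts)] += 1
        counts[np.argmax(counts)] -= 1
    positions = tuple(
        (np.arange(m) + 0.5) * (L / m) for m, L in zip(counts, lengths)
    )
    return GenomeSpec(
        chrom_lengths=lengths,
        snp_counts=counts,
        snp_positions=positions,
        scale_factor=float(scale_factor),
    )


# (n_qtl, h2_qtl) at full genome scale; trait h2 = 0.33 throughout.
SIM_PRESETS: dict[str, tuple[int, float]] = {
    "SIM1": (0, 0.0),
    "SIM2": (198, 0.11),
    "SIM3": (4500, 0.11),
    "SIM4": (198, 0.33),
    "SIM5": (4500, 0.33),
}


@dataclass(frozen=True)
class TraitArchitecture:
    """Additive trait: a finite QTL set plus an infinitesimal polygenic rest.

    ``h2_qtl`` is the fraction of phenotypic variance explained by the QTL
    set; ``h2_total - h2_qtl`` is carried by the polygenic term.  QTL allele
    substitution effects are drawn from gamma(``gamma_shape``) with random
    sign and rescaled so the founder QTL-value variance equals
    ``h2_qtl * vp``.
    """

    n_qtl: int
    h2_qtl: float
    h2_total: float = 0.33
    vp: float = 0.13
    gamma_shape: float = 0.40
    mutation_rate: float = 1e-5
    name: str = ""
    qtl_chrom: np.ndarray | None = field(default=None, compare=False)
    qtl_pos_cm: np.ndarray | None = field(default=None, compare=False)
    qtl_effects: np.ndarray | None = field(default=None, compare=False)

    def __post_init__(self):
        if not (0.0 <= self.h2_qtl <= self.h2_total <= 1.0):
            raise InvalidSpecError(
                f"need 0 <= h2_qtl ({self.h2_qtl}) <= h2_total "
                f"({self.h2_total}) <= 1"
            )
        if self.vp <= 0:
            raise InvalidSpecError("phenotypic variance must be positive")
        if self.n_qtl < 0:
            raise InvalidSpecError("n_qtl must be >= 0")

    @property
    def sigma2_qtl(self) -> float:
        return self.h2_qtl * self.vp

    @property
    def sigma2_poly(self) -> float:
        return (self.h2_total - self.h2_qtl) * self.vp

    @property
    def sigma2_u(self) -> float:
        return self.h2_total * self.vp

    @property
    def sigma2_e(self) -> float:
        return (1.0 - self.h2_total) * self.vp

    def with_qtls(self, chrom, pos_cm, effects) -> "TraitArchitecture":
        return replace(
            self, qtl_chrom=np.asarray(chrom), qtl_pos_cm=np.asarray(pos_cm),
            qtl_effects=None if effects is None else np.asarray(effects),
        )


def trait_architecture(
    sim: str,
    genome: GenomeSpec | None = None,
    max_qtl: int | None = 1500,
) -> TraitArchitecture:
    """Trait architecture preset SIM1-SIM5.

    QTL counts are kept at the design values (198 or 4,500) regardless of
    genome size: the selection dynamics of the trait — how fast directional
    selection erodes QTL variance — depend on the per-QTL effect variance,
    not on QTL-per-cM density.  ``max_qtl`` caps the count on reduced
    genomes to bound simulation cost (the cap raises per-QTL variance
    threefold for the 4,500-QTL presets; set ``max_qtl=None`` for the exact
    full-scale architecture).
    """
    try:
        n_qtl, h2_qtl = SIM_PRESETS[sim]
    except KeyError:
        raise InvalidSpecError(f"unknown trait preset {sim!r}") from None
    if (
        genome is not None
        and max_qtl is not None
        and genome.genome_length < FULL_GENOME_LENGTH_CM
    ):
        n_qtl = min(n_qtl, max_qtl)
    return TraitArchitecture(n_qtl=n_qtl, h2_qtl=h2_qtl, name=sim)
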