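"""Simulation configuration for synthetic GWAS cohorts.

The generator emulates the substrate of a male-pattern-baldness case/control
study: a male cohort with autosomal and X-chromosome SNPs in LD blocks, a
liability-threshold binary trait with high prevalence and heritability split
across the two chromosome classes, and secondary traits whose genetic overlap
with the primary trait is confined to named pathway subsets of the loci.
"""

from __future__ import annotations

from dataclasses import dataclass, field


class ConfigurationError(ValueError):
    """Raised when a simulation configuration violates its invariants."""


@dataclass(frozen=True)
class PathwaySpec:
    """A named pathway: which loci it contains and how strongly its genetic
    value leaks into each secondary trait.

    ``slopes`` maps secondary-trait name -> per-unit slope on that trait's
    liability/mean for the pathway's (standardised) genetic value. Opposite
    signs across pathways produce the cancellation phenomenon in the overall
    polygenic score.
    """

    name: str
    loci: tuple[int, ...]
    slopes: dict[str, float] = field(default_factory=dict)


@dataclass(frozen=True)
class SimulationConfig:
    n_individuals: int = 20_000
    n_snps_autosomal: int = 400
    n_snps_x: int = 40
    maf_range: tuple[float, float] = (0.05, 0.5)
    ld_block_size: int = 10
    ld_decay: float = 0.5
    n_loci: int = 10
    distinct_per_locus_range: tuple[int, int] = (1, 5)
    h2_autosomal: float = 0.82
    h2_x: float = 0.12
    prevalence: float = 0.59
    pathways: tuple[PathwaySpec, ...] = ()
    secondary_trait_noise: float = 1.0
    #: give every locus the same genetic variance within its component, so
    #: pathways with equally many loci carry equal weight in the overall score
    equalise_locus_h2: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ConfigurationError(f"maf_range must satisfy 0 < lo <= hi <= 0.5, got {self.maf_range}")
        if self.ld_block_size < 1:
            raise ConfigurationError("ld_block_size must be >= 1")
        if not (0.0 <= self.ld_decay < 1.0):
            raise ConfigurationError("ld_decay must lie in [0, 1)")
        if self.h2_autosomal < 0 or self.h2_x < 0 or self.h2_autosomal + self.h2_x >= 1:
            raise ConfigurationError("need h2_autosomal, h2_x >= 0 and h2_autosomal + h2_x < 1")
        if not (0.0 < self.prevalence < 1.0):
            raise ConfigurationError("prevalence must lie in (0, 1)")
        a, b = self.distinct_per_locus_range
        if not (1 <= a <= b <= 5):
            raise ConfigurationError("distinct_per_locus_range must be within 1..5")
        if self.n_loci < 0:
            raise ConfigurationError("n_loci must be >= 0")
        for pw in self.pathways:
            bad = [l for l in pw.loci if not (1 <= l <= self.n_loci)]
            if bad:
                raise ConfigurationError(f"pathway {pw.name!r} references unknown loci {bad}")

    @property
    def n_snps(self) -> int:
        return self.n_snps_autosomal + self.n_snps_x
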