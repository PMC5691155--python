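"""In-memory genotype panel and simulation ground-truth containers."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: column order for the SNP metadata table
SNP_META_COLUMNS = ["snp", "chr", "pos", "a1", "a2", "maf"]


@dataclass
class GenotypePanel:
    """Individuals x SNPs dosage matrix with SNP metadata.

    Dosages count copies of the effect allele (``a1``) and lie in [0, 2].
    Males carry X dosages in {0, 2} (full dosage compensation coding).
    Positions are 1-based and strictly increasing within a chromosome.
    """

    dosages: np.ndarray  # (n_individuals, n_snps) float64
    snp_meta: pd.DataFrame  # columns SNP_META_COLUMNS
    sex: np.ndarray  # (n_individuals,) 1 = male, 2 = female
    iids: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be a 2-D individuals x SNPs array")
        if len(self.snp_meta) != self.dosages.shape[1]:
            raise ValueError("snp_meta rows must match the number of SNP columns")
        missing = [c for c in SNP_META_COLUMNS if c not in self.snp_meta.columns]
        if missing:
            raise ValueError(f"snp_meta is missing columns {missing}")
        if self.dosages.size and (self.dosages.min() < -1e-9 or self.dosages.max() > 2 + 1e-9):
            raise ValueError("dosages must lie within [0, 2]")
        for chrom, grp in self.snp_meta.groupby("chr", sort=False):
            pos = grp["pos"].to_numpy()
            if np.any(np.diff(pos) <= 0):
                raise ValueError(f"positions must be strictly increasing on chromosome {chrom}")
        if self.iids is None:
            self.iids = np.array([f"ind{i + 1}" for i in range(self.dosages.shape[0])])
        self.sex = np.asarray(self.sex)
        if self.sex.shape[0] != self.dosages.shape[0]:
            raise ValueError("sex must have one entry per individual")

    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    @property
    def snp_ids(self) -> np.ndarray:
        return self.snp_meta["snp"].to_numpy()

    def column_index(self, snp_ids) -> np.ndarray:
        """Column positions of ``snp_ids``, in the order given."""
        lookup = pd.Series(np.arange(self.n_snps), index=self.snp_meta["snp"])
        missing = [s for s in snp_ids if s not in lookup.index]
        if missing:
            raise KeyError(f"SNPs absent from panel: {missing}")
        return lookup.loc[list(snp_ids)].to_numpy()

    def dosage_of(self, snp_ids) -> np.ndarray:
        return self.dosages[:, self.column_index(snp_ids)]

    def observed_maf(self) -> np.ndarray:
        """Observed minor-allele frequency per SNP (allele-count based)."""
        p = self.dosages.mean(axis=0) / 2.0
        return np.minimum(p, 1.0 - p)


@dataclass
class TruthRecord:
    """Ground truth written by the trait simulator, for recovery tests."""

    causal_effects: pd.DataFrame  # columns: snp, locus, beta (liability scale)
    locus_snps: dict[int, list[str]]  # locus id -> member SNP ids (window)
    locus_causal: dict[int, list[str]]  # locus id -> causal SNP ids
    h2_autosomal: float = 0.0
    h2_x: float = 0.0
    liability_threshold: float = 0.0
    pathway_slopes: dict[str, dict[str, float]] = field(default_factory=dict)
    genetic_values: dict[str, np.ndarray] = field(default_factory=dict)
    locus_genetic_values: dict[int, np.ndarray] = field(default_factory=dict)

    def validate_against(self, panel: GenotypePanel) -> None:
        known = set(panel.snp_ids)
        bad = set(self.causal_effects["snp"]) - known
        if bad:
            raise ValueError(f"causal SNPs absent from panel: {sorted(bad)}")
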