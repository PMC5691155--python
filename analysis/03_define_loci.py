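"""Partition replicated SNPs into loci and select conditionally distinct SNPs.

Reads the summary statistics written by 02_association_scan.py (or rebuilds
them), applies the replication filter (p < 0.05, concordant direction), the
>500 kb gap rule, stepwise conditional selection within each locus, and the
at-least-one-distinct-SNP pruning.

Outputs: results/locus_table.tsv (Table-1-style), results/loci.bed,
results/distinct_snps.tsv.
"""

import pandas as pd

import pathpgs as pg
from pathpgs import io as pio
from pathpgs.loci import locus_table, write_bed

from common import COVARIATES, RESULTS, build_cohort, ensure_dirs

ensure_dirs()
panel, pheno, truth = build_cohort()
cov = pheno[COVARIATES]
y = pheno["mpb"].to_numpy()

disc_path = RESULTS / "discovery_sumstats.tsv"
rep_path = RESULTS / "replication_meta.tsv"
if disc_path.exists() and rep_path.exists():
    scan = pio.read_sumstats(disc_path)
    rep = pio.read_sumstats(rep_path)
else:
    scan = pg.two_step_scan(panel, y, cov, mac_min=100)
    rep = scan  # degenerate fallback when 02 has not been run

gws = scan[scan["P"] < 5e-8]
replicated, fraction, missing = pg.replicate_filter(gws, rep, p_rep=0.05)
print(f"replication: {len(replicated)}/{len(gws)} SNPs "
      f"({100 * (fraction or 0):.1f}%), {len(missing)} failed")

loci = pg.define_loci(scan[scan["SNP"].isin(replicated["SNP"])], p_select=1e-5)
for locus in loci:
    locus.distinct_snps = pg.select_distinct_snps(panel, y, cov, locus)
loci = pg.prune_loci(loci)
print(f"{len(loci)} loci (truth: {len(truth.locus_causal)}), "
      f"{sum(l.n_distinct for l in loci)} distinct SNPs "
      f"(truth: {len(truth.causal_effects)})")

locus_table(loci).to_csv(RESULTS / "locus_table.tsv", sep="\t", index=False)
write_bed(loci, RESULTS / "loci.bed")
pd.DataFrame(
    [(l.id, s) for l in loci for s in l.distinct_snps], columns=["locus", "snp"]
).to_csv(RESULTS / "distinct_snps.tsv", sep="\t", index=False)
print("wrote", RESULTS / "locus_table.tsv")
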