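"""Simulate the synthetic study cohort and write its fixtures.

Outputs: results/cohort_summary.tsv (trait and truth summaries), the pathway
GMT under results/, and the full genotype VCF + phenotype table under
scratch/ (regenerable, so kept out of the tracked results).
"""

import json

import pathpgs as pg
from pathpgs import io as pio

from common import CONFIG, RESULTS, SCRATCH, build_cohort, ensure_dirs

ensure_dirs()
panel, pheno, truth = build_cohort()

print(f"cohort: {panel.n_individuals} men, {panel.n_snps} SNPs "
      f"({(panel.snp_meta['chr'] == 'X').sum()} on X)")
print(f"case fraction {pheno['mpb'].mean():.3f} (target {CONFIG.prevalence})")
g = truth.genetic_values["mpb"]
print(f"realised liability h2 {g.var() / pheno['liability'].var():.3f} "
      f"(target {CONFIG.h2_autosomal + CONFIG.h2_x})")

pg.emit_fixtures(
    panel, pheno,
    {f"locus{lid}": snps for lid, snps in truth.locus_causal.items()},
    SCRATCH / "cohort",
)
pio.write_gmt({pw.name: [f"locus{l}" for l in pw.loci] for pw in CONFIG.pathways},
              RESULTS / "pathways.gmt")

summary = {
    "n_individuals": panel.n_individuals,
    "n_snps": panel.n_snps,
    "case_fraction": round(float(pheno["mpb"].mean()), 4),
    "n_loci": len(truth.locus_causal),
    "n_causal_snps": int(len(truth.causal_effects)),
    "distinct_per_locus": {k: len(v) for k, v in truth.locus_causal.items()},
}
(RESULTS / "cohort_summary.json").write_text(json.dumps(summary, indent=2) + "\n")
print("wrote", RESULTS / "cohort_summary.json")
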