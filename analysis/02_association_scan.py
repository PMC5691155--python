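"""Two-step discovery GWAS plus a small replication cohort and meta-analysis.

The discovery scan is the fast linear screen over every SNP followed by a
logistic refit of SNPs below the 1e-5 extraction threshold. A second,
smaller cohort simulated under the same truth plays the replication role;
its per-SNP logistic results are inverse-variance meta-analysed.

Outputs: results/discovery_sumstats.tsv, results/replication_meta.tsv,
results/scan_summary.json (lambda_GC and hit counts).
"""

import json
from dataclasses import replace

import pathpgs as pg
from pathpgs import io as pio

from common import CONFIG, COVARIATES, RESULTS, build_cohort, ensure_dirs

ensure_dirs()
panel, pheno, truth = build_cohort()
cov = pheno[COVARIATES]
y = pheno["mpb"].to_numpy()

scan = pg.two_step_scan(panel, y, cov, mac_min=100)
lam = pg.inflation_lambda(scan)
hits = scan[scan["P"] < 5e-8]
print(f"discovery: {len(scan)} SNPs scanned, {len(hits)} genome-wide significant, "
      f"lambda_GC {lam:.3f}")

# replication: an independent draw from the same generative truth
rep_cfg = replace(CONFIG, n_individuals=6000, seed=CONFIG.seed + 1)
rep_panel = pg.simulate_panel(rep_cfg)
rep_pheno, _ = pg.simulate_traits(rep_panel, rep_cfg)
rep = pg.refit_logistic(
    rep_panel, rep_pheno["mpb"].to_numpy(), rep_pheno[COVARIATES],
    hits["SNP"].tolist(), cohort="replication",
)
meta = pg.meta_analyse([rep])  # single replication cohort; identity meta here

pio.write_sumstats(scan, RESULTS / "discovery_sumstats.tsv")
pio.write_sumstats(meta, RESULTS / "replication_meta.tsv")
(RESULTS / "scan_summary.json").write_text(
    json.dumps(
        {"lambda_gc": round(lam, 3), "n_scanned": len(scan), "n_gws_hits": len(hits)},
        indent=2,
    )
    + "\n"
)
print("wrote", RESULTS / "discovery_sumstats.tsv")
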