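"""Packaged reference tables from the male-pattern-baldness GWAS.

Two small TSV fixtures ship with the package: the 71-locus summary table
(chromosome, interval, replication status, distinct/significant SNP counts)
and the 28-row pathway composition table mapping each enriched pathway to
its member loci and distinct SNPs. They serve as worked-example inputs for
the locus and score machinery; the study's three explicitly merged pathway
pairs are exposed alongside.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

#: the pathway pairs whose scores were merged because their locus sets are
#: identical (the study's explicit merges)
EXPLICIT_PATHWAY_MERGES: list[list[str]] = [
    ["Apoptosis", "Apoptotic signalling pathway"],
    ["Wnt signalling pathway", "Wnt signalling pathway and pluripotency"],
    ["WNT ligand biogenesis and trafficking", "Wnt signalling in kidney disease"],
]


def _read(name: str) -> pd.DataFrame:
    with resources.files("pathpgs.data").joinpath(name).open() as fh:
        return pd.read_csv(fh, sep="\t", dtype={"chr": str, "top_p": str})


def load_locus_table() -> pd.DataFrame:
    """The 71-locus summary: locus, chr, start, end, replicated (Y = known,
    N = novel), n_distinct_snps, n_significant_snps, genes, top_p."""
    return _read("mpb_loci.tsv")


def load_pathway_table() -> pd.DataFrame:
    """Pathway composition: pathway, ';'-separated member loci, number of
    distinct SNPs contributed, and the ';'-separated SNP list."""
    return _read("mpb_pathways.tsv")


def pathway_loci_mapping(table: pd.DataFrame | None = None) -> dict[str, tuple[int, ...]]:
    table = load_pathway_table() if table is None else table
    return {
        str(r["pathway"]): tuple(int(x) for x in str(r["loci"]).split(";"))
        for _, r in table.iterrows()
    }


def pathway_snp_mapping(table: pd.DataFrame | None = None) -> dict[str, list[str]]:
    table = load_pathway_table() if table is None else table
    return {str(r["pathway"]): str(r["snps"]).split(";") for _, r in table.iterrows()}
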