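"""Gene co-membership graph and Louvain pathway communities.

Uses the packaged pathway table: each pathway's member loci are mapped to
the locus table's selected genes, the co-membership graph counts how many
pathways each gene pair shares, and Louvain partitions the genes into
communities (the wnt / apoptosis / TGF-beta-like groupings emerge from the
shared locus structure).

Outputs: results/gene_communities.tsv, results/comembership_edges.tsv.
"""

import pathpgs as pg
from pathpgs import tables
from pathpgs.communities import partition_table, write_edgelist

from common import RESULTS, ensure_dirs

ensure_dirs()
loci = tables.load_locus_table().set_index("locus")
membership = {}
for name, locus_ids in tables.pathway_loci_mapping().items():
    genes = []
    for l in locus_ids:
        cell = str(loci.loc[l, "genes"]).replace("(trans-eQTL)", "")
        genes.extend(g for g in cell.split("-") if g and g != ".")
    if genes:
        membership[name] = genes

graph = pg.build_comembership(membership)
parts, q = pg.detect_communities(graph, seed=0)
print(f"{graph.number_of_nodes()} genes, {graph.number_of_edges()} edges, "
      f"{len(parts)} communities, modularity Q = {q:.3f}")
for k, comm in enumerate(sorted(parts, key=len, reverse=True)[:3], start=1):
    print(f"community {k} ({len(comm)} genes): {', '.join(sorted(comm)[:8])} ...")

partition_table(parts).to_csv(RESULTS / "gene_communities.tsv", sep="\t", index=False)
write_edgelist(graph, RESULTS / "comembership_edges.tsv")
print("wrote", RESULTS / "gene_communities.tsv")
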