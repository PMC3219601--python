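"""Three-way cistrome partition and the TSS radar enrichment statistic.

A synthetic design plants responsive genes preferentially near PBX1-unique
and PBX1&ERa shared sites; the radar table recovers ratios near 2 for those
classes and near 1 elsewhere.
"""

from pioneerscan import venn_partition, radar_table
from pioneerscan.synthetic import SyntheticDesign, gen_cistromes, gen_genes

design = SyntheticDesign(seed=5, n_genes=3_000, n_responsive=300)
truth = gen_cistromes(design)
gene_truth = gen_genes(design, truth.class_sites)

partition = venn_partition(
    truth.cistromes["ERa"], truth.cistromes["FoxA1"], truth.cistromes["PBX1"]
)
print(partition.summary("ERa").to_string(index=False))

table = radar_table(
    partition,
    {"dependent": gene_truth.dependent},
    gene_truth.null,
    gene_truth.genes,
    window=20_000,
)
cols = ["class_label", "n_resp_with", "n_null_with", "ratio", "p_value"]
print(table[cols].to_string(index=False))
# Ratios >> 1 with small Fisher p mark site classes whose +-20 kb TSS
# neighbourhoods are over-represented among the dependent genes.
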