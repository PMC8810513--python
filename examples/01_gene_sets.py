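"""Gene-set algebra: merge literature and database lists, intersect diseases.

Builds two tiny disease gene lists the way DisGeNET-plus-literature lists
are assembled (scored database genes filtered at GDA > 0.2, unscored
literature genes passing), then prints the union/intersection counts.
"""

from comorbnet import (
    GeneRecord,
    GeneSet,
    apply_gda_policy,
    intersect_gene_sets,
    merge_gene_sets,
)

literature = GeneSet("alzheimers", [
    GeneRecord(348, "APOE", frozenset({"literature"})),
    GeneRecord(627, "BDNF", frozenset({"literature"})),
    GeneRecord(3552, "IL1A", frozenset({"literature"})),
])
database = GeneSet("alzheimers", [
    GeneRecord(348, "APOE", frozenset({"disgenet"}), gda_score=0.9),
    GeneRecord(7124, "TNF", frozenset({"disgenet"}), gda_score=0.45),
    GeneRecord(1029, "CDKN2A", frozenset({"disgenet"}), gda_score=0.15),  # below 0.2
])

ad = apply_gda_policy(merge_gene_sets(literature, database, "alzheimers"), 0.2)
mdd = GeneSet("depression", [
    GeneRecord(627, "BDNF", frozenset({"literature"})),
    GeneRecord(7124, "TNF", frozenset({"disgenet"}), gda_score=0.3),
    GeneRecord(6532, "SLC6A4", frozenset({"literature"})),
])
shared = intersect_gene_sets(ad, mdd, "shared")

print(f"disease A genes after GDA > 0.2: {len(ad)}")        # 4 (CDKN2A dropped)
print(f"disease B genes:                 {len(mdd)}")        # 3
print(f"shared genes:                    {len(shared)}")     # 2 (BDNF, TNF)
print("shared records:", [(r.gene_id, r.symbol, sorted(r.sources)) for r in shared])
# The shared genes are the comorbidity candidates every later stage builds on.
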