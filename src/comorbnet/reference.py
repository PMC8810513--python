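"""Counts reported by the original AD–MDD comorbidity analysis.

These numbers come from the published study this package re-implements
as a reusable pipeline.  They are recorded for orientation and for
arithmetic sanity checks only: the gene-list, GO, and KEGG counts depend
on the 2021 database snapshots and on web-tool settings (background
universe, pathway-size filters) that were never published, so they are
NOT reproducible from first principles and are never used as test
expectations for computed results.
"""

from __future__ import annotations

#: Whether each group of counts can be recomputed without the original
#: (unpublished / snapshot-dependent) inputs.
REPRODUCIBLE = False

# Gene-set assembly (literature + DisGeNET at GDA score > 0.2)
GENES = {
    "ad_literature": 587,
    "ad_disgenet": 146,
    "ad_total": 650,
    "mdd_disgenet": 266,
    "mdd_literature": 255,
    "mdd_total": 447,
    "shared": 77,
}

# Enrichment (2021 GO / KEGG snapshots via web tools; snapshot-dependent)
ENRICHMENT = {
    "go_bp_terms_shared_genes": 311,
    "kegg_ad_significant": 153,
    "kegg_mdd_significant": 146,
    "kegg_shared": 102,
    "kegg_ad_specific": 51,
    "kegg_mdd_specific": 44,
}

# Pathway cross-talk networks (shared-pathway and disease-specific)
CROSSTALK = {
    "shared_net_pathways": 101,  # 102 minus one set too small to score
    "shared_net_genes": 56,
    "shared_net_nodes": 157,
    "shared_net_edges": 2767,
    "shared_net_pp_edges": 2380,
    "shared_net_pg_edges": 387,
    "specific_net_pathways_ad": 32,
    "specific_net_pathways_mdd": 36,
    "specific_net_genes_ad": 186,
    "specific_net_genes_mdd": 117,
    "specific_net_genes_shared": 39,
    "specific_net_nodes": 410,
    "specific_net_edges": 1371,
    "specific_net_pp_edges": 386,
    "specific_net_pg_edges": 985,
}

# Interactome stages (merged PPIN; snapshot-dependent source databases)
PPIN = {
    "interactome_nodes": 15435,
    "interactome_edges": 218161,
    "ad_net_nodes": 9089,
    "ad_net_edges": 32065,
    "mdd_net_nodes": 6541,
    "mdd_net_edges": 18221,
    "union_net_nodes": 10203,
    "union_net_edges": 45385,
    "overlap_net_nodes": 3001,
    "overlap_net_edges": 4900,
    "overlap_first_neighbors": 2629,
    "novel_candidates_min6": 37,
    "novel_candidates_min9": 7,
    "top_candidate_degree": 12,  # ELAVL1
}

#: The reported overlap edge count (4,900) differs by one from the
#: inclusion–exclusion identity |A| + |B| - |A∪B| = 32,065 + 18,221 -
#: 45,385 = 4,901; the discrepancy is in the source numbers themselves
#: and is surfaced, never absorbed.
OVERLAP_EDGE_DISCREPANCY = (
    PPIN["ad_net_edges"] + PPIN["mdd_net_edges"] - PPIN["union_net_edges"]
) - PPIN["overlap_net_edges"]
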