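"""Classify genes across two laminae into convergent / unique / divergent
categories and apply the uDEG appending rule.

A gene significant (raw p < 0.05) in both laminae is convergent when the
log2 fold changes agree in sign and divergent when they oppose; a gene
significant in only one lamina is unique to it.  Each lamina's uDEG set is
its unique genes plus all divergent genes.
"""

import pandas as pd

from laminadiv import DEGTable, category_counts, classify_genes, udeg_set

table_a = DEGTable(
    "L3",
    pd.DataFrame(
        {
            "gene_id": ["APP", "DYRK1A", "GRIN2B", "DLG4", "ITGB1", "SOD1"],
            "lfc": [1.2, -0.8, 1.0, 0.5, 0.3, -0.1],
            "p_value": [0.001, 0.02, 0.02, 0.01, 0.40, 0.90],
        }
    ),
)
table_b = DEGTable(
    "L5",
    pd.DataFrame(
        {
            "gene_id": ["APP", "DYRK1A", "GRIN2B", "DLG4", "ITGB1", "SOD1"],
            "lfc": [0.9, -1.1, -0.5, 0.4, -0.6, 0.2],
            "p_value": [0.03, 0.005, 0.03, 0.60, 0.002, 0.75],
        }
    ),
)

classified = classify_genes(table_a, table_b, alpha=0.05)
print(classified[["gene_id", "category", "sig_tier_a", "sig_tier_b"]].to_string(index=False))
print()
print("category counts:", {k: v for k, v in category_counts(classified).items() if v})
udeg_a = udeg_set(classified, "a")
udeg_b = udeg_set(classified, "b")
print(f"uDEG sets: L3={sorted(udeg_a)}  L5={sorted(udeg_b)}")
print("Note GRIN2B is divergent (up in L3, down in L5) so it belongs to BOTH uDEG sets;")
print("|uDEG| = |unique| + |divergent| for each lamina.")
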