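"""Five-cohort comparison: flag matrix, layer-specific labels and ontology
ancestors.

A term is "layer specific" for lamina A when it is significant for A's
uDEGs and A's full DEG list while the other lamina's full list is silent or
significant in the opposite direction; terms significant in both full lists
with the same direction are genotype-shared.  Ancestors in the term DAG
carry their own labels — nothing is propagated.
"""

import networkx as nx
import pandas as pd

from laminadiv.laminaspec import (
    COHORTS,
    build_flag_matrix,
    label_ancestors,
    label_terms,
)


def frame(cohort, rows):
    return pd.DataFrame(
        [{"set_id": s, "p_value": p, "adj_p": p, "activation_z": z} for s, p, z in rows]
    )


# three terms: one A-layer-specific, one genotype-shared, one A-unique-only
results = {
    "a_unique": frame("a_unique", [("SYNAPSE", 0.001, 2.0), ("RIBOSOME", 0.3, 0.0), ("AUTOPHAGY", 0.01, -1.5)]),
    "b_unique": frame("b_unique", [("SYNAPSE", 0.8, 0.0)]),
    "a_all": frame("a_all", [("SYNAPSE", 0.004, 1.5), ("RIBOSOME", 0.02, 1.0)]),
    "b_all": frame("b_all", [("RIBOSOME", 0.01, 0.9)]),
    "convergent": frame("convergent", [("RIBOSOME", 0.03, 1.0)]),
}

matrix = build_flag_matrix(results, alpha=0.05)
print("flag matrix (term x cohort):")
print(matrix.to_string())

labels = label_terms(matrix)
print("\nlabels:")
print(labels.to_string(index=False))

graph = nx.DiGraph([("SYNAPSE", "SIGNALING"), ("SIGNALING", "PROCESS"), ("AUTOPHAGY", "PROCESS")])
ancestors = label_ancestors(labels, graph, ["SYNAPSE"])
print("\nancestors of SYNAPSE with their own labels:")
print(ancestors.to_string(index=False))
print("\nSYNAPSE is a_layer_specific: significant in a_unique and a_all while b_all is")
print("silent; RIBOSOME is genotype_shared (both full lists significant, same direction).")
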