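import math

import numpy as np
import pandas as pd
import pytest

from laminadiv.io import DEGTable


def make_table(label, rows):
    """rows: list of (gene_id, lfc, p_value)."""
    return DEGTable(
        lamina_label=label,
        data=pd.DataFrame(rows, columns=["gene_id", "lfc", "p_value"]),
    )


def classify_one_oracle(p_a, lfc_a, p_b, lfc_b, alpha=0.05):
    """Independent per-gene re-application of the classification rules."""
    sig_a = p_a is not None and not math.isnan(p_a) and p_a < alpha
    sig_b = p_b is not None and not math.isnan(p_b) and p_b < alpha
    if sig_a and sig_b:
        sa = 0 if lfc_a == 0 else (1 if lfc_a > 0 else -1)
        sb = 0 if lfc_b == 0 else (1 if lfc_b > 0 else -1)
        if sa * sb < 0:
            return "divergent"
        if sa + sb > 0:
            return "convergent_up"
        if sa + sb < 0:
            return "convergent_down"
        return "convergent_flat"
    if sig_a:
        return "unique_a"
    if sig_b:
        return "unique_b"
    return "not_significant"


def random_paired_tables(rng, n_genes=50, p_shared=0.8):
    """Random paired tables where some genes appear in only one lamina."""
    genes = [f"G{i:03d}" for i in range(n_genes)]
    rows_a, rows_b = [], []
    for g in genes:
        in_a = rng.random() < p_shared or rng.random() < 0.5
        in_b = rng.random() < p_shared or not in_a
        lfc_a, lfc_b = rng.normal(0, 1, 2)
        p_a, p_b = rng.uniform(1e-6, 1, 2)
        if in_a:
            rows_a.append((g, lfc_a, p_a))
        if in_b:
            rows_b.append((g, lfc_b, p_b))
    return make_table("A", rows_a), make_table("B", rows_b)


@pytest.fixture
def toy_tables():
    """Six genes spanning every category between the two laminae."""
    table_a = make_table(
        "A",
        [
            ("CONVUP", 1.2, 0.001),
            ("CONVDN", -0.8, 0.02),
            ("DIVG", 1.0, 0.02),
            ("UNIQA", 0.5, 0.01),
            ("UNIQB", 0.3, 0.40),
            ("NS", -0.1, 0.90),
        ],
    )
    table_b = make_table(
        "B",
        [
            ("CONVUP", 0.9, 0.03),
            ("CONVDN", -1.1, 0.005),
            ("DIVG", -0.5, 0.03),
            ("UNIQA", 0.4, 0.60),
            ("UNIQB", -0.6, 0.002),
            ("NS", 0.2, 0.75),
        ],
    )
    return table_a, table_b


@pytest.fixture
def rng():
    return np.random.default_rng(20240)
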