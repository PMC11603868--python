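"""Open over-representation analysis with a directional activation score.

Each gene set is tested against a query (e.g. one cohort's uDEGs) within a
background universe using the upper-tail hypergeometric probability
P(X >= k), with Benjamini-Hochberg adjustment across all tested sets.  The
background universe should be the genes actually tested for differential
expression (the lamina's DEG table), not the genome.

Directionality is summarized per set by a signed-proportion z statistic

    z = (n_up - n_down) / sqrt(n_up + n_down)

over the overlapping genes with a known direction of change.  This is an
open approximation to commercial activation scores: positive z means the
set's overlapping genes are predominantly upregulated, negative
predominantly downregulated, zero (or no directed genes) mixed/undetermined.
No numeric equivalence with any proprietary score is claimed.
"""

from __future__ import annotations

import math
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .errors import ParameterError, ValidationError
from .io import GeneSetCollection

#: Columns of the enrichment frame produced by :func:`enrich_sets`.
ENRICHMENT_COLUMNS = (
    "set_id",
    "name",
    "cohort",
    "k",
    "n",
    "K",
    "N",
    "p_value",
    "adj_p",
    "activation_z",
    "direction",
    "significant",
)


def hypergeom_pvalue(k: int, n: int, K: int, N: int) -> float:
    """Upper-tail hypergeometric probability P(X >= k).

    ``k`` overlap, ``n`` query size, ``K`` set size in the universe, ``N``
    universe size; requires 0 <= k <= min(n, K) <= N.
    """
    if not (0 <= k <= min(n, K) <= N) or n > N:
        raise ParameterError(
            f"inconsistent counts: k={k}, n={n}, K={K}, N={N}"
        )
    # sf(k-1) = P(X >= k)
    return float(hypergeom.sf(k - 1, N, K, n))


def activation_score(
    overlap_genes: set[str],
    directions: Mapping[str, int],
    *,
    threshold: float = 0.0,
) -> tuple[float, str]:
    """Signed-proportion activation z over the overlapping genes.

    ``directions`` maps gene -> +1/-1 where the direction of change is
    known; overlapping genes absent from it contribute nothing.  Returns
    ``(z, label)`` with label ``up`` (z > threshold), ``down``
    (z < -threshold), ``mixed`` otherwise, or ``(nan, "NA")`` when no
    overlapping gene has a direction.
    """
    n_up = sum(1 for g in overlap_genes if directions.get(g) == 1)
    n_down = sum(1 for g in overlap_genes if directions.get(g) == -1)
    total = n_up + n_down
    if total == 0:
        return math.nan, "NA"
    z = (n_up - n_down) / math.sqrt(total)
    if z > threshold:
        label = "up"
    elif z < -threshold:
        label = "down"
    else:
        label = "mixed"
    return z, label


def enrich_sets(
    query: set[str],
    universe: set[str],
    sets: GeneSetCollection,
    directions: Mapping[str, int] | None = None,
    alpha: float = 0.05,
    *,
    cohort_label: str = "",
    significance: str = "adjusted",
) -> pd.DataFrame:
    """Test every gene set for over-representation in ``query``.

    Sets are restricted to the universe before testing (K counts universe
    members only); sets with no universe member are skipped.  ``adj_p`` is
    Benjamini-Hochberg across all tested sets; the ``significant`` flag uses
    ``adj_p < alpha`` by default or the raw p with ``significance="raw"``.

    Raises :class:`ValidationError` listing offenders if the query is not a
    subset of the universe.
    """
    if significance not in ("adjusted", "raw"):
        raise ParameterError(f"significance must be 'adjusted' or 'raw', got {significance!r}")
    if not 0 < alpha < 1:
        raise ParameterError(f"alpha must be in (0, 1), got {alpha}")
    stray = query - universe
    if stray:
        raise ValidationError(
            f"query contains {len(stray)} gene(s) outside the universe: "
            f"{sorted(stray)[:10]}"
        )
    directions = directions or {}
    N = len(universe)
    n = len(query)
    rows = []
    for gs in sets:
        members = gs.members & universe
        K = len(members)
        if K == 0:
            continue
        overlap = members & query
        k = len(overlap)
        z, direction = activation_score(overlap, directions)
        rows.append(
            {
                "set_id": gs.set_id,
                "name": gs.name,
                "cohort": cohort_label,
                "k": k,
                "n": n,
                "K": K,
                "N": N,
                "p_value": hypergeom_pvalue(k, n, K, N),
                "activation_z": z,
                "direction": direction,
            }
        )
    df = pd.DataFrame(rows, columns=[c for c in ENRICHMENT_COLUMNS if c not in ("adj_p", "significant")])
    if len(df):
        df["adj_p"] = benjamini_hochberg(df["p_value"].to_numpy())
        flag_col = "adj_p" if significance == "adjusted" else "p_value"
        df["significant"] = df[flag_col] < alpha
    else:
        df["adj_p"] = pd.Series(dtype=float)
        df["significant"] = pd.Series(dtype=bool)
    return df[list(ENRICHMENT_COLUMNS)].sort_values("p_value", ignore_index=True)


def benjamini_hochberg(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (FDR)."""
    _, adj, _, _ = multipletests(pvalues, method="fdr_bh")
    return adj
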