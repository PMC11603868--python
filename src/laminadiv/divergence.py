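"""Cross-lamina gene classification and per-lamina summaries.

Given the differential-expression tables of two laminae (here called A and
B; in the motivating study, cortical layer 3 and layer 5 pyramidal
neurons), each gene is placed in exactly one category:

* ``convergent_up`` / ``convergent_down`` — significant in both laminae with
  the same log2-fold-change (LFC) direction;
* ``divergent`` — significant in both with opposite LFC signs;
* ``unique_a`` / ``unique_b`` — significant in only one lamina;
* ``not_significant`` — significant in neither.

The "unique DEG" (uDEG) set of a lamina is its unique genes plus the
divergent genes, which belong to both laminae's uDEG sets.  Significance
uses the raw per-gene p-value at ``alpha`` (default 0.05); a stricter
p < 0.01 tier is recorded alongside.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InsufficientDataError, ParameterError, ValidationError
from .io import DEGTable, GeneAnnotation, BIOTYPES, UNKNOWN_BIOTYPE

logger = logging.getLogger(__name__)

CATEGORIES = (
    "convergent_up",
    "convergent_down",
    "convergent_flat",
    "unique_a",
    "unique_b",
    "divergent",
    "not_significant",
)

TIERS = ("p01", "p05", "ns")

#: Columns of the classified-gene frame produced by :func:`classify_genes`.
CLASSIFIED_COLUMNS = (
    "gene_id",
    "lfc_a",
    "p_a",
    "lfc_b",
    "p_b",
    "category",
    "sig_tier_a",
    "sig_tier_b",
)


def _tier(p: pd.Series) -> pd.Series:
    out = pd.Series("ns", index=p.index, dtype=object)
    out[p < 0.05] = "p05"
    out[p < 0.01] = "p01"
    out[p.isna()] = "ns"
    return out


def classify_genes(
    table_a: DEGTable,
    table_b: DEGTable,
    alpha: float = 0.05,
    *,
    missing_policy: str = "nonsignificant",
) -> pd.DataFrame:
    """Classify every gene appearing in either table.

    Parameters
    ----------
    alpha
        Raw p-value significance threshold, in (0, 1).
    missing_policy
        How to treat genes present in only one table: ``"nonsignificant"``
        (default) treats them as not significant in the absent lamina, so
        they remain eligible for ``unique_*``; ``"exclude"`` drops them.

    Returns
    -------
    DataFrame with :data:`CLASSIFIED_COLUMNS`; ``lfc_x``/``p_x`` are NaN for
    genes absent from that lamina's table.
    """
    if not 0 < alpha < 1:
        raise ParameterError(f"alpha must be in (0, 1), got {alpha}")
    if missing_policy not in ("nonsignificant", "exclude"):
        raise ParameterError(f"unknown missing_policy {missing_policy!r}")

    a = table_a.data.rename(columns={"lfc": "lfc_a", "p_value": "p_a"})
    b = table_b.data.rename(columns={"lfc": "lfc_b", "p_value": "p_b"})
    how = "inner" if missing_policy == "exclude" else "outer"
    df = a.merge(b, on="gene_id", how=how)

    sig_a = (df["p_a"] < alpha).fillna(False).to_numpy()
    sig_b = (df["p_b"] < alpha).fillna(False).to_numpy()
    sign_a = np.sign(df["lfc_a"].fillna(0.0).to_numpy())
    sign_b = np.sign(df["lfc_b"].fillna(0.0).to_numpy())

    both = sig_a & sig_b
    category = np.select(
        [
            both & (sign_a * sign_b < 0),
            both & (sign_a + sign_b > 0),
            both & (sign_a + sign_b < 0),
            both,  # both signs exactly zero: direction "flat"
            sig_a & ~sig_b,
            sig_b & ~sig_a,
        ],
        [
            "divergent",
            "convergent_up",
            "convergent_down",
            "convergent_flat",
            "unique_a",
            "unique_b",
        ],
        default="not_significant",
    )
    n_flat = int((category == "convergent_flat").sum())
    if n_flat:
        logger.warning("%d gene(s) significant in both laminae with LFC exactly 0", n_flat)

    out = pd.DataFrame(
        {
            "gene_id": df["gene_id"],
            "lfc_a": df["lfc_a"],
            "p_a": df["p_a"],
            "lfc_b": df["lfc_b"],
            "p_b": df["p_b"],
            "category": category,
            "sig_tier_a": _tier(df["p_a"]),
            "sig_tier_b": _tier(df["p_b"]),
        }
    ).sort_values("gene_id", ignore_index=True)
    counts = out["category"].value_counts().to_dict()
    logger.info("classified %d genes: %s", len(out), counts)
    return out


def category_counts(classified: pd.DataFrame) -> dict[str, int]:
    """Counts per category over all defined categories (zeros included)."""
    vc = classified["category"].value_counts()
    return {c: int(vc.get(c, 0)) for c in CATEGORIES}


def udeg_set(classified: pd.DataFrame, lamina: str) -> set[str]:
    """The uDEG set of one lamina: its unique genes plus all divergent genes.

    Divergent genes are significant in both laminae with opposite direction
    and are appended to both laminae's uDEG sets, so
    ``|uDEG_x| = |unique_x| + |divergent|``.
    """
    if lamina not in ("a", "b"):
        raise ParameterError(f"lamina must be 'a' or 'b', got {lamina!r}")
    mask = classified["category"].isin([f"unique_{lamina}", "divergent"])
    return set(classified.loc[mask, "gene_id"])


def significant_set(classified: pd.DataFrame, lamina: str, alpha: float = 0.05) -> set[str]:
    """All genes significant in one lamina (the lamina's full DEG list)."""
    if lamina not in ("a", "b"):
        raise ParameterError(f"lamina must be 'a' or 'b', got {lamina!r}")
    mask = classified[f"p_{lamina}"] < alpha
    return set(classified.loc[mask.fillna(False), "gene_id"])


def bin_by_lfc(
    classified: pd.DataFrame, lamina: str, width: float = 0.25
) -> pd.DataFrame:
    """Histogram one lamina's uDEGs by LFC in fixed-width bins.

    Bins are half-open and closed on the boundary nearer zero:
    ``[k*width, (k+1)*width)`` for LFC >= 0 and ``[-(k+1)*width, -k*width)``
    for LFC < 0, giving a deterministic, mirror-symmetric histogram.

    Returns a DataFrame with columns ``bin_low``, ``bin_high``,
    ``direction`` (``up`` for LFC >= 0, ``down`` otherwise) and ``count``,
    sorted by ``bin_low``.
    """
    if width <= 0:
        raise ParameterError(f"bin width must be > 0, got {width}")
    genes = udeg_set(classified, lamina)
    sub = classified[classified["gene_id"].isin(genes)]
    lfc = sub[f"lfc_{lamina}"].dropna().to_numpy()
    k = np.floor(np.abs(lfc) / width).astype(int)
    low = np.where(lfc >= 0, k * width, -(k + 1) * width)
    rows = pd.DataFrame(
        {
            "bin_low": low,
            "bin_high": low + width,
            "direction": np.where(lfc >= 0, "up", "down"),
        }
    )
    out = (
        rows.groupby(["bin_low", "bin_high", "direction"])
        .size()
        .reset_index(name="count")
        .sort_values(["bin_low", "direction"], ignore_index=True)
    )
    return out


def lfc_correlation(
    table_a: DEGTable,
    table_b: DEGTable,
    gene_subset: set[str] | None = None,
) -> float:
    """Pearson correlation of paired LFCs over shared genes.

    ``gene_subset`` restricts the comparison (e.g. to both laminae's full
    DEG lists); ``None`` uses every gene present in both tables.  Requires
    at least three shared genes.
    """
    a = table_a.data.set_index("gene_id")["lfc"]
    b = table_b.data.set_index("gene_id")["lfc"]
    shared = a.index.intersection(b.index)
    if gene_subset is not None:
        shared = shared.intersection(pd.Index(gene_subset))
    if len(shared) < 3:
        raise InsufficientDataError(
            f"need >= 3 shared genes for a correlation, got {len(shared)}"
        )
    r, _ = stats.pearsonr(a.loc[shared], b.loc[shared])
    return float(r)


@dataclass
class SubsetTally:
    """Biotype composition of a gene subset (e.g. one chromosome's uDEGs).

    ``fractions`` is ``None`` when the subset is empty (fractions undefined).
    """

    label: str
    n_total: int
    counts: dict[str, int]
    fractions: dict[str, float] | None

    def __post_init__(self) -> None:
        if sum(self.counts.values()) != self.n_total:
            raise ValidationError("biotype counts do not sum to n_total")
        if self.fractions is not None:
            total = sum(self.fractions.values())
            if not math.isclose(total, 1.0, abs_tol=1e-12):
                raise ValidationError(f"fractions sum to {total}, not 1")


def subset_tally(
    genes: set[str],
    annotation: GeneAnnotation,
    chromosome: str | None = None,
) -> SubsetTally:
    """Restrict ``genes`` to one chromosome and tally biotypes.

    With ``chromosome=None`` no restriction is applied and genes missing
    from the annotation are counted under the ``unknown`` biotype.  With a
    chromosome given, only genes annotated to it are kept (a gene of
    unknown location cannot be placed on a chromosome).
    """
    if chromosome is None:
        subset = set(genes)
        label = "all"
    else:
        subset = {g for g in genes if annotation.chromosome(g) == chromosome}
        label = f"chromosome {chromosome}"
    counts = {bt: 0 for bt in (*BIOTYPES, UNKNOWN_BIOTYPE)}
    for g in subset:
        counts[annotation.biotype(g)] += 1
    n = len(subset)
    fractions = {bt: c / n for bt, c in counts.items()} if n else None
    return SubsetTally(label=label, n_total=n, counts=counts, fractions=fractions)
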